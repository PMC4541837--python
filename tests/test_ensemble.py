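import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migrainecast.ensemble import (
    EnsembleModel,
    RankEntry,
    build_average_model,
    cross_validate,
    ensemble_size,
    horizon_from_fit_curve,
    linear_decider,
    rank_entries,
    repair_prediction,
)
from migrainecast.ssm import compute_fit, fit_n4sid
from tests.conftest import toy_bump_dataset


def bump(n, lo, hi, height=1.0):
    """Triangular excursion on an all-zero trace (zero-crossings at lo/hi)."""
    x = np.zeros(n)
    mid = (lo + hi) // 2
    x[lo:mid] = np.linspace(0, height, mid - lo, endpoint=False)
    x[mid:hi] = np.linspace(height, 0, hi - mid, endpoint=False)
    return x


class TestLinearDecider:
    def test_threshold_point(self):
        tr = linear_decider(np.array([0.5]))
        assert tr.probability[0] == 50.0

    def test_saturation(self):
        tr = linear_decider(np.array([1.0, 1.4]))
        np.testing.assert_array_equal(tr.probability, [100.0, 100.0])

    def test_negative_oscillation_clamps_to_zero(self):
        tr = linear_decider(np.array([-0.3]))
        assert tr.probability[0] == 0.0

    def test_detection_opens_at_threshold(self):
        pred = bump(200, 50, 150)
        tr = linear_decider(pred)
        assert len(tr.detections) == 1
        a, b = tr.detections[0]
        assert a <= 60 and b >= 140


class TestRepairPrediction:
    def test_all_zero_unchanged(self):
        tr = linear_decider(np.zeros(500))
        out = repair_prediction(tr)
        np.testing.assert_array_equal(out.predicted, 0.0)
        assert out.detections == []

    def test_long_event_kept_with_marks(self):
        pred = bump(400, 100, 220)  # 120-min excursion, >60 supra-threshold
        tr = linear_decider(pred)
        out = repair_prediction(tr)
        assert len(out.detections) == 1
        a, b = out.detections[0]
        assert a == pytest.approx(100, abs=2)
        assert b == pytest.approx(220, abs=2)
        np.testing.assert_array_equal(out.predicted, tr.predicted)

    def test_short_blips_removed_long_event_kept(self):
        n = 2000
        pred = bump(n, 100, 130) + bump(n, 300, 330) + bump(n, 600, 625)
        pred += bump(n, 1000, 1180)  # the real event: 180 min wide
        tr = linear_decider(pred)
        out = repair_prediction(tr)
        assert len(out.detections) == 1
        assert np.all(out.predicted[:700] == 0.0)
        np.testing.assert_array_equal(out.predicted[1000:1180], tr.predicted[1000:1180])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        n = 1500
        pred = sum(
            bump(n, int(lo), int(lo) + int(w))
            for lo, w in zip(rng.uniform(0, n - 200, 6), rng.uniform(20, 150, 6))
        )
        out1 = repair_prediction(linear_decider(pred))
        out2 = repair_prediction(out1)
        np.testing.assert_array_equal(out1.predicted, out2.predicted)
        assert out1.detections == out2.detections

    def test_repair_never_decreases_fit_on_spurious_blips(self):
        # true event + spurious blips outside it: removal can only help
        n = 2000
        true_curve = bump(n, 1000, 1200)
        pred = true_curve + bump(n, 100, 130) + bump(n, 400, 440)
        tr = linear_decider(pred)
        before = compute_fit(true_curve, tr.predicted)
        out = repair_prediction(tr)
        after = compute_fit(true_curve, out.predicted)
        assert after >= before

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_matches_brute_force_oracle(self, seed):
        # oracle: zero every maximal supra-threshold run spanning < 60 min
        rng = np.random.default_rng(seed)
        n = 3000
        pred = np.zeros(n)
        pos = 100
        while pos < n - 250:
            width = int(rng.integers(10, 200))
            pred += bump(n, pos, pos + width, height=float(rng.uniform(0.6, 1.2)))
            pos += width + int(rng.integers(80, 400))
        tr = linear_decider(pred)
        expected = tr.predicted.copy()
        above = expected >= 0.5
        runs, in_run, lo = [], False, 0
        for i, flag in enumerate(above):
            if flag and not in_run:
                lo, in_run = i, True
            elif not flag and in_run:
                runs.append((lo, i))
                in_run = False
        if in_run:
            runs.append((lo, n))
        for lo, hi in runs:
            if hi - lo < 60:
                a, b = lo, hi
                while a > 0 and expected[a - 1] > 0:
                    a -= 1
                while b < n and expected[b] > 0:
                    b += 1
                expected[a:b] = 0.0
        out = repair_prediction(tr)
        np.testing.assert_array_equal(out.predicted, expected)


class TestHorizonFromFitCurve:
    def test_monotone_curve(self):
        ks = np.arange(1, 101)
        fits = 100.0 - ks  # crosses 70 at k=30
        assert horizon_from_fit_curve(ks, fits) == 30

    def test_never_reaches_threshold(self):
        ks = np.arange(1, 20)
        assert horizon_from_fit_curve(ks, np.full(19, 50.0)) == 0

    def test_oscillation_needs_sustained_drop(self):
        ks = np.arange(1, 11)
        fits = np.array([90, 65, 90, 65, 90, 65, 60, 60, 60, 60], dtype=float)
        # isolated dips ignored; sustained drop starts at k=6
        assert horizon_from_fit_curve(ks, fits) == 5

    def test_never_drops(self):
        ks = np.arange(1, 6)
        assert horizon_from_fit_curve(ks, np.full(5, 80.0)) == 5


class TestRanking:
    def entries(self):
        # reference scenario: avg 22 first, tie at 20 broken by min
        return [
            RankEntry(model_id=2, fh_min=17, fh_average=20, fh_max=22, fh_sigma=2),
            RankEntry(model_id=6, fh_min=18, fh_average=22, fh_max=25, fh_sigma=2),
            RankEntry(model_id=13, fh_min=19, fh_average=20, fh_max=21, fh_sigma=1),
            RankEntry(model_id=8, fh_min=17, fh_average=20, fh_max=24, fh_sigma=3),
        ]

    def test_average_horizon_leads(self):
        ranking = rank_entries(self.entries())
        assert ranking.order()[0] == 6

    def test_tie_broken_by_min_then_max(self):
        ranking = rank_entries(self.entries())
        # avg 20 tie: min 19 beats min 17; min 17 tie: max 24 beats 22
        assert ranking.order() == [6, 13, 8, 2]

    def test_invariant_min_le_avg_le_max(self):
        for e in self.entries():
            assert e.fh_min <= e.fh_average <= e.fh_max


class TestEnsembleSize:
    @pytest.mark.parametrize("m,size", [(15, 5), (8, 3), (9, 3), (2, 1), (1, 1), (3, 1)])
    def test_one_third_rule(self, m, size):
        assert ensemble_size(m) == size


def _toy_models_and_migraines(n_models=3, seed=0):
    migraines = toy_bump_dataset(n_models, seed=seed)
    models = {
        i: fit_n4sid(u, y, nx=3, ph=10, input_names=("a", "b"))
        for i, (u, y) in migraines.items()
    }
    return models, migraines


class TestCrossValidate:
    def test_single_pair_stats_collapse(self):
        models, migraines = _toy_models_and_migraines(2)
        ranking = cross_validate(
            {0: models[0]}, {0: migraines[0], 1: migraines[1]},
            horizons=np.arange(1, 16),
        )
        e = ranking.entries[0]
        assert e.fh_min == e.fh_average == e.fh_max
        assert len(e.horizons) == 1

    def test_requires_two_migraines(self):
        models, migraines = _toy_models_and_migraines(1)
        with pytest.raises(ValueError):
            cross_validate(models, {0: migraines[0]})

    def test_stats_ordering_invariant(self):
        models, migraines = _toy_models_and_migraines(3)
        ranking = cross_validate(models, migraines, horizons=np.arange(1, 21))
        for e in ranking.entries:
            assert e.fh_min <= e.fh_average <= e.fh_max


class TestBuildAverageModel:
    def test_identical_members_equal_single_prediction(self):
        models, migraines = _toy_models_and_migraines(3)
        ens = EnsembleModel(members=[models[0], models[0]], feature_set=("a", "b"))
        u, y = migraines[1]
        tr_ens = ens.predict(u, y, 5)
        single = EnsembleModel(members=[models[0]], feature_set=("a", "b"))
        tr_one = single.predict(u, y, 5)
        np.testing.assert_allclose(tr_ens.predicted, tr_one.predicted)

    def test_top_third_selected(self):
        models, migraines = _toy_models_and_migraines(3)
        ranking = cross_validate(models, migraines, horizons=np.arange(1, 11))
        ens = build_average_model(ranking, models)
        assert len(ens.members) == 1  # round(3/3)

    def test_fewer_than_three_models_warns(self):
        models, migraines = _toy_models_and_migraines(2)
        ranking = cross_validate(models, migraines, horizons=np.arange(1, 11))
        with pytest.warns(UserWarning):
            ens = build_average_model(ranking, models)
        assert len(ens.members) == 1

    def test_mixed_feature_sets_rejected(self):
        models, _ = _toy_models_and_migraines(3)
        ranking = rank_entries(
            [RankEntry(model_id=0, fh_min=1, fh_average=5, fh_max=9, fh_sigma=1)]
        )
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            build_average_model(ranking, {0: models[0]}, feature_set=("x", "z"))
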