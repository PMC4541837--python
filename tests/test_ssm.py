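import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migrainecast.ssm import (
    ConstantOutputError,
    StateSpaceModel,
    WindowTooShortError,
    compute_fit,
    fit_n4sid,
    grid_combinations,
    predict_k_ahead,
    simulate,
    train_grid,
)
from tests.conftest import make_lti, simulate_lti


class TestComputeFit:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.5, 0.9, 0.2])
        assert compute_fit(y, y) == 100.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0, 5.0])
        assert compute_fit(y, np.full(4, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # ||y-yhat|| = 1, ||y-mean|| = sqrt(2) -> 100*(1 - 1/sqrt(2))
        assert compute_fit([0, 1, 2], [0, 1, 1]) == pytest.approx(
            100.0 * (1 - 1 / np.sqrt(2)), abs=1e-10
        )

    def test_constant_y_raises(self):
        with pytest.raises(ConstantOutputError):
            compute_fit([1.0, 1.0, 1.0], [1.0, 1.0, 2.0])

    def test_nan_warmup_ignored(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([np.nan, 2.0, 3.0, 4.0])
        assert compute_fit(y, yhat) == 100.0

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_norms(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(50)
        yhat = rng.standard_normal(50)
        # independent oracle: explicit sums of squares
        num = np.sqrt(np.sum((y - yhat) ** 2))
        den = np.sqrt(np.sum((y - np.sum(y) / y.size) ** 2))
        oracle = 100.0 * (1.0 - num / den)
        assert compute_fit(y, yhat) == pytest.approx(oracle, rel=1e-12)


class TestFitN4sid:
    def test_noise_free_third_order_recovery(self):
        rng = np.random.default_rng(0)
        A, B, C, D = make_lti(3, 2, rng)
        u = rng.standard_normal((2000, 2))
        y = simulate_lti(A, B, C, D, u)
        u2 = rng.standard_normal((2000, 2))
        y2 = simulate_lti(A, B, C, D, u2)
        model = fit_n4sid(u, y, nx=3, ph=15)
        assert compute_fit(y2, simulate(model, u2)) >= 95.0

    def test_white_noise_output_uninformative(self):
        rng = np.random.default_rng(1)
        u = np.zeros((1500, 2))
        y = rng.standard_normal(1500)
        model = fit_n4sid(u, y, nx=2, ph=10)
        yhat = predict_k_ahead(model, u, y, 30)
        assert abs(compute_fit(y, yhat)) < 30.0

    def test_input_scale_invariance(self):
        rng = np.random.default_rng(2)
        A, B, C, D = make_lti(3, 2, rng)
        u = rng.standard_normal((1500, 2))
        y = simulate_lti(A, B, C, D, u)
        m1 = fit_n4sid(u, y, nx=3, ph=12)
        m2 = fit_n4sid(2.0 * u, y, nx=3, ph=12)
        p1 = predict_k_ahead(m1, u, y, 5)
        p2 = predict_k_ahead(m2, 2.0 * u, y, 5)
        np.testing.assert_allclose(p1[5:], p2[5:], atol=1e-6)

    def test_window_too_short_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(WindowTooShortError):
            fit_n4sid(rng.standard_normal((200, 4)), rng.standard_normal(200), nx=3, ph=100)

    def test_rank_deficiency_reduces_order(self):
        # first-order process requested at order 6: order drops, flag set
        rng = np.random.default_rng(4)
        u = rng.standard_normal((1500, 1))
        A, B, C, D = make_lti(1, 1, rng)
        y = simulate_lti(A, B, C, D, u)
        model = fit_n4sid(u, y, nx=6, ph=10)
        assert model.nx <= 6
        if model.nx < 6:
            assert model.order_reduced

    @pytest.mark.parametrize("seed", range(5))
    def test_predictor_always_stable(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C, D = make_lti(4, 3, rng)
        u = rng.standard_normal((1200, 3))
        y = simulate_lti(A, B, C, D, u, noise_sd=0.3, rng=rng)
        model = fit_n4sid(u, y, nx=4, ph=12)
        rho = np.max(np.abs(np.linalg.eigvals(model.predictor_matrix())))
        assert rho < 1.0


class TestPredictKAhead:
    def test_noise_free_prediction_near_exact(self):
        rng = np.random.default_rng(5)
        A, B, C, D = make_lti(3, 2, rng)
        u = rng.standard_normal((1500, 2))
        y = simulate_lti(A, B, C, D, u)
        model = fit_n4sid(u, y, nx=3, ph=15)
        yhat = predict_k_ahead(model, u, y, 1)
        assert compute_fit(y, yhat) >= 95.0

    def test_short_horizon_beats_long_on_stochastic_data(self):
        # Monte-Carlo: k=1 error variance <= k=30 error variance
        var1, var30 = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            A, B, C, D = make_lti(3, 2, rng)
            u = rng.standard_normal((1500, 2))
            y = simulate_lti(A, B, C, D, u, noise_sd=0.5, rng=rng)
            model = fit_n4sid(u, y, nx=3, ph=12)
            e1 = y - predict_k_ahead(model, u, y, 1)
            e30 = y - predict_k_ahead(model, u, y, 30)
            var1.append(np.nanvar(e1))
            var30.append(np.nanvar(e30))
        assert np.mean(var1) <= np.mean(var30)

    def test_zero_input_zero_state_predicts_zero(self):
        model = StateSpaceModel(
            A=np.array([[0.5]]), B=np.array([[1.0]]), C=np.array([[1.0]]),
            D=np.array([[0.0]]), K=np.array([[0.1]]), nx=1, ph=5,
            input_names=("u0",), u_mean=np.zeros(1), u_std=np.ones(1),
            y_mean=0.0, y_std=1.0,
        )
        u = np.zeros((50, 1))
        y = np.zeros(50)
        yhat = predict_k_ahead(model, u, y, 3)
        np.testing.assert_allclose(yhat[3:], 0.0, atol=1e-15)

    def test_warmup_is_nan(self):
        model = StateSpaceModel(
            A=np.array([[0.5]]), B=np.array([[1.0]]), C=np.array([[1.0]]),
            D=np.array([[0.0]]), K=np.array([[0.0]]), nx=1, ph=5,
            input_names=("u0",), u_mean=np.zeros(1), u_std=np.ones(1),
            y_mean=0.0, y_std=1.0,
        )
        yhat = predict_k_ahead(model, np.ones((20, 1)), np.ones(20), 4)
        assert np.all(np.isnan(yhat[:4])) and np.all(np.isfinite(yhat[4:]))

    def test_invalid_horizon(self):
        model = StateSpaceModel(
            A=np.array([[0.5]]), B=np.array([[1.0]]), C=np.array([[1.0]]),
            D=np.array([[0.0]]), K=np.array([[0.0]]), nx=1, ph=5,
            input_names=("u0",), u_mean=np.zeros(1), u_std=np.ones(1),
            y_mean=0.0, y_std=1.0,
        )
        with pytest.raises(ValueError):
            predict_k_ahead(model, np.ones((20, 1)), np.ones(20), 0)
        with pytest.warns(UserWarning):
            predict_k_ahead(model, np.ones((200, 1)), np.ones(200), 101)


class TestTrainGrid:
    def test_grid_enumeration_has_200_pairs(self):
        assert len(grid_combinations()) == 200

    def test_short_window_rows_skipped_and_logged(self):
        rng = np.random.default_rng(6)
        A, B, C, D = make_lti(2, 2, rng)
        u = rng.standard_normal((400, 2))
        y = simulate_lti(A, B, C, D, u)
        res = train_grid(u, y, ph_values=(10, 100), nx_values=(2,))
        assert (100, 2) in res.skipped
        assert res.entries[(100, 2)] is None
        assert res.best == (10, 2)

    def test_deterministic_on_identical_windows(self):
        rng = np.random.default_rng(7)
        A, B, C, D = make_lti(2, 2, rng)
        u = rng.standard_normal((900, 2))
        y = simulate_lti(A, B, C, D, u)
        r1 = train_grid(u, y, ph_values=(10, 20), nx_values=(2, 3))
        r2 = train_grid(u.copy(), y.copy(), ph_values=(10, 20), nx_values=(2, 3))
        assert r1.best == r2.best
        for key in r1.entries:
            assert r1.entries[key] == pytest.approx(r2.entries[key], abs=1e-9)

    def test_recovers_short_memory_process(self):
        # generator memory ~ a few minutes: the best past horizon stays small
        rng = np.random.default_rng(8)
        A, B, C, D = make_lti(3, 2, rng, rho=0.7)
        u = rng.standard_normal((1500, 2))
        y = simulate_lti(A, B, C, D, u, noise_sd=0.05, rng=rng)
        res = train_grid(u, y, ph_values=tuple(range(5, 65, 5)), nx_values=(2, 3))
        assert res.best is not None
        assert res.best[0] <= 60

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(9)
        A, B, C, D = make_lti(2, 2, rng)
        u = rng.standard_normal((800, 2))
        y = simulate_lti(A, B, C, D, u)
        model = fit_n4sid(u, y, nx=2, ph=10, input_names=("TEMP", "EDA"))
        back = StateSpaceModel.from_dict(model.to_dict())
        np.testing.assert_allclose(back.A, model.A)
        np.testing.assert_allclose(back.K, model.K)
        assert back.input_names == model.input_names
        p1 = predict_k_ahead(model, u, y, 7)
        p2 = predict_k_ahead(back, u, y, 7)
        np.testing.assert_allclose(p1[7:], p2[7:])
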