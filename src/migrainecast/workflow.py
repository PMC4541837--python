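"""End-to-end study protocol: split, train, validate, rank, test, real time.

Ties the stages together for one patient: episode-level train/test split,
per-migraine training-grid search, cross-validation ranking, average-model
construction per feature subset, hierarchy assembly for sensor-fault
fallback, and a minute-by-minute real-time replay that selects the ensemble
by sensor availability, predicts at the subset's validated average horizon
(capped at 30 min), and raises alarms through the decider/repair path.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from migrainecast.ensemble import (
    DECIDER_THRESHOLD,
    FIT_THRESHOLD,
    EnsembleModel,
    ModelRanking,
    build_average_model,
    cross_validate,
    horizon_from_fit_curve,
    linear_decider,
    repair_prediction,
)
from migrainecast.evaluation import (
    HierarchyEntry,
    ModelHierarchy,
    NoModelError,
    SensorStatus,
    sdms2_select,
)
from migrainecast.pain import PainAnnotation, build_symptomatic_curve, evaluate_curve
from migrainecast.repair import FEATURES, SynchronizedFrame
from migrainecast.ssm import (
    DEFAULT_NX_GRID,
    DEFAULT_PH_GRID,
    StateSpaceModel,
    compute_fit,
    train_grid,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "split_dataset",
    "episode_windows",
    "train_patient_models",
    "run_feature_subset_study",
    "simulate_realtime",
    "feature_subsets",
]


@dataclass
class StudyConfig:
    """Protocol knobs; defaults follow the study design."""

    split_fraction: float = 0.75
    seed: int = 0
    horizons: tuple[int, int] = (1, 100)
    fit_threshold: float = FIT_THRESHOLD
    decider_threshold: float = DECIDER_THRESHOLD
    repair_min_event: float = 60.0
    future_horizon: int = 30
    ph_values: tuple[int, ...] = DEFAULT_PH_GRID
    nx_values: tuple[int, ...] = DEFAULT_NX_GRID
    pre_context: float = 360.0  # training window starts this long before aura
    eval_pre: float = 120.0  # evaluation window margin before aura
    eval_post: float = 60.0  # evaluation window margin after pain end
    n_train: int | None = None  # explicit override of the split size
    include_duos: bool = False  # two-feature subsets excluded by default

    def __post_init__(self) -> None:
        if not (0 < self.fit_threshold < 100 and 0 < self.decider_threshold < 100):
            raise ValueError("thresholds must lie in (0, 100)")
        if self.horizons[0] < 1 or self.horizons[1] < self.horizons[0]:
            raise ValueError("horizons must be a positive ascending range")

    def horizon_array(self) -> np.ndarray:
        return np.arange(self.horizons[0], self.horizons[1] + 1)


def split_dataset(
    episodes: list, config: StudyConfig
) -> tuple[list, list]:
    """Seeded per-episode split into training and test sets.

    The training size is ``round(split_fraction * n)`` unless
    ``config.n_train`` overrides it (the protocol's 'around 75 %').
    """
    n = len(episodes)
    if n < 4:
        raise ValueError("need at least 4 episodes to split")
    n_train = config.n_train if config.n_train is not None else int(round(config.split_fraction * n))
    if not 1 <= n_train < n:
        raise ValueError(f"invalid training size {n_train} for {n} episodes")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    train = [episodes[i] for i in sorted(order[:n_train])]
    test = [episodes[i] for i in sorted(order[n_train:])]
    return train, test


def feature_subsets(config: StudyConfig, features=FEATURES) -> list[tuple[str, ...]]:
    """The quad plus every triad (plus duos when enabled)."""
    subsets = [tuple(features)]
    subsets += [s for s in itertools.combinations(features, 3)]
    if config.include_duos:
        subsets += [s for s in itertools.combinations(features, 2)]
    return subsets


@dataclass
class Episode:
    """One migraine with its curve and window bounds on the frame grid."""

    index: int
    annotation: PainAnnotation
    curve: object
    train_window: tuple[float, float]
    eval_window: tuple[float, float]


def episode_windows(
    frame: SynchronizedFrame,
    annotations: list[PainAnnotation],
    config: StudyConfig,
) -> list[Episode]:
    """Attach training and evaluation windows to each annotated migraine."""
    eps = []
    g0, g1 = frame.grid[0], frame.grid[-1]
    for i, ann in enumerate(annotations):
        curve = build_symptomatic_curve(ann)
        tw = (max(ann.aura_start - config.pre_context, g0),
              min(ann.pain_end + config.eval_post, g1))
        ew = (max(ann.aura_start - config.eval_pre, g0),
              min(ann.pain_end + config.eval_post, g1))
        eps.append(Episode(index=i, annotation=ann, curve=curve,
                           train_window=tw, eval_window=ew))
    return eps


def _window_arrays(
    frame: SynchronizedFrame,
    episode: Episode,
    features: tuple[str, ...],
    window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    sel = (frame.grid >= window[0]) & (frame.grid <= window[1])
    u = frame.data.loc[sel, list(features)].to_numpy()
    y = evaluate_curve(episode.curve, frame.grid[sel])
    return u, y


def train_patient_models(
    frame: SynchronizedFrame,
    episodes: list[Episode],
    config: StudyConfig,
    features: tuple[str, ...] = FEATURES,
) -> dict[int, StateSpaceModel]:
    """Grid-search one model per training migraine (best 30-min-ahead fit)."""
    models = {}
    for ep in episodes:
        u, y = _window_arrays(frame, ep, features, ep.train_window)
        res = train_grid(
            u, y, input_names=features,
            ph_values=config.ph_values, nx_values=config.nx_values,
            fh_train=config.future_horizon,
        )
        if res.best_model is None:
            warnings.warn(f"episode {ep.index}: no grid entry could be fitted")
            continue
        models[ep.index] = res.best_model
    return models


def _ensemble_horizons(
    ensemble: EnsembleModel,
    migraines: dict[int, tuple[np.ndarray, np.ndarray]],
    holdout_ids: list[int],
    horizons: np.ndarray,
    threshold: float,
) -> np.ndarray:
    hs = []
    for mid in holdout_ids:
        u, y = migraines[mid]
        fits = np.empty(horizons.size)
        for idx, k in enumerate(horizons):
            trace = ensemble.predict(u, y, int(k))
            try:
                fits[idx] = compute_fit(y, trace.predicted)
            except ValueError:
                fits[idx] = -np.inf
        hs.append(horizon_from_fit_curve(horizons, fits, threshold=threshold))
    return np.array(hs, dtype=float)


@dataclass
class SubsetResult:
    feature_set: tuple[str, ...]
    ranking: ModelRanking
    ensemble: EnsembleModel
    fh_min: float
    fh_average: float
    fh_max: float
    fh_sigma: float


@dataclass
class StudyResult:
    subsets: list[SubsetResult]
    hierarchy: ModelHierarchy
    train_ids: list[int]
    test_ids: list[int]

    def table(self) -> list[dict]:
        return [
            {
                "features": "-".join(s.feature_set),
                "fh_average": s.fh_average,
                "fh_min": s.fh_min,
                "fh_max": s.fh_max,
                "fh_sigma": s.fh_sigma,
            }
            for s in self.subsets
        ]


def run_feature_subset_study(
    frame: SynchronizedFrame,
    annotations: list[PainAnnotation],
    config: StudyConfig,
) -> StudyResult:
    """Full train-validate-rank-ensemble pass for every feature subset.

    Episodes are split once; each subset trains per-migraine models on the
    training set, cross-validates them, keeps the top third as the average
    model, and scores the ensemble's achievable horizon on the training
    migraines not used as members.  Subsets are ordered into the fallback
    hierarchy by decreasing average horizon.
    """
    episodes = episode_windows(frame, annotations, config)
    train_eps, test_eps = split_dataset(episodes, config)
    horizons = config.horizon_array()
    results = []
    for subset in feature_subsets(config):
        models = train_patient_models(frame, train_eps, config, features=subset)
        if len(models) < 2:
            warnings.warn(f"subset {subset}: too few trainable migraines, skipped")
            continue
        migraines = {
            ep.index: _window_arrays(frame, ep, subset, ep.eval_window)
            for ep in train_eps
            if ep.index in models
        }
        ranking = cross_validate(models, migraines, horizons=horizons,
                                 threshold=config.fit_threshold)
        ens = build_average_model(ranking, models, feature_set=subset)
        member_ids = {e.model_id for e in ranking.entries[: len(ens.members)]}
        holdout = [mid for mid in migraines if mid not in member_ids] or list(migraines)
        hs = _ensemble_horizons(ens, migraines, holdout, horizons, config.fit_threshold)
        ens.fh_min, ens.fh_average = float(hs.min()), float(hs.mean())
        ens.fh_max, ens.fh_sigma = float(hs.max()), float(hs.std())
        results.append(
            SubsetResult(
                feature_set=tuple(subset), ranking=ranking, ensemble=ens,
                fh_min=ens.fh_min, fh_average=ens.fh_average,
                fh_max=ens.fh_max, fh_sigma=ens.fh_sigma,
            )
        )
    ordered = sorted(results, key=lambda r: -r.fh_average)
    hierarchy = ModelHierarchy(
        entries=[
            HierarchyEntry(feature_set=r.feature_set, ensemble=r.ensemble,
                           h=(r.fh_min, r.fh_average, r.fh_max))
            for r in ordered
        ]
    )
    return StudyResult(
        subsets=results,
        hierarchy=hierarchy,
        train_ids=[e.index for e in train_eps],
        test_ids=[e.index for e in test_eps],
    )


class _MemberFilter:
    """Incremental innovation-form filter state for one ensemble member."""

    def __init__(self, model: StateSpaceModel):
        self.m = model
        self.x = np.zeros(model.A.shape[0])

    def update(self, u_raw: np.ndarray, y_raw: float) -> None:
        m = self.m
        un = (u_raw - m.u_mean) / m.u_std
        yn = (y_raw - m.y_mean) / m.y_std
        e = yn - (m.C @ self.x)[0] - (m.D @ un)[0]
        self.x = m.A @ self.x + m.B @ un + m.K[:, 0] * e

    def predict(self, u_raw: np.ndarray, k: int) -> float:
        m = self.m
        un = (u_raw - m.u_mean) / m.u_std
        z = self.x
        for _ in range(k - 1):
            z = m.A @ z + m.B @ un
        yn = (m.C @ z)[0] + (m.D @ un)[0]
        return float(np.clip(yn * m.y_std + m.y_mean, -0.2, 1.2))


def simulate_realtime(
    frame: SynchronizedFrame,
    y_series: np.ndarray,
    hierarchy: ModelHierarchy,
    config: StudyConfig,
    faults: list[tuple[str, float, float, str]] | None = None,
    truth_events: list[tuple[float, float]] | None = None,
    warmup: float = 120.0,
    alarm_sustain: int = 3,
    refractory: float = 360.0,
) -> list[dict]:
    """Replay a frame minute by minute and log alarms as JSON-able records.

    At each step the sensor status (scripted ``faults`` as
    ``(feature, start_min, end_min, mode)``) selects an ensemble via the
    fallback hierarchy; the selected ensemble predicts at its validated
    average horizon capped at ``config.future_horizon``; an alarm fires when
    the predicted probability stays above the decider threshold for
    ``alarm_sustain`` consecutive minutes, at most once per ``refractory``
    window.  Suspensions and model switches are logged too.
    """
    faults = faults or []
    grid = frame.grid
    data = frame.data
    feature_cols = {f: data[f].to_numpy() for f in data.columns}
    log: list[dict] = []
    filters: dict[int, list[_MemberFilter]] = {
        idx: [_MemberFilter(m) for m in entry.ensemble.members]
        for idx, entry in enumerate(hierarchy.entries)
    }
    active_idx: int | None = None
    supra_run = 0
    last_alarm = -np.inf

    def status_at(t: float) -> SensorStatus:
        states = {f: "ok" for f in FEATURES}
        for feat, f0, f1, mode in faults:
            if f0 <= t < f1:
                states[feat] = mode
        return SensorStatus(states=states)

    for ti, t in enumerate(grid):
        status = status_at(t)
        try:
            entry = sdms2_select(hierarchy, status)
        except NoModelError:
            if active_idx is not None:
                log.append({"t": float(t), "type": "suspend"})
            active_idx = None
            continue
        idx = hierarchy.entries.index(entry)
        if idx != active_idx:
            log.append(
                {"t": float(t), "type": "switch",
                 "feature_set": list(entry.feature_set), "h": list(entry.h)}
            )
            active_idx = idx

        # advance every entry's filters with the (possibly faulted) data
        for j, e in enumerate(hierarchy.entries):
            u_raw = np.array([feature_cols[f][ti] for f in e.feature_set])
            if not np.all(np.isfinite(u_raw)):
                continue
            y_raw = float(y_series[ti])
            for flt in filters[j]:
                flt.update(u_raw, y_raw)

        if t < grid[0] + warmup:
            continue
        k = int(np.clip(round(entry.h[1]), 1, config.future_horizon))
        u_now = np.array([feature_cols[f][ti] for f in entry.feature_set])
        if not np.all(np.isfinite(u_now)):
            continue
        preds = [flt.predict(u_now, k) for flt in filters[idx]]
        prob = 100.0 * float(np.clip(np.mean(preds), 0.0, 1.0))
        if prob >= config.decider_threshold:
            supra_run += 1
        else:
            supra_run = 0
        if supra_run >= alarm_sustain and t - last_alarm > refractory:
            rec = {
                "t": float(t), "type": "alarm", "predicted_for": float(t + k),
                "probability": prob, "feature_set": list(entry.feature_set),
            }
            if truth_events:
                leads = [ev[0] - t for ev in truth_events if ev[0] - t > -config.eval_post]
                rec["lead_minutes"] = float(min(leads, key=abs)) if leads else None
            log.append(rec)
            last_alarm = t
    return log


def log_to_jsonl(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")
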