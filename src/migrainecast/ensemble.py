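"""Model validation: decider, false-positive repair, ranking, average model.

The raw predicted symptomatic curve is mapped to a 0-100 % probability of an
ongoing attack by a linear decider (detection open while probability >= 50 %).
Because the linear predictors oscillate around zero in asymptomatic periods,
an iterative repair pass removes supra-threshold excursions shorter than
60 minutes and anchors surviving events at their zero crossings (Marks A/B).

Cross-validation scores every model against every other migraine across
prediction horizons 1..100 min; a model's achievable horizon per curve is the
largest horizon before the fit drops (sustainedly) below the 70 % threshold.
Models are ranked by average achievable horizon, and the top third form an
unweighted average ensemble whose mean prediction is repaired again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from migrainecast.ssm import OUTPUT_CLAMP, StateSpaceModel, compute_fit, predict_k_ahead

__all__ = [
    "PredictionTrace",
    "ModelRanking",
    "RankEntry",
    "EnsembleModel",
    "linear_decider",
    "repair_prediction",
    "horizon_from_fit_curve",
    "cross_validate",
    "build_average_model",
    "ensemble_size",
    "DECIDER_THRESHOLD",
    "FIT_THRESHOLD",
    "REPAIR_MIN_EVENT",
]

#: probability (%) above which a point counts as a positive.
DECIDER_THRESHOLD = 50.0
#: fit (%) threshold defining an achievable prediction horizon.
FIT_THRESHOLD = 70.0
#: supra-threshold excursions shorter than this (minutes) are false positives.
REPAIR_MIN_EVENT = 60.0
#: repair scans the trace in windows of this many minutes.
REPAIR_WINDOW = 360.0


@dataclass
class PredictionTrace:
    """A predicted curve with its probability mapping and detections."""

    grid: np.ndarray  # minutes
    predicted: np.ndarray
    probability: np.ndarray
    detections: list[tuple[float, float]] = field(default_factory=list)  # (A, B)

    def copy(self) -> "PredictionTrace":
        return PredictionTrace(
            grid=self.grid.copy(),
            predicted=self.predicted.copy(),
            probability=self.probability.copy(),
            detections=list(self.detections),
        )


def linear_decider(predicted: np.ndarray, grid: np.ndarray | None = None) -> PredictionTrace:
    """Project a predicted curve to 0-100 % probability; open detections at 50 %.

    The prediction is first clamped to the normalized curve scale, then
    linearly mapped: probability = 100 * clip(predicted, 0, 1).  NaN warm-up
    samples map to 0 %.
    """
    predicted = np.asarray(predicted, dtype=float)
    if grid is None:
        grid = np.arange(predicted.size, dtype=float)
    pred = np.clip(np.nan_to_num(predicted, nan=0.0), OUTPUT_CLAMP[0], OUTPUT_CLAMP[1])
    prob = 100.0 * np.clip(pred, 0.0, 1.0)
    trace = PredictionTrace(grid=np.asarray(grid, float), predicted=pred, probability=prob)
    trace.detections = _detect_intervals(trace)
    return trace


def _zero_bounds(pred: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
    """Expand [lo, hi) outwards to the nearest non-positive samples."""
    a = lo
    while a > 0 and pred[a - 1] > 0:
        a -= 1
    b = hi
    while b < pred.size and pred[b] > 0:
        b += 1
    return a, b


def _supra_runs(prob: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = prob >= threshold
    runs, in_run, lo = [], False, 0
    for i, flag in enumerate(above):
        if flag and not in_run:
            lo, in_run = i, True
        elif not flag and in_run:
            runs.append((lo, i))
            in_run = False
    if in_run:
        runs.append((lo, above.size))
    return runs


def _detect_intervals(trace: PredictionTrace) -> list[tuple[float, float]]:
    """Detection intervals (Marks A/B at zero crossings) for supra runs."""
    out = []
    for lo, hi in _supra_runs(trace.probability, DECIDER_THRESHOLD):
        a, b = _zero_bounds(trace.predicted, lo, hi)
        mark = (float(trace.grid[a]), float(trace.grid[min(b, trace.grid.size - 1)]))
        if out and mark[0] <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], mark[1]))
        else:
            out.append(mark)
    return out


def repair_prediction(
    trace: PredictionTrace,
    min_event: float = REPAIR_MIN_EVENT,
    window: float = REPAIR_WINDOW,
) -> PredictionTrace:
    """Iteratively remove supra-threshold excursions shorter than ``min_event``.

    Scanning the trace window by window: points with probability above the
    50 % decider threshold are positives; a forward search delimits the
    excursion, and if its farthest supra-threshold points span less than
    ``min_event`` minutes the excursion is a false positive and is zeroed
    between its zero crossings.  Survivors get Marks A/B at their zero
    crossings and the window restarts at Mark B.  Idempotent.
    """
    out = trace.copy()
    step = (out.grid[1] - out.grid[0]) if out.grid.size > 1 else 1.0
    n = out.grid.size
    detections: list[tuple[float, float]] = []
    pos = 0
    win_pts = max(int(round(window / step)), 1)
    while pos < n:
        seg_end = min(pos + win_pts, n)
        supra = np.flatnonzero(out.probability[pos:seg_end] >= DECIDER_THRESHOLD)
        if supra.size == 0:
            pos = seg_end
            continue
        lo = pos + supra[0]
        # forward search for the extent of this excursion
        hi = lo
        while hi < n and out.probability[hi] >= DECIDER_THRESHOLD:
            hi += 1
        span = (hi - lo) * step
        a, b = _zero_bounds(out.predicted, lo, hi)
        if span < min_event:
            out.predicted[a:b] = 0.0
            out.probability[a:b] = 0.0
            pos = b
        else:
            detections.append(
                (float(out.grid[a]), float(out.grid[min(b, n - 1)]))
            )
            pos = b if b > pos else pos + 1
    out.detections = detections
    return out


def horizon_from_fit_curve(
    horizons: np.ndarray,
    fits: np.ndarray,
    threshold: float = FIT_THRESHOLD,
    sustain: int = 3,
) -> int:
    """Largest horizon before the first sustained drop below ``threshold``.

    A drop counts as sustained when ``sustain`` consecutive horizons fall
    below the threshold; a curve that never reaches the threshold scores 0.
    """
    horizons = np.asarray(horizons)
    fits = np.asarray(fits, dtype=float)
    below = fits < threshold
    if below.all():
        return 0
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustain:
            start = i - sustain + 1
            return int(horizons[start - 1]) if start > 0 else 0
    # no sustained drop: last horizon that met the threshold
    return int(horizons[np.flatnonzero(~below)[-1]])


@dataclass
class RankEntry:
    model_id: int
    fh_min: float
    fh_average: float
    fh_max: float
    fh_sigma: float
    horizons: list[int] = field(default_factory=list)
    never_reached: int = 0  # curves that never met the fit threshold


@dataclass
class ModelRanking:
    """Per-model horizon statistics at the fit threshold, best first."""

    entries: list[RankEntry]

    def order(self) -> list[int]:
        return [e.model_id for e in self.entries]


def _rank_key(e: RankEntry) -> tuple:
    # ties on average broken by minimum, then maximum, then model index
    return (-e.fh_average, -e.fh_min, -e.fh_max, e.model_id)


def rank_entries(entries: list[RankEntry]) -> ModelRanking:
    return ModelRanking(entries=sorted(entries, key=_rank_key))


def _evaluate_model_on_migraine(
    model: StateSpaceModel,
    u: np.ndarray,
    y: np.ndarray,
    horizons: np.ndarray,
) -> np.ndarray:
    """Fit-vs-horizon curve for one model on one migraine window (repaired)."""
    fits = np.empty(horizons.size)
    for idx, k in enumerate(horizons):
        yhat = predict_k_ahead(model, u, y, int(k), clamp=True)
        trace = linear_decider(yhat)
        trace = repair_prediction(trace)
        try:
            fits[idx] = compute_fit(y, trace.predicted)
        except ValueError:
            fits[idx] = -np.inf
    return fits


def cross_validate(
    models: dict[int, StateSpaceModel],
    migraines: dict[int, tuple[np.ndarray, np.ndarray]],
    horizons: np.ndarray | None = None,
    threshold: float = FIT_THRESHOLD,
) -> ModelRanking:
    """Validate every model against every other migraine.

    ``migraines`` maps episode id to its ``(u, y)`` evaluation window; model
    ``i`` (trained on episode ``i``) is scored on all ``j != i``, producing
    M-1 fit-vs-horizon curves whose threshold crossings aggregate into
    min/avg/max/sigma horizon statistics.
    """
    if len(migraines) < 2:
        raise ValueError("cross-validation needs at least 2 migraines")
    if horizons is None:
        horizons = np.arange(1, 101)
    entries = []
    for mid, model in models.items():
        hs, flagged = [], 0
        for jid, (u, y) in migraines.items():
            if jid == mid:
                continue
            fits = _evaluate_model_on_migraine(model, u, y, horizons)
            h = horizon_from_fit_curve(horizons, fits, threshold=threshold)
            if h == 0:
                flagged += 1
            hs.append(h)
        hs_arr = np.array(hs, dtype=float)
        entries.append(
            RankEntry(
                model_id=mid,
                fh_min=float(hs_arr.min()),
                fh_average=float(hs_arr.mean()),
                fh_max=float(hs_arr.max()),
                fh_sigma=float(hs_arr.std()),
                horizons=[int(h) for h in hs],
                never_reached=flagged,
            )
        )
    return rank_entries(entries)


def ensemble_size(n_models: int) -> int:
    """One-third rule: round(M/3), never below 1."""
    if n_models < 3:
        return 1
    return max(int(round(n_models / 3.0)), 1)


@dataclass
class EnsembleModel:
    """Unweighted average of the top-ranked models (shared feature subset)."""

    members: list[StateSpaceModel]
    feature_set: tuple[str, ...]
    fh_min: float = 0.0
    fh_average: float = 0.0
    fh_max: float = 0.0
    fh_sigma: float = 0.0

    @property
    def h(self) -> tuple[float, float, float]:
        return (self.fh_min, self.fh_average, self.fh_max)

    def predict(self, u: np.ndarray, y: np.ndarray, k: int) -> PredictionTrace:
        """Mean member prediction at horizon ``k``, decided and repaired."""
        preds = np.vstack([predict_k_ahead(m, u, y, k, clamp=True) for m in self.members])
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore", category=RuntimeWarning)
                mean_pred = np.nanmean(preds, axis=0)
        trace = linear_decider(mean_pred)
        return repair_prediction(trace)


def build_average_model(
    ranking: ModelRanking,
    models: dict[int, StateSpaceModel],
    feature_set: tuple[str, ...] | None = None,
) -> EnsembleModel:
    """Pick the top round(M/3) ranked models as an unweighted ensemble."""
    import warnings as _warnings

    m = len(ranking.entries)
    size = ensemble_size(m)
    if m < 3:
        _warnings.warn("fewer than 3 models; ensemble degenerates to a single model")
    chosen = [models[e.model_id] for e in ranking.entries[:size]]
    feats = feature_set or chosen[0].input_names
    if any(mm.input_names != tuple(feats) for mm in chosen):
        raise ValueError("ensemble members must share the feature subset")
    return EnsembleModel(members=chosen, feature_set=tuple(feats))
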