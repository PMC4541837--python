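"""Detection scoring, sensor-fault robustness, and fallback model selection.

A true positive requires both an overlapping detection interval and a fit of
at least 70 % over the migraine period — a detection without a reliable fit
counts as a miss.  Rates follow

    TPR = Tp / (Tp + Fn)        PPV = Tp / (Tp + Fp)
    F   = 2 * TPR * PPV / (TPR + PPV)

with PPV reported as 100 % when there are no detections at all (the zero-Tp
reporting convention).  The sensor-dependent model selection system (SDMS2)
holds a precomputed hierarchy of feature-subset ensembles and, given the live
sensor status, returns the first entry whose features are all available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from migrainecast.ensemble import FIT_THRESHOLD, EnsembleModel, cross_validate
from migrainecast.synthetic import LOSS_VALUE, SATURATION_VALUES

__all__ = [
    "ConfusionCounts",
    "SensorStatus",
    "HierarchyEntry",
    "ModelHierarchy",
    "NoModelError",
    "score_detections",
    "f_score",
    "f_score_from_rates",
    "run_fault_suite",
    "sdms2_select",
]


class NoModelError(RuntimeError):
    """No hierarchy entry is satisfiable with the available sensors."""


@dataclass
class ConfusionCounts:
    Tp: int = 0
    Fp: int = 0
    Fn: int = 0

    def __post_init__(self) -> None:
        if min(self.Tp, self.Fp, self.Fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SensorStatus:
    """Per-feature sensor state: 'ok', 'lost', or 'saturated'."""

    states: dict[str, str]
    saturation_values: dict[str, float] = field(
        default_factory=lambda: dict(SATURATION_VALUES)
    )

    def ok_features(self) -> frozenset:
        return frozenset(f for f, s in self.states.items() if s == "ok")

    def fault_value(self, feature: str) -> float:
        if self.states.get(feature) == "lost":
            return LOSS_VALUE
        if self.states.get(feature) == "saturated":
            return self.saturation_values[feature]
        raise ValueError(f"feature {feature} has no fault")


@dataclass
class HierarchyEntry:
    feature_set: tuple[str, ...]
    ensemble: EnsembleModel
    h: tuple[float, float, float]  # (fh_min, fh_average, fh_max)


@dataclass
class ModelHierarchy:
    """Feature-subset ensembles in fixed preference order (best first)."""

    entries: list[HierarchyEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = frozenset(e.feature_set)
            if key in seen:
                raise ValueError("hierarchy feature sets must be distinct")
            seen.add(key)


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return min(a[1], b[1]) - max(a[0], b[0])


def score_detections(
    detections: list[tuple[float, float]],
    truth_events: list[tuple[float, float]],
    fit_per_event: list[float] | None = None,
    min_overlap: float = 1.0,
    fit_threshold: float = FIT_THRESHOLD,
) -> ConfusionCounts:
    """Event-level confusion counts on a shared timeline (minutes).

    An event is a true positive when some detection overlaps it by at least
    ``min_overlap`` minutes AND its event-window fit meets the threshold;
    otherwise it is a miss.  Detections overlapping no event are false
    positives.  ``fit_per_event`` defaults to all-pass.
    """
    if fit_per_event is None:
        fit_per_event = [100.0] * len(truth_events)
    if len(fit_per_event) != len(truth_events):
        raise ValueError("fit_per_event must align with truth_events")
    tp = fn = 0
    used = [False] * len(detections)
    for ev, fit in zip(truth_events, fit_per_event):
        hit = False
        for di, det in enumerate(detections):
            if _overlap(det, ev) >= min_overlap:
                used[di] = True
                hit = True
        if hit and fit >= fit_threshold:
            tp += 1
        else:
            fn += 1
    fp = sum(
        1
        for di, det in enumerate(detections)
        if not any(_overlap(det, ev) >= min_overlap for ev in truth_events)
    )
    return ConfusionCounts(Tp=tp, Fp=fp, Fn=fn)


def f_score_from_rates(tpr: float, ppv: float) -> float:
    """Harmonic mean of TPR and PPV, both in percent."""
    if tpr + ppv == 0:
        return 0.0
    return 2.0 * tpr * ppv / (tpr + ppv)


def f_score(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(TPR %, PPV %, F %) from confusion counts.

    PPV with zero detections is reported as 100 % so that undetected-event
    rows read (TPR=0, PPV=100, F=0).  All-zero counts are an error.
    """
    if counts.Tp == 0 and counts.Fp == 0 and counts.Fn == 0:
        raise ValueError("no events and no detections: score undefined")
    tpr = 100.0 * counts.Tp / (counts.Tp + counts.Fn) if counts.Tp + counts.Fn else 0.0
    if counts.Tp + counts.Fp == 0:
        ppv = 100.0
    else:
        ppv = 100.0 * counts.Tp / (counts.Tp + counts.Fp)
    return tpr, ppv, f_score_from_rates(tpr, ppv)


def apply_fault(frame, status: SensorStatus):
    """Return a copy of ``frame`` with faulty features overwritten.

    Lost features read the loss constant, saturated features their per-sensor
    saturation constant, over the whole window; the input frame is untouched.
    """
    out = frame.copy()
    for feat, state in status.states.items():
        if state == "ok" or feat not in out.data.columns:
            continue
        out.data[feat] = status.fault_value(feat)
    return out


def run_fault_suite(
    models,
    migraines: dict[int, tuple[np.ndarray, np.ndarray]],
    faults: list[SensorStatus],
    feature_names: tuple[str, ...],
    horizons: np.ndarray | None = None,
) -> list[dict]:
    """Recompute cross-validation horizons under each fault mode.

    ``migraines`` maps ids to (u, y) windows with columns in
    ``feature_names`` order; each fault overwrites the affected columns with
    its constant and reruns the horizon analysis at the fit threshold,
    producing one row per fault with the ensemble-level statistics.
    """
    if horizons is None:
        horizons = np.arange(1, 101)
    rows = []
    for status in faults:
        corrupted = {}
        for mid, (u, y) in migraines.items():
            u2 = np.array(u, dtype=float, copy=True)
            for feat, state in status.states.items():
                if state == "ok":
                    continue
                if feat not in feature_names:
                    continue  # fault on a feature outside the set: no-op
                u2[:, feature_names.index(feat)] = status.fault_value(feat)
            corrupted[mid] = (u2, y)
        ranking = cross_validate(models, corrupted, horizons=horizons)
        fh = np.array([e.fh_average for e in ranking.entries])
        rows.append(
            {
                "fault": {f: s for f, s in status.states.items() if s != "ok"},
                "fh_average": float(np.mean([e.fh_average for e in ranking.entries])),
                "fh_min": float(np.min([e.fh_min for e in ranking.entries])),
                "fh_max": float(np.max([e.fh_max for e in ranking.entries])),
                "fh_sigma": float(np.std(fh)),
            }
        )
    return rows


def sdms2_select(hierarchy: ModelHierarchy, status: SensorStatus) -> HierarchyEntry:
    """First hierarchy entry whose feature set is fully available.

    Deterministic and order-respecting: the returned entry has the minimal
    index among satisfiable entries.  Raises :class:`NoModelError` when no
    entry can run (prediction suspended).
    """
    ok = status.ok_features()
    for entry in hierarchy.entries:
        if set(entry.feature_set) <= ok:
            return entry
    raise NoModelError(f"no model available for sensors {sorted(ok)}")
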