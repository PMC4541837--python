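"""Symptomatic pain curve: from subjective annotations to a normalized curve.

Patients annotate each attack with three timestamps (aura start, pain start,
pain end) and a sequence of signed punctual pain-change marks on an unlimited
scale.  The marks are cumulatively summed into a piecewise-linear profile,
normalized to a unit maximum, and fitted with two semi-Gaussian halves that
share their peak: a rising half ``exp(-(t-mu1)^2 / (2 sigma1^2))`` for
``t <= mu1`` and a falling half with ``(mu2, sigma2)`` for ``t >= mu2``.
The resulting curve is the model output ``y`` for all downstream stages.

All times are float minutes on the recording's own clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PainAnnotation",
    "SymptomaticCurve",
    "NoPeakError",
    "build_symptomatic_curve",
    "evaluate_curve",
]

#: curve value used to anchor sigma when a half has too few marks to fit:
#: the curve is required to decay to this value at the annotated boundary.
ANCHOR_LEVEL = 0.05

#: residual fraction of the peak above which the profile is considered
#: truncated (pain never returned toward zero, e.g. aborted by medication).
TRUNCATION_LEVEL = 0.25


class NoPeakError(ValueError):
    """Raised when the cumulative pain profile never becomes positive."""


@dataclass
class PainAnnotation:
    """One migraine attack as reported by the patient.

    Parameters
    ----------
    aura_start, pain_start, pain_end
        Timestamps in minutes; ``aura_start <= pain_start < pain_end``.
    marks
        Signed pain-change marks ``(t, delta)`` on the unlimited scale,
        all inside ``[aura_start, pain_end]``.
    global_index
        Overall 0-10 pain index for the whole attack (stored, not modeled).
    """

    aura_start: float
    pain_start: float
    pain_end: float
    marks: list[tuple[float, float]] = field(default_factory=list)
    global_index: int = 5

    def __post_init__(self) -> None:
        if not (self.aura_start <= self.pain_start < self.pain_end):
            raise ValueError(
                "require aura_start <= pain_start < pain_end, got "
                f"{self.aura_start}, {self.pain_start}, {self.pain_end}"
            )
        for t, _ in self.marks:
            if not (self.aura_start <= t <= self.pain_end):
                raise ValueError(f"mark at t={t} outside [aura_start, pain_end]")
        self.marks = sorted(self.marks, key=lambda m: m[0])


@dataclass
class SymptomaticCurve:
    """Two semi-Gaussians sharing a plateau between ``mu1`` and ``mu2``."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if self.mu1 > self.mu2:
            raise ValueError("mu1 must not exceed mu2")

    def __call__(self, times) -> np.ndarray:
        return evaluate_curve(self, times)


def evaluate_curve(curve: SymptomaticCurve, times) -> np.ndarray:
    """Evaluate the normalized curve on ``times`` (minutes); values in [0, 1]."""
    t = np.asarray(times, dtype=float)
    out = np.ones_like(t)
    rising = t <= curve.mu1
    falling = t >= curve.mu2
    out[rising] = np.exp(-((t[rising] - curve.mu1) ** 2) / (2.0 * curve.sigma1**2))
    out[falling] = np.exp(-((t[falling] - curve.mu2) ** 2) / (2.0 * curve.sigma2**2))
    return out


def _anchor_sigma(span: float) -> float:
    # solve exp(-span^2 / (2 sigma^2)) = ANCHOR_LEVEL for sigma
    span = max(span, 1.0)
    return span / np.sqrt(2.0 * np.log(1.0 / ANCHOR_LEVEL))


def _fit_half_sigma(dt: np.ndarray, p: np.ndarray, x0: float) -> float:
    """Least-squares sigma for exp(-dt^2 / (2 sigma^2)) ~ p, dt >= 0."""
    keep = (dt > 0) & (p > 1e-6) & (p < 1.0)
    if keep.sum() < 3:
        return x0
    dt, p = dt[keep], p[keep]
    res = least_squares(
        lambda s: np.exp(-(dt**2) / (2.0 * s[0] ** 2)) - p,
        x0=[x0],
        bounds=([1e-3], [np.inf]),
    )
    return float(res.x[0])


def build_symptomatic_curve(annotation: PainAnnotation) -> SymptomaticCurve:
    """Fit the two-semi-Gaussian curve to one attack's annotation.

    The signed marks are cumulatively summed into a piecewise-linear profile
    (0 at ``aura_start``), normalized to a unit maximum; the peak location
    becomes ``mu1 = mu2`` and each sigma is fitted by least squares to its
    half of the profile, with a boundary-anchor fallback when a half carries
    fewer than three usable marks.

    Raises
    ------
    NoPeakError
        If no cumulative value is positive (all marks non-positive).
    """
    if not annotation.marks:
        raise NoPeakError("annotation has no marks")
    mt = np.array([m[0] for m in annotation.marks], dtype=float)
    cum = np.cumsum([m[1] for m in annotation.marks])
    peak_val = cum.max()
    if peak_val <= 0:
        raise NoPeakError("cumulative pain profile never positive")
    prof = np.clip(cum / peak_val, 0.0, None)
    peak_t = float(mt[int(np.argmax(cum))])
    truncated = prof[-1] > TRUNCATION_LEVEL

    # piecewise-linear profile on a 1-min grid, pinned to 0 at aura_start
    knots_t = np.concatenate(([annotation.aura_start], mt))
    knots_p = np.concatenate(([0.0], prof))
    order = np.argsort(knots_t)
    grid = np.arange(annotation.aura_start, annotation.pain_end + 1.0)
    pgrid = np.interp(grid, knots_t[order], knots_p[order])

    rise = grid <= peak_t
    fall = grid >= peak_t
    sigma1 = _fit_half_sigma(
        peak_t - grid[rise], pgrid[rise], _anchor_sigma(peak_t - annotation.aura_start)
    )
    sigma2 = _fit_half_sigma(
        grid[fall] - peak_t, pgrid[fall], _anchor_sigma(annotation.pain_end - peak_t)
    )
    return SymptomaticCurve(
        mu1=peak_t, sigma1=sigma1, mu2=peak_t, sigma2=sigma2, truncated=truncated
    )
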