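"""Preprocessing: multi-rate channels to a gap-free 1-sample/min frame.

Three stages mirror the acquisition pipeline:

* :func:`ecg_to_hr` — R-peak detection on the raw ECG (band-pass,
  differentiate, square, moving-window integrate, adaptive threshold) and
  conversion of RR intervals to an instantaneous heart-rate channel.
* :func:`synchronize` — anti-alias FIR low-pass (linear phase, delay
  compensated) and decimation of every channel to a shared 1-minute grid;
  sensor gaps propagate into a per-feature imputed mask.
* :func:`gp_fill` — Gaussian-process regression (squared-exponential +
  white-noise kernel, hyperparameters by marginal-likelihood maximization)
  fills the masked grid points with the posterior mean and records the
  posterior standard deviation as a confidence band.

Times are float minutes; raw channel sample times are float seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "ChannelSeries",
    "SynchronizedFrame",
    "synchronize",
    "gp_fill",
    "ecg_to_hr",
    "FEATURES",
]

#: canonical feature order of the synchronized frame.
FEATURES = ("TEMP", "EDA", "HR", "SpO2")

UNITS = {"TEMP": "degC", "EDA": "uS", "HR": "bpm", "SpO2": "%", "ECG": "raw"}

#: gaps longer than this (minutes) are left unimputed by gp_fill.
MAX_IMPUTABLE_GAP = 120.0


@dataclass
class ChannelSeries:
    """One sensor channel at its native rate.

    ``times`` are seconds from the recording origin, strictly increasing;
    samples falling inside ``gaps`` (minute intervals) have been removed.
    """

    name: str
    rate: float  # Hz
    times: np.ndarray  # seconds
    values: np.ndarray
    units: str = ""
    gaps: list[tuple[float, float]] = field(default_factory=list)  # minutes

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.units:
            self.units = UNITS.get(self.name, "")

    def copy(self) -> "ChannelSeries":
        return replace(
            self,
            times=self.times.copy(),
            values=self.values.copy(),
            gaps=list(self.gaps),
        )


@dataclass
class SynchronizedFrame:
    """Four features on a uniform 1-minute grid.

    ``imputed`` flags grid points that fall inside sensor gaps; ``confidence``
    holds the GP posterior standard deviation where a point was filled
    (0 where observed, NaN where still missing).  ``absent`` lists features
    for which no usable channel existed — consumed by the sensor-dependent
    model selection stage.
    """

    grid: np.ndarray  # minutes
    data: pd.DataFrame
    imputed: pd.DataFrame
    confidence: pd.DataFrame
    absent: frozenset = frozenset()

    def copy(self) -> "SynchronizedFrame":
        return SynchronizedFrame(
            grid=self.grid.copy(),
            data=self.data.copy(),
            imputed=self.imputed.copy(),
            confidence=self.confidence.copy(),
            absent=self.absent,
        )

    def features_array(self, names=FEATURES) -> np.ndarray:
        return self.data.loc[:, list(names)].to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        flags = self.imputed.apply(
            lambda row: "|".join(c for c in self.imputed.columns if row[c]), axis=1
        )
        out["imputed_flags"] = flags
        out.insert(0, "timestamp", self.grid)
        out.to_csv(path, index=False)


def _design_fir(decim: int, taps_per_factor: int = 10) -> np.ndarray:
    """Linear-phase Hamming FIR with cutoff at the target Nyquist (1/120 Hz)."""
    numtaps = taps_per_factor * decim + 1
    return signal.firwin(numtaps, 1.0 / decim, window="hamming")


def _channel_to_grid(ch: ChannelSeries, grid_min: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Filter+decimate one channel onto the minute grid; returns (values, imputed)."""
    n_out = grid_min.size
    decim = int(round(ch.rate * 60.0))
    start_s = grid_min[0] * 60.0
    # reconstruct the uniform native-rate sequence over the grid span,
    # linearly bridging gaps (those grid points are masked anyway)
    t_native = start_s + np.arange(int(round((n_out - 1) * 60.0 * ch.rate)) + 1) / ch.rate
    if ch.times.size < 2:
        return np.full(n_out, np.nan), np.ones(n_out, dtype=bool)
    x = np.interp(t_native, ch.times, ch.values)
    if decim <= 1:
        # already at (or below) the target rate: no filtering, direct sampling
        vals = np.interp(grid_min * 60.0, t_native, x)
    else:
        h = _design_fir(decim)
        vals = signal.resample_poly(x, up=1, down=decim, window=h, padtype="line")
        vals = vals[:n_out]
        if vals.size < n_out:
            vals = np.pad(vals, (0, n_out - vals.size), mode="edge")
    imputed = np.zeros(n_out, dtype=bool)
    for g0, g1 in ch.gaps:
        imputed |= (grid_min >= g0 - 0.5) & (grid_min <= g1 + 0.5)
    # span not covered by actual samples counts as gap too
    cov0, cov1 = ch.times[0] / 60.0, ch.times[-1] / 60.0
    imputed |= (grid_min < cov0 - 1.0) | (grid_min > cov1 + 1.0)
    return vals, imputed


def synchronize(
    channels: list[ChannelSeries],
    start: float | None = None,
    end: float | None = None,
) -> SynchronizedFrame:
    """Decimate all channels to a common 1-minute grid.

    Each channel is low-pass filtered with a linear-phase FIR whose cutoff
    sits at the 1/120 Hz Nyquist of the target rate (polyphase
    implementation, group delay compensated) and sampled on the shared grid.
    Channels named ``ECG`` are ignored here; convert with :func:`ecg_to_hr`
    first.  Features with no channel are marked absent and filled with NaN.
    """
    by_name = {c.name: c for c in channels if c.name in FEATURES}
    usable = [c for c in by_name.values() if c.times.size >= 2]
    if not usable:
        raise ValueError("no usable channels to synchronize")
    if start is None:
        start = max(np.ceil(c.times[0] / 60.0) for c in usable)
    if end is None:
        end = min(np.floor(c.times[-1] / 60.0) for c in usable)
    grid = np.arange(start, end + 1e-9)
    data, imputed, conf = {}, {}, {}
    absent = set()
    for name in FEATURES:
        ch = by_name.get(name)
        if ch is None or ch.times.size < 2:
            absent.add(name)
            data[name] = np.full(grid.size, np.nan)
            imputed[name] = np.ones(grid.size, dtype=bool)
            conf[name] = np.full(grid.size, np.nan)
            continue
        vals, mask = _channel_to_grid(ch, grid)
        vals = np.where(mask, np.nan, vals)
        data[name] = vals
        imputed[name] = mask
        conf[name] = np.where(mask, np.nan, 0.0)
    return SynchronizedFrame(
        grid=grid,
        data=pd.DataFrame(data, index=grid),
        imputed=pd.DataFrame(imputed, index=grid),
        confidence=pd.DataFrame(conf, index=grid),
        absent=frozenset(absent),
    )


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    runs = []
    in_run = False
    for idx, flag in enumerate(mask):
        if flag and not in_run:
            lo, in_run = idx, True
        elif not flag and in_run:
            runs.append((lo, idx))
            in_run = False
    if in_run:
        runs.append((lo, mask.size))
    return runs


def gp_fill(
    frame: SynchronizedFrame,
    max_gap: float = MAX_IMPUTABLE_GAP,
    min_observed: int = 30,
    context: float = 180.0,
    max_context_points: int = 200,
) -> SynchronizedFrame:
    """Fill masked grid points with the GP posterior mean.

    For each gap no longer than ``max_gap`` minutes, a GP with a
    squared-exponential + white-noise kernel is fitted on observed points
    within ``context`` minutes of the gap (hyperparameters by
    marginal-likelihood maximization) and the posterior mean/std written into
    the frame.  Observed samples are never modified.  Features with fewer
    than ``min_observed`` observed points are refused and stay absent.
    """
    out = frame.copy()
    absent = set(out.absent)
    for name in FEATURES:
        mask = out.imputed[name].to_numpy().copy()
        vals = out.data[name].to_numpy().copy()
        conf = out.confidence[name].to_numpy().copy()
        observed = ~mask & np.isfinite(vals)
        if observed.sum() < min_observed:
            absent.add(name)
            continue
        grid = out.grid
        for lo, hi in _gap_runs(mask):
            length = grid[hi - 1] - grid[lo] + 1.0 if hi > lo else 0.0
            if length > max_gap:
                continue
            c_lo, c_hi = grid[lo] - context, grid[min(hi, grid.size - 1)] + context
            ctx = observed & (grid >= c_lo) & (grid <= c_hi)
            idx = np.flatnonzero(ctx)
            if idx.size < 10:
                continue
            if idx.size > max_context_points:
                idx = idx[np.linspace(0, idx.size - 1, max_context_points).astype(int)]
            t_obs = grid[idx][:, None]
            y_obs = vals[idx]
            y_mu, y_sd = y_obs.mean(), max(y_obs.std(), 1e-9)
            kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
                length_scale=30.0, length_scale_bounds=(1.0, 1e4)
            ) + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-10, 1e1))
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=False, n_restarts_optimizer=0, alpha=1e-10
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(t_obs, (y_obs - y_mu) / y_sd)
            t_gap = grid[lo:hi][:, None]
            mean, std = gp.predict(t_gap, return_std=True)
            vals[lo:hi] = mean * y_sd + y_mu
            conf[lo:hi] = std * y_sd
        out.data[name] = vals
        out.confidence[name] = conf
    out.absent = frozenset(absent)
    return out


def ecg_to_hr(ecg: ChannelSeries, window_s: float = 10.0) -> ChannelSeries:
    """Derive a 1 Hz heart-rate channel from raw ECG by R-peak detection.

    Band-pass (5-15 Hz), differentiate, square, moving-window integrate,
    then adaptive thresholding against a rolling amplitude estimate; HR in
    bpm is 60/RR interpolated to 1 Hz.  Windows of ``window_s`` seconds with
    no detectable peak become gaps.  The result should be passed through
    :func:`synchronize` and :func:`gp_fill` like any other channel.
    """
    fs = ecg.rate
    if ecg.times.size < int(fs):
        return ChannelSeries(
            name="HR",
            rate=1.0,
            times=np.array([]),
            values=np.array([]),
            units="bpm",
            gaps=[(ecg.times[0] / 60.0, ecg.times[-1] / 60.0)] if ecg.times.size else [],
        )
    x = ecg.values - np.mean(ecg.values)
    nyq = fs / 2.0
    b, a = signal.butter(2, [min(5.0 / nyq, 0.9), min(15.0 / nyq, 0.95)], btype="band")
    filt = signal.filtfilt(b, a, x)
    sq = np.gradient(filt) ** 2
    win = max(int(0.15 * fs), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    # adaptive threshold: fraction of a slow rolling amplitude envelope
    env_win = max(int(2.0 * fs), 1)
    from scipy.ndimage import maximum_filter1d

    env = maximum_filter1d(integ, size=env_win)
    thresh = 0.3 * np.maximum(env, 1e-12 + 0.1 * integ.max())
    peaks, _ = signal.find_peaks(integ, height=thresh, distance=int(0.25 * fs))
    peak_t = ecg.times[0] + peaks / fs

    t0, t1 = ecg.times[0], ecg.times[-1]
    grid_s = np.arange(np.ceil(t0), np.floor(t1) + 1e-9)
    if peak_t.size < 3:
        return ChannelSeries(
            name="HR", rate=1.0, times=np.array([]), values=np.array([]),
            units="bpm", gaps=[(t0 / 60.0, t1 / 60.0)],
        )
    rr = np.diff(peak_t)
    hr = np.clip(60.0 / np.maximum(rr, 1e-3), 20.0, 240.0)
    hr_t = 0.5 * (peak_t[:-1] + peak_t[1:])
    hr_grid = np.interp(grid_s, hr_t, hr)
    # windows without any detected peak become gaps (minutes)
    gaps: list[tuple[float, float]] = []
    edges = np.arange(t0, t1, window_s)
    for w0 in edges:
        if not np.any((peak_t >= w0) & (peak_t < w0 + window_s)):
            gaps.append((w0 / 60.0, (w0 + window_s) / 60.0))
    # merge adjacent gap windows
    merged: list[tuple[float, float]] = []
    for g in gaps:
        if merged and g[0] <= merged[-1][1] + 1e-9:
            merged[-1] = (merged[-1][0], g[1])
        else:
            merged.append(g)
    return ChannelSeries(
        name="HR", rate=1.0, times=grid_s, values=hr_grid, units="bpm", gaps=merged
    )
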