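"""Synthetic ambulatory patient generator with known ground truth.

No clinical recordings accompany the modeling method, so every downstream
stage is exercised on generated patients: four channels at their native
acquisition rates (TEMP/EDA at 1 Hz, SpO2 at 3 Hz, HR at 1 Hz or a raw
250 Hz ECG), each the sum of a per-channel baseline, a 24-hour circadian
sinusoid, a slow random walk, measurement noise, and a linear readout of a
stable first-order latent state excited by a pre-ictal driver that starts a
configurable lead time before each pain onset.  Ground truth (event
timestamps, driver trace, true symptomatic curves, annotations) is returned
alongside, and gaps/saturations can be injected afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from migrainecast.pain import PainAnnotation, SymptomaticCurve, evaluate_curve
from migrainecast.repair import ChannelSeries

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "MigraineEvent",
    "RawRecording",
    "CapacityError",
    "generate_patient",
    "inject_gaps",
    "synthesize_ecg",
    "SATURATION_VALUES",
    "LOSS_VALUE",
]

#: per-feature saturation fault constants (TEMP degC, EDA uS, HR bpm, SpO2 %).
SATURATION_VALUES = {"TEMP": 35.0, "EDA": 25.0, "HR": 100.0, "SpO2": 80.0}
#: sensor-loss fault constant.
LOSS_VALUE = 0.0

# per-channel generator profile: baseline, circadian amplitude, pre-ictal
# effect gain, random-walk step sd (per minute), native rate in Hz
_PROFILES = {
    "TEMP": dict(baseline=33.5, circadian=0.4, gain=0.9, rw=0.002, rate=1.0),
    "EDA": dict(baseline=4.0, circadian=0.8, gain=2.5, rw=0.005, rate=1.0),
    "HR": dict(baseline=72.0, circadian=4.0, gain=10.0, rw=0.02, rate=1.0),
    "SpO2": dict(baseline=97.0, circadian=0.4, gain=-1.8, rw=0.002, rate=3.0),
}

_ANCHOR = math.sqrt(2.0 * math.log(20.0))  # curve = 0.05 at the boundaries


class CapacityError(ValueError):
    """Requested events cannot be placed without overlap in the duration."""


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the seed fully determines the output."""

    duration_days: float = 14.0
    n_migraines: int = 6
    lead_time: float = 60.0  # minutes the driver precedes pain onset
    attack_duration_range: tuple[float, float] = (120.0, 300.0)
    aura_duration_range: tuple[float, float] = (20.0, 45.0)
    snr_db: float | None = 20.0  # None or inf disables noise
    gap_rate: float = 2.0  # expected gaps per day per channel
    gap_length_range: tuple[float, float] = (5.0, 30.0)
    seed: int = 0
    circadian_scale: float = 1.0
    random_walk_scale: float = 1.0
    include_ecg: bool = False
    active_channels: tuple[str, ...] = ("TEMP", "EDA", "HR", "SpO2")
    #: channels generated without the pre-ictal readout (irrelevant features)
    unresponsive_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.lead_time <= 0:
            raise ValueError("lead_time must be positive")
        if self.n_migraines < 0:
            raise ValueError("n_migraines must be non-negative")
        if self.gap_rate < 0:
            raise ValueError("gap_rate must be non-negative")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")

    @property
    def noise_free(self) -> bool:
        return self.snr_db is None or np.isinf(self.snr_db)


@dataclass
class MigraineEvent:
    aura_start: float
    pain_start: float
    peak_time: float
    pain_end: float

    def __post_init__(self) -> None:
        if not (self.aura_start < self.pain_start < self.peak_time < self.pain_end):
            raise ValueError("event timestamps must be strictly ordered")


@dataclass
class GroundTruth:
    """Everything the generator knows that a real study would not."""

    events: list[MigraineEvent]
    driver_grid: np.ndarray  # minutes
    driver: np.ndarray  # latent pre-ictal driver values
    true_curves: list[SymptomaticCurve]
    annotations: list[PainAnnotation]

    def pain_series(self, grid: np.ndarray) -> np.ndarray:
        """Ground-truth symptomatic curve evaluated on ``grid`` (minutes)."""
        y = np.zeros(np.asarray(grid, dtype=float).size)
        for c in self.true_curves:
            y = np.maximum(y, evaluate_curve(c, grid))
        return y


@dataclass
class RawRecording:
    channels: dict[str, ChannelSeries]
    duration_min: float
    seed: int = 0
    gaps_injected: bool = False

    def copy(self) -> "RawRecording":
        return RawRecording(
            channels={k: c.copy() for k, c in self.channels.items()},
            duration_min=self.duration_min,
            seed=self.seed,
            gaps_injected=self.gaps_injected,
        )


def _place_events(cfg: SyntheticConfig, rng: np.random.Generator) -> list[MigraineEvent]:
    total = cfg.duration_days * 1440.0
    lo_guard = cfg.lead_time + 240.0  # context before aura
    post_guard = 120.0
    events: list[MigraineEvent] = []
    max_dur = cfg.attack_duration_range[1] + cfg.aura_duration_range[1]
    if cfg.n_migraines * (lo_guard + max_dur + post_guard) > total:
        raise CapacityError(
            f"{cfg.n_migraines} events do not fit in {cfg.duration_days} days"
        )
    for _ in range(500):
        starts = np.sort(
            rng.uniform(lo_guard + cfg.aura_duration_range[1],
                        total - max_dur - post_guard, size=cfg.n_migraines)
        )
        if cfg.n_migraines < 2 or np.all(
            np.diff(starts) > lo_guard + max_dur + post_guard
        ):
            events = []
            for s in starts:
                dur = rng.uniform(*cfg.attack_duration_range)
                aura = rng.uniform(*cfg.aura_duration_range)
                peak = s + 0.35 * dur
                events.append(
                    MigraineEvent(
                        aura_start=s - aura, pain_start=s, peak_time=peak,
                        pain_end=s + dur,
                    )
                )
            return events
    raise CapacityError("could not place non-overlapping events; reduce n_migraines")


def _true_curve(ev: MigraineEvent) -> SymptomaticCurve:
    sigma1 = max(ev.peak_time - ev.aura_start, 1.0) / _ANCHOR
    sigma2 = max(ev.pain_end - ev.peak_time, 1.0) / _ANCHOR
    return SymptomaticCurve(mu1=ev.peak_time, sigma1=sigma1, mu2=ev.peak_time, sigma2=sigma2)


def _annotation_for(ev: MigraineEvent, curve: SymptomaticCurve,
                    rng: np.random.Generator, n_marks: int = 9) -> PainAnnotation:
    # marks sampled along the attack; deltas are successive curve increments
    ts = np.sort(rng.uniform(ev.aura_start + 1.0, ev.pain_end - 1.0, size=n_marks))
    ts = np.unique(np.round(ts))
    levels = evaluate_curve(curve, ts)
    deltas = np.diff(np.concatenate(([0.0], levels)))
    scale = rng.uniform(3.0, 8.0)  # unlimited subjective scale
    marks = [(float(t), float(d * scale)) for t, d in zip(ts, deltas)]
    return PainAnnotation(
        aura_start=ev.aura_start, pain_start=ev.pain_start, pain_end=ev.pain_end,
        marks=marks, global_index=int(rng.integers(3, 10)),
    )


def generate_patient(config: SyntheticConfig) -> tuple[RawRecording, GroundTruth]:
    """Generate one patient's raw recording plus its ground truth.

    Channels are emitted at their native rates with no gaps (use
    :func:`inject_gaps` afterwards).  With ``include_ecg=True`` the HR
    channel is replaced by a 250 Hz template-based ECG whose instantaneous
    rate follows the target heart rate.
    """
    rng = np.random.default_rng(config.seed)
    total_min = config.duration_days * 1440.0
    grid = np.arange(0.0, total_min)  # 1-min ground-truth grid

    events = _place_events(config, rng) if config.n_migraines else []
    curves = [_true_curve(ev) for ev in events]
    annotations = [_annotation_for(ev, c, rng) for ev, c in zip(events, curves)]

    # latent pre-ictal driver: the future pain curve, advanced by lead_time
    driver = np.zeros(grid.size)
    for c in curves:
        driver = np.maximum(driver, evaluate_curve(c, grid + config.lead_time))

    channels: dict[str, ChannelSeries] = {}
    for name in config.active_channels:
        prof = _PROFILES[name]
        # stable first-order latent filter, spectral radius < 0.98 per seed
        tau = rng.uniform(2.0, 6.0)
        a = math.exp(-1.0 / tau)
        x = np.empty(grid.size)
        acc = 0.0
        for t in range(grid.size):
            acc = a * acc + (1.0 - a) * driver[t]
            x[t] = acc
        phase = rng.uniform(0.0, 1440.0)
        circ = config.circadian_scale * prof["circadian"] * np.sin(
            2.0 * np.pi * (grid - phase) / 1440.0
        )
        walk = np.cumsum(
            rng.standard_normal(grid.size)
            * prof["rw"] * config.random_walk_scale
        )
        responsive = name not in config.unresponsive_channels
        minute_vals = prof["baseline"] + circ + walk
        if responsive:
            minute_vals = minute_vals + prof["gain"] * x
        rate = prof["rate"]
        t_native = np.arange(0.0, total_min * 60.0, 1.0 / rate)
        vals = np.interp(t_native / 60.0, grid, minute_vals)
        if not config.noise_free:
            sigma = abs(prof["gain"]) * 10.0 ** (-config.snr_db / 20.0)
            vals = vals + rng.standard_normal(t_native.size) * sigma
        channels[name] = ChannelSeries(name=name, rate=rate, times=t_native, values=vals)

    if config.include_ecg and "HR" in channels:
        hr_minutes = np.interp(grid, channels["HR"].times / 60.0, channels["HR"].values)
        channels["ECG"] = synthesize_ecg(hr_minutes, rng=rng)
        del channels["HR"]

    recording = RawRecording(channels=channels, duration_min=total_min, seed=config.seed)
    truth = GroundTruth(
        events=events, driver_grid=grid, driver=driver,
        true_curves=curves, annotations=annotations,
    )
    return recording, truth


def synthesize_ecg(hr_minutes: np.ndarray, fs: float = 250.0,
                   rng: np.random.Generator | None = None) -> ChannelSeries:
    """Template-based quasi-periodic pulse train at instantaneous rate ``hr``.

    Not clinically realistic: a Gaussian R-spike per beat is enough to
    exercise the peak-detection path of :func:`migrainecast.repair.ecg_to_hr`.
    """
    hr_minutes = np.asarray(hr_minutes, dtype=float)
    total_s = hr_minutes.size * 60.0
    t = np.arange(0.0, total_s, 1.0 / fs)
    hr_t = np.interp(t / 60.0, np.arange(hr_minutes.size, dtype=float), hr_minutes)
    phase = np.cumsum(hr_t / 60.0) / fs  # beats elapsed
    beat_idx = np.flatnonzero(np.diff(np.floor(phase)) > 0)
    sig = np.zeros(t.size)
    half = int(0.02 * fs)
    template = np.exp(-0.5 * (np.arange(-half, half + 1) / (0.01 * fs)) ** 2)
    for b in beat_idx:
        lo, hi = max(b - half, 0), min(b + half + 1, t.size)
        sig[lo:hi] += template[half - (b - lo): half + (hi - b)]
    if rng is not None:
        sig = sig + 0.01 * rng.standard_normal(t.size)
    return ChannelSeries(name="ECG", rate=fs, times=t, values=sig, units="raw")


def inject_gaps(recording: RawRecording, config: SyntheticConfig) -> RawRecording:
    """Remove samples inside randomly drawn gap intervals (non-destructive).

    Gap starts follow a Poisson process with ``gap_rate`` per day per
    channel; lengths are uniform in ``gap_length_range`` minutes.  The drawn
    intervals are recorded on each channel's gap list.
    """
    if config.gap_rate < 0:
        raise ValueError("gap_rate must be non-negative")
    if recording.gaps_injected or any(c.gaps for c in recording.channels.values()):
        raise ValueError("recording already carries gap annotations")
    out = recording.copy()
    if config.gap_rate == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBADCAB]))
    duration_days = recording.duration_min / 1440.0
    for name in sorted(out.channels):
        ch = out.channels[name]
        n_gaps = rng.poisson(config.gap_rate * duration_days)
        if n_gaps == 0:
            continue
        starts = np.sort(rng.uniform(0.0, recording.duration_min, size=n_gaps))
        lengths = rng.uniform(*config.gap_length_range, size=n_gaps)
        merged: list[tuple[float, float]] = []
        for s, l in zip(starts, lengths):
            e = min(s + l, recording.duration_min)
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        keep = np.ones(ch.times.size, dtype=bool)
        for g0, g1 in merged:
            keep &= ~((ch.times >= g0 * 60.0) & (ch.times < g1 * 60.0))
        out.channels[name] = ChannelSeries(
            name=ch.name, rate=ch.rate, times=ch.times[keep],
            values=ch.values[keep], units=ch.units, gaps=merged,
        )
    out.gaps_injected = True
    return out
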