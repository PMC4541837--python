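"""Serialization: channel CSVs, annotation JSON, frames, models, hierarchies.

On disk every timestamp is ISO-8601; in memory times are float minutes (or
seconds for raw channel samples) from a recording origin, which is stored in
the files so round trips are exact to CSV precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from migrainecast.pain import PainAnnotation
from migrainecast.repair import ChannelSeries, SynchronizedFrame
from migrainecast.ssm import StateSpaceModel
from migrainecast.synthetic import GroundTruth, MigraineEvent, RawRecording

DEFAULT_ORIGIN = pd.Timestamp("2024-01-01T00:00:00")

__all__ = [
    "write_channel_csv",
    "read_channel_csv",
    "write_recording",
    "write_annotations",
    "read_annotations",
    "write_ground_truth",
    "read_ground_truth",
    "write_frame_csv",
    "read_frame_csv",
    "write_models",
    "read_models",
]


def _iso(minutes_or_seconds: np.ndarray, origin: pd.Timestamp, unit: str) -> pd.DatetimeIndex:
    return origin + pd.to_timedelta(minutes_or_seconds, unit=unit)


def write_channel_csv(ch: ChannelSeries, path, origin: pd.Timestamp = DEFAULT_ORIGIN) -> None:
    ts = _iso(ch.times, origin, "s")
    pd.DataFrame({"timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                  "value": ch.values}).to_csv(path, index=False)


def read_channel_csv(path, name: str, origin: pd.Timestamp = DEFAULT_ORIGIN) -> ChannelSeries:
    """Load a channel CSV; rate is inferred from the median sample spacing
    and gaps are reconstructed from timestamp jumps larger than 2 samples."""
    df = pd.read_csv(path)
    t = (pd.to_datetime(df["timestamp_iso8601"]) - origin).dt.total_seconds().to_numpy()
    v = df["value"].to_numpy(dtype=float)
    dt = np.median(np.diff(t)) if t.size > 1 else 1.0
    rate = 1.0 / dt
    gaps = []
    jumps = np.flatnonzero(np.diff(t) > 2.5 * dt)
    for j in jumps:
        gaps.append(((t[j] + dt) / 60.0, t[j + 1] / 60.0))
    return ChannelSeries(name=name, rate=rate, times=t, values=v, gaps=gaps)


def write_recording(rec: RawRecording, outdir, origin: pd.Timestamp = DEFAULT_ORIGIN) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ch in rec.channels.items():
        write_channel_csv(ch, outdir / f"{name}.csv", origin)


def _ann_to_dict(a: PainAnnotation, origin: pd.Timestamp) -> dict:
    def iso(m):
        return (origin + pd.to_timedelta(m, unit="m")).isoformat()

    return {
        "aura_start": iso(a.aura_start),
        "pain_start": iso(a.pain_start),
        "pain_end": iso(a.pain_end),
        "marks": [{"t": iso(t), "delta": d} for t, d in a.marks],
        "global_index": a.global_index,
    }


def _ann_from_dict(d: dict, origin: pd.Timestamp) -> PainAnnotation:
    def mins(s):
        return (pd.Timestamp(s) - origin).total_seconds() / 60.0

    return PainAnnotation(
        aura_start=mins(d["aura_start"]),
        pain_start=mins(d["pain_start"]),
        pain_end=mins(d["pain_end"]),
        marks=[(mins(m["t"]), float(m["delta"])) for m in d["marks"]],
        global_index=int(d.get("global_index", 5)),
    )


def write_annotations(annotations: list[PainAnnotation], path,
                      origin: pd.Timestamp = DEFAULT_ORIGIN) -> None:
    with open(path, "w") as fh:
        json.dump([_ann_to_dict(a, origin) for a in annotations], fh, indent=1)


def read_annotations(path, origin: pd.Timestamp = DEFAULT_ORIGIN) -> list[PainAnnotation]:
    with open(path) as fh:
        return [_ann_from_dict(d, origin) for d in json.load(fh)]


def write_ground_truth(truth: GroundTruth, path,
                       origin: pd.Timestamp = DEFAULT_ORIGIN) -> None:
    def iso(m):
        return (origin + pd.to_timedelta(float(m), unit="m")).isoformat()

    payload = {
        "events": [
            {"aura_start": iso(e.aura_start), "pain_start": iso(e.pain_start),
             "peak_time": iso(e.peak_time), "pain_end": iso(e.pain_end)}
            for e in truth.events
        ],
        "true_curves": [
            {"mu1": c.mu1, "sigma1": c.sigma1, "mu2": c.mu2, "sigma2": c.sigma2}
            for c in truth.true_curves
        ],
        "driver_grid": truth.driver_grid.tolist(),
        "driver": truth.driver.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path, origin: pd.Timestamp = DEFAULT_ORIGIN) -> dict:
    with open(path) as fh:
        payload = json.load(fh)

    def mins(s):
        return (pd.Timestamp(s) - origin).total_seconds() / 60.0

    payload["events"] = [
        MigraineEvent(
            aura_start=mins(e["aura_start"]), pain_start=mins(e["pain_start"]),
            peak_time=mins(e["peak_time"]), pain_end=mins(e["pain_end"]),
        )
        for e in payload["events"]
    ]
    return payload


def write_frame_csv(frame: SynchronizedFrame, path) -> None:
    frame.to_csv(path)


def read_frame_csv(path) -> SynchronizedFrame:
    df = pd.read_csv(path)
    grid = df["timestamp"].to_numpy(dtype=float)
    features = [c for c in df.columns if c not in ("timestamp", "imputed_flags")]
    data = df[features].astype(float)
    data.index = grid
    flags = df.get("imputed_flags")
    imputed = pd.DataFrame(False, index=grid, columns=features)
    if flags is not None:
        for i, cell in enumerate(flags.fillna("")):
            for f in str(cell).split("|"):
                if f in features:
                    imputed.iloc[i, imputed.columns.get_loc(f)] = True
    conf = pd.DataFrame(0.0, index=grid, columns=features)
    absent = frozenset(f for f in features if data[f].isna().all())
    return SynchronizedFrame(grid=grid, data=data, imputed=imputed,
                             confidence=conf, absent=absent)


def write_models(models: dict[int, StateSpaceModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): m.to_dict() for k, m in models.items()}, fh)


def read_models(path) -> dict[int, StateSpaceModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): StateSpaceModel.from_dict(v) for k, v in raw.items()}
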