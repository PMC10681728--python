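"""Readers and writers for the package's on-disk formats.

Traces, tracks and counts travel as plain CSV (pandas); image stacks and
kymographs as (multi-page) TIFF (tifffile); configuration, calibration and
simulation ground truth as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .config import ImagingConfig
from .kymo import Kymograph, TranslocationTrack
from .outcomes import ColonyCounts
from .photobleach import IntensityTrace, PhotobleachCalibration, StepEvent

PathLike = Union[str, Path]


# -- traces -----------------------------------------------------------------

def write_traces_csv(path: PathLike, traces: Sequence[IntensityTrace]) -> None:
    """CSV columns: trace_id, frame, time_s, intensity."""
    rows = []
    for k, tr in enumerate(traces):
        label = tr.label if tr.label is not None else str(k)
        for f, v in enumerate(tr.values):
            rows.append((label, f, f * tr.frame_interval, v))
    pd.DataFrame(
        rows, columns=["trace_id", "frame", "time_s", "intensity"]
    ).to_csv(path, index=False)


def read_traces_csv(path: PathLike, background: float = 0.0) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    traces = []
    for label, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        t = g["time_s"].to_numpy()
        interval = float(np.median(np.diff(t))) if len(t) > 1 else 0.2
        traces.append(
            IntensityTrace(
                values=g["intensity"].to_numpy(dtype=float),
                frame_interval=interval,
                background=background,
                label=str(label),
            )
        )
    return traces


def write_steps_csv(path: PathLike, steps_per_trace: dict) -> None:
    """CSV columns: trace_id, frame, amplitude, direction."""
    rows = [
        (label, e.frame, e.amplitude, e.direction)
        for label, events in steps_per_trace.items()
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["trace_id", "frame", "amplitude", "direction"]
    ).to_csv(path, index=False)


# -- tracks -----------------------------------------------------------------

def write_track_csv(path: PathLike, track: TranslocationTrack) -> None:
    """CSV columns: frame, time_s, position_px, segment_label."""
    labels = np.array(["unclassified"] * track.n_frames, dtype=object)
    for seg in track.segments:
        labels[seg.start : seg.stop] = seg.label
    pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "time_s": track.times,
            "position_px": track.positions,
            "segment_label": labels,
        }
    ).to_csv(path, index=False)


def read_track_csv(path: PathLike) -> TranslocationTrack:
    df = pd.read_csv(path).sort_values("frame")
    return TranslocationTrack(
        positions=df["position_px"].to_numpy(dtype=float),
        times=df["time_s"].to_numpy(dtype=float),
    )


# -- images -----------------------------------------------------------------

def write_tiff(path: PathLike, data: np.ndarray) -> None:
    """Write a kymograph (2-D) or stack (3-D, paged) as float32 TIFF."""
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(path)


def write_kymograph(path: PathLike, kymo: Kymograph) -> None:
    write_tiff(path, kymo.data)


def read_kymograph(path: PathLike, config: ImagingConfig) -> Kymograph:
    return Kymograph(
        data=read_tiff(path),
        frame_interval=config.frame_interval,
        bp_per_pixel=config.bp_per_pixel,
        roi=str(path),
    )


# -- points / intensities ----------------------------------------------------

def write_points_csv(path: PathLike, points: np.ndarray, intensities=None) -> None:
    """CSV columns: position_y_px, position_x_px[, intensity]."""
    points = np.atleast_2d(points)
    d = {"position_y_px": points[:, 0], "position_x_px": points[:, 1]}
    if intensities is not None:
        d["intensity"] = np.asarray(intensities)
    pd.DataFrame(d).to_csv(path, index=False)


def read_points_csv(path: PathLike):
    df = pd.read_csv(path)
    pts = df[["position_y_px", "position_x_px"]].to_numpy(dtype=float)
    inten = df["intensity"].to_numpy(dtype=float) if "intensity" in df else None
    return pts, inten


# -- counts -----------------------------------------------------------------

def write_counts_csv(path: PathLike, counts: ColonyCounts) -> None:
    pd.DataFrame(
        {
            "replicate": np.arange(counts.n_replicates),
            "selective_count": counts.selective,
            "nonselective_count": counts.nonselective,
            "dilution_factor": counts.dilution_factor,
            "volume_selective_ul": counts.volume_selective_ul,
            "volume_nonselective_ul": counts.volume_nonselective_ul,
        }
    ).to_csv(path, index=False)


def read_counts_csv(path: PathLike) -> ColonyCounts:
    df = pd.read_csv(path)
    return ColonyCounts(
        selective=df["selective_count"].to_numpy(dtype=int),
        nonselective=df["nonselective_count"].to_numpy(dtype=int),
        dilution_factor=float(df["dilution_factor"].iloc[0]),
        volume_selective_ul=float(df.get("volume_selective_ul", pd.Series([30.0])).iloc[0]),
        volume_nonselective_ul=float(
            df.get("volume_nonselective_ul", pd.Series([30.0])).iloc[0]
        ),
    )


# -- JSON sidecars ----------------------------------------------------------

def write_json(path: PathLike, obj) -> None:
    if hasattr(obj, "to_jsonable"):
        obj = obj.to_jsonable()
    elif hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def read_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_calibration(path: PathLike, calib: PhotobleachCalibration) -> None:
    write_json(
        path,
        {
            "unit_mean": calib.unit_mean,
            "unit_sd": calib.unit_sd,
            "n_events": calib.n_events,
        },
    )


def read_calibration(path: PathLike) -> PhotobleachCalibration:
    d = read_json(path)
    return PhotobleachCalibration(
        unit_mean=d["unit_mean"], unit_sd=d["unit_sd"], n_events=d["n_events"]
    )
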