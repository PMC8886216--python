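"""Reading and writing frame stacks, traces and analysis outputs.

Frame stacks are read from multi-page TIFF, raw NumPy array files (.npy /
.npz) or, read-only, from AVI/MP4 containers. Intensities are converted to a
floating representation but never rescaled: the composite signal is
scale-covariant, so ratios and times are unaffected by the native scale,
while absolute values remain comparable across files of the same format.
Color input is converted to luminance by channel averaging.

TIFF round-trips store the frame rate in the ImageJ ``finterval`` metadata
field so stacks written here are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import BeatTable, PeakRecord
from .composite import CompositeTrace, FrameStack
from .traces import ShorteningTrace

__all__ = [
    "read_stack",
    "write_stack",
    "write_beat_table",
    "read_beat_table",
    "read_shortening_csv",
    "write_trace_csv",
]

_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv"}


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:  # (t, h, w, channels) -> luminance by channel average
        return frames.astype(np.float32).mean(axis=-1)
    return frames


def read_stack(path: str | Path, fps_override: float | None = None) -> FrameStack:
    """Read a frame stack from TIFF, raw array file or video container.

    ``fps_override`` takes precedence over any frame rate found in the file
    metadata; it is required for formats that carry none (.npy, plain TIFF).

    Raises
    ------
    FileNotFoundError, ValueError
        Unreadable file, fewer than 2 frames, or missing frame rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    fps = fps_override

    if suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = tif.imagej_metadata or {}
        if fps is None and meta.get("finterval"):
            fps = 1.0 / float(meta["finterval"])
    elif suffix == ".npy":
        frames = np.load(path)
    elif suffix == ".npz":
        with np.load(path) as data:
            frames = data["frames"]
            if fps is None and "fps" in data:
                fps = float(data["fps"])
    elif suffix in _VIDEO_SUFFIXES:
        import imageio.v3 as iio

        frames = iio.imread(path)
        if fps is None:
            meta = iio.immeta(path)
            fps = float(meta["fps"]) if "fps" in meta else None
    else:
        raise ValueError(f"unsupported frame-stack format: {path.name}")

    frames = _to_grayscale(np.asarray(frames))
    if frames.ndim == 2:
        raise ValueError(f"{path.name}: fewer than 2 frames")
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError(f"{path.name}: fewer than 2 frames")
    if fps is None:
        raise ValueError(
            f"{path.name} carries no frame rate; pass fps_override"
        )
    return FrameStack(frames=frames, fps=float(fps))


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack to multi-page TIFF (with fps metadata) or .npz."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path,
            stack.frames.astype(np.float32),
            imagej=True,
            metadata={"finterval": 1.0 / stack.fps, "axes": "TYX"},
        )
    elif suffix == ".npz":
        np.savez(path, frames=stack.frames, fps=stack.fps)
    else:
        raise ValueError(f"unsupported output format: {path.name}")


def write_beat_table(table: BeatTable, base: str | Path) -> None:
    """Write a beat table to ``<base>.peaks.csv``, ``<base>.beats.csv`` and
    ``<base>.summary.json``.

    CSVs are UTF-8 with '.' decimal separators; an empty table produces
    header-only CSVs and null summaries. Peak and beat indices are 1-based
    in the files.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    peaks = table.peaks_frame()
    peaks.insert(0, "peak", np.arange(1, len(peaks) + 1))
    peaks.to_csv(base.with_suffix(base.suffix + ".peaks.csv"), index=False)
    table.beats.to_csv(base.with_suffix(base.suffix + ".beats.csv"), index=False)
    with open(base.with_suffix(base.suffix + ".summary.json"), "w") as fh:
        json.dump(table.summaries, fh, indent=2)


def read_beat_table(base: str | Path) -> BeatTable:
    """Read back a beat table written by :func:`write_beat_table`."""
    base = Path(base)
    peaks_df = pd.read_csv(base.with_suffix(base.suffix + ".peaks.csv"))
    beats = pd.read_csv(base.with_suffix(base.suffix + ".beats.csv"))
    with open(base.with_suffix(base.suffix + ".summary.json")) as fh:
        summaries = json.load(fh)
    peaks = [
        PeakRecord(
            index=int(row["index"]),
            time=float(row["time"]),
            amplitude=float(row["amplitude"]),
            ratio_drop1=float(row["ratio_drop1"]),
            ratio_drop2=float(row["ratio_drop2"]),
            label=str(row["label"]),
        )
        for _, row in peaks_df.iterrows()
    ]
    return BeatTable(peaks=peaks, beats=beats, summaries=summaries)


def read_shortening_csv(path: str | Path) -> ShorteningTrace:
    """Read a two-column (time_s, length) CSV as a shortening trace.

    The sampling must be uniform; dt is taken as the median time step and a
    >1% deviation anywhere raises an error.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: time_s, length")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.abs(steps - dt).max() > 0.01 * dt:
        raise ValueError("trace sampling must be uniform")
    return ShorteningTrace(values=v, dt=dt, t0=float(t[0]))


def write_trace_csv(trace: CompositeTrace, path: str | Path) -> None:
    """Export a composite trace as a two-column (time_s, delta_s) CSV."""
    pd.DataFrame({"time_s": trace.times, "delta_s": trace.values}).to_csv(
        path, index=False
    )
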