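"""Beat measures for 1-D contraction traces (sarcomere length / cell length).

The rectified first-difference derivative |dL/dt| of a shortening trace has
the same double-peak-per-beat structure as the video composite signal: a
contraction velocity peak followed by a relaxation velocity peak. The video
classifier and beat measures therefore apply unchanged, which lets isolated
cell shortening recordings (e.g. drug-treatment comparisons) be analyzed with
the same T / delta_rc / ratio_cr vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import BeatTable, beat_measures, classify_peaks, detect_peaks
from .composite import CompositeTrace

__all__ = ["ShorteningTrace", "rectified_derivative", "trace_measures"]


@dataclass
class ShorteningTrace:
    """Evenly sampled cell-length or sarcomere-length samples.

    Values may be in micrometres or normalized units; the beat measures are
    invariant to adding a constant and to sign flips (shortening vs
    lengthening convention), since only |dL/dt| is used.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 3:
            raise ValueError("a shortening trace needs at least 3 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("trace values must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.dt


def rectified_derivative(trace: ShorteningTrace) -> CompositeTrace:
    """|dL/dt| by first differences.

    The output has N-1 samples; difference k is assigned to the time of
    sample k+1, matching the later-frame convention of the video composite
    signal.
    """
    if len(trace.values) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    vals = np.abs(np.diff(trace.values)) / trace.dt
    times = trace.times[1:]
    return CompositeTrace(values=vals, times=times, tau_frames=1, fps=1.0 / trace.dt)


def trace_measures(
    trace: ShorteningTrace,
    skip_first_beats: int = 1,
    min_prominence_frac: float = 0.1,
    min_separation_s: float = 0.05,
    random_state: int = 0,
) -> BeatTable:
    """Beat measures of a 1-D contraction trace.

    Runs :func:`rectified_derivative` and the video beat pipeline, then drops
    the first ``skip_first_beats`` beats before computing summaries — the
    first contraction of a recording is often a transient (the convention
    used when comparing short paced recordings).

    Raises
    ------
    ValueError
        If fewer than ``skip_first_beats + 1`` beats are found.
    """
    deriv = rectified_derivative(trace)
    peaks = detect_peaks(
        deriv,
        min_prominence_frac=min_prominence_frac,
        min_separation_s=min_separation_s,
    )
    labeled = classify_peaks(peaks, deriv, random_state=random_state)
    table = beat_measures(labeled)
    if table.n_beats < skip_first_beats + 1:
        raise ValueError(
            f"found {table.n_beats} beats, need more than skip_first_beats="
            f"{skip_first_beats}"
        )
    if skip_first_beats:
        from .beats import _summaries

        table.beats = table.beats.iloc[skip_first_beats:].reset_index(drop=True)
        table.beats["beat"] = np.arange(1, len(table.beats) + 1)
        table.summaries = _summaries(table.beats)
    return table
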