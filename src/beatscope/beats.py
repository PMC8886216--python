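"""Peak detection, contraction/relaxation classification and beat measures.

Within one beat the composite motion signal shows two maxima: a sharp,
usually taller peak produced by the contraction (shortening) phase and a
wider, lower peak produced by relaxation (re-lengthening). Classifying the
detected peaks into those two families gives three beat-wise measures:

* ``T`` — beat period, time between consecutive contraction peaks (s);
* ``delta_rc`` — time from a contraction peak to the following relaxation
  peak (s);
* ``ratio_cr`` — contraction peak amplitude over relaxation peak amplitude
  (dimensionless; > 1 means contraction is faster than relaxation).

Classification uses three criteria: contraction and relaxation peaks
alternate in time; the two families separate as clusters in the
(inter-peak interval, peak amplitude) plane; and the signal drops faster
around contraction peaks, quantified by ``ratio_drop`` — the mean of the
samples k positions before and after a peak divided by the peak value.
All criteria are ratio- or time-based, so the labels are invariant to
intensity scaling of the underlying video.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .composite import CompositeTrace

__all__ = [
    "PeakRecord",
    "BeatTable",
    "detect_peaks",
    "ratio_drop",
    "classify_peaks",
    "beat_measures",
    "estimate_noise_floor",
    "trend_vs_period",
]

CONTRACTION = "contraction"
RELAXATION = "relaxation"
UNCLASSIFIED = "unclassified"

#: peaks closer than this many samples to either trace end cannot carry a
#: ratio_drop2 and are excluded from classification
_BOUNDARY_K = 2


@dataclass
class PeakRecord:
    """One detected local maximum of a composite trace."""

    index: int
    time: float
    amplitude: float
    ratio_drop1: float
    ratio_drop2: float
    label: str = UNCLASSIFIED


@dataclass
class BeatTable:
    """Classified peaks, per-beat measures and acquisition summaries.

    ``beats`` has one row per contraction peak paired with the *next*
    relaxation peak; ``summaries`` holds unweighted means and sample SDs of
    T, delta_rc and ratio_cr over the retained beats (None when undefined).
    """

    peaks: list[PeakRecord] = field(default_factory=list)
    beats: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["beat", "t_contraction", "T", "delta_rc", "ratio_cr"]
        )
    )
    summaries: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def peaks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "index": p.index,
                    "time": p.time,
                    "amplitude": p.amplitude,
                    "ratio_drop1": p.ratio_drop1,
                    "ratio_drop2": p.ratio_drop2,
                    "label": p.label,
                }
                for p in self.peaks
            ],
            columns=["index", "time", "amplitude", "ratio_drop1", "ratio_drop2", "label"],
        )


def ratio_drop(trace: CompositeTrace, peak_index: int, k: int) -> float:
    """Amplitude-drop ratio around a peak.

    Mean of the two samples at offsets ``-k`` and ``+k`` from the peak,
    divided by the peak sample value. Lower values mean a sharper peak.

    Raises
    ------
    ValueError
        If ``peak_index +- k`` falls outside the trace (the ratio is then
        undefined and the peak is unclassifiable) or the peak value is zero.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(trace)
    if peak_index - k < 0 or peak_index + k >= n:
        raise ValueError(
            f"ratio_drop undefined: peak at index {peak_index} is within {k} "
            f"samples of the trace boundary"
        )
    peak = trace.values[peak_index]
    if peak == 0:
        raise ValueError("ratio_drop undefined for a zero-amplitude peak")
    return float(
        0.5 * (trace.values[peak_index - k] + trace.values[peak_index + k]) / peak
    )


def _parabolic_refine(values: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak offset (in samples) and refined amplitude.

    Fits a least-squares parabola through the five samples around a local
    maximum (three at the trace ends); the apex locates the peak to a
    fraction of a sample, which matters for wide (relaxation) peaks whose
    sampled top is nearly flat and easily tilted by noise.
    """
    if 2 <= i < len(values) - 2:
        v = values[i - 2 : i + 3]
        b1 = (-2 * v[0] - v[1] + v[3] + 2 * v[4]) / 10.0
        b2 = (2 * v[0] - v[1] - 2 * v[2] - v[3] + 2 * v[4]) / 14.0
        if b2 < 0:
            delta = float(np.clip(-b1 / (2 * b2), -0.5, 0.5))
            b0 = (-3 * v[0] + 12 * v[1] + 17 * v[2] + 12 * v[3] - 3 * v[4]) / 35.0
            apex = float(b0 + b1 * delta + b2 * delta * delta)
            return delta, max(apex, float(v[2]))
    a, b, c = values[i - 1], values[i], values[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0, float(b)
    delta = float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    return delta, float(b - 0.25 * (a - c) * delta)


def detect_peaks(
    trace: CompositeTrace,
    min_prominence_frac: float = 0.1,
    min_separation_s: float = 0.05,
    refine_times: bool = False,
) -> list[PeakRecord]:
    """Detect strict local maxima of a composite trace.

    Peaks must exceed a prominence of ``min_prominence_frac`` times the
    signal range and be separated by at least ``min_separation_s`` seconds.
    Each record carries ``ratio_drop1`` and ``ratio_drop2`` (NaN when the
    peak sits too close to a trace end for the ratio to be defined).

    With ``refine_times=True`` peak times and amplitudes are refined to
    sub-sample precision by a three-point parabolic fit around each maximum
    (indices stay integer); recommended when per-beat timing at better than
    one frame interval is needed.

    A constant (degenerate) trace yields an empty list, not an error.
    """
    from scipy.signal import find_peaks

    if len(trace) < 3:
        raise ValueError("peak detection needs at least 3 samples")
    values = trace.values
    vrange = float(values.max() - values.min())
    if vrange == 0.0:
        return []
    distance = max(1, int(round(min_separation_s * trace.fps)))
    idx, _ = find_peaks(values, prominence=min_prominence_frac * vrange, distance=distance)
    records = []
    for i in idx:
        drops = []
        for k in (1, 2):
            try:
                drops.append(ratio_drop(trace, int(i), k))
            except ValueError:
                drops.append(float("nan"))
        time, amp = float(trace.times[i]), float(values[i])
        if refine_times and 0 < i < len(values) - 1:
            delta, amp = _parabolic_refine(values, int(i))
            time = time + delta / trace.fps
        records.append(
            PeakRecord(
                index=int(i),
                time=time,
                amplitude=amp,
                ratio_drop1=drops[0],
                ratio_drop2=drops[1],
            )
        )
    return records


def _two_means(features: np.ndarray, random_state: int) -> np.ndarray | None:
    """Cluster standardized features into 2 groups; None if degenerate."""
    from sklearn.cluster import KMeans

    sd = features.std(axis=0)
    if (sd == 0).any():
        return None
    z = (features - features.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
    labels = km.fit_predict(z)
    if len(np.unique(labels)) < 2:
        return None
    if np.allclose(km.cluster_centers_[0], km.cluster_centers_[1]):
        return None
    return labels


def classify_peaks(
    peaks: list[PeakRecord],
    trace: CompositeTrace,
    random_state: int = 0,
) -> list[PeakRecord]:
    """Label detected peaks as contraction or relaxation.

    Pipeline: (a) 2-means clustering of the peaks in the standardized
    (inter-peak interval, peak amplitude) plane; (b) the cluster with the
    lower mean ``ratio_drop2`` (faster amplitude loss, i.e. sharper peaks) is
    labeled contraction; (c) an alternation pass enforces strictly
    alternating labels in time order — of two consecutive same-label peaks
    the one closer to its cluster centroid keeps the label, the other is
    flagged unclassified.

    Fewer than 4 classifiable peaks leaves everything unclassified. If the
    2-means step degenerates (identical centroids), a median split on
    ``ratio_drop2`` is used instead.

    Returns a new list; the input records are not modified.
    """
    peaks = [replace(p, label=UNCLASSIFIED) for p in sorted(peaks, key=lambda p: p.time)]
    eligible = [i for i, p in enumerate(peaks) if np.isfinite(p.ratio_drop2)]
    if len(peaks) < 4 or len(eligible) < 4:
        return peaks

    times = np.array([p.time for p in peaks])
    amps = np.array([p.amplitude for p in peaks])
    # time since the previous detected peak; the first peak uses its forward gap
    dt_markers = np.empty_like(times)
    dt_markers[1:] = np.diff(times)
    dt_markers[0] = dt_markers[1] if len(times) > 1 else 0.0

    feats = np.column_stack([dt_markers[eligible], amps[eligible]])
    cluster = _two_means(feats, random_state)
    drop2 = np.array([peaks[i].ratio_drop2 for i in eligible])
    if cluster is None:
        cluster = (drop2 > np.median(drop2)).astype(int)
        if len(np.unique(cluster)) < 2:
            return peaks

    mean_drop = [drop2[cluster == c].mean() for c in (0, 1)]
    if mean_drop[0] == mean_drop[1]:
        # degenerate tie: contraction peaks are the taller family
        mean_amp = [amps[eligible][cluster == c].mean() for c in (0, 1)]
        contraction_cluster = int(np.argmax(mean_amp))
    else:
        contraction_cluster = int(np.argmin(mean_drop))

    for j, i in enumerate(eligible):
        peaks[i].label = (
            CONTRACTION if cluster[j] == contraction_cluster else RELAXATION
        )

    # distance of each eligible peak to its own cluster centroid, in
    # standardized feature space, used to resolve alternation violations
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / sd
    centroids = np.array([z[cluster == c].mean(axis=0) for c in (0, 1)])
    dist = {
        i: float(np.linalg.norm(z[j] - centroids[cluster[j]]))
        for j, i in enumerate(eligible)
    }

    # alternation pass: repeatedly demote the worse of any adjacent same-label pair
    changed = True
    while changed:
        changed = False
        labeled = [i for i, p in enumerate(peaks) if p.label != UNCLASSIFIED]
        for a, b in zip(labeled, labeled[1:]):
            if peaks[a].label == peaks[b].label:
                worse = a if dist[a] > dist[b] else b
                peaks[worse].label = UNCLASSIFIED
                changed = True
                break
    return peaks


def estimate_noise_floor(trace: CompositeTrace, percentile: float = 10.0) -> float:
    """Diastolic noise floor of a composite trace.

    Independent per-pixel sensor noise contributes to the rectified mean of
    Eq.-style frame differences in quadrature with the motion signal, so the
    trace never returns to zero between beats. The floor is estimated as a
    low percentile of the trace; subtracting it in quadrature
    (``sqrt(A**2 - floor**2)``) recovers motion-only peak amplitudes.
    """
    if len(trace) == 0:
        return 0.0
    return float(np.percentile(trace.values, percentile))


def _corrected_amplitude(a: float, noise_floor: float) -> float:
    return float(np.sqrt(max(a * a - noise_floor * noise_floor, 0.0)))


def beat_measures(peaks: list[PeakRecord], noise_floor: float = 0.0) -> BeatTable:
    """Per-beat measures and acquisition summaries from labeled peaks.

    A beat pairs a contraction peak with the immediately following
    relaxation peak; the beat period T is the time to the next contraction
    peak (the last beat has no T). Beats spanning unclassified peaks are
    dropped from the table rather than interpolated.

    Parameters
    ----------
    peaks : list of PeakRecord
        Labeled peaks (see :func:`classify_peaks`).
    noise_floor : float, optional
        When nonzero, peak amplitudes are corrected as
        ``sqrt(A**2 - noise_floor**2)`` before forming ``ratio_cr``. The
        default 0 reproduces the plain amplitude ratio.
    """
    peaks = sorted(peaks, key=lambda p: p.time)
    rows = []
    contraction_ids = [i for i, p in enumerate(peaks) if p.label == CONTRACTION]
    for bi, i in enumerate(contraction_ids):
        if i + 1 >= len(peaks) or peaks[i + 1].label != RELAXATION:
            continue  # orphan contraction: no immediate relaxation partner
        c, r = peaks[i], peaks[i + 1]
        a_c = _corrected_amplitude(c.amplitude, noise_floor)
        a_r = _corrected_amplitude(r.amplitude, noise_floor)
        if a_r == 0:
            continue
        # T only if the next contraction follows with nothing unclassified between
        period = np.nan
        nxt = [j for j in contraction_ids if j > i]
        if nxt:
            j = nxt[0]
            between_ok = all(
                peaks[m].label != UNCLASSIFIED for m in range(i + 1, j)
            )
            if between_ok and j == i + 2:
                period = peaks[j].time - c.time
        rows.append(
            {
                "beat": len(rows) + 1,
                "t_contraction": c.time,
                "T": period,
                "delta_rc": r.time - c.time,
                "ratio_cr": a_c / a_r,
            }
        )
    beats = pd.DataFrame(rows, columns=["beat", "t_contraction", "T", "delta_rc", "ratio_cr"])
    return BeatTable(peaks=peaks, beats=beats, summaries=_summaries(beats))


def _summaries(beats: pd.DataFrame) -> dict:
    out: dict = {"n_beats": int(len(beats))}
    for col, name in [("T", "T"), ("delta_rc", "delta_rc"), ("ratio_cr", "ratio_cr")]:
        vals = beats[col].dropna().to_numpy() if len(beats) else np.array([])
        out[f"{name}_mean"] = float(np.mean(vals)) if len(vals) else None
        out[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return out


def trend_vs_period(pairs) -> tuple[float, float, float]:
    """Ordinary least-squares trend of an acquisition summary vs mean period.

    Parameters
    ----------
    pairs : sequence of (mean_period, mean_measure)

    Returns
    -------
    (slope, intercept, correlation)
        A constant measure gives slope 0 and correlation 0; constant periods
        are a degenerate design and raise ``ValueError``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (period, measure) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all mean periods equal: slope undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
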