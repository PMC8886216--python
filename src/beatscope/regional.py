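"""Regional synchrony analysis of local composite signals.

Pipeline: an energy map of the local signals separates beating from static
grid cells; per active cell the maximum lagged Pearson correlation against
the global signal locates regions whose activity does not follow the bulk;
connected components of low-correlation cells form clusters, whose mean
signals are compared pairwise by the same lagged-correlation measure.

Lag conventions: a positive lag means the first-named signal lags (comes
after) the reference, i.e. ``local(t) ~ global(t - lag)``. Cluster matrices
are built so that ``cluster_cc`` is symmetric with a unit diagonal and
``cluster_lag`` is antisymmetric with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beats import detect_peaks
from .composite import CompositeTrace, LocalGrid

__all__ = [
    "EnergyMap",
    "SyncResult",
    "energy_map",
    "threshold_energy",
    "suggest_log_threshold",
    "sync_map",
    "low_cc_clusters",
    "cluster_cc_matrix",
    "estimate_period",
]


@dataclass
class EnergyMap:
    """Mean squared temporal derivative of each local composite signal."""

    energy: np.ndarray
    log_energy: np.ndarray
    mask: np.ndarray | None = None
    log_threshold: float | None = None


@dataclass
class SyncResult:
    """Correlation/lag maps and low-correlation clusters of a recording."""

    energy: EnergyMap
    cc_map: np.ndarray
    lag_map: np.ndarray
    fps: float
    max_lag_s: float
    cluster_labels: np.ndarray | None = None
    cluster_signals: np.ndarray | None = None
    cluster_cc: np.ndarray | None = None
    cluster_lag: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        if self.cluster_labels is None:
            return 0
        return int(self.cluster_labels.max())


def energy_map(grid: LocalGrid) -> EnergyMap:
    """Energy E of every local composite signal.

    E is the mean over samples of the squared first-difference temporal
    derivative of the local signal (units: (dS units / s)^2). Static cells
    have E = 0 and log-energy -inf (natural log).
    """
    if grid.n_samples < 2:
        raise ValueError("local signals need at least 2 samples")
    deriv = np.diff(grid.signals, axis=2) * grid.fps
    energy = np.mean(deriv**2, axis=2)
    with np.errstate(divide="ignore"):
        log_energy = np.log(energy)
    return EnergyMap(energy=energy, log_energy=log_energy)


def threshold_energy(emap: EnergyMap, log_threshold: float) -> EnergyMap:
    """Set the active-cell mask to ``log(E) > log_threshold``.

    Zero-energy cells (log undefined, -inf) never pass. Returns a new
    EnergyMap; the input is not modified.
    """
    mask = emap.log_energy > log_threshold
    return EnergyMap(
        energy=emap.energy,
        log_energy=emap.log_energy,
        mask=mask,
        log_threshold=float(log_threshold),
    )


def suggest_log_threshold(emap: EnergyMap) -> float:
    """Otsu split of the finite log-energies.

    A heuristic convenience for bimodal (static + beating) fields of view;
    the threshold is an analysis parameter the user should confirm against
    the log-energy histogram.
    """
    from skimage.filters import threshold_otsu

    finite = emap.log_energy[np.isfinite(emap.log_energy)]
    if finite.size == 0:
        return np.inf
    if np.ptp(finite) == 0:
        return float(finite[0]) - 1.0
    return float(threshold_otsu(finite))


def _max_corr_lag(
    x: np.ndarray,
    y: np.ndarray,
    max_lag_frames: int,
    min_overlap: int,
) -> tuple[float, int]:
    """Maximum Pearson correlation of x against y over integer-frame lags.

    Positive lag means x lags y (``x(t) ~ y(t - lag)``). Each overlapping
    segment pair is mean-centered and normalized per lag, so shorter
    overlaps are not penalized. Ties are broken toward the smallest |lag|,
    then negative before positive. Returns (cc, lag_frames); cc is NaN if
    every candidate lag has a zero-variance segment.
    """
    n = len(x)
    lags = sorted(range(-max_lag_frames, max_lag_frames + 1), key=lambda l: (abs(l), l > 0))
    best_cc, best_lag = np.nan, 0
    for lag in lags:
        if lag >= 0:
            xs, ys = x[lag:], y[: n - lag]
        else:
            xs, ys = x[: n + lag], y[-lag:]
        if len(xs) < max(2, min_overlap):
            continue
        xc = xs - xs.mean()
        yc = ys - ys.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0:
            continue
        cc = float((xc @ yc) / denom)
        if not np.isfinite(best_cc) or cc > best_cc:
            best_cc, best_lag = cc, lag
    return best_cc, best_lag


def estimate_period(trace: CompositeTrace) -> float:
    """Estimate the beat period of a global composite signal (s).

    Each beat contributes two peaks (contraction + relaxation), so the
    interval between every second peak spans exactly one period; the median
    of those spans is robust to a missed or spurious peak. Falls back to a
    quarter of the trace duration when fewer than 3 peaks are found.
    """
    try:
        peaks = detect_peaks(trace)
    except ValueError:
        peaks = []
    if len(peaks) >= 3:
        times = np.array([p.time for p in peaks])
        return float(np.median(times[2:] - times[:-2]))
    return trace.duration / 4.0


def sync_map(
    grid: LocalGrid,
    global_trace: CompositeTrace,
    mask: np.ndarray,
    max_lag_s: float | None = None,
    min_overlap_frac: float = 0.5,
) -> SyncResult:
    """Maximum-correlation and lag maps of local signals vs the global signal.

    For every masked cell, the Pearson correlation with the global trace is
    computed at every integer-frame lag in ``[-max_lag, +max_lag]`` over the
    overlapping segments; the map stores the maximum and its lag (positive =
    the local signal lags the global one). Cells with a zero-variance local
    signal are flagged undefined (NaN) and removed from the mask.

    ``max_lag_s`` defaults to one estimated beat period of the global signal
    to avoid locking onto the neighboring beat.
    """
    gr, gc, n = grid.signals.shape
    if n != len(global_trace):
        raise ValueError("local and global signals must have the same length")
    if grid.fps != global_trace.fps:
        raise ValueError("local and global signals must share the same fps")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (gr, gc):
        raise ValueError(f"mask shape {mask.shape} does not match grid {(gr, gc)}")
    if max_lag_s is None:
        max_lag_s = estimate_period(global_trace)
    duration = n / grid.fps
    if not 0 < max_lag_s < duration / 2:
        raise ValueError(
            f"max_lag_s must lie in (0, duration/2) = (0, {duration / 2:.3g})"
        )
    max_lag_frames = max(1, int(round(max_lag_s * grid.fps)))
    min_overlap = int(np.ceil(min_overlap_frac * n))

    cc_map = np.full((gr, gc), np.nan)
    lag_map = np.full((gr, gc), np.nan)
    out_mask = mask.copy()
    y = global_trace.values
    for gy, gx in zip(*np.nonzero(mask)):
        x = grid.signals[gy, gx]
        if np.ptp(x) == 0:
            out_mask[gy, gx] = False
            continue
        cc, lag = _max_corr_lag(x, y, max_lag_frames, min_overlap)
        if not np.isfinite(cc):
            out_mask[gy, gx] = False
            continue
        cc_map[gy, gx] = cc
        lag_map[gy, gx] = lag / grid.fps
    emap = EnergyMap(
        energy=np.full((gr, gc), np.nan),
        log_energy=np.full((gr, gc), np.nan),
        mask=out_mask,
    )
    return SyncResult(
        energy=emap, cc_map=cc_map, lag_map=lag_map, fps=grid.fps, max_lag_s=float(max_lag_s)
    )


def low_cc_clusters(
    result: SyncResult,
    cc_threshold: float = 0.4,
    connectivity: int = 4,
    min_cells: int = 2,
) -> SyncResult:
    """Connected components of masked cells with cc below threshold.

    Components are labeled 1..K in decreasing size (0 = background);
    components smaller than ``min_cells`` are discarded. K may be 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    mask = result.energy.mask
    candidate = mask & (result.cc_map < cc_threshold)
    labeled, k = ndimage.label(candidate, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, k + 1))
    order = [
        lbl
        for lbl in (np.argsort(-sizes) + 1)
        if sizes[lbl - 1] >= min_cells
    ]
    out = np.zeros_like(labeled)
    for new, old in enumerate(order, start=1):
        out[labeled == old] = new
    result.cluster_labels = out
    return result


def cluster_cc_matrix(
    grid: LocalGrid,
    labels: np.ndarray,
    max_lag_s: float,
    min_overlap_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean cluster signals and pairwise maximum-correlation / lag matrices.

    The cluster signal is the unweighted mean of its member cells' local
    composite signals. ``cc[i, j]`` is the maximum lagged Pearson correlation
    between cluster signals i and j, ``lag[i, j]`` the lag (s) at which it is
    attained, positive when cluster j lags cluster i. By construction the cc
    matrix is symmetric with unit diagonal and the lag matrix antisymmetric
    with zero diagonal.
    """
    labels = np.asarray(labels)
    k = int(labels.max())
    if k < 1:
        raise ValueError("need at least one cluster")
    n = grid.n_samples
    signals = np.empty((k, n))
    for i in range(1, k + 1):
        cells = labels == i
        if not cells.any():
            raise ValueError(f"cluster {i} has no cells")
        signals[i - 1] = grid.signals[cells].mean(axis=0)
    max_lag_frames = max(1, int(round(max_lag_s * grid.fps)))
    min_overlap = int(np.ceil(min_overlap_frac * n))
    cc = np.eye(k)
    lag = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            c, l = _max_corr_lag(signals[j], signals[i], max_lag_frames, min_overlap)
            cc[i, j] = cc[j, i] = c
            lag[i, j] = l / grid.fps
            lag[j, i] = -lag[i, j]
    return signals, cc, lag
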