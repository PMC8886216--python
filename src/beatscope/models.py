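"""Model/Results interface tying the analysis stages together.

Two statsmodels-style entry points cover the common workflows:

``BeatModel``
    Global contractility of one acquisition. Built from a video frame stack,
    a precomputed composite trace or a 1-D shortening trace; ``fit()``
    detects and classifies peaks and returns a :class:`BeatResults` with the
    per-beat table, acquisition summaries (mean +- SD of T, delta_rc and
    ratio_cr) and a text ``summary()``.

``SynchronyModel``
    Regional synchrony of a video. ``fit()`` computes the energy map,
    correlation/lag maps against the global signal, low-correlation clusters
    and the cluster-to-cluster correlation/lag matrices, returned as a
    :class:`SynchronyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .beats import (
    BeatTable,
    beat_measures,
    classify_peaks,
    detect_peaks,
    estimate_noise_floor,
)
from .composite import CompositeTrace, FrameStack, LocalGrid, global_delta_s, local_delta_s
from .regional import (
    SyncResult,
    cluster_cc_matrix,
    energy_map,
    low_cc_clusters,
    suggest_log_threshold,
    sync_map,
    threshold_energy,
)
from .traces import ShorteningTrace, rectified_derivative

__all__ = ["BeatModel", "BeatResults", "SynchronyModel", "SynchronyResults"]


class BeatModel:
    """Beat-level contractility analysis of a composite motion trace."""

    def __init__(self, trace: CompositeTrace):
        self.trace = trace

    @classmethod
    def from_stack(cls, stack: FrameStack, tau_frames: int = 4) -> "BeatModel":
        """Build from a video frame stack via the global composite signal."""
        return cls(global_delta_s(stack, tau_frames=tau_frames))

    @classmethod
    def from_video(
        cls, path: str | Path, fps_override: float | None = None, tau_frames: int = 4
    ) -> "BeatModel":
        return cls.from_stack(_io.read_stack(path, fps_override), tau_frames)

    @classmethod
    def from_shortening(cls, trace: ShorteningTrace) -> "BeatModel":
        """Build from a 1-D cell/sarcomere length trace via |dL/dt|."""
        return cls(rectified_derivative(trace))

    def fit(
        self,
        min_prominence_frac: float = 0.1,
        min_separation_s: float = 0.05,
        noise_floor: float | str = "auto",
        refine_times: bool = False,
        skip_first_beats: int = 0,
        random_state: int = 0,
    ) -> "BeatResults":
        """Detect, classify and measure beats.

        ``noise_floor='auto'`` estimates the diastolic floor of the trace
        (10th percentile) and corrects peak amplitudes in quadrature before
        forming ratio_cr; pass 0 for the plain amplitude ratio.
        ``refine_times=True`` refines peak times/amplitudes to sub-sample
        precision by parabolic interpolation.
        """
        try:
            peaks = detect_peaks(
                self.trace,
                min_prominence_frac=min_prominence_frac,
                min_separation_s=min_separation_s,
                refine_times=refine_times,
            )
        except ValueError:
            peaks = []
        labeled = classify_peaks(peaks, self.trace, random_state=random_state)
        floor = (
            estimate_noise_floor(self.trace)
            if noise_floor == "auto"
            else float(noise_floor)
        )
        table = beat_measures(labeled, noise_floor=floor)
        if skip_first_beats and table.n_beats > skip_first_beats:
            from .beats import _summaries

            table.beats = table.beats.iloc[skip_first_beats:].reset_index(drop=True)
            table.beats["beat"] = np.arange(1, len(table.beats) + 1)
            table.summaries = _summaries(table.beats)
        params = {
            "min_prominence_frac": min_prominence_frac,
            "min_separation_s": min_separation_s,
            "noise_floor": floor,
            "refine_times": refine_times,
            "skip_first_beats": skip_first_beats,
            "random_state": random_state,
            "tau_frames": self.trace.tau_frames,
            "fps": self.trace.fps,
        }
        return BeatResults(model=self, table=table, params=params)


@dataclass
class BeatResults:
    """Per-beat measures, acquisition summaries and diagnostics."""

    model: BeatModel
    table: BeatTable
    params: dict = field(default_factory=dict)

    @property
    def beats(self):
        return self.table.beats

    @property
    def peaks(self):
        return self.table.peaks_frame()

    @property
    def summaries(self) -> dict:
        return self.table.summaries

    @property
    def n_beats(self) -> int:
        return self.table.n_beats

    def summary(self) -> str:
        """Text summary table of the acquisition."""
        s = self.summaries
        n_peaks = len(self.table.peaks)
        n_unc = sum(1 for p in self.table.peaks if p.label == "unclassified")

        def fmt(mean, sd, unit):
            if mean is None:
                return "          n/a"
            sd_s = f" +- {sd:.4g}" if sd is not None else ""
            return f"{mean:10.4g}{sd_s} {unit}"

        lines = [
            "Beat analysis summary",
            "=" * 46,
            f"samples:              {len(self.model.trace)}  @ {self.params['fps']:g} fps",
            f"tau_frames:           {self.params['tau_frames']}",
            f"peaks detected:       {n_peaks}  (unclassified: {n_unc})",
            f"beats:                {self.n_beats}",
            f"noise floor:          {self.params['noise_floor']:.4g}",
            "-" * 46,
            f"period T:         {fmt(s['T_mean'], s['T_sd'], 's')}",
            f"delta_RC:         {fmt(s['delta_rc_mean'], s['delta_rc_sd'], 's')}",
            f"ratio_C/R:        {fmt(s['ratio_cr_mean'], s['ratio_cr_sd'], 'n.u.')}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, base: str | Path) -> None:
        _io.write_beat_table(self.table, base)

    def plot(self, ax=None):
        """Composite trace with classified peaks marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        tr = self.model.trace
        ax.plot(tr.times, tr.values, lw=0.8, color="tab:blue", label=r"$\Delta S$")
        style = {"contraction": ("v", "tab:red"), "relaxation": ("^", "tab:orange"),
                 "unclassified": ("x", "gray")}
        for label, (marker, color) in style.items():
            pts = [(p.time, p.amplitude) for p in self.table.peaks if p.label == label]
            if pts:
                t, a = zip(*pts)
                ax.plot(t, a, marker, color=color, ms=5, ls="none", label=label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"$\Delta S$ (a.u./s)")
        ax.legend(loc="upper right", fontsize=8)
        return ax


class SynchronyModel:
    """Regional synchrony analysis of a beating-monolayer video."""

    def __init__(self, stack: FrameStack, tau_frames: int = 4, nsub: int = 10):
        self.stack = stack
        self.tau_frames = int(tau_frames)
        self.nsub = int(nsub)
        self.grid: LocalGrid = local_delta_s(stack, tau_frames=self.tau_frames, nsub=self.nsub)
        self.global_trace: CompositeTrace = global_delta_s(stack, tau_frames=self.tau_frames)

    @classmethod
    def from_video(
        cls,
        path: str | Path,
        fps_override: float | None = None,
        tau_frames: int = 4,
        nsub: int = 10,
    ) -> "SynchronyModel":
        return cls(_io.read_stack(path, fps_override), tau_frames=tau_frames, nsub=nsub)

    def fit(
        self,
        log_energy_threshold: float | None = None,
        cc_threshold: float = 0.4,
        max_lag_s: float | None = None,
        connectivity: int = 4,
        min_cells: int = 2,
    ) -> "SynchronyResults":
        """Energy mask, correlation/lag maps and low-correlation clusters.

        ``log_energy_threshold=None`` uses an Otsu split of the finite
        log-energies as a starting suggestion; for quantitative work inspect
        the log-energy histogram and set the threshold explicitly.
        """
        emap = energy_map(self.grid)
        if log_energy_threshold is None:
            log_energy_threshold = suggest_log_threshold(emap)
        emap = threshold_energy(emap, log_energy_threshold)
        result = sync_map(self.grid, self.global_trace, emap.mask, max_lag_s=max_lag_s)
        # keep the thresholded energies; sync_map may have removed
        # zero-variance (undefined) cells from the mask
        refined = result.energy.mask
        from .regional import EnergyMap

        result.energy = EnergyMap(
            energy=emap.energy,
            log_energy=emap.log_energy,
            mask=refined,
            log_threshold=float(log_energy_threshold),
        )
        result = low_cc_clusters(
            result,
            cc_threshold=cc_threshold,
            connectivity=connectivity,
            min_cells=min_cells,
        )
        if result.n_clusters >= 1:
            sigs, cc, lag = cluster_cc_matrix(
                self.grid, result.cluster_labels, max_lag_s=result.max_lag_s
            )
            result.cluster_signals = sigs
            result.cluster_cc = cc
            result.cluster_lag = lag
        params = {
            "tau_frames": self.tau_frames,
            "nsub": self.nsub,
            "log_energy_threshold": float(log_energy_threshold),
            "cc_threshold": cc_threshold,
            "max_lag_s": result.max_lag_s,
            "connectivity": connectivity,
            "min_cells": min_cells,
        }
        return SynchronyResults(model=self, result=result, params=params)


@dataclass
class SynchronyResults:
    """Maps, clusters and matrices from a regional synchrony fit."""

    model: SynchronyModel
    result: SyncResult
    params: dict = field(default_factory=dict)

    @property
    def energy(self):
        return self.result.energy

    @property
    def cc_map(self):
        return self.result.cc_map

    @property
    def lag_map(self):
        return self.result.lag_map

    @property
    def cluster_labels(self):
        return self.result.cluster_labels

    @property
    def cluster_cc(self):
        return self.result.cluster_cc

    @property
    def cluster_lag(self):
        return self.result.cluster_lag

    @property
    def n_clusters(self) -> int:
        return self.result.n_clusters

    def summary(self) -> str:
        r = self.result
        active = int(r.energy.mask.sum())
        total = r.energy.mask.size
        cc_vals = r.cc_map[r.energy.mask]
        lines = [
            "Regional synchrony summary",
            "=" * 46,
            f"grid:                 {r.energy.mask.shape[0]} x {r.energy.mask.shape[1]} cells "
            f"({self.params['nsub']} px)",
            f"log(E) threshold:     {self.params['log_energy_threshold']:.3g}",
            f"active cells:         {active} / {total}",
            f"max lag searched:     {self.params['max_lag_s']:.3g} s",
        ]
        if active:
            lines += [
                f"median cc:            {np.median(cc_vals):.3f}",
                f"cells with cc < {self.params['cc_threshold']:g}:  "
                f"{int((cc_vals < self.params['cc_threshold']).sum())}",
            ]
        lines.append(f"low-cc clusters:      {r.n_clusters}")
        if r.n_clusters and r.cluster_lag is not None:
            off = np.abs(r.cluster_lag[np.triu_indices(r.n_clusters, 1)])
            if off.size:
                lines.append(f"max |cluster lag|:    {off.max():.3f} s")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_maps(self, axes=None):
        """Log-energy, correlation, lag and cluster maps as heat maps."""
        import matplotlib.pyplot as plt

        r = self.result
        if axes is None:
            _, axes = plt.subplots(1, 4, figsize=(16, 4))
        panels = [
            (r.energy.log_energy, "log(E)", "viridis"),
            (np.where(r.energy.mask, r.cc_map, np.nan), "max CC", "magma"),
            (np.where(r.energy.mask, r.lag_map, np.nan), "lag (s)", "coolwarm"),
            (
                np.where(r.cluster_labels > 0, r.cluster_labels, np.nan)
                if r.cluster_labels is not None
                else np.full_like(r.cc_map, np.nan),
                "clusters",
                "tab10",
            ),
        ]
        for ax, (img, title, cmap) in zip(axes, panels):
            im = ax.imshow(img, cmap=cmap, interpolation="nearest")
            ax.set_title(title)
            plt.colorbar(im, ax=ax, fraction=0.046)
        return axes
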