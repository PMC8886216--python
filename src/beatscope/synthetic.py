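"""Synthetic contraction waveforms and textured beating-monolayer videos.

The generator provides ground-truthed inputs for every pipeline stage
without any recorded data. A beat is modeled as a pair of Gaussian velocity
pulses: a narrow contraction pulse of width ``tau_c`` followed by a wider
relaxation pulse of width ``tau_r``, with areas balanced so the tissue
returns to rest each cycle. Two time constants control exactly the
contraction/relaxation rate asymmetry the beat measures respond to:

* ground-truth ``Ratio_C/R = tau_r / tau_c`` (``> 1`` iff contraction is
  faster than relaxation, as observed in beating monolayers);
* ground-truth ``delta_rc = 1.5 * (tau_c + tau_r)`` (peak-to-peak time),
  strictly increasing in either time constant.

Videos displace a smooth random texture radially toward each region's
centroid by the instantaneous shortening fraction (bilinear interpolation),
then add white Gaussian pixel noise, so the composite motion signal arises
from genuine texture motion as in phase-contrast recordings. Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.special import ndtr

from .composite import FrameStack
from .traces import ShorteningTrace

__all__ = [
    "WaveformSpec",
    "Region",
    "VideoSpec",
    "WaveformGroundTruth",
    "GroundTruth",
    "make_sl_trace",
    "make_video",
    "make_heterogeneous_video",
    "region_grid_cells",
]

#: contraction velocity peak sits this many tau_c after the beat onset
CONTRACTION_OFFSET_FACTOR = 2.5
#: relaxation peak follows the contraction peak by this factor times (tau_c + tau_r)
RC_SPACING_FACTOR = 1.5
#: pulses are considered finished this many widths past their peak
PULSE_TAIL_FACTOR = 3.0
#: fine-grid refinement factor for the brute-force ground-truth oracle
ORACLE_REFINE = 100
#: displacement saturation radius (px): contraction is driven by local cell
#: clusters, so the displacement of a pixel grows with its distance from the
#: contraction center only up to this scale (~20 um at typical 10x optics)
DISPLACEMENT_R0 = 30.0
#: period (s) of the slow precession of each region's bulk-drift direction
DRIFT_ROTATION_PERIOD = 10.0


@dataclass
class WaveformSpec:
    """Parameters of the periodic two-pulse contraction waveform.

    Parameters
    ----------
    pcl : float
        Pacing cycle length (s).
    tau_c, tau_r : float
        Contraction / relaxation velocity-pulse widths (s). Defaults mimic a
        neonatal monolayer beating at PCL 0.5 s with contraction nearly
        twice as fast as relaxation.
    amplitude : float
        Fractional shortening at peak contraction, in (0, 1).
    n_beats : int
        Number of beats generated.
    dt : float
        Sample interval of 1-D traces (s).
    onset_jitter_sd : float
        SD of Gaussian jitter applied to each beat onset (s).
    """

    pcl: float
    tau_c: float = 0.035
    tau_r: float = 0.065
    amplitude: float = 0.08
    n_beats: int = 10
    dt: float = 0.01
    onset_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pcl", "tau_c", "tau_r", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.onset_jitter_sd < 0:
            raise ValueError("onset_jitter_sd must be >= 0")
        if not self.tau_c + self.tau_r < self.pcl:
            raise ValueError("tau_c + tau_r must be smaller than pcl")
        # the relaxation tail (ends 4*tau_c + 4.5*tau_r after onset) must not
        # reach the next beat's contraction pulse (starts pcl - 0.5*tau_c
        # after onset), otherwise beats merge and the truth is ill-posed
        if 4.5 * (self.tau_c + self.tau_r) > self.pcl:
            raise ValueError(
                "contraction/relaxation pulses do not fit within one cycle; "
                "decrease tau_c/tau_r or increase pcl"
            )

    @property
    def t_contraction_offset(self) -> float:
        return CONTRACTION_OFFSET_FACTOR * self.tau_c

    @property
    def t_relaxation_offset(self) -> float:
        return self.t_contraction_offset + RC_SPACING_FACTOR * (self.tau_c + self.tau_r)

    @property
    def duration(self) -> float:
        return self.n_beats * self.pcl


@dataclass
class WaveformGroundTruth:
    """Brute-force fine-grid truth for one contraction waveform.

    Peak times and amplitudes refer to ``|d(shortening)/dt|`` evaluated on a
    grid ``ORACLE_REFINE`` times finer than the trace sampling; ``scale``
    converts fractional shortening to the trace's physical units.
    """

    contraction_times: np.ndarray
    relaxation_times: np.ndarray
    contraction_amps: np.ndarray
    relaxation_amps: np.ndarray
    onsets: np.ndarray
    scale: float = 1.0

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.contraction_times)

    @property
    def delta_rc(self) -> np.ndarray:
        return self.relaxation_times - self.contraction_times

    @property
    def ratio_cr(self) -> np.ndarray:
        return self.contraction_amps / self.relaxation_amps


def _beat_onsets(spec: WaveformSpec, rng: np.random.Generator) -> np.ndarray:
    onsets = np.arange(spec.n_beats) * spec.pcl
    if spec.onset_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.onset_jitter_sd, spec.n_beats)
        # keep beats ordered and pulses within their cycle
        jitter = np.clip(jitter, -0.2 * spec.pcl, 0.2 * spec.pcl)
        onsets = onsets + jitter
    return onsets


def _shortening_fraction(
    times: np.ndarray, onsets: np.ndarray, spec: WaveformSpec
) -> np.ndarray:
    """Normalized shortening waveform in [0, 1] (before amplitude scaling).

    Integral of the two Gaussian velocity pulses: rises from 0 to ~1 through
    the contraction pulse, returns to 0 through the relaxation pulse.
    """
    w = np.zeros_like(times, dtype=float)
    for onset in onsets:
        t_c = onset + spec.t_contraction_offset
        t_r = onset + spec.t_relaxation_offset
        # window must cover the 6-sigma support of BOTH pulses, otherwise
        # truncation leaves a step whose gradient pollutes the oracle
        lo = np.searchsorted(times, min(t_c - 6 * spec.tau_c, t_r - 6 * spec.tau_r))
        hi = np.searchsorted(times, max(t_r + 6 * spec.tau_r, t_c + 6 * spec.tau_c))
        seg = times[lo:hi]
        w[lo:hi] += ndtr((seg - t_c) / spec.tau_c) - ndtr((seg - t_r) / spec.tau_r)
    return w


def _ground_truth(
    spec: WaveformSpec, onsets: np.ndarray, scale: float
) -> WaveformGroundTruth:
    """Fine-grid brute-force oracle for the |d(shortening)/dt| peaks."""
    fine_dt = spec.dt / ORACLE_REFINE
    t_end = onsets[-1] + spec.pcl
    fine_t = np.arange(0.0, t_end, fine_dt)
    w = spec.amplitude * _shortening_fraction(fine_t, onsets, spec)
    speed = np.abs(np.gradient(w, fine_dt))
    ct, rt, ca, ra = [], [], [], []
    for onset in onsets:
        t_c = onset + spec.t_contraction_offset
        t_r = onset + spec.t_relaxation_offset
        mid = 0.5 * (t_c + t_r)
        lo, mi = np.searchsorted(fine_t, [onset, mid])
        hi = np.searchsorted(fine_t, onset + spec.pcl)
        i_c = lo + int(np.argmax(speed[lo:mi]))
        i_r = mi + int(np.argmax(speed[mi:hi]))
        ct.append(fine_t[i_c])
        rt.append(fine_t[i_r])
        ca.append(speed[i_c])
        ra.append(speed[i_r])
    return WaveformGroundTruth(
        contraction_times=np.array(ct),
        relaxation_times=np.array(rt),
        contraction_amps=scale * np.array(ca),
        relaxation_amps=scale * np.array(ra),
        onsets=onsets.copy(),
        scale=scale,
    )


def make_sl_trace(
    spec: WaveformSpec, seed: int = 0, sl_rest: float = 1.9
) -> tuple[ShorteningTrace, WaveformGroundTruth]:
    """Sarcomere-length trace for a waveform spec, with fine-grid truth.

    ``sl_rest`` is the diastolic sarcomere length (um); the trace is
    ``sl_rest * (1 - amplitude * w(t))`` sampled at ``spec.dt``. Ground-truth
    amplitudes are in um/s (``scale = sl_rest``).
    """
    rng = np.random.default_rng(seed)
    onsets = _beat_onsets(spec, rng)
    truth = _ground_truth(spec, onsets, scale=sl_rest)
    times = np.arange(0.0, spec.duration, spec.dt)
    w = spec.amplitude * _shortening_fraction(times, onsets, spec)
    values = sl_rest * (1.0 - w)
    return ShorteningTrace(values=values, dt=spec.dt), truth


@dataclass
class Region:
    """A rectangular or mask-defined patch of the field of view.

    ``rect`` is (row0, col0, height, width) in pixels; alternatively a
    boolean ``mask`` of the full frame selects arbitrary shapes (e.g. a
    background with a hole). ``delay`` shifts the region's waveform in time.
    """

    waveform: WaveformSpec
    rect: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = None
    delay: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise ValueError("specify exactly one of rect or mask")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    def pixel_mask(self, height: int, width: int) -> np.ndarray:
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (height, width):
                raise ValueError("region mask shape does not match the frame")
            return mask
        r0, c0, h, w = self.rect
        if r0 < 0 or c0 < 0 or r0 + h > height or c0 + w > width:
            raise ValueError(f"region rect {self.rect} lies outside the frame")
        mask = np.zeros((height, width), dtype=bool)
        mask[r0 : r0 + h, c0 : c0 + w] = True
        return mask


@dataclass
class VideoSpec:
    """Synthetic beating-monolayer video description.

    ``texture_scale`` is the Gaussian smoothing length of the random texture
    in pixels (its SD is normalized to 1 intensity unit, so ``noise_sd`` is
    directly the sensor noise as a fraction of texture contrast).
    """

    height: int = 120
    width: int = 120
    fps: float = 50.0
    duration: float = 10.0
    texture_scale: float = 3.0
    noise_sd: float = 0.05
    regions: list[Region] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("frame must be at least 2 x 2 pixels")
        if not self.fps > 0 or not self.duration > 0:
            raise ValueError("fps and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.regions:
            raise ValueError("at least one region is required")
        occupied = np.zeros((self.height, self.width), dtype=bool)
        for reg in self.regions:
            mask = reg.pixel_mask(self.height, self.width)
            if (occupied & mask).any():
                raise ValueError("regions must not overlap")
            occupied |= mask

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class GroundTruth:
    """Per-region waveform truth plus the imposed inter-region structure."""

    regions: list[WaveformGroundTruth]
    delays: list[float]
    region_names: list[str]
    independent: list[bool] = field(default_factory=list)

    @property
    def low_cc_target(self) -> int | None:
        """Index of the region marked as beating at an independent rhythm."""
        for i, flag in enumerate(self.independent):
            if flag:
                return i
        return None


def _make_texture(height: int, width: int, scale: float, rng) -> np.ndarray:
    tex = gaussian_filter(rng.standard_normal((height, width)), scale)
    sd = tex.std()
    if sd > 0:
        tex = tex / sd
    return (100.0 + tex).astype(np.float32)


def make_video(
    spec: VideoSpec, independent: list[bool] | None = None
) -> tuple[FrameStack, GroundTruth]:
    """Render a textured contracting video with known ground truth.

    Each region's texture is displaced radially toward the region centroid
    in proportion to its instantaneous shortening fraction, using bilinear
    interpolation; Gaussian noise is then added per pixel per frame. The
    output is deterministic for a fixed ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    tex_rng, noise_rng, *region_rngs = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(spec.regions))
    ]
    texture = _make_texture(spec.height, spec.width, spec.texture_scale, tex_rng)
    n_frames = spec.n_frames
    frame_times = np.arange(n_frames) / spec.fps
    frames = np.broadcast_to(texture, (n_frames,) + texture.shape).copy()

    truths, delays, names, indep = [], [], [], []
    for ri, region in enumerate(spec.regions):
        wspec = region.waveform
        n_beats = int(np.ceil((spec.duration + region.delay) / wspec.pcl)) + 1
        wspec = WaveformSpec(
            pcl=wspec.pcl,
            tau_c=wspec.tau_c,
            tau_r=wspec.tau_r,
            amplitude=wspec.amplitude,
            n_beats=n_beats,
            dt=1.0 / spec.fps,
            onset_jitter_sd=wspec.onset_jitter_sd,
        )
        onsets = _beat_onsets(wspec, region_rngs[ri])
        truth = _ground_truth(wspec, onsets, scale=1.0)
        # report events on the video clock (region waveform starts at `delay`)
        truth = WaveformGroundTruth(
            contraction_times=truth.contraction_times + region.delay,
            relaxation_times=truth.relaxation_times + region.delay,
            contraction_amps=truth.contraction_amps,
            relaxation_amps=truth.relaxation_amps,
            onsets=truth.onsets + region.delay,
            scale=1.0,
        )
        mask = region.pixel_mask(spec.height, spec.width)
        rows, cols = np.nonzero(mask)
        cy, cx = rows.mean(), cols.mean()
        # radial contraction toward the centroid, with two locality
        # corrections to the toy kinematics: (i) the displacement grows with
        # distance from the centroid only up to DISPLACEMENT_R0 — contraction
        # is driven by cell-scale foci, so a pixel at the far periphery does
        # not move proportionally to its full centroid distance; (ii) a bulk
        # drift of the same scale — in a monolayer every patch is also tugged
        # by its surroundings, so the cells at the centroid are not static
        theta0 = region_rngs[ri].uniform(0.0, 2 * np.pi)
        r = np.hypot(rows - cy, cols - cx)
        radial = DISPLACEMENT_R0 / (DISPLACEMENT_R0 + r)
        # bulk tug from the surroundings, same scale for every region; since
        # the radial displacement magnitude a*r*R0/(R0+r) is strictly below
        # a*R0, the two terms can never cancel and no cell is left static
        drift = DISPLACEMENT_R0
        frac = wspec.amplitude * _shortening_fraction(
            frame_times - region.delay, onsets, wspec
        )
        for ti in np.nonzero(frac > 1e-12)[0]:
            a = frac[ti]
            # the drift direction precesses slowly (10 s period) so the
            # radial and drift terms never cancel at a fixed pixel for long
            theta = theta0 + 2 * np.pi * frame_times[ti] / DRIFT_ROTATION_PERIOD
            gy, gx = drift * np.sin(theta), drift * np.cos(theta)
            coords = np.vstack(
                [
                    cy + (rows - cy) * (1.0 + a * radial) + a * gy,
                    cx + (cols - cx) * (1.0 + a * radial) + a * gx,
                ]
            )
            frames[ti, rows, cols] = map_coordinates(
                texture, coords, order=1, mode="reflect"
            )
        truths.append(truth)
        delays.append(region.delay)
        names.append(region.name or f"region{ri}")
        indep.append(False if independent is None else bool(independent[ri]))

    if spec.noise_sd > 0:
        frames = frames + spec.noise_sd * noise_rng.standard_normal(
            frames.shape, dtype=np.float32
        )
    stack = FrameStack(frames=frames, fps=spec.fps)
    return stack, GroundTruth(
        regions=truths, delays=delays, region_names=names, independent=indep
    )


def make_heterogeneous_video(
    spec: VideoSpec, independent_region: int
) -> tuple[FrameStack, GroundTruth]:
    """As :func:`make_video`, with one region beating at its own rhythm.

    ``independent_region`` designates the region whose pacing cycle length
    differs from the rest; the ground truth marks it as the expected
    low-correlation target for the regional synchrony pipeline.
    """
    if len(spec.regions) < 2:
        raise ValueError("a heterogeneous video needs at least two regions")
    if not 0 <= independent_region < len(spec.regions):
        raise ValueError("independent_region out of range")
    flags = [i == independent_region for i in range(len(spec.regions))]
    return make_video(spec, independent=flags)


def region_grid_cells(
    region: Region, height: int, width: int, nsub: int, full: bool = True
) -> np.ndarray:
    """Boolean grid-cell map of a region under an nsub x nsub tiling.

    With ``full=True`` a cell counts only when every one of its pixels lies
    inside the region (cells straddling the boundary are excluded).
    """
    mask = region.pixel_mask(height, width)
    gr, gc = height // nsub, width // nsub
    blocks = mask[: gr * nsub, : gc * nsub].reshape(gr, nsub, gc, nsub)
    frac = blocks.mean(axis=(1, 3))
    return frac >= 1.0 if full else frac > 0.0
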