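"""Composite inter-frame motion signals for beating-cell videomicroscopy.

The global composite signal is the mean absolute pixel intensity difference
between frames separated by a delay of ``tau_frames`` frames, divided by that
delay expressed in seconds:

    dS(t) = mean_ij |M_ij(t) - M_ij(t - tau)| / tau_s,   tau_s = tau_frames/fps

making dS a rate (intensity units per second) that acts as a surrogate for the
mean tissue motion speed. The local variant applies the same formula to each
``nsub x nsub`` pixel block of the field of view, yielding a coarse grid of
motion signals used for regional synchrony analysis.

Both signals are scale-covariant: multiplying every frame by ``c > 0``
multiplies every sample by exactly ``c``, so ratio- and time-based beat
measures downstream do not depend on camera gain or bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "CompositeTrace",
    "LocalGrid",
    "global_delta_s",
    "local_delta_s",
]


@dataclass
class FrameStack:
    """Ordered grayscale frames with frame-rate metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, n_rows, n_cols)
        Intensity values on their native scale (never rescaled on read).
    fps : float
        Acquisition frame rate in Hz.
    t0 : float, optional
        Time of the first frame in seconds. Frame ``k`` is at ``t0 + k/fps``.
    """

    frames: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float32)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, rows, cols); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must all be finite")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of every frame (s)."""
        return self.t0 + np.arange(self.n_frames) / self.fps

    @property
    def duration(self) -> float:
        """Time spanned from first to last frame (s)."""
        return (self.n_frames - 1) / self.fps


@dataclass
class CompositeTrace:
    """A composite motion signal dS(t) with its delay parameter.

    ``values[k]`` is assigned to the time of the *later* frame of the pair, so
    ``times`` starts at ``t0 + tau_frames/fps`` and the trace has
    ``n_frames - tau_frames`` samples.
    """

    values: np.ndarray
    times: np.ndarray
    tau_frames: int
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("values and times must be 1-D arrays of equal length")
        if (self.values < 0).any():
            raise ValueError("composite signal values must be non-negative")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if (dt <= 0).any():
                raise ValueError("times must be strictly increasing")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0


@dataclass
class LocalGrid:
    """Grid of local composite signals, one per nsub x nsub pixel block.

    ``signals`` has shape (grid_rows, grid_cols, n_samples); blocks tile the
    field of view from the top-left corner and trailing pixels that do not
    fill a block are discarded.
    """

    signals: np.ndarray
    times: np.ndarray
    nsub_y: int
    nsub_x: int
    tau_frames: int
    fps: float

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 3:
            raise ValueError("signals must be 3-D (grid_rows, grid_cols, time)")
        if (self.signals < 0).any():
            raise ValueError("local composite signals must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.signals.shape[:2]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def cell_trace(self, gy: int, gx: int) -> CompositeTrace:
        """The local signal of one grid cell as a :class:`CompositeTrace`."""
        return CompositeTrace(
            values=self.signals[gy, gx],
            times=self.times,
            tau_frames=self.tau_frames,
            fps=self.fps,
        )


def _check_tau(tau_frames: int, n_frames: int) -> None:
    if int(tau_frames) != tau_frames or tau_frames < 1:
        raise ValueError(f"tau_frames must be a positive integer, got {tau_frames}")
    if tau_frames >= n_frames:
        raise ValueError(
            f"tau_frames ({tau_frames}) must be smaller than the number of frames "
            f"({n_frames})"
        )


def global_delta_s(stack: FrameStack, tau_frames: int = 4) -> CompositeTrace:
    """Global composite motion signal of a frame stack.

    Parameters
    ----------
    stack : FrameStack
    tau_frames : int, optional
        Frame delay tau. Larger delays suppress the sensor-noise floor but act
        as a wider moving window over the motion waveform (see the methods
        note); the default of 4 frames is a noise/sharpness compromise at
        50 fps.

    Returns
    -------
    CompositeTrace
        ``n_frames - tau_frames`` samples, each the mean absolute frame
        difference divided by ``tau_frames / fps`` (intensity units / s).
    """
    tau_frames = int(tau_frames)
    _check_tau(tau_frames, stack.n_frames)
    tau_s = tau_frames / stack.fps
    diffs = np.abs(
        stack.frames[tau_frames:].astype(np.float64)
        - stack.frames[:-tau_frames].astype(np.float64)
    )
    values = diffs.mean(axis=(1, 2)) / tau_s
    times = stack.t0 + np.arange(tau_frames, stack.n_frames) / stack.fps
    return CompositeTrace(values=values, times=times, tau_frames=tau_frames, fps=stack.fps)


def local_delta_s(stack: FrameStack, tau_frames: int = 4, nsub: int = 10) -> LocalGrid:
    """Local composite signals over an nsub x nsub tiling of the frame.

    Each grid cell's signal is the global formula restricted to its pixel
    block. Blocks tile the frame from the top-left corner; trailing rows and
    columns that do not fill a block are discarded (not padded). With the
    default block size of 10 px, a 640 x 480 acquisition yields a 48 x 64
    grid.
    """
    tau_frames = int(tau_frames)
    _check_tau(tau_frames, stack.n_frames)
    nsub = int(nsub)
    n_t, n_y, n_x = stack.frames.shape
    if nsub < 1:
        raise ValueError("nsub must be a positive integer")
    if nsub > n_y or nsub > n_x:
        raise ValueError(
            f"nsub ({nsub}) exceeds the frame dimensions ({n_y} x {n_x})"
        )
    gr, gc = n_y // nsub, n_x // nsub
    cropped = stack.frames[:, : gr * nsub, : gc * nsub].astype(np.float64)
    diffs = np.abs(cropped[tau_frames:] - cropped[:-tau_frames])
    # (t, gr, nsub, gc, nsub) -> mean over in-block pixels
    blocks = diffs.reshape(diffs.shape[0], gr, nsub, gc, nsub)
    tau_s = tau_frames / stack.fps
    signals = blocks.mean(axis=(2, 4)) / tau_s  # (t, gr, gc)
    signals = np.moveaxis(signals, 0, 2)  # (gr, gc, t)
    times = stack.t0 + np.arange(tau_frames, n_t) / stack.fps
    return LocalGrid(
        signals=signals,
        times=times,
        nsub_y=nsub,
        nsub_x=nsub,
        tau_frames=tau_frames,
        fps=stack.fps,
    )
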