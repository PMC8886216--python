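"""Shared fixtures: small frame stacks and cached synthetic videos."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import beatscope as bs

# analysis defaults used by the recovery tests: tau of 2 frames keeps the
# frame-difference window narrower than the contraction pulse (see methods)
TAU_RECOVERY = 2


def brute_force_global(frames: np.ndarray, fps: float, tau: int) -> np.ndarray:
    """Pixel-loop oracle for the global composite signal."""
    n_t, n_y, n_x = frames.shape
    out = []
    for t in range(tau, n_t):
        acc = 0.0
        for j in range(n_y):
            for i in range(n_x):
                acc += abs(float(frames[t, j, i]) - float(frames[t - tau, j, i]))
        out.append(acc / (n_y * n_x) / (tau / fps))
    return np.array(out)


def brute_force_local(frames: np.ndarray, fps: float, tau: int, nsub: int) -> np.ndarray:
    """Pixel-loop oracle for the gridded local composite signals."""
    n_t, n_y, n_x = frames.shape
    gr, gc = n_y // nsub, n_x // nsub
    out = np.zeros((gr, gc, n_t - tau))
    for gy in range(gr):
        for gx in range(gc):
            block = frames[:, gy * nsub : (gy + 1) * nsub, gx * nsub : (gx + 1) * nsub]
            out[gy, gx] = brute_force_global(block, fps, tau)
    return out


@lru_cache(maxsize=3)
def _cached_single_region_video(seed: int, noise_sd: float, duration: float):
    wf = bs.WaveformSpec(pcl=0.5)
    spec = bs.VideoSpec(
        height=160,
        width=160,
        fps=50.0,
        duration=duration,
        noise_sd=noise_sd,
        regions=[bs.Region(waveform=wf, rect=(0, 0, 160, 160))],
        seed=seed,
    )
    return bs.make_video(spec)


@pytest.fixture(scope="session")
def single_region_video():
    """Factory for a 50 fps 160x160 single-region beating video (PCL 0.5 s)."""

    def factory(seed: int = 3, noise_sd: float = 0.0, duration: float = 30.0):
        return _cached_single_region_video(seed, noise_sd, duration)

    return factory


@lru_cache(maxsize=4)
def _cached_two_region_video(seed: int, delay: float):
    wf = bs.WaveformSpec(pcl=0.5)
    spec = bs.VideoSpec(
        height=120,
        width=120,
        fps=50.0,
        duration=20.0,
        noise_sd=0.05,
        regions=[
            bs.Region(waveform=wf, rect=(10, 10, 50, 100), name="A"),
            bs.Region(waveform=wf, rect=(60, 10, 50, 100), delay=delay, name="B"),
        ],
        seed=seed,
    )
    return bs.make_video(spec), spec


@pytest.fixture(scope="session")
def two_region_video():
    """Factory for a two-region video where region B lags region A."""

    def factory(seed: int = 7, delay: float = 0.1):
        return _cached_two_region_video(seed, delay)

    return factory


def heterogeneous_spec(seed: int) -> tuple[bs.VideoSpec, bs.Region]:
    """A background at PCL 0.5 s with an embedded 40x40 region at PCL 0.77 s,
    surrounded by a 10 px static border (pure texture + noise)."""
    h = w = 140
    border = np.ones((h, w), bool)
    border[:10, :] = border[-10:, :] = False
    border[:, :10] = border[:, -10:] = False
    inner = bs.Region(waveform=bs.WaveformSpec(pcl=0.77), rect=(60, 60, 40, 40), name="indep")
    hole = border.copy()
    hole[60:100, 60:100] = False
    background = bs.Region(waveform=bs.WaveformSpec(pcl=0.5), mask=hole, name="bg")
    spec = bs.VideoSpec(
        height=h, width=w, fps=50.0, duration=30.0, noise_sd=0.05,
        regions=[background, inner], seed=seed,
    )
    return spec, inner
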