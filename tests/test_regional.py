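"""Energy maps, lagged-correlation maps and cluster extraction."""

import numpy as np
import pytest

import beatscope as bs
from beatscope.regional import _max_corr_lag


def _grid_from_signals(signals, fps=50.0, tau=1):
    signals = np.asarray(signals, dtype=float)
    n = signals.shape[2]
    times = np.arange(tau, tau + n) / fps
    return bs.LocalGrid(
        signals=signals, times=times, nsub_y=10, nsub_x=10, tau_frames=tau, fps=fps
    )


def _trace(values, fps=50.0, tau=1):
    values = np.asarray(values, dtype=float)
    times = np.arange(tau, tau + len(values)) / fps
    return bs.CompositeTrace(values=values, times=times, tau_frames=tau, fps=fps)


def test_energy_of_constant_and_alternating_signals():
    fps = 20.0
    const = np.zeros((1, 1, 8))
    alt = np.tile([0.0, 1.0], 4)[None, None, :]
    grid = _grid_from_signals(np.concatenate([const, alt], axis=0), fps=fps)
    emap = bs.energy_map(grid)
    assert emap.energy[0, 0] == 0.0
    assert emap.log_energy[0, 0] == -np.inf
    assert emap.energy[1, 0] == pytest.approx(fps**2)


def test_single_beating_cell_yields_single_nonzero_energy():
    rng = np.random.default_rng(0)
    signals = np.zeros((3, 3, 40))
    signals[1, 2] = np.abs(np.sin(np.arange(40) / 3.0))
    emap = bs.energy_map(_grid_from_signals(signals))
    nz = emap.energy > 0
    assert nz.sum() == 1 and nz[1, 2]


def test_threshold_masks_by_log_energy():
    signals = np.zeros((2, 1, 10))
    signals[0, 0] = np.tile([0, 1.0], 5)
    emap = bs.energy_map(_grid_from_signals(signals, fps=50.0))
    low = bs.threshold_energy(emap, -100.0)
    assert low.mask[0, 0] and not low.mask[1, 0]  # zero energy never passes
    assert not bs.threshold_energy(emap, np.inf).mask.any()


def test_bruteforce_all_lags_oracle_matches_max_corr():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    max_lag = 6
    cc, lag = _max_corr_lag(x, y, max_lag, min_overlap=20)
    # independent oracle: plain corrcoef on every overlap
    best = -2.0
    for l in range(-max_lag, max_lag + 1):
        xs, ys = (x[l:], y[: 40 - l]) if l >= 0 else (x[:40 + l], y[-l:])
        c = np.corrcoef(xs, ys)[0, 1]
        best = max(best, c)
    assert cc == pytest.approx(best, abs=1e-12)
    assert cc <= 1 + 1e-12


def test_sync_map_identical_cells_have_unit_cc_zero_lag():
    v = np.abs(np.sin(np.arange(200) / 5.0)) + 0.1
    signals = np.tile(v, (2, 2, 1))
    grid = _grid_from_signals(signals)
    res = bs.sync_map(grid, _trace(v), np.ones((2, 2), bool), max_lag_s=0.5)
    np.testing.assert_allclose(res.cc_map, 1.0, atol=1e-12)
    np.testing.assert_allclose(res.lag_map, 0.0)


def test_shifted_cell_reports_its_lag():
    fps = 50.0
    rng = np.random.default_rng(1)
    v = np.abs(np.sin(np.arange(400) / 7.0)) + 0.05 * rng.random(400)
    shift = 3
    shifted = np.r_[np.full(shift, v[0]), v[:-shift]]  # cell lags the global
    signals = np.stack([v, shifted])[:, None, :]
    grid = _grid_from_signals(signals, fps=fps)
    res = bs.sync_map(grid, _trace(v, fps=fps), np.ones((2, 1), bool), max_lag_s=0.4)
    assert res.lag_map[0, 0] == pytest.approx(0.0)
    assert res.lag_map[1, 0] == pytest.approx(shift / fps)
    assert res.cc_map[1, 0] >= 0.99


def test_white_noise_cell_has_low_cc():
    rng = np.random.default_rng(7)
    n = 1500  # 30 s at 50 fps
    t = np.arange(n) / 50.0
    global_v = np.abs(np.sin(2 * np.pi * t / 0.5)) + 0.1
    noise_cell = np.abs(rng.normal(1.0, 0.3, n))
    signals = np.stack([global_v, noise_cell])[:, None, :]
    grid = _grid_from_signals(signals)
    res = bs.sync_map(grid, _trace(global_v), np.ones((2, 1), bool), max_lag_s=0.5)
    assert res.cc_map[1, 0] < 0.2


def test_zero_variance_cell_is_flagged_undefined():
    v = np.abs(np.sin(np.arange(100) / 5.0))
    signals = np.stack([v, np.full(100, 2.0)])[:, None, :]
    grid = _grid_from_signals(signals)
    res = bs.sync_map(grid, _trace(v), np.ones((2, 1), bool), max_lag_s=0.3)
    assert np.isnan(res.cc_map[1, 0])
    assert not res.energy.mask[1, 0]


def _sync_result_with(cc_map, mask):
    emap = bs.EnergyMap(
        energy=np.ones_like(cc_map), log_energy=np.zeros_like(cc_map), mask=mask
    )
    return bs.SyncResult(
        energy=emap, cc_map=cc_map, lag_map=np.zeros_like(cc_map), fps=50.0, max_lag_s=0.5
    )


def test_low_cc_cluster_extraction_and_size_filter():
    cc = np.ones((5, 6))
    cc[0:2, 0:2] = 0.1       # 4-cell blob
    cc[4, 3:6] = 0.2         # 3-cell blob
    cc[2, 5] = 0.05          # isolated single cell
    mask = np.ones((5, 6), bool)
    res = bs.low_cc_clusters(_sync_result_with(cc, mask), cc_threshold=0.4, min_cells=2)
    labels = res.cluster_labels
    assert res.n_clusters == 2
    assert set(np.unique(labels[0:2, 0:2])) == {1}  # largest first
    assert set(np.unique(labels[4, 3:6])) == {2}
    assert labels[2, 5] == 0  # single cell discarded
    # all-high map -> no clusters
    res2 = bs.low_cc_clusters(_sync_result_with(np.ones((5, 6)), mask))
    assert res2.n_clusters == 0


def test_cluster_matrices_for_identical_and_delayed_signals():
    fps = 50.0
    t = np.arange(600) / fps
    v = np.abs(np.sin(2 * np.pi * t / 0.5)) + 0.1
    delayed = np.interp(t - 0.1, t, v, left=v[0])  # cluster 2 lags cluster 1
    signals = np.zeros((2, 2, 600))
    signals[0, 0] = signals[0, 1] = v
    signals[1, 0] = signals[1, 1] = delayed
    grid = _grid_from_signals(signals, fps=fps)
    labels = np.array([[1, 1], [2, 2]])
    sigs, cc, lag = bs.cluster_cc_matrix(grid, labels, max_lag_s=0.2)
    assert cc[0, 0] == 1.0 and cc[1, 1] == 1.0
    assert lag[0, 0] == 0.0 and lag[1, 1] == 0.0
    assert cc[0, 1] > 0.99
    assert lag[0, 1] == pytest.approx(0.1, abs=0.5 / fps)
    # identical clusters: unit cc, zero lag
    _, cc_s, lag_s = bs.cluster_cc_matrix(
        _grid_from_signals(np.tile(v, (2, 2, 1)), fps=fps), np.array([[1, 2], [0, 0]]),
        max_lag_s=0.2,
    )
    assert cc_s[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert lag_s[0, 1] == 0.0


def test_single_cluster_gives_trivial_matrices():
    v = np.abs(np.sin(np.arange(100) / 5.0)) + 0.1
    grid = _grid_from_signals(v[None, None, :])
    sigs, cc, lag = bs.cluster_cc_matrix(grid, np.array([[1]]), max_lag_s=0.2)
    assert cc.shape == (1, 1) and cc[0, 0] == 1.0 and lag[0, 0] == 0.0


def test_matrix_structure_symmetry_and_antisymmetry():
    rng = np.random.default_rng(5)
    signals = np.abs(rng.normal(1, 0.5, (2, 2, 300)))
    grid = _grid_from_signals(signals)
    labels = np.array([[1, 2], [3, 4]])
    _, cc, lag = bs.cluster_cc_matrix(grid, labels, max_lag_s=0.3)
    np.testing.assert_array_equal(cc, cc.T)
    np.testing.assert_array_equal(lag, -lag.T)
    np.testing.assert_array_equal(np.diag(cc), np.ones(4))
    np.testing.assert_array_equal(np.diag(lag), np.zeros(4))
    assert np.all(np.abs(cc) <= 1 + 1e-12)


def test_estimate_period_from_double_peak_signal():
    t = np.arange(1000) / 50.0
    v = np.zeros_like(t)
    for k in range(40):
        v += 2 * np.exp(-((t - (k * 0.5 + 0.1)) ** 2) / (2 * 0.03**2))
        v += 1 * np.exp(-((t - (k * 0.5 + 0.3)) ** 2) / (2 * 0.06**2))
    period = bs.estimate_period(_trace(v))
    assert period == pytest.approx(0.5, rel=0.15)
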