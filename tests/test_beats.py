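"""Peak detection, classification and beat measures."""

import numpy as np
import pytest

import beatscope as bs
from beatscope.beats import CONTRACTION, RELAXATION, UNCLASSIFIED


def pulse_train(
    fps=50.0,
    n_beats=8,
    pcl=0.5,
    amp_c=2.0,
    amp_r=1.0,
    sig_c=0.03,
    sig_r=0.07,
    drop_relaxation_of_beat=None,
):
    """Composite-style trace with one sharp-tall and one wide-short peak per
    beat; contraction peak at onset+0.10 s, relaxation at onset+0.30 s."""
    t = np.arange(0, n_beats * pcl, 1.0 / fps)
    v = np.zeros_like(t)
    events = []
    for k in range(n_beats):
        t_c, t_r = k * pcl + 0.10, k * pcl + 0.30
        v += amp_c * np.exp(-((t - t_c) ** 2) / (2 * sig_c**2))
        events.append((t_c, CONTRACTION))
        if drop_relaxation_of_beat != k:
            v += amp_r * np.exp(-((t - t_r) ** 2) / (2 * sig_r**2))
            events.append((t_r, RELAXATION))
    trace = bs.CompositeTrace(values=v, times=t, tau_frames=1, fps=fps)
    return trace, events


def test_detects_simple_local_maxima():
    trace = bs.CompositeTrace(
        values=np.array([0, 1, 0, 2, 0.0]), times=np.arange(5) / 5.0, tau_frames=1, fps=5.0
    )
    peaks = bs.detect_peaks(trace, min_separation_s=0.05)
    assert [p.index for p in peaks] == [1, 3]
    assert peaks[1].amplitude == 2.0


def test_constant_trace_yields_no_peaks():
    trace = bs.CompositeTrace(
        values=np.ones(10), times=np.arange(10) / 50.0, tau_frames=1, fps=50.0
    )
    assert bs.detect_peaks(trace) == []


def test_two_peaks_detected_per_beat(single_region_video):
    stack, gt = single_region_video(duration=5.0)  # 10 beats
    res = bs.BeatModel.from_stack(stack, tau_frames=2).fit()
    n_events = len(gt.regions[0].contraction_times) + len(gt.regions[0].relaxation_times)
    # all interior events found (boundary beats may lose a peak to the trace edge)
    assert abs(len(res.table.peaks) - n_events) <= 2


def test_ratio_drop_arithmetic_and_boundaries():
    trace = bs.CompositeTrace(
        values=np.array([0.4, 1.0, 0.6]), times=np.arange(3) / 50.0, tau_frames=1, fps=50.0
    )
    assert bs.ratio_drop(trace, 1, 1) == pytest.approx(0.5)
    flat = bs.CompositeTrace(
        values=np.ones(3), times=np.arange(3) / 50.0, tau_frames=1, fps=50.0
    )
    assert bs.ratio_drop(flat, 1, 1) == pytest.approx(1.0)  # plateau: no drop
    with pytest.raises(ValueError):
        bs.ratio_drop(trace, 0, 1)
    with pytest.raises(ValueError):
        bs.ratio_drop(trace, 1, 2)


def test_classification_separates_sharp_tall_from_wide_short():
    trace, events = pulse_train()
    peaks = bs.classify_peaks(bs.detect_peaks(trace), trace)
    labeled = [p for p in peaks if p.label != UNCLASSIFIED]
    assert len(labeled) >= 2 * 8 - 2
    for p in labeled:
        t_true, lbl_true = min(events, key=lambda e: abs(e[0] - p.time))
        assert p.label == lbl_true
    # contraction peaks drop faster around the maximum
    rd_c = [p.ratio_drop2 for p in labeled if p.label == CONTRACTION]
    rd_r = [p.ratio_drop2 for p in labeled if p.label == RELAXATION]
    assert max(rd_c) < min(rd_r)


def test_missing_relaxation_flags_orphan_and_keeps_other_beats():
    trace, _ = pulse_train(drop_relaxation_of_beat=3)
    peaks = bs.classify_peaks(bs.detect_peaks(trace), trace)
    table = bs.beat_measures(peaks)
    assert sum(1 for p in peaks if p.label == UNCLASSIFIED) >= 1
    # beats 4 and 5 (around the gap) are lost, the others survive intact
    assert 5 <= table.n_beats <= 7
    assert np.allclose(table.beats["delta_rc"].dropna(), 0.20, atol=0.021)


def test_fewer_than_four_peaks_stay_unclassified():
    trace = bs.CompositeTrace(
        values=np.array([0, 1, 0, 2, 0, 1.5, 0.0]),
        times=np.arange(7) / 10.0,
        tau_frames=1,
        fps=10.0,
    )
    peaks = bs.classify_peaks(bs.detect_peaks(trace, min_separation_s=0.1), trace)
    assert all(p.label == UNCLASSIFIED for p in peaks)


def test_classification_invariant_to_intensity_scaling():
    trace, _ = pulse_train()
    labels = [p.label for p in bs.classify_peaks(bs.detect_peaks(trace), trace)]
    for c in (0.01, 137.0):
        scaled = bs.CompositeTrace(
            values=c * trace.values, times=trace.times, tau_frames=1, fps=trace.fps
        )
        labels_c = [p.label for p in bs.classify_peaks(bs.detect_peaks(scaled), scaled)]
        assert labels_c == labels


def test_beat_measures_representative_acquisition():
    # two beats: contractions at 1.00/1.64 s (amp 1.9), relaxations at
    # 1.22/1.86 s (amp 1.0) -> T = 0.64 s, delta_rc = 0.22 s, ratio = 1.9
    peaks = [
        bs.PeakRecord(50, 1.00, 1.9, 0.5, 0.3, CONTRACTION),
        bs.PeakRecord(61, 1.22, 1.0, 0.9, 0.8, RELAXATION),
        bs.PeakRecord(82, 1.64, 1.9, 0.5, 0.3, CONTRACTION),
        bs.PeakRecord(93, 1.86, 1.0, 0.9, 0.8, RELAXATION),
    ]
    table = bs.beat_measures(peaks)
    assert table.n_beats == 2
    assert table.beats["T"].iloc[0] == pytest.approx(0.64)
    assert np.isnan(table.beats["T"].iloc[1])  # last beat has no successor
    assert table.beats["delta_rc"].tolist() == pytest.approx([0.22, 0.22])
    assert table.beats["ratio_cr"].tolist() == pytest.approx([1.9, 1.9])
    assert table.summaries["delta_rc_mean"] == pytest.approx(0.22)


def test_equal_amplitudes_give_unit_ratio():
    peaks = [
        bs.PeakRecord(0, 0.1, 1.5, 0.5, 0.3, CONTRACTION),
        bs.PeakRecord(1, 0.3, 1.5, 0.9, 0.8, RELAXATION),
    ]
    table = bs.beat_measures(peaks)
    assert table.beats["ratio_cr"].iloc[0] == pytest.approx(1.0)


def test_noise_floor_correction_recovers_quadrature_amplitudes():
    peaks = [
        bs.PeakRecord(0, 0.1, 2.5, 0.5, 0.3, CONTRACTION),
        bs.PeakRecord(1, 0.3, 1.3, 0.9, 0.8, RELAXATION),
    ]
    floor = 0.5
    table = bs.beat_measures(peaks, noise_floor=floor)
    expect = np.sqrt(2.5**2 - floor**2) / np.sqrt(1.3**2 - floor**2)
    assert table.beats["ratio_cr"].iloc[0] == pytest.approx(expect)


def test_trend_exact_line_and_degenerate_cases():
    x = np.array([0.5, 0.8, 1.1, 1.4, 1.7])
    slope, intercept, corr = bs.trend_vs_period(np.column_stack([x, 0.072 * x + 0.166]))
    assert slope == pytest.approx(0.072)
    assert intercept == pytest.approx(0.166)
    assert corr == pytest.approx(1.0)
    slope, intercept, corr = bs.trend_vs_period(np.column_stack([x, np.full(5, 2.0)]))
    assert slope == 0.0 and corr == 0.0
    with pytest.raises(ValueError):
        bs.trend_vs_period(np.column_stack([np.ones(5), x]))


def test_trend_recovers_slope_from_noisy_line():
    rng = np.random.default_rng(11)
    x = rng.uniform(0.5, 2.0, 200)
    y = 0.072 * x + 0.166
    y_noisy = y + rng.normal(0, 0.1 * np.ptp(y), 200)
    slope, _, corr = bs.trend_vs_period(np.column_stack([x, y_noisy]))
    assert slope == pytest.approx(0.072, rel=0.05)
    assert corr > 0.9
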