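# Methods

## The composite motion signal

For a grayscale stack M(t) at frame rate fps, the global composite signal is

    ΔS(t) = mean_ij |M_ij(t) − M_ij(t−τ)| / τ_s ,   τ_s = tau_frames / fps.

Two conventions are deliberate and documented because the defining formula
leaves them open:

* **τ in the denominator is in seconds**, not frames, so ΔS is a rate
  (intensity units · s⁻¹) and values are comparable across frame rates.
  Nothing downstream depends on this choice — every beat measure is a time
  or a ratio — but absolute ΔS values do.
* **ΔS(t) is assigned to the later frame of the pair.** The alternative
  (interval midpoint) would shift all peak times by τ_s/2; since both
  contraction and relaxation peaks shift equally, T and Δ_R–C are unchanged
  either way, and the later-frame convention keeps peaks aligned with the
  moment the motion has been observed.

Intensities are converted to floating point but never rescaled on read: ΔS
is homogeneous in intensity (c·M ⇒ c·ΔS), and the classifier and all beat
measures are built only from ratios and times, so camera gain and bit depth
are irrelevant to the results.

Local signals apply the same formula to each nsub×nsub pixel block (default
10 px), tiling from the top-left corner; trailing pixels that do not fill a
block are dropped rather than padded, so every grid cell averages the same
number of pixels and the unweighted mean of the local signals equals the
global signal exactly whenever nsub divides both dimensions (a tested
identity).

### Choosing tau_frames

The τ-frame difference is a moving window of width τ_s over the motion
waveform. Two opposing effects:

* the rectified sensor-noise floor of ΔS scales as 1/τ_s — larger τ
  suppresses noise;
* a window wider than a velocity pulse smears it; because the contraction
  pulse is the narrower one, smearing biases Ratio_C/R downward (for a
  Gaussian velocity pulse of width σ and window T the peak is attenuated by
  (σ√2π/T)·erf(T/(2√2 σ)), ≈ 5% at T = σ, ≈ 20% at T = 2.3 σ).

The library default is 4 frames (a reasonable noise/sharpness compromise at
50 fps for typical cultures). The validation runs use tau_frames = 2 because
the generator's contraction pulse width (tau_c = 0.035 s ≈ 1.75 frames at
50 fps) makes a 4-frame window the dominant error source. Rule of thumb:
keep τ_s at or below the contraction time constant.

## Peak detection and classification

Detection is `scipy.signal.find_peaks` with a prominence threshold relative
to the signal range (default 0.1 — the two per-beat peaks are order-of-range
features) and a minimum separation (default 0.05 s, well below any
physiological Δ_R–C). A constant trace yields no peaks, not an error.

With `refine_times=True` peak times and amplitudes are refined by a
least-squares parabola through the five samples around each maximum (three
at trace ends). The relaxation peak is wide and nearly flat on top, so its
argmax alone can slip ±1 frame under noise; the parabolic apex localizes it
to a fraction of a frame and keeps per-beat Δ_R–C errors below one frame
interval at sensor noise up to 20% of texture contrast.

Classification combines three criteria:

1. **Cluster separation** — 2-means (10 restarts, fixed seed) on the
   standardized (Δt_markers, ΔS_peaks) plane, where Δt_markers is the time
   since the previous detected peak (the first peak uses its forward gap).
   Standardization makes the step scale-invariant in both axes.
2. **Peak sharpness** — the cluster with the lower mean ratio_drop2 (mean of
   the samples two positions before/after the peak divided by the peak) is
   the contraction family: contraction peaks lose amplitude faster around
   the maximum. The before/after samples are averaged for symmetry. If the
   two clusters degenerate to identical centroids the classifier falls back
   to a median split on ratio_drop2; if the drop means tie exactly, the
   taller family is taken as contraction.
3. **Alternation** — labels must alternate in time. Violating pairs are
   resolved by keeping the peak closer to its cluster centroid
   (standardized distance) and flagging the other unclassified; the pass
   repeats until no violation remains.

Peaks within two samples of a trace end carry no ratio_drop2 and stay
unclassified; fewer than four classifiable peaks leave everything
unclassified (no meaningful clustering). Beats that span unclassified peaks
are dropped from the per-beat table rather than interpolated.

## Beat measures and the noise floor

Per beat: T = time to the next contraction peak (the last beat has none),
Δ_R–C = relaxation time − contraction time, Ratio_C/R = contraction
amplitude / relaxation amplitude. Acquisition summaries are unweighted
means ± sample SD over beats.

Because ΔS is a rectified mean, independent per-pixel sensor noise does not
average away but adds a floor: for a pixel-wise Gaussian motion-signal
distribution, ΔS ≈ c·sqrt(σ²_motion + 2σ²_noise), so raw amplitude ratios
are biased toward 1 as noise grows. The pipeline therefore estimates the
diastolic floor F as the 10th percentile of the trace and corrects peak
amplitudes in quadrature, A′ = sqrt(A² − F²), before forming Ratio_C/R
(`noise_floor="auto"`; pass 0 for the plain ratio). On noiseless input the
floor is ≈ 0 and the correction is a no-op; at 20% noise it reduces the
mean Ratio_C/R error on synthetic videos from ≈ 30% to under 10%. T and
Δ_R–C need no correction — the floor is a smooth offset that does not move
peak times.

The residual −5…−9% Ratio_C/R bias on synthetic videos has two understood
sources: the τ-window smearing above, and the mild sub-linearity of
|ΔM| in displacement once the per-window displacement approaches the
texture correlation length.

`trend_vs_period` fits an ordinary least-squares line of an acquisition
summary against mean period (the period-dependence analysis); a constant
measure returns slope 0 / correlation 0, constant periods are a degenerate
design and raise.

## 1-D shortening traces

Sarcomere-length or cell-length recordings are analyzed through the
rectified first-difference derivative |dL/dt| (length N−1, assigned to the
later sample — the same convention as ΔS), then the identical peak pipeline
with no trace-specific tuning. Measures are invariant to adding a constant
and to sign flips. `trace_measures` skips the first beat(s) by default
(`skip_first_beats=1`), the convention for short paced recordings whose
first contraction is a transient.

## Regional synchrony

* **Energy**: E = mean of (first-difference dΔS/dt)² per grid cell;
  log-energy uses the natural log (a convention — thresholds are user
  parameters), with log 0 = −∞ so static cells never pass the mask.
  The threshold separating the sensor-noise mode from the beating modes of
  the log-E histogram is an analysis parameter to be read off the
  histogram; `suggest_log_threshold` offers an Otsu split of the finite
  log-energies as a starting point, which is a heuristic, not part of the
  method — it misleads when the field has no static cells or when beating
  regions of very different motion amplitude coexist.
* **CC/lag maps**: per masked cell, Pearson correlation with the global
  signal at every integer-frame lag in [−L, +L], each overlap segment
  mean-centered and normalized per lag (shorter overlaps are not
  penalized; minimum overlap one half of the trace). The map stores the
  maximum and its lag; positive lag = the local signal lags the global.
  L defaults to one estimated beat period (median spacing of every second
  detected peak of the global signal — two peaks per beat), preventing
  lock-on to the neighboring beat. Ties between equal-cc lags resolve to
  the smallest |lag|, negative before positive. Zero-variance cells are
  flagged undefined and removed from the mask.
* **Clusters**: connected components (4-connectivity by default) of masked
  cells with cc below threshold (default 0.4), labeled 1..K by decreasing
  size; components below `min_cells` (default 2) are discarded.
* **Cluster matrices**: cluster signals are unweighted means of member-cell
  local signals; pairwise maximum correlation and lag are computed once per
  (i, j) pair and mirrored, so cluster_cc is symmetric with an exactly unit
  diagonal and cluster_lag antisymmetric with an exactly zero diagonal.

## The synthetic generator

The generator emulates what the analysis needs from a recording — textured
frames whose motion follows a two-phase contraction waveform — not the
optics or biology of a particular preparation.

**Waveform.** Each beat is a pair of Gaussian velocity pulses: contraction
of width tau_c, relaxation of width tau_r, areas balanced so the tissue
returns to rest. The pulse pair is placed at fixed multiples of the time
constants (contraction peak 2.5·tau_c after onset; relaxation peak
1.5·(tau_c+tau_r) later), so the ground truth obeys

    Ratio_C/R = tau_r / tau_c ,   Δ_R–C = 1.5 (tau_c + tau_r),

both strictly increasing in tau_r — the asymmetry the beat measures are
designed to read out, controlled by exactly two knobs. A smooth pulse shape
is essential: any waveform with a velocity kink at beat onset (e.g. a pure
rising exponential) puts the contraction "peak" on a discontinuity whose
sampled amplitude depends on the sampling phase by tens of percent,
making sub-10% amplitude recovery ill-posed at video frame rates.
Ground truth is nevertheless computed by brute force — |d(shortening)/dt|
peaks located on a 100× refined grid per beat — not from the design
formulas, so tests compare against what the waveform actually does.

Defaults: tau_c = 0.035 s, tau_r = 0.065 s (Ratio ≈ 1.86, Δ_R–C ≈ 0.15 s —
the regime reported for healthy neonatal monolayers, contraction roughly
twice as fast as relaxation), amplitude = 8% fractional shortening,
PCL = 0.5 s. A validity constraint 4.5·(tau_c+tau_r) ≤ pcl keeps each
beat's pulses (with 3σ tails) inside its cycle; outside it beats merge and
ground truth would be ill-posed. Optional Gaussian onset jitter models
rhythm variability.

**Video.** A Gaussian-smoothed random texture (smoothing length
`texture_scale`, SD normalized to 1 so `noise_sd` reads directly as a
fraction of texture contrast, mean offset 100) is warped per region by
bilinear inverse mapping. The displacement of a pixel at distance r from
the region centroid is

    u = a(t) · [ (p − c) · R0/(R0 + r)  +  R0 · ĝ(t) ] ,

with a(t) the instantaneous shortening fraction and R0 = 30 px. The first
term is radial contraction toward the centroid with a saturating lever arm:
contraction is driven by cell-scale foci (R0 ≈ 20 µm at typical 10×
magnification), so displacement must not grow without bound with region
size — unbounded growth would make motion amplitude an artifact of the
field-of-view and push the periphery into the nonlinear |ΔM| regime. The
second term is a bulk drift of the same scale (every patch of a monolayer
is also tugged by its surroundings); its direction ĝ precesses slowly
(10 s period) so the two terms never cancel at a fixed pixel for long.
Since |radial| < a·R0 = |drift| strictly, no cell inside a beating region
is ever static — without the drift term the cells at the region centroid
would not move at all, a toy-kinematics artifact with no counterpart in
real tissue. Gaussian sensor noise is added per pixel per frame; everything
is deterministic given the spec seed (independent substreams for texture,
noise and per-region randomness).

**What passing tests do and do not show.** The generator shares the
analysis' idealizations: stationary rhythm, spatially uniform kinetics
within a region, white sensor noise, no photobleaching, no focus drift, no
cell migration, no out-of-plane motion. Recovery of T/Δ_R–C/Ratio_C/R from
generator output therefore validates the signal path — Eq-style composite
signal, detection, classification, measures, maps — under controlled
conditions; it does not certify accuracy on real cultures, where kinetics
vary beat to beat, textures deform non-affinely, and the contraction
waveform is not two-Gaussian. The measures' *definitions* are
waveform-agnostic; the *recovery tolerances* quoted are generator-specific.

## Validation problem sizes

The recovery studies use 30 s, 50 fps, 160×160 px videos (≈ 60 beats,
1500 frames) over 10 seeds at 0% and 20% noise; heterogeneity detection
uses 140×140 px with a 40×40 independent region (PCL 0.77 s vs 0.5 s
background, max-lag window = one beat period, log-E threshold 5.0 — between
the sensor-noise mode ≈ 4 and the beating modes ≥ 6 of the histogram);
the monotonicity sweep covers a 5×5 (tau_c, tau_r) grid at PCL 1 s through
the full 1-D trace pipeline. These sizes are large enough that quantization
(one frame = 0.02 s) and estimator noise, not sample size, set the error.

## Known limitations

* ΔS aggregates all motion; it cannot separate contraction from rigid
  drift or vibration. Slow drift raises the floor estimate, not the peaks.
* Relaxation waveforms with a double-hump velocity profile (seen in some
  ionic-model simulations) can move the relaxation marker between humps;
  the pipeline takes the global maximum of the relaxation window.
* The 2-means step assumes the two peak families are the dominant
  structure; heavily arrhythmic traces (missing peaks, multi-peak
  complexes) degrade to partially unclassified output rather than failing,
  and such recordings are better inspected through the regional pipeline.
* MP4/AVI input is read-only and subject to codec loss; quantitative work
  should use TIFF or raw arrays.
* The noise-floor quadrature correction assumes an approximately Gaussian
  pixel-wise motion-signal distribution; structured noise (line noise,
  flicker) violates it.
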