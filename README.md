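# beatscope

Contractility and regional-synchrony analysis of videomicroscopy recordings
of beating cell cultures (neonatal cardiomyocyte monolayers, stem-cell
derived cardiomyocyte sheets), aimed at low-cost functional screening:
rhythm, contraction kinetics and spatial homogeneity extracted from nothing
but a phase-contrast video — no dyes, no electrodes.

## The signal and the measures

Let M(t) be the camera frame at time t. The **composite motion signal** is
the mean absolute pixel difference between frames separated by a delay of
τ frames,

&nbsp;&nbsp;&nbsp;&nbsp;ΔS(t) = (1 / NxNy) Σᵢⱼ |Mᵢⱼ(t) − Mᵢⱼ(t−τ)| / τΔt,&nbsp;&nbsp;Δt = 1/fps,

a surrogate for mean tissue speed. Each beat produces **two** ΔS maxima: a
sharp, tall peak from contraction (shortening) and a wider, lower one from
relaxation — exactly the shape of the rectified sarcomere-shortening
velocity |dSL/dt|. Peaks are classified automatically using three criteria:
contraction/relaxation alternate in time; the two families separate as
clusters in the (inter-peak interval Δt_markers, amplitude ΔS_peaks) plane
(2-means); and the signal drops faster around contraction peaks, measured by
Ratio_drop = mean(ΔS at ±k samples)/ΔS_peak.

Per beat this yields

* **T** — period, time between consecutive contraction peaks (s);
* **Δ_R–C** — time from the contraction peak to the following relaxation
  peak (s);
* **Ratio_C/R** — contraction / relaxation peak amplitude; > 1 means
  contraction is faster than relaxation, as healthy cardiomyocytes show.

For spatial analysis the same signal is computed on an n×n-pixel grid
(local ΔS), cells are gated by the energy E = ⟨(dΔS/dt)²⟩ of their signal,
and each active cell is compared with the global ΔS by maximum lagged
Pearson correlation. Connected groups of low-correlation cells expose
regions beating out of sync (or at their own rhythm), and cluster-to-cluster
correlation/lag matrices quantify their timing relations.

A fully ground-truthed synthetic-video generator (two-time-constant
contraction waveform driving radial displacement of a random texture, plus
sensor noise) makes every stage testable without recorded data.

## Worked example

```python
import beatscope as bs

wf = bs.WaveformSpec(pcl=0.5)                     # 120 bpm pacing
spec = bs.VideoSpec(height=160, width=160, fps=50, duration=30,
                    noise_sd=0.1,                 # 10% of texture contrast
                    regions=[bs.Region(waveform=wf, rect=(0, 0, 160, 160))],
                    seed=42)
stack, truth = bs.make_video(spec)

model = bs.BeatModel.from_stack(stack, tau_frames=2)
result = model.fit(refine_times=True)
print(result.summary())
```

```
Beat analysis summary
==============================================
samples:              1498  @ 50 fps
tau_frames:           2
peaks detected:       120  (unclassified: 0)
beats:                60
noise floor:          2.82
----------------------------------------------
period T:                0.5 +- 0.0002069 s
delta_RC:             0.1547 +- 0.0007251 s
ratio_C/R:             1.644 +- 0.01478 n.u.
==============================================
```

All 120 peaks (60 beats × contraction + relaxation) are found and labeled;
the period matches the imposed 0.5 s pacing to sub-millisecond precision,
Δ_R–C is within a fraction of a frame of the generator truth (0.152 s), and
Ratio_C/R (truth 1.79) is recovered within ~8% — the residual bias comes
from the τ-frame window slightly smearing the sharper contraction peak (see
`docs/methods.md`). Real recordings are analyzed the same way via
`BeatModel.from_video("myculture.tif", fps_override=50)`; 1-D
sarcomere-length or cell-shortening traces via `BeatModel.from_shortening`.

Regional analysis mirrors this interface:

```python
sync = bs.SynchronyModel(stack, tau_frames=2, nsub=10).fit(
    log_energy_threshold=5.0, cc_threshold=0.4)
print(sync.summary())         # active cells, low-cc clusters, cluster lags
sync.plot_maps()              # log-energy / CC / lag / cluster heat maps
```

The same workflows are scriptable from the shell:

```sh
beatscope simulate spec.yaml -o video.tif     # synthetic video + truth JSON
beatscope beats video.tif -o run/             # peak/beat CSVs + summary
beatscope regional video.tif -o run/          # energy/CC/lag/cluster maps
beatscope trace shortening.csv -o run/        # 1-D trace analysis
```

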