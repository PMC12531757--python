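# heartchip

Quantification toolkit for imaging readouts of vascularized,
perfusable heart-on-a-chip models of myocardial ischemia: calcium-transient
beat analysis with coefficient-of-variation arrhythmia indices,
microvascular network morphometry, tracer-based vascular permeability, and
liposome extravasation colocalization — together with seeded synthetic-data
generators that make every analysis testable by parameter recovery.

It is aimed at groups running GCaMP cardiomyocyte recordings and CD31
confocal stacks on microphysiological chips who want the standard
ImageJ/MATLAB-style measurements as reproducible, scriptable Python with
explicit units and provenance.

## What it measures

**Calcium transients** (`heartchip.calcium`). From a ΔF/F0 = (F − F0)/F0
trace, each beat contributes an onset (10 % amplitude crossing), peak,
amplitude (peak − local baseline), time to peak, and time to 80 % decay
(first post-peak time at peak − 0.8·amplitude). Per recording:

- beat frequency f = 1/mean(IBI), with IBI the interval between
  consecutive peaks;
- CV(f) = sd(fᵢ)/mean(fᵢ) over instantaneous frequencies fᵢ = 1/IBIᵢ and
  CV(amplitude), the arrhythmia indices (sample sd, n−1);
- day-0 normalization for longitudinal drug studies: every metric divided
  by the same chip's pre-treatment value.

**Vessel morphometry** (`heartchip.vessels`). Max projection → Gaussian
blur (σ = 2 px) → triangle threshold → erosion → median despeckle →
2-D skeletonization. Metrics: vessel area fraction, total network length
(orthogonal steps 1 px, diagonal √2 px), mean diameter = area / skeleton
length, connectivity = junctions / endpoints, and the extravascular
fraction of a liposome channel outside the (optionally dilated) vessel
mask.

**Permeability** (`heartchip.permeability`). Linear-regime tracer influx,
dI_t/dt = P · (I_v − I_b) · S/V with S/V = 4/d for a cylindrical vessel,
so the apparent permeability is

    P = slope / (I_v − I_b) × d/4        [cm s⁻¹, d in cm]

with the slope fitted by least squares over all frames (0–12 min).

**Statistics** (`heartchip.stats`). Normality-gated group comparison:
Shapiro–Wilk per group; all normal → one-way ANOVA + Dunnett
control-vs-each; otherwise Kruskal–Wallis + Dunn (Holm-adjusted); plus the
two-tailed unpaired Student's t-test for two groups.

**Synthetic data** (`heartchip.synthetic`). Seeded generators for beat
trains (gamma inter-beat intervals, lognormal amplitudes, linear-rise /
exponential-decay transients with analytically exact time-to-peak and
decay80), planar vessel networks with known centerline length, diameters,
junction/endpoint counts and coverage, tracer influx stacks with known P,
and liposome/vessel pairs with an exact extravascular fraction. Every
artifact carries a JSON-serializable `GroundTruth`.

## Worked example

```
heartchip demo --seed 1 --out demo_out
```

generates one synthetic bundle (trace, network, tracer stack, liposome
pair), runs every analysis, and prints the ground-truth vs recovered
report (abridged):

```json
{
  "calcium":      {"true_frequency": 1.04, "recovered_frequency": 1.0471,
                   "true_n_beats": 31, "recovered_n_beats": 31},
  "vessels":      {"true_coverage": 0.6454, "recovered_area_fraction": 0.6482,
                   "true_mean_diameter_um": 22.9, "recovered_mean_diameter_um": 18.35},
  "permeability": {"true_cm_per_s": 3.3e-06, "recovered_cm_per_s": 3.3e-06},
  "extravasation": {"true_fraction": 0.618, "recovered_fraction": 0.618}
}
```

Reading it: the beat count and frequency are recovered to within one
sample; permeability inverts the influx model exactly; the extravascular
fraction is exact by pixel count. The mean diameter on this *dense* (64.5 %
coverage) mesh reads 18.4 µm against a 22.9 µm tube truth — the
area/length estimator counts junction-overlap area once, a documented
limitation of the metric on dense networks (see `docs/methods.md`);
diameter-recovery experiments therefore use a sparse chain-dominated
geometry where the estimator is identifiable.

The same workflows are available as `heartchip simulate ...`,
`heartchip analyze calcium|vessels|permeability|extravasation`, and
`heartchip stats` on your own TIFF/CSV data, or directly from Python:

```python
from heartchip import BeatTrainParams, gen_calcium_trace, analyze_trace
trace, truth = gen_calcium_trace(BeatTrainParams(mean_frequency=1.48, seed=1))
summary = analyze_trace(trace)
print(summary.frequency, summary.cv_frequency)   # 1.4793... 0.0517...
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated synthetic data, the recovery of the
study's headline condition values: mean beating rate in the healthy and
vasoconstrictor-treated states, the treated/healthy amplitude ratio,
mean vessel diameter at both conditions, healthy network coverage, the
ischemic-model extravascular liposome percentage, and the day-7/day-0
amplitude fold under high-dose liposomal treatment. It writes one JSON
object mapping each target id to the recomputed value and the sample size
used. Runtime is about 1–2 minutes on one CPU.
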