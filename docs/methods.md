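# Methods

This note records the models, conventions, and calibration choices behind
`heartchip`, in the package's own words: what each procedure assumes, what
the synthetic generators emulate (and do not), and where numerical
behaviour was a design decision rather than a forced consequence.

## 1. Calcium-transient model and beat analysis

### Generator

A recording is modelled as

    F(t) = F0 · exp(−β t) · (1 + Σᵢ s(t − tᵢ; aᵢ)) + ε,   ε ~ N(0, σ²)

with baseline `F0` (default 100 a.u.), photobleaching rate β (default 0),
additive sensor noise σ, and one transient per beat:

    s(τ; a) = a·τ/T_p            for 0 ≤ τ ≤ T_p       (linear rise)
            = a·exp(−(τ−T_p)/τ_d) for τ > T_p           (exponential decay)

with τ_d = T₈₀/ln 5, so the signal at T_p + T₈₀ is exactly 0.2·a: the two
kinetic readouts (time to peak, time to 80 % decay) are analytically exact
properties of the template. Defaults T_p = 0.2 s, T₈₀ = 0.4 s are typical
GCaMP6f transient kinetics at ~1 Hz spontaneous beating; acquisition
defaults are 30 s at 10 ms sampling.

Inter-beat intervals are gamma distributed with shape 1/CV² and scale
mean·CV² — positive support and exact first two moments for any requested
(mean frequency, IBI CV). Per-beat amplitudes are lognormal with matched
mean and CV. CV = 0 degenerates to exact constants. Overlapping transients
sum; configurations in which a transient cannot complete within one mean
period (T_p + T₈₀ ≥ 1/f) are rejected. A beat is only emitted if its peak
fits inside the recording (a truncated final rise is undetectable in
principle and so is not rendered or counted).

Not emulated: motion artifacts, focus drift, calcium alternans,
pixel-level spatial structure within an ROI (traces are generated at the
ROI-mean level). A green recovery test therefore establishes correctness
of the trace-level analysis, not robustness to spatial artifacts.

### Analyzer

ΔF/F0 uses F0 = 10th percentile of the full trace by default (tolerant to
slow drift without needing a pre-beat quiet window; `min` and
`pre-window` selectable). Peaks are `scipy.signal.find_peaks` local maxima
with prominence ≥ 0.2 × (5th–95th percentile range) and separation
≥ 0.2 s (> the ~5 Hz physiological ceiling). Per beat, the local baseline
is the minimum between the previous peak and this one; the onset is the
last upward crossing of baseline + 10 % amplitude before the peak
(linearly interpolated), and decay80 the first interpolated crossing of
peak − 0.8·amplitude. Frequency is 1/mean(IBI) — robust to partial beats
at the edges — and all CVs use the n−1 standard deviation. Fewer than two
beats yield no frequency; fewer than three, no CVs (flagged as missing,
never zero).

**Known bias.** With ~1 Hz beating and T₈₀ = 0.4 s the signal never quite
returns to baseline between beats, so the percentile-F0 sits a few per
cent above the true baseline and the measured ΔF/F0 amplitude is ~5–10 %
below the generator amplitude, with the shortfall growing with amplitude.
Ratios of amplitudes between two arms measured at the same beat rate
cancel most of this (residual ~2 %); this is why amplitude-ratio and
fold-change experiments in the tests and acceptance script simulate both
arms at the same frequency — the comparison isolates the amplitude
effect, as a paired experimental design would.

## 2. Vessel network rendering and morphometry

### Generator

Networks are edge subsets of a Delaunay triangulation over blue-noise
(dart-throwing) node placements — planar by construction, so junction
(graph degree ≥ 3) and endpoint (degree 1) counts are exact by
bookkeeping. Edges are admitted in seeded random order until the measured
foreground fraction reaches the target coverage; edges meeting a kept edge
below a minimum angle are rejected, edges that would create a branch point
are admitted with probability `branch_prob` per round (chains fill first),
and `enforce_clearance` optionally rejects any tube that would touch an
unrelated tube. Tubes are stamped as exact Euclidean distance fields
(pixels within d/2 of the centerline; no anti-aliasing), so pixel counts,
and hence the stored coverage, are exact. Unreachable coverage raises an
error rather than clipping.

Intensities emulate a CD31 max projection at modest SNR: background
200 ± 60 a.u., vessels 350 a.u. with per-segment lognormal brightness
variation (CV 0.1). These defaults are part of a deliberate
generator/pipeline co-design (below). Not emulated: PSF/optics, true 3-D
structure and z-bleedthrough, staining gradients at tissue scale.

### Pipeline calibration (co-design)

The pipeline is blur (σ = 2 px) → triangle threshold → erosion (3×3
cross) → binary median despeckle (radius 2 px). On a blurred two-level
image the triangle threshold lands near the foot of the dominant
(background) histogram peak, i.e. low on the edge ramp, which dilates the
mask by ~2.5 px per side. The erosion count is not dictated by the
procedure the pipeline reimplements (tool defaults unstated), so it is a
free parameter: two iterations, together with the low-contrast intensity
defaults above, cancel the threshold halo. The calibration target was the
mask-recovery invariant — IoU ≥ 0.95 against the rendered truth and
coverage recovered within ±0.02 — verified across seeds in the test
suite; it was fixed before the acceptance quantities were measured and is
not revisited per experiment.

### Skeleton conventions

`skeletonize` (Zhang–Suen-style thinning, topology preserving) gives the
1-px skeleton. Arm counts use connected groups of neighbors in the
circular 8-neighborhood (a bend pixel with three neighbors in two
contiguous groups is *not* a junction). Total length sums adjacent pixel
pairs at 1 px (orthogonal) and √2 px (diagonal) times the mandatory pixel
size. Thinning of tubes much wider than a pixel produces two artifacts
with well-known remedies, both off by default and enabled for
topology-grade analysis:

- **spur pruning** (`spur_prune_px`): terminal branches shorter than the
  given length, attached to a junction, are thinning debris from caps and
  elbows; and
- **junction-zone counting** (`junction_merge_radius_px`): junction
  pixels are dilated into zones and a zone counts as one junction only if
  ≥ 3 distinct branches leave it — this merges the Y-pairs that an
  X-crossing splits into and ignores thickened bends; tips inside a zone
  are not endpoints. A radius of about the tube diameter's half restores
  the centerline-graph count.

Mean diameter = foreground area / skeleton length. **Limitation:** on
dense meshes the union of tubes counts junction-overlap area once, so the
estimator under-reads the true tube width (measured ≈ −20 % at 64.5 %
coverage with 22.9 µm tubes — on the *perfect* mask, not a pipeline
artifact). Diameter-recovery experiments therefore use the sparse,
chain-dominated stated world (`diameter_recovery_params`: coverage 0.25,
node spacing 70 µm, min angle 45°, branch probability 0.1, clearance
enforced), where the estimator is unbiased to ~2 % across seeds;
junction/endpoint-recovery experiments use thin tubes
(`topology_recovery_params`: 12 µm tubes, coverage 0.12, min angle 60°),
where the skeleton is graph-faithful. Coverage-recovery experiments use
the dense 64.5 % world. Connectivity (junctions/endpoints) is undefined
(None) without endpoints, and degenerate masks (area but no length) are
flagged, never silently zeroed.

## 3. Permeability

Forward model: vessel lumen constant at I_v; perivascular tissue

    I_t(t) = I_b + P · (I_v − I_b) · (4/d) · t,      d in cm

the cylindrical surface-to-volume form (V/S = d/4; an area/perimeter
variant can be supplied via `geometric_factor`). The inverse is the
least-squares slope of I_t versus time over all frames divided by
(I_v − I_b) and multiplied by d/4 — exact on noise-free synthetic stacks
and within 10 % at 1 % noise over 20 seeds (tested). Frames with tissue
intensity ≥ 95 % of I_v are excluded with a warning (unless fewer than
two would remain, in which case all are kept and flagged); a negative
slope is reported as-is with a washout/photobleaching warning.

Note on magnitudes: at the defaults (d ≈ 23 µm, 12 min window), P around
3×10⁻⁶ cm s⁻¹ drives the *linear* model's tissue term past the vessel
intensity — physically the influx saturates; the generator flags this
(`linear_regime_violated`) and the inverse remains exact because the
model stays linear mathematically. Tests that want a physically sensible
regime use a larger geometric factor. In real measurements the effective
measurement volume is much larger than the vessel, which rescales the
intensity terms without changing the slope/ratio structure.

## 4. Statistics

Normality is Shapiro–Wilk at α = 0.05 per group (the conventional choice
in the graphing software this workflow mirrors; the source procedure does
not name its test). All groups normal → one-way ANOVA with Dunnett's
control-vs-each post hoc (`scipy.stats.dunnett`, seeded: its p-values are
Monte-Carlo integrals of a multivariate t and would otherwise differ in
the last digits between runs). Any group non-normal → Kruskal–Wallis with
Dunn's rank post hoc (hand-implemented: pooled mid-ranks, tie correction
Σ(t³−t)/(12(N−1)), two-sided normal p, Holm adjustment by default). The
branch taken, the per-group normality verdicts, and any degenerate-input
flags are part of the result. Because both post hocs control the
family-wise error, the workflow's type-I calibration is asserted on the
family-wise rate (fraction of null replicates with any significant
comparison), measured ≈ 0.053 at α = 0.05.

## 5. Reproducibility

Every generator takes one explicit integer seed and touches no global
random state; fixed seed ⇒ byte-identical output (tested). Each synthetic
artifact carries exactly one `GroundTruth` (generator name, full
parameters, derived truths, seed) that round-trips through JSON. Pipeline
reports embed the full `RunConfig`, its hash, the seed, and package
versions, so any analysis is re-runnable from its own output. The
acceptance script derives all stream seeds from the single `--seed`
argument.
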