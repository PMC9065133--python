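# Methods

This note documents the generative model, the analysis chain, the
numerical choices behind both, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Generative model (synthetic data)

**Occupancy.** An intasome presents `n_sites = 16` LEDGF/p75 binding
sites. Sites are occupied independently with probability `occupancy_p`
(binomial occupancy). The experiment reports only per-condition averages;
independence is the minimal model for sixteen structurally equivalent,
surface-exposed sites with no stated cooperativity. Condition presets
calibrate `occupancy_p` so the binomial mean matches the observed
stoichiometry: 6/16 at 0.2 M NaCl, 4/16 at 0.5 M, 2/16 at 1.0 M. An
occupied site carries an active fluorophore with probability
`labeling_efficiency` (default 1.0; labeling was monitored experimentally
but no efficiency is reported).

**Photobleaching.** Each active fluorophore survives frame-to-frame with
probability `1 − bleach_rate`; its recorded bleach frame b (the last
bright frame) is geometric, the discrete analogue of exponential-in-time
bleaching. The default `bleach_rate = 0.005`/frame makes the expected
completeness over the 900-frame (3 min × 5 Hz) movie
`1 − 0.995^900 ≈ 0.989`, consistent with the stated >95% bleaching within
the illuminated field. About 1% of fluorophores therefore survive the
movie; their bleach frames are recorded as ≥ `n_frames` and such traces
surface downstream as "unstable" (incomplete bleaching) or "zero-step"
exclusions, as they would in the real analysis.

**Intensities.** Each fluorophore's unit intensity is drawn once,
Normal(`unit_step_mean` = 50 arb. units, CV `unit_step_cv` = 0.15,
truncated positive), and held until bleaching; trace noise is additive
Gaussian with `noise_sd = 0.15 × unit_step_mean`. Neither scale is printed
in the source experiment; 15% step dispersion and 15% per-frame noise make
individual steps resolvable but not trivially so, which is the regime the
pairwise-difference method was designed for. The Cy3 reference intensity
of a single intasome is Normal(100, 25) truncated positive, so coincident
double complexes typically exceed the 200 arb.-unit exclusion threshold —
the calibration that makes the printed cutoff meaningful in simulation.
Blinking is not simulated; unstable profiles are instead exercised by an
artifact injector that adds persistent upward jumps.

**Fields.** Rendered fields are 512×512 px at 0.16 μm/px (81.92 μm edge,
matching the stated 81.9 μm), with a Poisson number of intasomes (mean
400) at uniform subpixel positions, a 2-D Gaussian PSF (σ = 0.13 μm),
constant background (10) plus a linear gradient (5 across the field), a
camera offset (100), and per-pixel Gaussian read noise
(`read_noise_sd = 1.0`, a separate field-level parameter; see Design
choices). The spot count parameter is treated as the true plating density
even though the source experiment reports 400 as a *detection* count.
Optics beyond the Gaussian PSF (evanescent-depth profile, EM-gain noise
cascade) are out of scope; shot noise is available as an option and off by
default.

**Reproducibility.** Every intasome draws from its own RNG substream
`SeedSequence(seed, spawn_key=(index,))`, so per-trace output is
bit-identical under a fixed (config, seed) and independent of batch size.

## Image processing

The chain reproduces the published processing order: denoise → rolling-
ball background subtraction → bright-spot detection on the temporal mean
of the 5 initial Cy3 frames → per-spot Surf649 trace extraction.

- **Denoising.** The acquisition software's proprietary "advanced
  denoising at a value of 5" is re-specified as Gaussian smoothing with
  σ = strength/5 px (strength 5 ⇒ σ = 1 px): mild, parameterized, monotone
  in strength, identity at 0.
- **Rolling ball.** Grayscale opening with a **flat disk** footprint of
  the ball radius (0.48 μm = 3 px). The flat element is the
  scale-equivariant limit of the classical rolling ball: opening with a
  nonflat (hemisphere) element ties an intensity height to a pixel radius,
  so background subtraction would not commute with photometric rescaling —
  breaking the pipeline's linearity guarantee — and clips spot flux in an
  amplitude-dependent way that distorts step sizes in extracted traces.
- **Detection.** Candidates are local maxima of a scale-normalized
  Laplacian-of-Gaussian response at σ ≈ aperture/3 (matched to the PSF
  core; a kernel at the full 4.875 px aperture radius merges resolvable
  neighbors). The contrast score is the robust SNR of the aperture mean:
  (aperture mean − annulus median) / (annulus MAD·1.4826 / √N_aperture),
  thresholded at the printed 14.5. The annulus (inner radius aperture+2 px,
  width 3 px) uses median/MAD statistics so neighboring spots do not bias
  the local background. Non-maximum suppression is Euclidean at one
  aperture *radius*, keeping the higher-contrast member: at 400
  uniformly placed spots per field, suppression at a full aperture
  diameter would remove ~20% of true spots and cannot reproduce the ~400
  detections per field the acquisition averaged. Centroids are refined to
  subpixel precision by intensity-weighted center of mass. Measured on
  default synthetic fields: recall 0.99 and precision 1.00 against
  non-overlapping ground truth, ~370 detections per field.
- **Extraction.** Per-frame intensity = aperture sum − annulus median ×
  aperture area, on the processed stacks; the Cy3 reference is the same
  measure averaged over the 5 snapshot frames. Apertures clipped by the
  field edge flag the trace for exclusion. Extracted traces correlate with
  the true active-fluorophore time course at r ≈ 0.99 at default noise.

## Step counting

Per trace: median-smooth (window 5 frames — preserves step edges,
suppresses single-frame outliers) → robust noise estimate
σ̂ = median(|ΔI|)/(√2·0.6745) from the raw successive differences (the raw
trace, not the smoothed one, carries the per-frame noise) → pool all
pairwise earlier-minus-later differences of the smoothed trace → Gaussian
kernel density with bandwidth h = max(σ̂, 0.05·ŝ), where ŝ is the largest
single-frame drop (the floor keeps noiseless densities non-degenerate) →
count qualifying local maxima at d > d_min = max(3σ̂, 0.5h), which excludes
the dominant zero-difference peak. The sign convention (earlier minus
later) puts bleaching steps on the positive axis. All thresholds are
ratios of trace-derived quantities, so the count is invariant to positive
rescaling and additive offsets.

**Peak qualification.** A local maximum qualifies if its prominence is at
least 0.2% of the tallest positive-side peak; qualifying peaks closer than
max(h, 0.5 × first-peak position) merge to the taller one. Both knobs are
config-exposed and were calibrated on equal-step benchmarks. The
qualification threshold must be small because the k-th multiple's peak is
carried only by (first plateau × last plateau) frame pairs — a few percent
of the tallest peak's mass even for equal plateau durations — so any
threshold above ~5% mathematically cannot count 16 steps. The merge radius
reflects a resolution limit of the construction: with 15% step-size
dispersion, the cluster of subset-sums around a given multiple splits at
sub-step spacings that carry no extra step information.

**Exclusion filters** run in a fixed order so each excluded trace carries
exactly one reason: edge_clipped → bright_cy3 (Cy3 > 200 arb. units) →
unstable → zero_steps. "Unstable" means a median-smoothed upward
single-frame transition larger than the estimated unit step
(re-brightening), or a final-10%-of-frames mean above 20% of the
initial-10% mean (incomplete bleaching); the incompleteness rule only
applies to traces that show at least one step, so constant traces fall
through to the zero-step exclusion. Cohort bookkeeping asserts
n_traces = n_included + Σ per-reason exclusions on every run.

**Change-point oracle.** An independent validation route: exact dynamic
programming yields the globally RSS-optimal piecewise-constant fit for
m = 0..20 change points; m is selected by
BIC = n·ln(RSS/n) + (2m+1)·ln(n), and the step count is the number of
downward level transitions. A relative RSS floor (10⁻¹² of the trace
variance per frame) keeps the noiseless case well-defined, where BIC then
prefers the smallest m reaching the floor.

## Statistics

Per-condition summaries follow the box-and-whisker convention of the
source figure: boxes at the 25th–75th percentiles, median line, whiskers
at the 10th/90th percentiles, values outside the whiskers listed as
outliers (not Tukey 1.5·IQR). Percentiles use linear interpolation between
closest ranks; the plotting software used for the original analysis does
not document its rule, and the choice is config-visible in one place.
"Average" is the arithmetic mean of included counts; medians are reported
alongside. Cross-condition comparison is a tie-corrected Wilcoxon rank-sum
z with two-sided p; for small cohorts (combined n ≤ 12) the p-value is
computed by exhaustive enumeration of all assignments, which is exact
under ties.

## Measured performance and known limitations

All numbers below are produced by the test suite and analysis scripts at
the package's default study conditions.

- Salt-series recovery (500 traces/condition): cohort means 5.92 / 3.96 /
  2.25 against generative means 6 / 4 / 2. The 1.0 M cohort mean exceeds
  2 by construction: ~12% of intasomes carry zero labeled subunits there
  and are excluded as zero-step traces, so the included-cohort mean is
  E[k | k ≥ 1] ≈ 2.27 — the same selection the real analysis applies.
- Equal-step exactness: k̂ = k for k = 0..16 on noiseless, well-separated
  staircases; a seeded 16-step benchmark at 5% noise is counted exactly.
- Estimator vs change-point oracle: 97.5% exact agreement at default
  noise with uniform unit steps and bleach events separated by at least
  the smoothing window (k = 1..8). Under the full study conditions — 15%
  step-size dispersion and unconditioned geometric bleach times —
  agreement drops to ~0.90: plateaus shorter than the smoothing window
  and split size clusters defeat the two methods in different ways. This
  is an information limit of 5 Hz sampling with stochastic bleach times,
  not a disagreement about resolvable steps; per-trace exactness falls
  with k while the *mean* bias stays within ±0.5 up to k = 16.
- Detection density: ~370 detections per synthetic 512×512 field at the
  printed settings against 400 simulated spots; the deficit is dominated
  by genuinely coincident spots (closer than one aperture radius) that
  merge into a single detection.

What passing these benchmarks does **not** show: the simulator draws
equal-variance Gaussian noise (no EM-gain excess noise), simulates no
blinking or stage drift, uses a symmetric Gaussian PSF, and ties the Cy3
scale to a clean bimodal single/double distribution. Real data violates
all of these to some degree; the printed thresholds (contrast 14.5,
Cy3 > 200) were tuned by the original authors on real images, and their
values are carried here as defaults rather than re-derived.

## Problem sizes

Defaults were chosen to keep the full simulation-to-statistics cycle
interactive: 500 traces per condition for cohort statistics (standard
error of the mean ≈ 0.1 steps), 900-frame traces as acquired, 20 full
fields for the detection-density benchmark, and reduced field extents
(96–160 px) for the two-channel end-to-end demos, which exercise the
identical code path as full fields.
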