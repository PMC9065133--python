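# smstoich — single-molecule photobleaching stoichiometry

`smstoich` counts how many fluorescently labeled subunits are bound to a
surface-immobilized protein–DNA complex by single-molecule TIRF
photobleaching, and aggregates the counts into per-condition statistics.
It was built around a concrete experiment: lentiviral (MVV) intasomes —
hexadecameric integrase assemblies presenting sixteen binding sites for the
host factor LEDGF/p75 — are immobilized via a Cy3-labeled viral DNA end,
incubated with SNAP-Surface649-labeled LEDGF/p75, and imaged at 5 Hz while
the Surf649 dyes photobleach. Each irreversible intensity drop is one dye,
so the number of bleaching steps per spot reports the number of bound
LEDGF/p75 molecules, as a function of ionic strength (0.2 / 0.5 / 1.0 M
NaCl washes).

No raw imaging data is deposited for that experiment, so the package ships
a first-class synthetic-data generator that emulates the acquisition
(512×512 EMCCD fields, 160 nm pixels, 5-frame Cy3 snapshots flanking a
3-minute Surf649 movie, ~400 spots per field, binomial site occupancy,
geometric photobleaching reaching >95% completion) with full ground truth,
making every stage of the analysis testable.

## The method

For a background-subtracted trace I(t_0..t_{n-1}), all n(n−1)/2 pairwise
differences between an earlier and a later frame are pooled:

    d_ij = I(t_j) − I(t_i),   t_i > t_j

For k bleaching steps of unit size s the pooled differences concentrate at
0, s, 2s, …, ks; a Gaussian kernel density is formed over the pooled values
(bandwidth set by the trace's own robust noise estimate) and the number of
qualifying local maxima on the positive axis is the step count k̂. The
estimate is invariant to rescaling and offsetting the trace. Spots are
found in the Cy3 reference channel after Gaussian denoising (strength 5 ⇒
σ = 1 px) and rolling-ball background subtraction (r = 0.48 μm), using
bright-spot detection with a 0.78 μm aperture and a noise-normalized
contrast threshold of 14.5. Traces are excluded if the Cy3 reference
exceeds 200 arb. units (likely overlapping complexes), if the aperture is
clipped by the field edge, if the profile is unstable (re-brightening or
incomplete bleaching), or if no step is found. An exact dynamic-programming
change-point fit with BIC model selection provides an independent oracle
for cross-validation of the estimator. Details: [docs/methods.md](docs/methods.md).

## Worked example

```python
from smstoich import FilterParams, condition_preset, count_cohort, simulate_cohort
from smstoich.stats import summarize_condition

cfg = condition_preset("salt_0.2M")      # 16 sites x p = 0.375 -> mean 6
traces, truth = simulate_cohort(cfg, 500, seed=11)
results = count_cohort(traces, FilterParams())
print(summarize_condition(results, "0.2 M NaCl"))
```

The full salt series is scripted under `analysis/` (run in order):

```bash
python analysis/01_simulate_salt_series.py
python analysis/02_detect_spots.py
python analysis/03_count_steps.py
python analysis/04_summarize_conditions.py
```

which prints (numbers from the scripts as shipped):

```
salt_0.2M: mean steps 5.92 (expected 6.0), n_included 486, per-trace bias -0.15, exclusions {'unstable': 14}
salt_0.5M: mean steps 3.96 (expected 4.0), n_included 483, per-trace bias -0.08, exclusions {'unstable': 15, 'zero_steps': 2}
salt_1.0M: mean steps 2.25 (expected 2.0), n_included 420, per-trace bias -0.03, exclusions {'unstable': 47, 'zero_steps': 33}
0.2 M NaCl: n=486 mean=5.92 median=6.0 IQR=[5.0, 7.0] whiskers=[4.0, 8.0] max=12
1.0 M NaCl: n=420 mean=2.25 median=2.0 IQR=[1.0, 3.0] whiskers=[1.0, 4.0] max=6
0.2 M NaCl vs 1.0 M NaCl: rank-sum z=+23.29, p=5e-120
```

The recovered cohort means (5.92 / 3.96 / 2.25) track the generative means
(6 / 4 / 2) within the estimator's bias budget; the cohort mean at 1.0 M
sits slightly above 2 because zero-step traces — which exist at low
occupancy — are excluded from the analyzed cohort, exactly as in the
imaging analysis the package reproduces. `02_detect_spots.py` reports
~374 detections per synthetic 512×512 field against the ~400 spots per
field the acquisition averaged.

A command-line interface mirrors the stages: `smstoich simulate | detect |
count | summarize | run-all` (see `smstoich --help`).

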