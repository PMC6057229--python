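# Methods

`topostat` implements four group-level analyses of multi-subject epoched EEG
that use the whole scalp topography — the vector of all sensor potentials at a
time point — rather than selected sensors. This note documents the models,
conventions, defaults and known limitations.

## Data model and extraction

An epochs dataset holds, per subject and condition, a `trials × sensors ×
timepoints` array in microvolts, with shared sensor and time axes (uniform
step `1000/sampling_rate` ms). Trial counts may differ across blocks. The
HDF5 container mirrors this layout exactly (root attributes `sampling_rate`,
`times`, `sensor_names`; one group per subject; one dataset per condition).

All analyses operate on a view produced by `extract()`:

* **Half-open time slicing.** A time range `[start, end)` in ms maps to
  sample indices by round-half-away-from-zero of `(t − times[0]) ·
  rate/1000`. Half-open slices make adjacent windows partition exactly.
* **Average reference.** By default every trial is re-referenced to its mean
  across the retained sensors at each timepoint; this removes the arbitrary
  recording reference and is the natural companion of GFP and the centred
  angle measure below. It can be disabled. Sensor subsetting, when requested,
  is applied before re-referencing. Re-referencing is skipped when the data
  is already average-referenced over the same sensor set, so extraction is
  exactly idempotent.
* **Windows.** A window grid tiles the extracted range left to right with
  nominal `window_ms` boundaries mapped to sample indices by the same
  rounding rule (so at 1100 Hz a 5 ms grid yields windows of 5 or 6 samples).
  A trailing remainder shorter than half a window is dropped; a longer one is
  kept as a short final window.
* **ERPs.** Subject-level ERPs are trial means; the group ERP is the
  *unweighted* mean of subject ERPs — each subject counts once regardless of
  trial count, matching group-level inference.
* **Missing sensors** are never imputed; a sensor unusable in any subject is
  excluded everywhere, with a logged warning.

## Distribution of significant sensors

Per window and sensor, each subject contributes the window mean of its ERP;
a two-sided paired t-test across subjects compares the two conditions, and
the number of sensors with `p < α` summarises the spatial extent of the
effect over time. This analysis is descriptive — by default no
multiple-comparison correction is applied (the map plays the role of an
"uncorrected p < 0.05" overview); Benjamini–Hochberg across sensors and
windows is available by flag. Degenerate sensors (zero-variance paired
differences) get `p = 1` when the mean difference is zero and `p = 0`
otherwise, instead of NaN.

## Global field power

For a topography `U` over `n` sensors,

    GFP(U) = sqrt( (1/n) Σᵢ (Uᵢ − ū)² ),    ū = (1/n) Σᵢ Uᵢ,

the RMS of the average-referenced values — a reference-free, magnitude-only
summary. GFP is invariant to adding a constant to all sensors and positively
homogeneous of degree 1.

GFP is a nonlinear transform, so the GFP of a group-averaged ERP is *not* the
mean of the per-subject GFPs (two subjects with opposed patterns have zero
group-ERP GFP but positive subject GFPs). Group summaries therefore always
average the per-subject GFP series; the SEM shown is across subjects. Group
statistics use GFP of subject ERPs; trial-level GFP is available but is not
the default. The windowed comparison takes each subject's window mean (or
peak, by flag) of GFP per condition and applies a two-sided paired t-test per
window; uncorrected by default, BH-FDR by flag.

## TANOVA

Pattern similarity between two topographies `A`, `B` is the cosine of their
high-dimensional angle, `cos θ = A·B / (|A||B|)`. Both vectors are
average-referenced first by default: together with the normalisation this
makes the measure independent of reference and of response magnitude, so it
isolates the spatial distribution of the field. `+1` means identical
patterns, `−1` polarity-reversed patterns. A zero-norm topography (possible
only for degenerate inputs) is an error; affected windows get `p = NaN` and a
logged warning rather than failing the whole run.

The observed statistic per window is the cosine between the window-mean
topographies of the two group-averaged ERPs. Its null distribution is built
by one of three label-shuffling strategies (default 1,000 shuffles):

1. **Pooled trials.** All trials of all subjects form one pool; condition
   labels are re-assigned at random preserving the original global
   per-condition counts; pseudo-condition topographies average the pooled
   trials directly (subject identity is discarded by construction).
2. **Within-subject trials.** Labels are re-assigned within each subject's
   trial pool (preserving per-subject counts); subject pseudo-ERPs are then
   averaged across subjects.
3. **Within-subject ERPs.** Subject × condition ERPs are computed once; each
   shuffle independently swaps (or not, with probability ½) the two labels
   within each subject. This is orders of magnitude faster and is the default
   pilot strategy. When `2^S ≤ n_shuffles` the full set of `2^S` assignments
   is enumerated exactly instead of sampled.

Preserving the original trial counts keeps the averaging variance of the
pseudo-conditions matched to the observed ones. All randomness is drawn up
front from the seed, so results are identical whatever the worker count used
to parallelise the computation.

**p-value convention.** The test is one-tailed on the left: a small cosine
means dissimilar patterns, which is the alternative of interest. For a
Monte-Carlo null, `p = (1 + #{null ≤ observed}) / (1 + N)` — the add-one rule
keeps `p > 0` and counts ties as extreme (conservative). For an exhaustively
enumerated null the identity assignment is itself in the null, so the plain
rank fraction `p = #{null ≤ observed} / N ≥ 1/N` is used. The same
conventions apply to the sign-flip group test in the decoding module (with
the inequality reversed, scores above chance being the alternative).

The three strategies are *estimators of different nulls* in general: with
between-subject topography variability, pooling trials across subjects
(Strategy 1) mixes subject structure that the within-subject strategies
preserve. Only under full trial exchangeability (no subject-specific
patterns) do they estimate the same null; the test suite checks their
agreement there as a paired comparison of per-dataset null means over
replicate datasets, because within one dataset the ERP-level null conditions
on quenched trial noise that no number of shuffles removes.

## Temporal correction

Two corrections are available for any windowed p-series:

* **cluster** — keep a window only if it lies in a maximal run of
  consecutive windows with `p < α` whose total duration strictly exceeds
  `min_duration_ms` (default 20 ms). Requires a uniform window grid. A 25 ms
  run at 5 ms windows survives; a 15 ms (or exactly 20 ms) run does not.
* **fdr_bh** — Benjamini–Hochberg step-up across all windows of one
  comparison.

Corrected significance is always a subset of uncorrected significance.

## Pattern classification

Per subject and window, each trial is reduced to its window-mean topography
(one sample, sensors as features; at least 4 trials per condition are
required). The default classifier is L2-regularised logistic regression with
`C = 1.0` on features standardised using the training folds only — a linear
model whose capacity suits the few hundred trials of a typical ERP study.
The score is AUC (robust to class imbalance), averaged over 25 stratified
Monte-Carlo splits with 30 % test fraction ("repeated random splitting", not
k-fold, matching the repeated-partition description of the procedure). Any
estimator with `fit` plus `decision_function`/`predict_proba` can be plugged
in; AUC is invariant to strictly monotone transforms of its scores, so the
two score interfaces are interchangeable.

Per window, the subject AUCs are tested against chance 0.5 with a one-sided
sign-flip permutation test on `scoreₛ − 0.5` (mean as statistic; exhaustive
enumeration when `2^S` fits in the permutation budget). Decoding is sensitive
to both magnitude and pattern differences, so it complements the two
dedicated measures. Per-subject-per-window split seeds and per-window
permutation seeds are derived from the configured seed via a seed tree, so
the whole analysis is reproducible from one integer.

## Synthetic data generator

The generator emulates a multi-subject ERP study: sources are centred unit
spatial patterns (circularly smoothed white noise over a ring layout — real
electrode geometry is irrelevant to the statistics under test) driven by
half-sine amplitude bumps in µV. Condition effects inside `[onset, offset)`
are either `magnitude_scale` (amplitude × scale; topography unchanged) or
`pattern_swap` (orthogonal unit pattern; GFP-matched by construction since
all patterns are centred unit vectors). Noise has three dials: white sensor
noise per sample (default 1 µV), subject pattern jitter (pattern + 0.2 ·
N(0,1), re-centred and renormalised, drawn once per subject), and per-trial
amplitude jitter (× (1 + 0.2 · N(0,1))). Default amplitudes (20 µV peak on a
unit pattern over ~70 sensors) put GFP in the 1–5 µV range typical of ERPs.
Everything is deterministic given the seed; `null_spec` strips all effects
for type-I studies.

What the generator does **not** emulate: 1/f and oscillatory background
activity, spatially correlated noise, realistic volume conduction, latency
jitter across trials and subjects, and artifacts. Passing tests therefore
demonstrate the statistical machinery (calibration, power, dissociation,
onset recovery) under clean assumptions, not performance on real recordings.

## Validation studies and their sizes

The validation module runs four studies, used both by the test suite and by
`scripts/acceptance.py`. Study sizes were chosen once to be informative yet
tractable on a single CPU core:

* **Type-I calibration** — 200 null datasets (16 subjects, 32 sensors, 40
  trials per condition, 100 Hz, 0–300 ms, 100 ms windows); per-window
  rejection rates of all four analyses at α = 0.05 are compared with α within
  3 Monte-Carlo standard errors. Decoding is evaluated on one 100 ms window
  per dataset.
* **Dissociation** — 100 replicates per effect kind (same sizes, 0–200 ms,
  effect in 100–200 ms): a ×1.5 amplitude effect must be caught by the GFP
  comparison (power ≥ 0.9) and ignored by TANOVA (rate ≈ α); an orthogonal,
  GFP-matched pattern swap the reverse; decoding must catch both.
* **Onset recovery** — 20 replicates of a strong pattern effect (low noise)
  starting at 100 ms in a 0–200 ms epoch, 20 ms windows, cluster correction
  (> 20 ms) at α = 0.01; the first corrected-significant window of TANOVA and
  of decoding must start within one window length of the onset. α = 0.01 is
  used here because with windows as long as the minimum cluster duration an
  isolated pre-onset false positive would otherwise survive correction at a
  ~5 % rate per window, making exact onset recovery a coin flip rather than a
  property of the method.
* **Determinism** — identical seed and configuration produce byte-identical
  result tables across repeated runs and across worker counts (randomness is
  pre-drawn from the seed; workers only split deterministic computation).

## Numerical choices and degenerate inputs

* Cosines are clipped to [−1, 1] after computation to absorb rounding.
* Paired t-tests resolve zero-variance differences deterministically (p = 1
  if the mean difference is also zero, else p = 0) instead of returning NaN.
* Ties between observed and null statistics count as extreme (conservative),
  with a 1e-12 absolute tolerance to absorb float noise in recomputed ties.
* Window grids reject windows shorter than one sample period; cluster
  correction rejects non-uniform grids.
* Time-axis uniformity is validated to 1e-9 ms on load.

## Limitations

* Only pairwise comparisons are supported (multi-condition omnibus TANOVA is
  out of scope), matching the pairwise design of all analyses here.
* Strategies 1 and 2 are trial-level and correspondingly slower; Strategy 3
  is the pilot default. They are not interchangeable estimators when
  subjects have distinct topographies (see above).
* Plotting is minimal by design: all figures derive from the saved TSV
  tables, which are the canonical output.
* The HDF5 reader expects the package's own layout; vendor raw formats and
  preprocessing (filtering, artifact rejection, baseline correction) are
  upstream concerns.
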