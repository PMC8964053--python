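# Methods

This package implements resting-state EEG microstate analysis — the
segmentation of multichannel scalp EEG into a small number of quasi-stable
topographic states — together with the group-statistics layer used in
two-group clinical comparisons, and a surrogate-EEG generator that plants a
known microstate structure so that every stage can be validated against
ground truth.

## The microstate model

At each time sample the average-referenced scalp potential is a vector
`v(t) ∈ R^C` (C channels, zero mean across channels).  The model assumes
`v(t) ≈ s(t) · a(t) · T_{L(t)}` where `L(t) ∈ {A, B, C, D}` is a piecewise
constant class sequence (segments of ~60–120 ms), `T_k` are unit-norm
average-referenced template maps, `a(t) ≥ 0` is an amplitude envelope and
`s(t) = ±1` an uninformative polarity.  Key quantities:

- **GFP** (global field power): the spatial standard deviation of `v(t)`,
  `GFP(t) = sqrt(Σ_c v_c(t)² / C)`.  GFP maxima mark moments of strong,
  stable topography; the maps at GFP peaks are the clustering input.
- **Spatial correlation**: Pearson correlation of two maps over channels.
  Polarity invariance means similarity is its absolute value.
- **Modified k-means**: restart-based alternating optimization.  Each map
  is assigned to the template maximizing squared spatial correlation; each
  template is updated to the principal eigenvector of the outer-product sum
  of its assigned maps (the polarity-invariant analogue of the cluster
  mean), re-centered and renormalized.  The objective, **GEV** (global
  explained variance), is
  `GEV = Σ_t (GFP_t · corr(v_t, T_{L(t)}))² / Σ_t GFP_t²`;
  both steps are monotone in GEV, so convergence is checked on its relative
  change (tolerance 1e-7, max 500 iterations, 20 restarts by default,
  restart streams spawned from one seed so the best-of-m result is a prefix
  property in m).  Empty clusters are re-seeded from the currently
  worst-fit map.  Ties in assignment break to the lowest class index.
- **Two-level aggregation**: subject-level template sets are aligned to a
  reference by exhaustive search over all K! permutations × 2^K signs
  (384 candidates at K = 4), averaged per class, re-centered, renormalized;
  the same alignment against a reference set gives canonical A–D labels.
- **Backfitting**: every sample is labeled by the template with maximal
  absolute spatial correlation (`all_samples` domain), or GFP peaks are
  labeled and each sample inherits the label of its nearest peak
  (`gfp_peaks_interpolated`).  Zero-variance samples stay unassigned.
  Epochs are processed independently.
- **Metrics** per class: *duration* (mean segment length, ms), *occurrence*
  (segment onsets per second), *contribution* (fraction of analyzed
  samples).  Segments are maximal same-label runs within an epoch.  Under
  the default `include` boundary policy, epoch-edge-truncated runs count,
  which preserves the identity `duration × occurrence = contribution ×
  1000` exactly whenever no sample is unassigned.  The
  `exclude_truncated` policy drops edge runs from the duration mean and
  onset count (contribution always keeps them).

### A note on per-sample backfitting of noisy data

With band-limited oscillatory activity the instantaneous SNR collapses at
every trough of the amplitude envelope, so per-sample argmax labeling
produces spurious one-sample segments there regardless of the global SNR.
This inflates occurrence and deflates duration.  Two standard remedies are
implemented: labeling in the GFP-peak domain with nearest-peak
interpolation, and a minimum-segment-duration constraint
(`smooth_labels`, which reassigns sub-threshold segments sample-by-sample
to the neighboring class with higher correlation).  Package defaults keep
both off (all-samples fitting, no smoothing); ground-truth recovery
analyses in the test suite and acceptance script apply a 10 ms minimum
duration, and the pipeline exposes `cluster.fit_domain` and
`cluster.smooth_ms` to enable either.

## The surrogate-EEG generator

`microstates.synth` emulates 64-channel, 500 Hz, 2-s-epoch
average-referenced resting EEG organized as a semi-Markov microstate
sequence:

- **Templates**: random zero-mean unit-norm maps; `well_separated` redraws
  until all pairwise |correlations| < 0.5; `orthogonal` Gram–Schmidts in
  the zero-mean subspace (which holds at most C−1 orthogonal maps).
- **Class sequence**: segments alternate classes (no self-transitions).
  Because the stationary segment frequencies of such a chain are
  proportional to `w(1−w)` rather than to the step weights `w`, the
  weights are obtained by numerically inverting `w(1−w) ∝ u` for the
  target frequencies `u`; the first segment is drawn from `u` directly.
- **Durations**: gamma (shape 2) by default — smooth, positive,
  dispersion-controllable — with `fixed` and `geometric` options; all
  rounded to samples and truncated below at 2 samples.  The shape default
  is a free choice (within-subject duration dispersion is rarely
  reported) and is exposed in the spec object.
- **Signal**: per segment, `sign × |sin(2π·10 Hz·t + φ)| × amplitude ×
  √C × T_k` with a random phase per epoch, so the clean GFP equals
  `amplitude × envelope` (default amplitude 5 µV).  The rectified 10 Hz
  envelope lies inside the 2–20 Hz analysis band and yields ~40
  well-defined GFP peaks per 2-s epoch.  Polarity flips with probability
  0.5 per segment, exercising the |correlation| logic.
- **Noise**: spatially and temporally white Gaussian projected onto the
  average-reference subspace, scaled so that (clean GFP RMS)/(noise GFP
  RMS) equals the requested SNR (default 4).

### Cohort layer

Per-subject per-class duration and occurrence parameters are drawn from
group-level normal targets (defaults encode a 23-vs-23 first-episode
schizophrenia vs. control cohort: effects concentrated on classes C and D,
with class-C duration/occurrence/contribution elevated and class-D
occurrence/contribution reduced in patients).  Two calibrations make the
realized metrics match the drawn parameters rather than only approximate
them:

1. **Time-budget rescaling.**  Class occupancies tile each second, so
   `Σ_k occ_k · dur_k = 1000 ms/s` must hold per subject; drawn durations
   are rescaled by the (small) factor that enforces the identity, keeping
   the drawn occurrence parameters exact and removing a convexity bias
   that otherwise inflates realized occurrence.
2. **Renewal onset correction.**  In an epoch of length T with an onset at
   t = 0, the expected onset count is ≈ `T/μ + 1/2 + cv²/2` (renewal
   theory), not `T/μ`; mean durations passed to the simulator are inflated
   by the matching factor.  The same inflation offsets the downward
   duration bias from epoch-edge truncation.

Symptom subscores (PANSS-like positive/negative/general, total = their
sum) are drawn for the patient group; the designated subscore (positive)
is drawn from a bivariate normal with the designated metric's standardized
draw (class-D occurrence) at target correlation r = −0.416.  Realized
sample correlations are slightly attenuated relative to the target because
the realized metric adds within-subject counting noise to the drawn
parameter.  Demographics (sex counts, age, education) scale the reference
cohort's composition to the requested group sizes.

What the generator does **not** emulate: volume-conducted source activity
(no forward model), 1/f background spectra, spatially correlated or
non-stationary noise, ocular/muscle artifacts, and within-segment
topography drift.  Passing tests therefore demonstrate the correctness of
the algorithmic machinery and its statistical calibration, not robustness
to every property of real EEG.

## Preprocessing

`read_recording` ingests EDF and BrainVision files via mne and a plain
tab-delimited matrix container (samples × channels, JSON sidecar with the
sampling rate).  EDF writing is a minimal 16-bit writer (quantization
error ≈ physical range / 65535).  The chain is: polyphase resampling to
500 Hz → 0.1–70 Hz bandpass → 48–52 Hz notch → non-overlapping 2-s epochs
(trailing remainder dropped) → peak-to-peak epoch rejection (default
150 µV, a deterministic stand-in for manual/ICA artifact removal — the
surrogate data carry no ocular artifacts) → common average reference →
2–20 Hz bandpass per epoch.  All filters are order-4 Butterworth applied
forward–backward (zero phase); per-epoch filtering uses reflection
padding.  Bad channels are dropped with a warning, not interpolated.  The
whole chain is deterministic and logged step by step.

The 2 Hz high-pass has an impulse response long relative to 60–80 ms
segments, so filtering smears segment boundaries; recovered metrics
through the full chain are accordingly noisier than on unfiltered
surrogate epochs (the pipeline tests bound this degradation).

## Statistics

- **Demographics**: Pearson χ² on the 2×2 sex table (no continuity
  correction by default; Yates optional) and pooled two-sample t-tests
  (Welch optional), accepting raw vectors or (mean, SD, n) summaries.
- **Omnibus mixed rm-ANOVA**: within factors parameter (3) × class (4),
  between factor group, on the raw metric values by default (the three
  parameters carry different units; a `zscore` option standardizes each
  parameter, which changes the interpretation of the parameter main
  effect).  Implementation: orthonormal (Helmert-based) contrasts per
  within effect; for contrast scores Z, Type III Wald sums of squares for
  the within effect (intercept) and its group interaction, with the
  residual within-group SS as error; the Greenhouse–Geisser epsilon is
  `tr(S)²/(p·tr(S²))` with S the *pooled within-group* covariance of the
  contrast scores (the error covariance, as in SPSS), clipped to
  [1/p, 1]; corrected p uses F(ε·df1, ε·df2).  ε = 1 reproduces the
  uncorrected p exactly.  The between main effect is a one-way ANOVA on
  subject means (no sphericity issue).  Validated against a from-scratch
  textbook cell-mean decomposition (all seven F ratios, rel. 1e-10) and
  against pingouin on balanced one-within designs.
- **Post-hoc simple effects**: two-group univariate ANOVA per metric cell;
  F = t² of the pooled t-test, df (1, n1+n2−2), partial η² = F/(F+df2)
  (identical to SS_effect/(SS_effect+SS_error)).  Gated by default on a
  significant group effect or group interaction in the omnibus test.
- **Correlations**: Pearson r with the analytic two-tailed p from
  t = r√(n−2)/√(1−r²); computed for every symptom subscore × metric pair
  in the scored group, pairwise-complete, uncorrected for multiplicity
  (a Holm option exists but is off, matching common reporting practice in
  this literature).

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down cohorts chosen to
exercise every code path with comfortable statistical margins: 6–8
subjects per group × 6–12 two-second epochs for signal-level analyses,
n = 200 per group (label sequences only) for moment-matching checks,
23 per group for drawn-cohort statistics, and 400–1000 null replicates for
type-I calibration.  Average-reference validation uses a relative
tolerance of 1e-6; template invariants 1e-10; k-means convergence 1e-7 on
relative GEV change.  All randomness flows through
`numpy.random.SeedSequence` spawning, so every result is reproducible from
a single seed.

## Known limitations

- No head-model realism in the generator (see above); GEV values on
  surrogate data (~97% at SNR 4) are higher than typical empirical values
  (~65–85%) because real EEG contains unmodeled variance.
- The alignment search is exhaustive in K! and is intended for K ≤ 6.
- K-selection criteria, transition-syntax analysis, and source
  localization are out of scope.
- The EDF writer targets plain continuous EDF (integer sampling rates,
  1-s records); it is not a general-purpose EDF+ implementation.
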