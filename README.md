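# microstates

Resting-state EEG **microstate analysis** for two-group clinical
comparisons, with a ground-truth surrogate-EEG generator.

Multichannel resting EEG can be parsed into a sequence of quasi-stable
scalp topographies ("microstates", conventionally four classes A–D), each
lasting ~60–120 ms.  Group differences in their temporal dynamics —
notably increased class C and decreased class D — are among the most
replicated EEG findings in schizophrenia research.  This package is aimed
at researchers who want a self-contained, testable implementation of that
analysis chain:

- **`microstates.synth`** — surrogate 64-channel, 500 Hz EEG built from a
  planted semi-Markov microstate sequence (gamma-distributed segment
  durations, random polarity, rectified-sinusoid envelope, GFP-scale SNR),
  plus a two-group cohort generator with group effects on classes C/D and
  a symptom score correlated with class-D occurrence.
- **`microstates.io_preproc`** — EDF / BrainVision / plain-text readers and
  the standard preprocessing chain (resample to 500 Hz, 0.1–70 Hz bandpass,
  48–52 Hz notch, 2-s epochs, amplitude rejection, common average
  reference, 2–20 Hz bandpass).
- **`microstates.core`** — the method itself: GFP and GFP-peak extraction,
  polarity-invariant **modified k-means** (assignment by squared spatial
  correlation, template update by principal eigenvector; objective = GEV,
  20 restarts), two-level template aggregation with exhaustive
  permutation × sign alignment, backfitting, label smoothing, and the
  duration / occurrence / contribution metrics.
- **`microstates.stats`** — Pearson χ², pooled/Welch t-tests, a mixed
  repeated-measures ANOVA (parameter × class within, group between) with
  the Greenhouse–Geisser correction, post-hoc univariate ANOVAs with
  partial η², and Pearson correlations against symptom subscores.
- **`microstates.pipeline` / CLI `microstates`** — YAML-configured
  end-to-end orchestration (`simulate → preprocess → segment → aggregate →
  backfit → metrics → stats → report`) with per-stage seeding, text-only
  artifacts, digests, and resumability.

The central quantity is the **global explained variance**

```
GEV = Σ_t (GFP_t · corr(v_t, T_label(t)))² / Σ_t GFP_t²
```

where `v_t` is the average-referenced topography at sample *t*, `T_k` the
unit-norm template maps, and `corr` the spatial Pearson correlation (used
as |corr| throughout — scalp polarity is uninformative).  Per-class
dynamics are *duration* (mean segment length, ms), *occurrence* (segment
onsets /s) and *contribution* (time coverage), which satisfy
`duration × occurrence = contribution × 1000` under the default
boundary policy.

See [`docs/methods.md`](docs/methods.md) for the full model, the
generator's calibrations, and numerical choices.

## Worked example

```python
import numpy as np
from microstates import core, synth

templates = synth.make_templates(64, 4, "well_separated", seed=7)
spec = synth.DynamicsSpec(n_epochs=10, snr=4.0)       # 10 x 2-s epochs
eps, truth = synth.simulate_subject(templates, spec, seed=1)

maps, gfp = core.extract_peak_maps(eps)               # GFP-peak maps
result = core.modified_kmeans(maps, k=4, n_restarts=20, seed=1)
print(f"peak maps: {maps.shape[0]}, GEV = {result.gev:.3f}")

canon = core.label_canonical(result.templates, templates)
seg = core.smooth_labels(core.backfit(eps, canon), min_duration_ms=10.0)
metrics = core.compute_metrics(seg)
print(metrics.to_frame().round(3).to_string(index=False))
print("planted occurrence:", np.round(truth.realized.occurrence_per_s, 2))
```

prints

```
peak maps: 798, GEV = 0.969
class  duration_ms  occurrence_per_s  contribution
    A       67.000              3.60         0.241
    B       61.750              3.60         0.222
    C       65.027              3.70         0.241
    D       69.624              4.25         0.296
planted occurrence: [3.8  3.75 3.95 4.45]
```

The four clustered templates explain 96.9% of the GFP-weighted variance of
the peak maps, and the recovered occurrence rates track the planted
ground truth to ~0.2/s.  The same flow runs from the shell:

```bash
microstates run --seed 5 --outdir demo --subjects 4 --epochs 8
microstates report --outdir demo
```

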