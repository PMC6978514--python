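# popcode

Population-coding analysis of multi-unit extracellular recordings from
behaving animals — built around the question of how amyloid pathology
degrades the *coding vocabulary* of hippocampal (dorsal CA1) ensembles.
The package implements the full analysis chain as a tested, reusable
library, together with a synthetic-data module that generates every input
with known ground truth, so each stage can be validated without access to
recorded data.

## What it computes

Given multi-channel raw voltage (or already-sorted spike trains) and wheel
behavior, the pipeline produces:

1. **Spike sorting** — common (mean) reference, ±8 robust-SD threshold
   detection, broadband-artifact removal, double-crossing consolidation,
   per-channel PCA (>80% variance) + Gaussian-mixture clustering, automated
   waveform curation, duplicate-unit merging, and QC (≥50 spikes, ≤10% of
   inter-spike intervals below 3 ms).
2. **Behavior** — 2-bit quadrature decoding to cm/s (150-ms smoothing at
   10-ms steps), running epochs where |v| > 1 cm/s, and summary statistics
   (proportion running, run velocity, inter-run intervals).
3. **Population statistics** — mean rates, z-scored sliding-window rate
   series, pairwise correlations overall and by behavioral state, and
   rate-matched shuffle nulls for state-dependent correlation changes.
4. **Pattern entropy** — 10-ms binarization, random 10-unit ensemble
   subsamples, the distribution over the 2^10 joint patterns ("words"),
   and the plug-in Shannon entropy

   H = − Σᵢ pᵢ log₂ pᵢ   (bits),

   overall and conditioned on running/stationary, with shuffle nulls and an
   animal-level bootstrap.
5. **Maximum-entropy models** — independent (first-order) and pairwise
   (Ising) models

   P(σ₁…σ_N) = exp( Σᵢ hᵢσᵢ + ½ Σ_{i≠j} J_ij σᵢσⱼ ) / Z,

   fitted by exact maximum likelihood (full 2^N enumeration, N ≤ 20) and
   scored by the Kullback–Leibler divergence D(data ‖ model), plus
   coactivity spectra P(k units active).
6. **Group comparison** — pooled two-sided Wilcoxon rank-sum tests with
   rank-biserial effect sizes across control-like and pathology-like groups.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/05_maxent_models.py` samples a known 5-unit Ising model,
refits it, and prints:

```
pairwise fit converged: True (max moment mismatch 7.47e-10)
coupling recovery: max |J_hat - J_true| = 0.040
KLD(data || independent) = 0.00206 bits
KLD(data || pairwise)    = 0.00003 bits
```

The pairwise model reproduces the generative couplings to within sampling
error and fits two orders of magnitude better than the rate-only model —
the gap measures how much pattern structure lives in the pairwise
interactions. `python examples/06_group_pipeline.py` runs a scaled-down
two-group comparison and prints the pooled medians and p-values showing the
pathology-like group's signature: lower correlations, lower entropy in both
behavioral states, a smaller entropy gain with running, and smaller KLDs
for both model orders.

A thin CLI wraps the pipeline for shell use:

```bash
popcode run --config analysis.yaml --out results/
popcode entropy --input raster.h5 --ensemble-size 10 --out entropy.tsv
popcode maxent-fit --dist patterns.tsv --order 2 --out model.yaml
```

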