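# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer should know about.

## Analysis chain

### Spike sorting

Raw voltage (channels × samples, 30 kHz, already band-limited to
500–3500 Hz) is mean-referenced: the across-channel mean is subtracted from
every channel at each sample, suppressing shared noise. Putative spikes are
contiguous excursions beyond ±8 noise standard deviations of zero, either
polarity, one event per excursion at the extremal sample. The noise SD is
estimated per channel from the median absolute deviation scaled by 1/0.6745,
so the spikes themselves cannot inflate the threshold.

Broadband artifacts are intervals during which at least 90% of channels are
simultaneously supra-threshold; all events within ±2 ms of such an interval
are discarded. The simultaneity criterion is evaluated on the *unreferenced*
trace: mean referencing cancels the common-mode component of an artifact
(that is its purpose), so the criterion could never fire after referencing.

Biphasic waveforms can cross the threshold at both polarities; same-channel
events within 1 ms are consolidated to the largest-amplitude peak.
Waveform snippets span 1 ms before to 2 ms after the aligned peak, across
the detecting channel and its 8 nearest neighbor channels. Per detecting
channel, snippets are projected onto the smallest principal subspace
explaining more than 80% of variance — capped at 10 components, because
with few units per channel the spectrum beyond the first several components
is flat noise and full-covariance mixture estimation degrades — and
partitioned by a Gaussian-mixture model whose component count (1–10)
minimizes BIC; labels are maximum posterior responsibility.

Pruning is automated where a manual step would be subjective: clusters are
rejected if their mean-waveform peak is below 8 noise SD or if positive and
negative peaks agree within 10% (symmetric waveforms are typically noise,
not somatic spikes). Units from different channels whose spike times
overlap heavily (≥50% of the smaller unit's spikes within 0.5 ms of the
other's) are treated as the same neuron and the smaller is dropped. Final
QC keeps units with ≥50 spikes and ≤10% of inter-spike intervals below
3 ms; the QC filter is idempotent.

### Behavior

A 2-bit quadrature (gray-code) state machine converts encoder transitions
into signed ticks: ±1 per legal transition, zero for repeats, and zero —
counted and logged — for illegal double steps. Ticks are calibrated to cm
(`cm_per_tick` is a required input; wheel geometry is not assumed), summed
into 10-ms steps, and smoothed with a *centered* 150-ms moving average (the
window centering is a package choice; a trailing window would lag running
onsets by ~75 ms). Running epochs are maximal intervals with |v| > 1 cm/s;
the absolute value is used because the wheel can be run forward or in
reverse. No minimum epoch duration or gap merging is applied. The
inter-run interval is the duration of a stationary epoch between two
consecutive running epochs.

### First- and second-order statistics

Mean rate is spike count over recording duration. Instantaneous rate series
are sliding spike counts (default 100-ms window, 10-ms steps — the window
width is a package default, exposed in configuration) z-scored once over
the full recording; state-conditioned correlations subset the z-scored
samples afterwards rather than re-normalizing per state, so a rate change
between states shows up in the conditioned series rather than being
normalized away. Correlations are product-moment coefficients; pairs with
constant series in the selected samples are reported missing.

The shuffle null redistributes each unit's exact spike count uniformly over
the recording. This is stronger than matching the mean rate in expectation:
the count is preserved per realization, making the null tighter, and all
temporal and cross-unit structure is destroyed. State-dependent correlation
changes Δr (running − stationary) are compared against the distribution of
Δr across repeated shuffles processed identically.

### Pattern entropy

Spike trains are binarized in non-overlapping 10-ms bins, half-open
`[k·w, (k+1)·w)`, 1 if the unit fired at least once. Ensembles of 10 units
(3–19 in sweeps) are subsampled uniformly without replacement within a
draw, independently across draws — a unit set may repeat across the 1000
draws. The pattern index encodes the joint state with unit 0 on the least
significant bit. Entropy is the plug-in estimator −Σ pᵢ log₂ pᵢ with
0·log 0 ≡ 0, deliberately without bias correction; the known Miller–Madow
bias (K−1)/(2 ln 2·n) is used in tests as an oracle, not in the estimator.
Note the asymptotic bias formula requires n·pᵢ ≫ 1 for all patterns; in the
sparse regimes typical of 10-ms cortical rasters the true bias is an order
of magnitude smaller than the formula suggests, so tests that check the
formula do so in a dense regime.

Behavioral conditioning keeps bins whose *centers* fall inside epochs of
the requested label (partial edge bins are excluded). State-dependent
entropy changes use a raster-level rate-matched shuffle — each unit's bins
are independently permuted, exactly preserving its spike-bin count — and
the same unit subsets in both states. Animal-level inference repeatedly
draws 250 subsample entropies per animal without replacement, averages per
animal, and compares group means across 5000 repetitions.

The firing-rate-matched entropy comparison pairs units across two rasters
by rate percentile and randomly deletes 1-bins from the higher-rate member
of each pair until the counts match (one-sided: deletion never creates
activity). This down-sampling surrogate is a pragmatic design of this
package.

### Maximum-entropy models

The pairwise (Ising) model is
P(σ) = exp(Σᵢ hᵢσᵢ + ½ Σ_{i≠j} J_ij σᵢσⱼ)/Z with σᵢ ∈ {0, 1}, symmetric J,
zero diagonal; the independent model is the J = 0 special case with the
closed form hᵢ = logit(mᵢ). Marginals are clipped to [ε, 1−ε] with
ε = 1/(2n) before the logit (ε = 10⁻⁶ with a warning when the sample count
is unknown). The ½ Σ_{i≠j} convention equals Σ_{i<j}; the alternative
convention differs only by J → 2J and is noted in serialized model files.

All quantities — partition function, model moments, gradients, Fisher
information — are computed by exact enumeration of the 2^N states (N ≤ 20
enforced), so fitting has no Monte Carlo error. The pairwise fit minimizes
the convex per-sample objective log Z(θ) − ⟨θ, T⟩ (T = empirical first and
second moments), whose gradient is exactly the model-minus-empirical moment
mismatch: an L-BFGS pass (initialized at the independent fit, J = 0) is
polished by damped Newton steps on the exact Fisher matrix with
backtracking. Convergence is declared on the sufficient statistics — max
absolute moment mismatch ≤ tol (default 10⁻⁶) — because moments, not
parameter increments, are the model's defining constraints. No
regularization is applied to J. When a unit never fires (or a pair never
co-fires) in the sample, the corresponding parameter diverges slowly toward
−∞ while the moment mismatch still converges below tolerance; the fit is
reported converged with the finite parameters reached.

Model fit quality is D(empirical ‖ model) in bits — the direction in which
maximum-likelihood nesting is exact, so D(emp‖pairwise) ≤ D(emp‖independent)
holds for every dataset, with equality iff empirical pairwise correlations
vanish. Zero-empirical-probability patterns contribute nothing; a zero
model probability on observed support flags infinity explicitly (impossible
for maximum-entropy models, whose probabilities are strictly positive).
The coactivity spectrum aggregates pattern probabilities by population
count, P(k) = Σ_{|σ|=k} p_σ.

### Group comparison

Unit-, pair- and subsample-level statistics are pooled across animals
within each group and compared with the two-sided Wilcoxon rank-sum test
(exact null for ≤25 per group without ties; tie-corrected normal
approximation otherwise), with rank-biserial correlation as the effect
size. Identical groups return p = 1. No multiple-comparison correction is
applied. Per-animal summaries are also emitted for animal-level analyses.

**Pooling caveat.** Under a true group null, pooled p-values are *not*
uniform: subsamples and pairs within an animal share that animal's
realization noise, so pooling pseudoreplicates and the pooled test is
anti-conservative. We verified this directly — with statistically identical
groups the median pooled p across seeds is far below 0.1, while animal-level
comparisons are calibrated. Pooled p-values should therefore be read as
descriptive of the pooled samples, and animal-level or bootstrap inference
used for population claims. This mirrors how such data are commonly
reported, but it is a genuine limitation.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of parameters and seed (bit-reproducible) and
default to the study conditions the pipeline targets: head-fixed running-
wheel recordings with ~6% time running at ~6 cm/s and ~17-s inter-run
intervals; control-like populations with mean rates near 1.65 Hz and
stronger positive couplings; pathology-like populations near 0.80 Hz with
weaker couplings; 4 animals per group, ~50 units per animal, 30 simulated
minutes, 10-ms bins.

* **Spike trains** are homogeneous Poisson at specified rates.
* **Binary rasters** are i.i.d. draws from an exactly enumerated Ising
  model distribution (categorical sampling over all 2^N patterns — exact,
  no Gibbs mixing questions; feasible because N ≤ 20). Populations larger
  than 20 units are built from independent 10-unit blocks with
  block-diagonal couplings; random ensembles that straddle blocks are then
  *not* exactly pairwise-distributed, which is the realistic situation for
  model evaluation. Per-unit rates are lognormal around the group mean
  (σ = 0.7, clipped to 0.2–12 Hz; the floor avoids near-empty units in
  short simulations), and the bias terms are solved so model marginals hit
  the target per-bin rates exactly given the sampled couplings.
* **State modulation** draws each bin from a stationary or running model by
  epoch membership, sharing one uniform variate per bin across the two
  inverse CDFs, so a recording with no running reproduces plain model
  sampling bit-for-bit. Running scales target rates by a per-group gain
  (1.35 control-like, 1.25 pathology-like) with couplings unchanged.
* **Raw traces** are 500–3500 Hz band-limited Gaussian noise (generated
  already filtered — the pipeline receives pre-filtered data, so the
  acquisition filter itself is not modeled) with biphasic three-channel
  templates inserted at Poisson times and, optionally, ~20-SD broadband
  artifacts spanning ≥95% of channels. Ground truth records every
  insertion at the waveform peak time.
* **Behavior** alternates exponential stationary bouts (mean 17 s) and
  exponential run bouts whose mean yields the target running fraction; the
  exponential form is a generator convention, not an empirical claim, and
  is exposed through `mean_iri`.

Not emulated: biophysical neuron models, electrode drift, overlapping-spike
waveform superposition at the same sample, LFP content, place fields, or
higher-than-second-order pattern structure. Passing tests therefore show
the *chain* is correct and calibrated on data matching its assumptions;
they do not show the assumptions hold for any particular recording.

## Problem sizes and numerical choices

Default analysis sizes follow the targeted study design (1000 entropy
subsamples of 10 units; 1000-rep shuffle nulls; 250-draw/5000-rep
bootstrap). The packaged acceptance runs use scaled sizes chosen to keep a
single-CPU run short while leaving every comparison decisively powered: 150
entropy subsamples and 40 pairwise fits per animal in the group pipeline,
200-rep shuffle nulls over two replicate 12-unit populations for
calibration, and a 16-channel/3-unit/300-s trace for sorting recovery.

Other numerics: logZ is validated against direct enumeration to 10⁻¹⁰;
pattern probabilities sum to 1 within 10⁻¹²; entropy of an empty subset or
raster is an error rather than 0/0; GMM fits that fail a Cholesky
factorization at some component count are skipped in the BIC scan;
correlation of a constant series is reported missing rather than 0.
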