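"""Two-group comparison: control-like vs amyloid-pathology-like populations.

Runs a scaled-down version of the full pipeline — synthetic state-modulated
populations per animal, correlations, subsampled pattern entropy by
behavioral state, and maximum-entropy fits — and prints the pooled group
comparison (two-sided Wilcoxon rank-sum).
"""

from popcode import AnalysisConfig, GroupParams
from popcode.pipeline import run_pipeline

cfg = AnalysisConfig(
    group_a=GroupParams(name="control", n_animals=2, n_units=20, duration=300.0),
    group_b=GroupParams(
        name="APP/PS1-like",
        n_animals=2,
        n_units=20,
        duration=300.0,
        mean_rate_hz=0.80,
        j_mean=0.05,
        j_sd=0.15,
        run_rate_gain=1.25,
    ),
    n_entropy_subsamples=50,
    n_maxent_fits=10,
    seed=7,
)
report = run_pipeline(cfg)

for name in ("rates_hz", "corr_overall", "entropy_overall", "entropy_delta",
             "kld_independent", "kld_pairwise"):
    m = report.metrics[name]
    print(f"{name:16s}: {m['mean_a']:+.4g} vs {m['mean_b']:+.4g}  (p = {m['p']:.3g})")
# The pathology-like group (lower rates, weaker couplings) shows lower
# correlations, lower entropy, a smaller entropy gain with running, and
# smaller KLDs for both model orders -- the expected population-coding
# signature of amyloid pathology.
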