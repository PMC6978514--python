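"""Sort a small synthetic multi-channel recording against its ground truth.

Generates 60 s of 8-channel band-limited noise with two inserted spike
waveforms (12x the noise SD), runs the full sorting chain (common reference,
8-SD threshold detection, artifact removal, double-crossing consolidation,
PCA + Gaussian-mixture clustering, curation, QC), and scores the result.
"""

import numpy as np

from popcode import gen_raw_recording, make_templates
from popcode.sorting import sort_recording

templates = make_templates(n_units=2, n_channels=8, amplitude_sd_units=12.0, seed=0)
raw, truth = gen_raw_recording(
    templates, rates=[2.0, 3.0], duration=60.0, n_channels=8, noise_sd=10.0, seed=1
)
trains, info = sort_recording(raw, seed=0)

print(f"ground truth: {[len(t) for t in truth.true_spike_times]} spikes per unit")
print(f"sorted {trains.n_units} units: {[u.n_spikes for u in trains.units]} spikes")
all_true = np.concatenate(truth.true_spike_times)
recovered = sum(
    1
    for u in trains.units
    for t in u.spike_times
    if np.min(np.abs(all_true - t)) <= 0.0005
)
print(f"recovery: {100 * recovered / len(all_true):.1f}% of true spikes matched within 0.5 ms")
# A well-sorted recording recovers essentially every inserted spike and
# assigns each to a single unit; QC discards low-count or refractory-violating
# clusters before they reach the analysis stages.
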