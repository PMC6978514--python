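"""Spike detection, artifact removal, clustering, and unit-level QC."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from popcode import (
    RawRecording,
    SortedUnit,
    autocorrelogram,
    cluster_spikes,
    common_reference,
    consolidate_double_crossings,
    detect_spikes,
    gen_raw_recording,
    make_templates,
    merge_duplicates,
    qc_units,
    remove_artifacts,
)
from popcode.core import SpikeEventSet
from popcode.sorting import robust_sd, sort_recording

FS = 30_000.0


def noise_recording(n_channels, duration, seed, sd=10.0):
    rng = np.random.default_rng(seed)
    return RawRecording(
        voltage=rng.normal(0, sd, (n_channels, int(duration * FS))), sampling_rate=FS
    )


def make_events(channels, peaks, amps, fs=FS):
    n = len(peaks)
    return SpikeEventSet(
        channel=np.asarray(channels),
        peak_sample=np.asarray(peaks),
        amplitude_sd=np.asarray(amps, dtype=float),
        waveforms=np.zeros((n, 1, 4), dtype=np.float32),
        snippet_channels=np.zeros((n, 1), dtype=int),
        sampling_rate=fs,
    )


class TestCommonReference:
    def test_identical_channels_cancel(self):
        x = np.random.default_rng(0).normal(size=1000)
        raw = RawRecording(voltage=np.stack([x, x]), sampling_rate=FS)
        out = common_reference(raw)
        assert np.allclose(out.voltage, 0.0, atol=1e-12)

    def test_zero_mean_input_unchanged(self):
        x = np.random.default_rng(1).normal(size=1000)
        raw = RawRecording(voltage=np.stack([x, -x]), sampling_rate=FS)
        out = common_reference(raw)
        assert np.allclose(out.voltage, raw.voltage, atol=1e-12)

    def test_common_mode_removed_template_shrinks(self):
        rng = np.random.default_rng(2)
        n_ch, n_s = 8, 30000
        base = rng.normal(0, 1, (n_ch, n_s))
        common = 50.0 * np.sin(np.linspace(0, 20, n_s))
        template = np.zeros(n_s)
        template[1000:1030] = 100.0
        v = base + common[None, :]
        v[3] += template
        out = common_reference(RawRecording(voltage=v, sampling_rate=FS))
        # channel means vanish sample-wise, removing the common-mode artifact
        assert np.allclose(out.voltage.mean(axis=0), 0.0, atol=1e-9)
        # single-channel template shrinks by exactly (1 - 1/n_channels)
        expected = base[3] - base.mean(axis=0) + template * (1 - 1 / n_ch)
        assert np.allclose(out.voltage[3], expected, atol=1e-9)

    def test_single_channel_rejected(self):
        raw = RawRecording(voltage=np.zeros((1, 100)), sampling_rate=FS)
        with pytest.raises(ValueError):
            common_reference(raw)


class TestDetectSpikes:
    def test_injected_templates_recovered(self):
        tpl = make_templates(1, 8, amplitude_sd_units=12.0, seed=0)
        raw, gt = gen_raw_recording(tpl, [2.0], 30.0, n_channels=8, noise_sd=10.0, seed=1)
        events = detect_spikes(common_reference(raw))
        true = gt.true_spike_times[0]
        hits = sum(np.min(np.abs(events.times - t)) <= 0.0005 for t in true)
        assert hits / len(true) >= 0.99

    def test_subthreshold_template_not_detected(self):
        tpl = make_templates(1, 4, amplitude_sd_units=5.0, seed=0)
        raw, gt = gen_raw_recording(tpl, [1.0], 20.0, n_channels=4, noise_sd=10.0, seed=2)
        events = detect_spikes(raw)
        true = gt.true_spike_times[0]
        hits = sum(np.min(np.abs(events.times - t), initial=np.inf) <= 0.0005 for t in true)
        assert hits == 0

    def test_gaussian_noise_false_event_rate(self):
        # P(|z| > 8) ~ 1.2e-15 per sample: a 10-s white-noise trace should
        # produce no events at all
        raw = noise_recording(2, 10.0, seed=3)
        assert detect_spikes(raw).n_events == 0

    def test_all_zero_trace_gives_empty_set(self):
        raw = RawRecording(voltage=np.zeros((2, 1000)), sampling_rate=FS)
        assert detect_spikes(raw).n_events == 0


class TestRemoveArtifacts:
    def test_artifact_events_removed_spikes_retained(self):
        tpl = make_templates(1, 20, amplitude_sd_units=12.0, seed=0)
        raw, gt = gen_raw_recording(
            tpl, [2.0], 30.0, n_channels=20, noise_sd=10.0, artifact_rate=0.2, seed=4
        )
        ref = common_reference(raw)
        events = detect_spikes(ref)
        # the simultaneity criterion is evaluated on the unreferenced trace,
        # where the artifact still spans ~95% of channels
        cleaned = remove_artifacts(events, raw)
        # events near artifact times are gone
        for t in gt.artifact_times:
            assert not np.any(np.abs(cleaned.times - (t + 0.001)) < 0.002)
        # most genuine spikes survive
        true = gt.true_spike_times[0]
        hits = sum(np.min(np.abs(cleaned.times - t), initial=np.inf) <= 0.0005 for t in true)
        assert hits / len(true) >= 0.9

    def test_no_artifacts_identity(self):
        tpl = make_templates(1, 4, seed=0)
        raw, _ = gen_raw_recording(tpl, [2.0], 10.0, n_channels=4, seed=5)
        events = detect_spikes(raw)
        cleaned = remove_artifacts(events, raw)
        assert cleaned.n_events == events.n_events

    def test_fraction_one_boundary_keeps_partial_artifacts(self):
        tpl = make_templates(1, 20, seed=0)
        raw, gt = gen_raw_recording(
            tpl, [0.0], 10.0, n_channels=20, noise_sd=10.0, artifact_rate=0.5, seed=6
        )
        events = detect_spikes(raw)
        kept = remove_artifacts(events, raw, channel_fraction=1.0)
        # artifacts hit 95% of channels, so the fraction-1.0 filter never fires
        assert kept.n_events == events.n_events


class TestConsolidateDoubleCrossings:
    def test_biphasic_double_count_merged(self):
        ev = make_events([0, 0], [1000, 1009], [8.5, 12.0])
        out = consolidate_double_crossings(ev)
        assert out.n_events == 1 and out.amplitude_sd[0] == 12.0

    def test_distant_spikes_kept(self):
        ev = make_events([0, 0], [1000, 1150], [9.0, 9.0])
        assert consolidate_double_crossings(ev).n_events == 2

    def test_three_crossings_within_window_keep_max(self):
        ev = make_events([0, 0, 0], [1000, 1012, 1024], [8.2, 14.0, 9.0])
        out = consolidate_double_crossings(ev)
        # brute-force expectation: chain within 1 ms collapses to the largest peak
        assert out.n_events == 1 and out.peak_sample[0] == 1012

    def test_different_channels_not_merged(self):
        ev = make_events([0, 1], [1000, 1001], [9.0, 9.0])
        assert consolidate_double_crossings(ev).n_events == 2


class TestClusterSpikes:
    def test_two_separated_templates_recovered(self):
        tpl = make_templates(2, 8, amplitude_sd_units=12.0, seed=3)
        tpl[0].channels = np.array([2, 3, 4])
        tpl[0].peak_channel = 3
        tpl[1].channels = np.array([2, 3, 4])
        tpl[1].peak_channel = 3
        tpl[1].waveform = -tpl[1].waveform  # opposite polarity: shapes well separated
        tpl[1].amplitude_sd_units = 15.0
        raw, gt = gen_raw_recording(tpl, [3.0, 3.0], 60.0, n_channels=8, noise_sd=10.0, seed=7)
        ref = common_reference(raw)
        events = consolidate_double_crossings(detect_spikes(ref))
        labels = cluster_spikes(events, seed=0)
        true_all = np.concatenate(gt.true_spike_times)
        unit_all = np.concatenate([np.full(len(t), u) for u, t in enumerate(gt.true_spike_times)])
        matched_pred, matched_true = [], []
        for lab, t in zip(labels, events.times):
            k = np.argmin(np.abs(true_all - t))
            if abs(true_all[k] - t) <= 0.0005:
                matched_pred.append(lab)
                matched_true.append(unit_all[k])
        assert adjusted_rand_score(matched_true, matched_pred) >= 0.95

    def test_single_template_single_cluster(self):
        tpl = make_templates(1, 8, amplitude_sd_units=14.0, seed=0)
        raw, _ = gen_raw_recording(tpl, [3.0], 40.0, n_channels=8, noise_sd=10.0, seed=8)
        events = consolidate_double_crossings(detect_spikes(common_reference(raw)))
        labels = cluster_spikes(events, seed=0)
        counts = np.bincount(labels)
        # dominant cluster holds nearly everything (BIC does not oversplit)
        assert counts.max() / counts.sum() >= 0.95

    def test_too_few_events_rejected(self):
        ev = make_events([0], [100], [9.0])
        with pytest.raises(ValueError):
            cluster_spikes(ev)


class TestQcUnits:
    def test_minimum_spike_count_boundary(self):
        good = SortedUnit(0, np.linspace(0, 59, 50))
        bad = SortedUnit(1, np.linspace(0, 59, 49))
        trains, report = qc_units([good, bad], duration=60.0)
        assert [u.unit_id for u in trains.units] == [0]
        assert report[0]["reason"] == "too_few_spikes"

    def test_isi_violation_fraction_boundary(self):
        # 100 spikes with 12% of ISIs below 3 ms -> discarded
        times = np.cumsum(np.where(np.arange(100) % 8 == 0, 0.002, 0.05))
        unit = SortedUnit(0, times)
        assert unit.isi_violation_fraction > 0.10
        trains, report = qc_units([unit], duration=times[-1] + 1)
        assert trains.n_units == 0 and report[0]["reason"] == "isi_violations"

    def test_poisson_unit_passes(self):
        from popcode import gen_poisson_trains

        trains, _ = gen_poisson_trains([2.0], 600.0, seed=9)
        unit = trains.units[0]
        # exponential ISI: P(isi < 3 ms) = 1 - exp(-2 * 0.003) ~ 0.6%
        assert unit.isi_violation_fraction < 0.05
        out, _ = qc_units([unit], duration=600.0)
        assert out.n_units == 1

    def test_idempotence(self):
        units = [SortedUnit(0, np.linspace(0, 99, 200))]
        once, _ = qc_units(units, duration=100.0)
        twice, _ = qc_units(once.units, duration=100.0)
        assert [u.unit_id for u in twice.units] == [u.unit_id for u in once.units]


class TestMergeDuplicates:
    def test_exact_duplicate_removed(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 100, 200))
        a, b = SortedUnit(0, t), SortedUnit(1, t.copy())
        assert len(merge_duplicates([a, b])) == 1

    def test_subset_unit_removed(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 100, 300))
        big, small = SortedUnit(0, t), SortedUnit(1, t[::3])
        kept = merge_duplicates([big, small])
        assert [u.unit_id for u in kept] == [0]

    def test_independent_poisson_units_retained(self):
        from popcode import gen_poisson_trains

        trains, _ = gen_poisson_trains([1.0, 1.0], 600.0, seed=2)
        # expected coincidence fraction ~ 2 * rate * window = 0.1%
        assert len(merge_duplicates(trains.units)) == 2


class TestAutocorrelogram:
    def test_periodic_train_peaks_at_multiples(self):
        unit = SortedUnit(0, np.arange(0, 10, 0.1))
        lags, counts = autocorrelogram(unit, max_lag=0.25, bin=0.001)
        peaks = np.abs(lags[counts > 0])
        off = np.minimum(peaks % 0.1, 0.1 - peaks % 0.1)
        assert np.all(off <= 0.002)

    def test_zero_lag_excludes_self_pairs(self):
        unit = SortedUnit(0, np.arange(0, 10, 0.5))
        lags, counts = autocorrelogram(unit)
        assert counts[np.abs(lags) < 0.0005].sum() == 0

    def test_poisson_flat_histogram(self):
        from popcode import gen_poisson_trains

        rate, duration = 20.0, 600.0
        trains, _ = gen_poisson_trains([rate], duration, seed=4)
        lags, counts = autocorrelogram(trains.units[0], max_lag=0.05, bin=0.005)
        expected = rate**2 * duration * 0.005
        se = np.sqrt(expected)
        off_zero = np.abs(lags) > 0.004
        assert np.all(np.abs(counts[off_zero] - expected) <= 4 * se)

    def test_too_few_spikes_empty(self):
        _, counts = autocorrelogram(SortedUnit(0, np.array([1.0])))
        assert counts.sum() == 0


class TestEndToEnd:
    def test_small_recording_high_recovery(self):
        tpl = make_templates(2, 8, amplitude_sd_units=12.0, seed=0)
        raw, gt = gen_raw_recording(tpl, [2.0, 3.0], 60.0, n_channels=8, noise_sd=10.0, seed=1)
        trains, _ = sort_recording(raw, seed=0)
        assert trains.n_units == 2
        all_true = np.concatenate(gt.true_spike_times)
        recovered = 0
        for u in trains.units:
            for t in u.spike_times:
                if np.min(np.abs(all_true - t)) <= 0.0005:
                    recovered += 1
        total_det = sum(u.n_spikes for u in trains.units)
        assert recovered / len(all_true) >= 0.9
        assert (total_det - recovered) / total_det < 0.02
        for u in trains.units:
            assert np.all((u.spike_times >= 0) & (u.spike_times < raw.duration))
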