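"""Binarization, pattern distributions, and subsampled ensemble entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcode import (
    BinaryRaster,
    EpochSet,
    PatternDistribution,
    SortedUnit,
    SpikeTrainSet,
    binarize,
    entropy_state_change,
    entropy_sweep,
    pattern_distribution,
    rate_matched_entropy,
    restrict_to_epochs,
    shannon_entropy,
    subsample_entropy,
    animal_level_bootstrap,
    gen_ising_raster,
    model_pattern_probs,
)
from popcode.entropy import rebin, shuffle_raster


def trains_from_lists(spike_lists, duration):
    units = [SortedUnit(unit_id=k, spike_times=np.array(t)) for k, t in enumerate(spike_lists)]
    return SpikeTrainSet(units=units, duration=duration)


class TestBinarize:
    def test_at_least_once_rule(self):
        r = binarize(trains_from_lists([[0.003, 0.007]], 0.05), 0.010)
        assert r.matrix[0, 0] == 1 and r.matrix[0].sum() == 1

    def test_half_open_boundary(self):
        r = binarize(trains_from_lists([[0.010]], 0.05), 0.010)
        assert r.matrix[0, 1] == 1 and r.matrix[0, 0] == 0

    def test_empty_train_all_zero(self):
        r = binarize(trains_from_lists([[]], 1.0), 0.010)
        assert r.matrix.sum() == 0 and r.n_bins == 100


class TestRestrictToEpochs:
    def test_full_cover_is_identity(self):
        r = binarize(trains_from_lists([[0.1, 0.5]], 1.0), 0.010)
        e = EpochSet.from_running_intervals(np.array([[0.0, 1.0]]), 1.0)
        assert np.array_equal(restrict_to_epochs(r, e, "running").matrix, r.matrix)

    def test_bin_count_arithmetic(self):
        r = binarize(trains_from_lists([[]], 10.0), 0.010)
        e = EpochSet.from_running_intervals(np.array([[1.0, 2.0]]), 10.0)
        assert restrict_to_epochs(r, e, "running").n_bins == 100

    def test_disjoint_epochs_additive(self):
        r = binarize(trains_from_lists([[]], 10.0), 0.010)
        e = EpochSet.from_running_intervals(np.array([[1.0, 2.0], [4.0, 4.5]]), 10.0)
        assert restrict_to_epochs(r, e, "running").n_bins == 150

    def test_empty_selection_raises(self):
        r = binarize(trains_from_lists([[]], 1.0), 0.010)
        e = EpochSet.from_running_intervals(np.empty((0, 2)), 1.0)
        with pytest.raises(ValueError):
            restrict_to_epochs(r, e, "running")


class TestPatternDistribution:
    def test_small_example(self):
        mat = np.array([[0, 0, 1, 1], [0, 0, 0, 1]])
        d = pattern_distribution(BinaryRaster(matrix=mat), [0, 1])
        assert np.allclose(d.p, [0.5, 0.25, 0.0, 0.25])

    def test_all_zero_raster_is_delta(self):
        d = pattern_distribution(BinaryRaster(matrix=np.zeros((3, 50))), [0, 1, 2])
        assert d.p[0] == 1.0

    def test_sampled_frequencies_match_model(self, small_ising):
        n = 10**5
        raster, _ = gen_ising_raster(small_ising, n, seed=9)
        d = pattern_distribution(raster, np.arange(5))
        p_true = model_pattern_probs(small_ising).p
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert np.all(np.abs(d.p - p_true) <= 3.5 * se + 1e-12)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            pattern_distribution(BinaryRaster(matrix=np.zeros((3, 10))), [0, 0])


class TestShannonEntropy:
    def test_uniform_1024_is_exactly_ten_bits(self):
        d = PatternDistribution(N=10, p=np.full(1024, 1 / 1024))
        assert shannon_entropy(d) == 10.0

    def test_delta_is_zero(self):
        p = np.zeros(8)
        p[3] = 1.0
        assert shannon_entropy(PatternDistribution(N=3, p=p)) == 0.0

    def test_closed_form(self):
        d = PatternDistribution(N=2, p=np.array([0.5, 0.25, 0.25, 0.0]))
        assert shannon_entropy(d) == pytest.approx(1.5, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(0, 10**6))
    def test_bounds_for_random_distributions(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(2**n, 0.3))
        h = shannon_entropy(PatternDistribution(N=n, p=p))
        assert 0.0 <= h <= n + 1e-12


class TestSubsampleEntropy:
    def test_population_equals_ensemble_size(self):
        mat = (np.random.default_rng(0).random((10, 500)) < 0.1).astype(np.uint8)
        res = subsample_entropy(BinaryRaster(matrix=mat), 10, n_subsamples=20, seed=1)
        # every draw selects the whole population (in permuted order), so the
        # entropies agree up to floating summation order
        assert res.entropies.std() < 1e-12

    def test_seed_determinism(self):
        mat = (np.random.default_rng(0).random((15, 500)) < 0.1).astype(np.uint8)
        r = BinaryRaster(matrix=mat)
        a = subsample_entropy(r, 10, 50, seed=5).entropies
        b = subsample_entropy(r, 10, 50, seed=5).entropies
        assert np.array_equal(a, b)

    def test_too_few_units_raises(self):
        with pytest.raises(ValueError, match="units"):
            subsample_entropy(BinaryRaster(matrix=np.zeros((5, 100))), 10)

    def test_plugin_bias_formula_in_dense_regime(self):
        # Miller-Madow asymptotics require n*p >> 1 for all patterns; in this
        # dense regime (K=16, all pattern probabilities >= 0.24%) the measured
        # bias should match (K-1)/(2 ln2 n) within a factor of 2
        rng = np.random.default_rng(11)
        q, n, reps = 0.3, 2000, 3000
        h_true = 4 * (-(q * np.log2(q) + (1 - q) * np.log2(1 - q)))
        vals = []
        for _ in range(reps):
            mat = (rng.random((4, n)) < q).astype(np.uint8)
            vals.append(
                shannon_entropy(pattern_distribution(BinaryRaster(matrix=mat), np.arange(4)))
            )
        bias = h_true - np.mean(vals)
        predicted = 15 / (2 * np.log(2) * n)
        assert predicted / 2 < bias < predicted * 2


class TestEntropyStateChange:
    def test_no_state_effect_when_models_identical(self, independent_model):
        from popcode import gen_state_modulated_population

        e = EpochSet.from_running_intervals(np.array([[30.0, 60.0]]), 120.0)
        raster, _ = gen_state_modulated_population(
            independent_model, independent_model, e, bin_width=0.010, seed=4
        )
        delta, null, _ = entropy_state_change(
            raster, e, ensemble_size=3, n_subsamples=10, n_shuffle_reps=50, seed=2
        )
        lo, hi = null.central_band(0.95)
        inside = np.mean((delta >= lo) & (delta <= hi))
        assert inside >= 0.7  # tiny-n smoke check; calibration tested at scale elsewhere

    def test_shuffle_preserves_unit_counts(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((6, 400)) < 0.2).astype(np.uint8)
        r = BinaryRaster(matrix=mat)
        shuffled = shuffle_raster(r, rng)
        assert np.array_equal(shuffled.matrix.sum(axis=1), mat.sum(axis=1))

    def test_insufficient_state_bins_raise(self, independent_model):
        from popcode import gen_ising_raster

        raster, _ = gen_ising_raster(independent_model, 200, seed=0)
        e = EpochSet.from_running_intervals(np.array([[0.0, 0.2]]), 2.0)
        with pytest.raises(ValueError, match="running"):
            entropy_state_change(raster, e, ensemble_size=3, n_subsamples=5, n_shuffle_reps=5)


class TestAnimalLevelBootstrap:
    def test_exchangeable_groups_center_on_zero(self):
        rng = np.random.default_rng(1)
        group = [rng.normal(1.0, 0.2, 400) for _ in range(4)]
        other = [rng.normal(1.0, 0.2, 400) for _ in range(4)]
        res = animal_level_bootstrap(group, other, n_draw=250, n_reps=500, seed=3)
        assert abs(res["mean"]) < 3 * res["sd"] / np.sqrt(1)  # centered null

    def test_constructed_offset_recovered(self):
        rng = np.random.default_rng(2)
        a = [rng.normal(1.25, 0.2, 400) for _ in range(4)]
        b = [rng.normal(1.0, 0.2, 400) for _ in range(4)]
        res = animal_level_bootstrap(a, b, n_draw=250, n_reps=500, seed=3)
        assert res["mean"] == pytest.approx(0.25, abs=0.05)

    def test_seed_determinism_and_ndraw_guard(self):
        a = [np.arange(300.0)]
        b = [np.arange(300.0) + 1]
        r1 = animal_level_bootstrap(a, b, n_draw=250, n_reps=50, seed=9)
        r2 = animal_level_bootstrap(a, b, n_draw=250, n_reps=50, seed=9)
        assert np.array_equal(r1["differences"], r2["differences"])
        with pytest.raises(ValueError):
            animal_level_bootstrap([np.arange(10.0)], b, n_draw=250, n_reps=10)


class TestEntropySweep:
    def test_independent_units_entropy_grows_with_ensemble_size(self):
        rng = np.random.default_rng(3)
        mat = (rng.random((20, 20000)) < 0.05).astype(np.uint8)
        grid = entropy_sweep(
            BinaryRaster(matrix=mat), ensemble_sizes=[3, 6, 9], n_subsamples=30, seed=0
        )
        means = [grid[(s, 0.010)].entropies.mean() for s in (3, 6, 9)]
        assert means[0] < means[1] < means[2]

    def test_coarser_bins_raise_marginal_entropy_below_half(self):
        rng = np.random.default_rng(4)
        mat = (rng.random((5, 40000)) < 0.02).astype(np.uint8)
        r = BinaryRaster(matrix=mat)
        fine = rebin(r, 0.010)
        coarse = rebin(r, 0.050)
        assert coarse.matrix.mean() > fine.matrix.mean()
        h_fine = subsample_entropy(fine, 3, 20, seed=1).entropies.mean()
        h_coarse = subsample_entropy(coarse, 3, 20, seed=1).entropies.mean()
        assert h_coarse > h_fine

    def test_per_cell_errors_propagate_without_abort(self):
        mat = np.zeros((4, 1000), dtype=np.uint8)
        grid = entropy_sweep(BinaryRaster(matrix=mat), ensemble_sizes=[3, 9], n_subsamples=5)
        assert isinstance(grid[(9, 0.010)], Exception)
        assert not isinstance(grid[(3, 0.010)], Exception)


class TestRateMatchedEntropy:
    def test_matching_is_one_sided_deletion(self):
        rng = np.random.default_rng(5)
        a = BinaryRaster(matrix=(rng.random((12, 20000)) < 0.04).astype(np.uint8))
        b = BinaryRaster(matrix=(rng.random((12, 20000)) < 0.02).astype(np.uint8))
        before_a, before_b = a.matrix.copy(), b.matrix.copy()
        rate_matched_entropy(a, b, ensemble_size=10, n_subsamples=10, seed=0)
        # inputs untouched, and the operation never turned a 0 into a 1
        assert np.array_equal(a.matrix, before_a) and np.array_equal(b.matrix, before_b)

    def test_bernoulli_rasters_converge_to_lower_rate_entropy(self):
        rng = np.random.default_rng(6)
        q_lo = 0.02
        a = BinaryRaster(matrix=(rng.random((10, 10**5)) < 0.04).astype(np.uint8))
        b = BinaryRaster(matrix=(rng.random((10, 10**5)) < q_lo).astype(np.uint8))
        res = rate_matched_entropy(a, b, ensemble_size=10, n_subsamples=20, seed=1)
        h_unit = -(q_lo * np.log2(q_lo) + (1 - q_lo) * np.log2(1 - q_lo))
        for key in ("a", "b"):
            assert res[key].entropies.mean() == pytest.approx(10 * h_unit, abs=0.03)
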