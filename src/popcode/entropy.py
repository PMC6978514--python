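"""Pattern (word) distributions and Shannon entropy of neuronal ensembles.

The pipeline follows the standard word-entropy recipe for population spike
data: spike trains are binarized in 10-ms non-overlapping bins (a unit
contributes 1 to a bin if it fired at least once inside it), random ensembles
of a fixed size (default 10 units) are subsampled from the population, the
relative frequency of the 2^N joint patterns is tabulated for each ensemble,
and the plug-in Shannon entropy  H = -sum_i p_i log2 p_i  is reported per
subsample.  Behavioral conditioning restricts the bins entering the pattern
counts to those whose centers fall inside running or stationary epochs.

Statistical inference mirrors the shuffle/bootstrap design used with such
data: significance of state-dependent entropy changes is assessed against
rate-matched shuffled populations (temporal structure destroyed, per-unit
spike counts preserved exactly), and animal-level group differences are
assessed by repeatedly averaging fixed-size draws of subsample entropies
within each animal.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BinaryRaster,
    EntropyResult,
    EpochSet,
    PatternDistribution,
    ShuffleNull,
    SpikeTrainSet,
)

__all__ = [
    "binarize",
    "restrict_to_epochs",
    "pattern_distribution",
    "shannon_entropy",
    "subsample_entropy",
    "entropy_state_change",
    "animal_level_bootstrap",
    "entropy_sweep",
    "rate_matched_entropy",
    "shuffle_raster",
]


def binarize(s: SpikeTrainSet, bin_width: float = 0.010) -> BinaryRaster:
    """Binarize spike trains over non-overlapping half-open bins.

    A bin is 1 iff the unit spiked at least once in ``[k*w, (k+1)*w)``; the
    number of bins is ``ceil(duration / w)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(s.duration / bin_width - 1e-9))
    mat = np.zeros((s.n_units, n_bins), dtype=np.uint8)
    for row, unit in enumerate(s.units):
        if unit.n_spikes:
            idx = np.floor(unit.spike_times / bin_width).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            mat[row, idx] = 1
    return BinaryRaster(
        matrix=mat, bin_width=bin_width, unit_ids=np.array([u.unit_id for u in s.units])
    )


def restrict_to_epochs(r: BinaryRaster, e: EpochSet, label: str) -> BinaryRaster:
    """Keep only bins whose centers fall inside epochs with the given label."""
    mask = e.mask_at(r.bin_centers(), label)
    # bins whose centers fall past the last epoch are edge bins; drop them
    mask &= r.bin_centers() < e.duration
    if not mask.any():
        raise ValueError(f"no bins fall inside '{label}' epochs")
    return BinaryRaster(
        matrix=r.matrix[:, mask], bin_width=r.bin_width, t0=r.t0, unit_ids=r.unit_ids
    )


def pattern_distribution(
    r: BinaryRaster, unit_subset: np.ndarray | list[int]
) -> PatternDistribution:
    """Relative frequency of the 2^N joint patterns of the selected units."""
    subset = np.asarray(unit_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("unit subset must be non-empty")
    if len(np.unique(subset)) != len(subset):
        raise ValueError("unit subset indices must be distinct")
    if subset.size > 20:
        raise ValueError("ensemble size limited to 20 (2^N enumeration)")
    n = len(subset)
    codes = _pattern_codes(r.matrix, subset)
    counts = np.bincount(codes, minlength=2**n)
    total = r.n_bins
    if total == 0:
        raise ValueError("raster has no bins")
    return PatternDistribution(N=n, p=counts / total, n_samples=total)


def _pattern_codes(matrix: np.ndarray, subset: np.ndarray) -> np.ndarray:
    weights = (1 << np.arange(len(subset))).astype(np.int64)
    return matrix[subset].astype(np.int64).T @ weights


def shannon_entropy(d: PatternDistribution) -> float:
    """Plug-in Shannon entropy in bits; 0*log 0 contributes 0."""
    p = d.p[d.p > 0]
    return float(np.sum(-p * np.log2(p)))


def _draw_subsets(
    n_units: int, ensemble_size: int, n_subsamples: int, rng: np.random.Generator
) -> np.ndarray:
    if n_units < ensemble_size:
        raise ValueError(
            f"need at least {ensemble_size} units, have {n_units}"
        )
    return np.stack(
        [rng.choice(n_units, size=ensemble_size, replace=False) for _ in range(n_subsamples)]
    )


def subsample_entropy(
    r: BinaryRaster,
    ensemble_size: int = 10,
    n_subsamples: int = 1000,
    seed: int | np.random.Generator = 0,
    subsets: np.ndarray | None = None,
) -> EntropyResult:
    """Plug-in entropy of random fixed-size ensemble subsamples.

    Subsamples are drawn uniformly without replacement within each draw and
    independently across draws; pass ``subsets`` to reuse a fixed collection
    (e.g. to condition the same ensembles on different behavioral states).
    """
    rng = np.random.default_rng(seed)
    if subsets is None:
        subsets = _draw_subsets(r.n_units, ensemble_size, n_subsamples, rng)
    ent = np.empty(len(subsets))
    for k, subset in enumerate(subsets):
        ent[k] = shannon_entropy(pattern_distribution(r, subset))
    return EntropyResult(
        entropies=ent,
        ensemble_size=ensemble_size,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        subsets=subsets,
    )


def shuffle_raster(r: BinaryRaster, rng: np.random.Generator) -> BinaryRaster:
    """Rate-matched shuffle: independently permute each unit's bins.

    Preserves every unit's spike-bin count exactly (hence its rate) while
    destroying temporal and cross-unit structure.
    """
    mat = r.matrix.copy()
    for row in mat:
        rng.shuffle(row)
    return BinaryRaster(matrix=mat, bin_width=r.bin_width, t0=r.t0, unit_ids=r.unit_ids)


def entropy_state_change(
    r: BinaryRaster,
    e: EpochSet,
    ensemble_size: int = 10,
    n_subsamples: int = 1000,
    n_shuffle_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    min_bins: int = 100,
) -> tuple[np.ndarray, ShuffleNull, np.ndarray]:
    """Running-minus-stationary entropy per subsample, with a shuffle null.

    Returns ``(delta, null, subsets)`` where ``delta[k]`` is the empirical
    entropy difference of subsample ``k`` conditioned on running vs stationary
    bins, and ``null.samples[rep, k]`` is the same statistic for a
    rate-matched shuffled population.
    """
    rng = np.random.default_rng(seed)
    centers = r.bin_centers()
    run_mask = e.mask_at(centers, "running") & (centers < e.duration)
    stat_mask = e.mask_at(centers, "stationary") & (centers < e.duration)
    for name, mask in (("running", run_mask), ("stationary", stat_mask)):
        if mask.sum() < min_bins:
            raise ValueError(f"fewer than {min_bins} bins in {name} state")

    subsets = _draw_subsets(r.n_units, ensemble_size, n_subsamples, rng)

    def conditioned_delta(matrix: np.ndarray) -> np.ndarray:
        run = BinaryRaster(matrix=matrix[:, run_mask], bin_width=r.bin_width)
        stat = BinaryRaster(matrix=matrix[:, stat_mask], bin_width=r.bin_width)
        out = np.empty(len(subsets))
        for k, subset in enumerate(subsets):
            h_run = shannon_entropy(pattern_distribution(run, subset))
            h_stat = shannon_entropy(pattern_distribution(stat, subset))
            out[k] = h_run - h_stat
        return out

    delta = conditioned_delta(r.matrix)
    null = np.empty((n_shuffle_reps, n_subsamples))
    for rep in range(n_shuffle_reps):
        shuffled = shuffle_raster(r, rng)
        null[rep] = conditioned_delta(shuffled.matrix)
    return delta, ShuffleNull(samples=null), subsets


def animal_level_bootstrap(
    group_a: list[np.ndarray],
    group_b: list[np.ndarray],
    n_draw: int = 250,
    n_reps: int = 5000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Animal-level bootstrap (without replacement) of a group difference.

    Per repetition, ``n_draw`` entropy values are drawn without replacement
    from each animal's subsample entropies, averaged per animal, and the two
    group means of those per-animal averages are differenced (A - B).
    """
    rng = np.random.default_rng(seed)
    for animal in [*group_a, *group_b]:
        if len(animal) < n_draw:
            raise ValueError(f"animal has {len(animal)} samples; need >= {n_draw}")
    diffs = np.empty(n_reps)
    for rep in range(n_reps):
        mean_a = np.mean(
            [np.mean(rng.choice(a, size=n_draw, replace=False)) for a in group_a]
        )
        mean_b = np.mean(
            [np.mean(rng.choice(b, size=n_draw, replace=False)) for b in group_b]
        )
        diffs[rep] = mean_a - mean_b
    return {
        "differences": diffs,
        "mean": float(diffs.mean()),
        "sd": float(diffs.std(ddof=1)),
        "ci95": (float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975))),
    }


def rebin(r: BinaryRaster, bin_width: float) -> BinaryRaster:
    """Coarsen a raster by OR-ing groups of consecutive bins.

    ``bin_width`` must be an integer multiple of the raster's bin width; this
    reproduces binarizing the underlying spike trains at the coarser width.
    """
    factor = bin_width / r.bin_width
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise ValueError("bin_width must be an integer multiple of the raster's")
    if k == 1:
        return r
    n_keep = (r.n_bins // k) * k
    grouped = r.matrix[:, :n_keep].reshape(r.n_units, -1, k).max(axis=2)
    return BinaryRaster(matrix=grouped, bin_width=bin_width, t0=r.t0, unit_ids=r.unit_ids)


def entropy_sweep(
    r: BinaryRaster,
    ensemble_sizes: list[int] | range = range(3, 20),
    bin_widths: list[float] | None = None,
    n_subsamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[int, float], EntropyResult | Exception]:
    """Subsample entropy over a grid of ensemble sizes and bin widths.

    Per-cell failures (e.g. too few units) are stored in the grid rather than
    aborting the sweep.
    """
    if bin_widths is None:
        bin_widths = [r.bin_width]
    ss = np.random.SeedSequence(
        seed if not isinstance(seed, np.random.Generator) else seed.integers(2**31)
    )
    grid: dict[tuple[int, float], EntropyResult | Exception] = {}
    for size in ensemble_sizes:
        for w in bin_widths:
            child = np.random.default_rng(ss.spawn(1)[0])
            try:
                coarse = rebin(r, w)
                grid[(size, w)] = subsample_entropy(
                    coarse, ensemble_size=size, n_subsamples=n_subsamples, seed=child
                )
            except ValueError as err:
                grid[(size, w)] = err
    return grid


def rate_matched_entropy(
    r_a: BinaryRaster,
    r_b: BinaryRaster,
    ensemble_size: int = 10,
    n_subsamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Compare subsample entropies after one-sided firing-rate matching.

    Units in each raster are rank-ordered by bin-wise rate and paired by rank
    percentile; within each pair, random 1-bins are deleted from the
    higher-rate unit until its count matches its partner's (deletion never
    creates activity, so the correction is one-sided).  Both matched rasters
    are then scored with ``subsample_entropy``.

    This down-sampling surrogate for rate correction is a pragmatic design of
    this package; it is deliberately simple and labeled as such.
    """
    if r_a.n_bins == 0 or r_b.n_bins == 0:
        raise ValueError("rasters must be non-empty")
    rng = np.random.default_rng(seed)
    a = r_a.matrix.copy()
    b = r_b.matrix.copy()
    order_a = np.argsort(a.mean(axis=1), kind="stable")
    order_b = np.argsort(b.mean(axis=1), kind="stable")
    # pair by rank percentile (handles unequal unit counts)
    ranks_b = np.linspace(0, 1, len(order_b))
    for frac, ia in zip(np.linspace(0, 1, len(order_a)), order_a):
        ib = order_b[np.argmin(np.abs(ranks_b - frac))]
        qa, qb = a[ia].mean(), b[ib].mean()
        if qa > qb:
            _delete_to_rate(a[ia], qb, rng)
        elif qb > qa:
            _delete_to_rate(b[ib], qa, rng)
    ra = BinaryRaster(matrix=a, bin_width=r_a.bin_width)
    rb = BinaryRaster(matrix=b, bin_width=r_b.bin_width)
    return {
        "a": subsample_entropy(ra, ensemble_size, n_subsamples, rng),
        "b": subsample_entropy(rb, ensemble_size, n_subsamples, rng),
    }


def _delete_to_rate(row: np.ndarray, target_rate: float, rng: np.random.Generator) -> None:
    ones = np.flatnonzero(row)
    target = int(round(target_rate * len(row)))
    excess = len(ones) - target
    if excess > 0:
        drop = rng.choice(ones, size=excess, replace=False)
        row[drop] = 0
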