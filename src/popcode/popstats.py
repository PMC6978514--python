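"""First- and second-order population statistics.

Mean firing rates, z-scored instantaneous rate series (sliding spike counts
on the binarized trains), product-moment pairwise correlations overall and
restricted to behavioral states, and rate-matched shuffle nulls for
state-dependent correlation changes.  The shuffle redistributes each unit's
exact spike count uniformly over the recording, which preserves the mean
rate per realization while destroying all temporal structure.
"""

from __future__ import annotations

import numpy as np

from .core import EpochSet, ShuffleNull, SortedUnit, SpikeTrainSet

__all__ = [
    "mean_firing_rates",
    "instantaneous_rate_zscore",
    "rate_series_matrix",
    "pairwise_correlations",
    "rate_matched_shuffle",
    "correlation_state_change",
]


def mean_firing_rates(s: SpikeTrainSet) -> np.ndarray:
    """Per-unit rate in Hz: total spikes / recording duration."""
    return np.array([u.n_spikes / s.duration for u in s.units])


def instantaneous_rate_zscore(
    unit: SortedUnit,
    duration: float,
    window_s: float = 0.1,
    step_s: float = 0.01,
) -> tuple[np.ndarray, bool]:
    """Sliding-window spike counts at ``step_s`` resolution, z-scored.

    The window is centered.  Returns ``(series, degenerate)``; a unit whose
    count series is constant (e.g. zero spikes) has an undefined z-score and
    yields an all-zero series with ``degenerate=True``.
    """
    if window_s < step_s:
        raise ValueError("window_s must be >= step_s")
    n_steps = int(np.ceil(duration / step_s - 1e-9))
    counts = np.zeros(n_steps)
    if unit.n_spikes:
        idx = np.floor(unit.spike_times / step_s).astype(int)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        np.add.at(counts, idx, 1.0)
    w = min(max(int(round(window_s / step_s)), 1), max(n_steps, 1))
    series = np.convolve(counts, np.ones(w), mode="same")
    sd = series.std()
    if sd == 0:
        return np.zeros(n_steps), True
    return (series - series.mean()) / sd, False


def rate_series_matrix(
    s: SpikeTrainSet, window_s: float = 0.1, step_s: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked z-scored rate series, ``(units x steps)``, plus degeneracy flags."""
    series, flags = [], []
    for u in s.units:
        z, bad = instantaneous_rate_zscore(u, s.duration, window_s, step_s)
        series.append(z)
        flags.append(bad)
    return np.vstack(series), np.asarray(flags)


def pairwise_correlations(
    series: np.ndarray,
    epochs: EpochSet | None = None,
    label: str | None = None,
    step_s: float = 0.01,
) -> np.ndarray:
    """Correlation matrix of rate series, optionally restricted to one state.

    ``series`` is ``(units x samples)`` of z-scored rates (z-scored once over
    the full recording; state conditioning subsets samples afterwards).
    Pairs with fewer than 2 usable samples, or involving a constant series in
    the selected samples, are NaN (missing).  Diagonal is set to 1.
    """
    if series.shape[0] < 2:
        raise ValueError("need >= 2 units")
    if epochs is not None and label is not None:
        centers = (np.arange(series.shape[1]) + 0.5) * step_s
        mask = epochs.mask_at(centers, label) & (centers < epochs.duration)
        series = series[:, mask]
    if series.shape[1] < 2:
        r = np.full((series.shape[0],) * 2, np.nan)
        np.fill_diagonal(r, 1.0)
        return r
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(series)
    np.fill_diagonal(r, 1.0)
    return r


def rate_matched_shuffle(
    s: SpikeTrainSet, seed: int | np.random.Generator = 0
) -> SpikeTrainSet:
    """Replace each unit's spikes by the same number of uniform random times.

    Preserves per-unit spike counts exactly (hence mean rates) and destroys
    all temporal and cross-unit structure.
    """
    rng = np.random.default_rng(seed)
    units = [
        SortedUnit(
            unit_id=u.unit_id,
            spike_times=np.sort(rng.uniform(0.0, s.duration, size=u.n_spikes)),
            isi_cutoff=u.isi_cutoff,
        )
        for u in s.units
    ]
    return SpikeTrainSet(units=units, duration=s.duration, group_label=s.group_label)


def upper_triangle(r: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(r.shape[0], k=1)
    return r[iu, ju]


def correlation_state_change(
    s: SpikeTrainSet,
    e: EpochSet,
    window_s: float = 0.1,
    step_s: float = 0.01,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, ShuffleNull]:
    """Per-pair correlation change (running - stationary) with a shuffle null.

    The empirical change is computed from the z-scored rate series restricted
    to each state; the null repeats the identical computation on ``n_reps``
    rate-matched shuffled populations.  Returns the upper-triangle pair
    vector and the null samples ``(n_reps x n_pairs)``.
    """
    for label in ("running", "stationary"):
        centers_ok = e.total_duration(label) >= 2 * step_s
        if not centers_ok:
            raise ValueError(f"state '{label}' has too few samples")
    rng = np.random.default_rng(seed)

    def delta_for(trains: SpikeTrainSet) -> np.ndarray:
        series, _ = rate_series_matrix(trains, window_s, step_s)
        r_run = pairwise_correlations(series, e, "running", step_s)
        r_stat = pairwise_correlations(series, e, "stationary", step_s)
        return upper_triangle(r_run) - upper_triangle(r_stat)

    empirical = delta_for(s)
    null = np.empty((n_reps, len(empirical)))
    for rep in range(n_reps):
        null[rep] = delta_for(rate_matched_shuffle(s, rng))
    return empirical, ShuffleNull(samples=null)
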