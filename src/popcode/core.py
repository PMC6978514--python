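"""Core data containers shared across the analysis stages.

All containers are thin dataclasses around numpy arrays.  Conventions used
throughout the package:

* time is in seconds, voltages in microvolts, rates in Hz;
* spike times of a unit are sorted ascending and lie in ``[0, duration)``;
* binary rasters are ``units x bins`` uint8 matrices over half-open bins
  ``[t0 + k*w, t0 + (k+1)*w)``;
* a population *pattern* (word) of an ``N``-unit ensemble is encoded as an
  integer in ``0 .. 2**N - 1`` with unit 0 on the least-significant bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawRecording",
    "SpikeEventSet",
    "SortedUnit",
    "SpikeTrainSet",
    "VelocityTrace",
    "EpochSet",
    "BinaryRaster",
    "PatternDistribution",
    "EntropyResult",
    "ShuffleNull",
]


@dataclass
class RawRecording:
    """Multi-channel extracellular voltage trace.

    Parameters
    ----------
    voltage
        ``(n_channels, n_samples)`` array in microvolts.
    sampling_rate
        Samples per second (typically 30000).
    channel_positions
        Optional ``(n_channels, 2)`` array of (shank, depth) labels; used only
        to define channel neighborhoods during clustering.
    """

    voltage: np.ndarray
    sampling_rate: float
    channel_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage)
        if self.voltage.ndim != 2 or self.voltage.shape[0] < 1:
            raise ValueError("voltage must be a (channels, samples) matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SpikeEventSet:
    """Detected supra-threshold events, prior to unit assignment.

    ``channel``, ``peak_sample`` and ``amplitude_sd`` are parallel arrays, one
    entry per event; ``waveforms`` is ``(n_events, n_snippet_channels,
    n_snippet_samples)`` with the event's detecting channel centered in the
    channel axis.  ``snippet_channels`` records which recording channel each
    snippet row came from (``-1`` marks out-of-probe padding rows).
    """

    channel: np.ndarray
    peak_sample: np.ndarray
    amplitude_sd: np.ndarray
    waveforms: np.ndarray
    snippet_channels: np.ndarray
    sampling_rate: float

    @property
    def n_events(self) -> int:
        return len(self.peak_sample)

    @property
    def times(self) -> np.ndarray:
        return self.peak_sample / self.sampling_rate

    def select(self, keep: np.ndarray) -> "SpikeEventSet":
        """Return a new event set restricted to a boolean or index mask."""
        return SpikeEventSet(
            channel=self.channel[keep],
            peak_sample=self.peak_sample[keep],
            amplitude_sd=self.amplitude_sd[keep],
            waveforms=self.waveforms[keep],
            snippet_channels=self.snippet_channels[keep],
            sampling_rate=self.sampling_rate,
        )


@dataclass
class SortedUnit:
    """A putative single unit: spike times plus waveform/QC metadata."""

    unit_id: int
    spike_times: np.ndarray
    mean_waveform: np.ndarray | None = None
    isi_cutoff: float = 0.003

    def __post_init__(self) -> None:
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def isi_violation_fraction(self) -> float:
        """Fraction of inter-spike intervals shorter than the refractory cutoff."""
        if self.n_spikes < 2:
            return 0.0
        isis = np.diff(self.spike_times)
        return float(np.mean(isis < self.isi_cutoff))


@dataclass
class SpikeTrainSet:
    """A sorted population: per-unit spike-time lists over one recording."""

    units: list[SortedUnit]
    duration: float
    group_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit ids must be unique")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def spike_times(self) -> list[np.ndarray]:
        return [u.spike_times for u in self.units]


@dataclass
class VelocityTrace:
    """Run-wheel velocity, signed (forward/reverse), sampled at a fixed step."""

    time: np.ndarray
    velocity: np.ndarray
    step: float = 0.010

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.shape != self.velocity.shape:
            raise ValueError("time and velocity must have the same shape")

    @property
    def duration(self) -> float:
        return float(len(self.time) * self.step)


@dataclass
class EpochSet:
    """Alternating running/stationary intervals covering a recording.

    ``starts``/``ends`` are parallel arrays of half-open intervals
    ``[start, end)``; ``labels`` holds ``"running"`` or ``"stationary"``.
    """

    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.starts) == len(self.ends) == len(self.labels)):
            raise ValueError("starts, ends and labels must be parallel")
        if np.any(self.ends <= self.starts):
            raise ValueError("epochs must have positive duration")
        if len(self.starts) > 1 and not np.allclose(self.ends[:-1], self.starts[1:]):
            raise ValueError("epochs must tile the recording without gaps")

    @classmethod
    def from_running_intervals(
        cls, run_intervals: np.ndarray, duration: float
    ) -> "EpochSet":
        """Build a covering epoch set from sorted, disjoint running intervals."""
        run_intervals = np.atleast_2d(np.asarray(run_intervals, dtype=float))
        starts, ends, labels = [], [], []
        cursor = 0.0
        if run_intervals.size:
            for s, e in run_intervals:
                if s > cursor:
                    starts.append(cursor)
                    ends.append(s)
                    labels.append("stationary")
                starts.append(s)
                ends.append(e)
                labels.append("running")
                cursor = e
        if cursor < duration:
            starts.append(cursor)
            ends.append(duration)
            labels.append("stationary")
        return cls(np.array(starts), np.array(ends), np.array(labels))

    @property
    def duration(self) -> float:
        return float(self.ends[-1]) if len(self.ends) else 0.0

    def label_at(self, times: np.ndarray) -> np.ndarray:
        """Epoch label of each time point (object array)."""
        times = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.starts, times, side="right") - 1, 0, None)
        return self.labels[idx]

    def mask_at(self, times: np.ndarray, label: str) -> np.ndarray:
        return self.label_at(times) == label

    def total_duration(self, label: str) -> float:
        sel = self.labels == label
        return float(np.sum(self.ends[sel] - self.starts[sel]))


@dataclass
class BinaryRaster:
    """Binarized population activity: ``units x bins`` 0/1 matrix."""

    matrix: np.ndarray
    bin_width: float = 0.010
    t0: float = 0.0
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be units x bins")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("raster entries must be 0/1")
        self.matrix = self.matrix.astype(np.uint8)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.matrix.shape[0])

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class PatternDistribution:
    """Probability vector over the ``2**N`` binary patterns of an ensemble.

    Pattern index encodes the joint state with unit 0 on the least-significant
    bit: index ``5`` for ``N=3`` means units 0 and 2 active.
    """

    N: int
    p: np.ndarray
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1 or self.N > 20:
            raise ValueError("ensemble size must be in 1..20")
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (2**self.N,):
            raise ValueError(f"p must have length 2**{self.N}")
        if np.any(self.p < -1e-15):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def marginals(self) -> np.ndarray:
        """Per-unit spike probability ``P(sigma_i = 1)``."""
        bits = pattern_bits(self.N)
        return self.p @ bits

    def second_moments(self) -> np.ndarray:
        """Matrix of pairwise co-activation probabilities ``P(sigma_i sigma_j = 1)``."""
        bits = pattern_bits(self.N)
        return (bits * self.p[:, None]).T @ bits


@dataclass
class EntropyResult:
    """Entropies (bits) of random same-size ensemble subsamples."""

    entropies: np.ndarray
    ensemble_size: int
    condition: str = "overall"
    seed: int | None = None
    subsets: np.ndarray | None = None

    @property
    def n_subsamples(self) -> int:
        return len(self.entropies)


@dataclass
class ShuffleNull:
    """Null distribution from repeated rate-matched shuffles."""

    samples: np.ndarray  # (n_reps, ...) statistic per shuffle repetition
    seed: int | None = None

    @property
    def n_reps(self) -> int:
        return self.samples.shape[0]

    def central_band(self, coverage: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        alpha = (1.0 - coverage) / 2.0
        lo = np.quantile(self.samples, alpha, axis=0)
        hi = np.quantile(self.samples, 1.0 - alpha, axis=0)
        return lo, hi


_BITS_CACHE: dict[int, np.ndarray] = {}


def pattern_bits(n: int) -> np.ndarray:
    """``(2**n, n)`` matrix of pattern bit expansions (unit 0 = LSB), cached."""
    if n not in _BITS_CACHE:
        codes = np.arange(2**n, dtype=np.int64)
        _BITS_CACHE[n] = ((codes[:, None] >> np.arange(n)) & 1).astype(float)
    return _BITS_CACHE[n]
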