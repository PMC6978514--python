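"""Run-wheel behavior: quadrature decoding, epoch segmentation, summaries.

Wheel motion is recorded by a 2-bit rotary encoder sampled at the acquisition
rate; the quadrature state machine converts state transitions into signed
ticks, which are calibrated to cm and smoothed with a centered 150-ms window
at 10-ms steps.  Running epochs are intervals where |velocity| exceeds
1 cm/s (the wheel can be run forward or in reverse); everything else is
stationary.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import EpochSet, VelocityTrace

__all__ = ["decode_quadrature", "segment_epochs", "behavior_summary"]

logger = logging.getLogger(__name__)

# quadrature (gray-code) transition table: +1 forward, -1 reverse, 0 no move
_ORDER = {0b00: 0, 0b01: 1, 0b11: 2, 0b10: 3}


def decode_quadrature(
    encoder_signal: np.ndarray,
    cm_per_tick: float,
    sampling_rate: float = 30_000.0,
    step: float = 0.010,
    smooth_window: float = 0.150,
) -> VelocityTrace:
    """Signed velocity (cm/s) from a 2-bit encoder state sequence.

    Illegal transitions (both bits flipping at once, i.e. a skipped state)
    are counted, logged, and contribute zero displacement.
    """
    if cm_per_tick <= 0:
        raise ValueError("cm_per_tick must be positive")
    states = np.asarray(encoder_signal, dtype=int)
    if states.size and not np.isin(states, list(_ORDER)).all():
        raise ValueError("encoder states must be 2-bit values {0b00,0b01,0b11,0b10}")
    phase = np.array([_ORDER[s] for s in states]) if states.size else np.array([], dtype=int)
    dphase = (np.diff(phase) + 2) % 4 - 2  # -1, 0, +1 legal; +/-2 illegal
    illegal = dphase == -2
    if illegal.any():
        logger.warning("%d illegal quadrature transitions (double steps)", illegal.sum())
    ticks = np.where(np.abs(dphase) == 2, 0, dphase).astype(float)

    step_samples = int(round(step * sampling_rate))
    n_steps = int(np.ceil(len(states) / step_samples))
    displacement = np.zeros(n_steps)
    bin_idx = np.arange(1, len(states)) // step_samples  # tick at sample k spans k-1 -> k
    np.add.at(displacement, bin_idx, ticks)
    velocity = displacement * cm_per_tick / step

    w = min(max(int(round(smooth_window / step)), 1), max(n_steps, 1))
    kernel = np.ones(w) / w
    # centered moving average; edges renormalized by actual kernel overlap
    smoothed = np.convolve(velocity, kernel, mode="same")
    norm = np.convolve(np.ones(n_steps), kernel, mode="same")
    smoothed = smoothed / norm
    return VelocityTrace(time=np.arange(n_steps) * step, velocity=smoothed, step=step)


def segment_epochs(v: VelocityTrace, run_threshold: float = 1.0) -> EpochSet:
    """Running where |velocity| > threshold; contiguous samples merged."""
    running = np.abs(v.velocity) > run_threshold
    intervals = []
    if running.any():
        edges = np.diff(running.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if running[0]:
            starts = np.r_[0, starts]
        if running[-1]:
            ends = np.r_[ends, len(running)]
        intervals = [(s * v.step, e * v.step) for s, e in zip(starts, ends)]
    return EpochSet.from_running_intervals(
        np.array(intervals).reshape(-1, 2), duration=v.duration
    )


def behavior_summary(e: EpochSet, v: VelocityTrace) -> dict:
    """Proportion of time running, mean |velocity| while running, mean IRI.

    The inter-run interval (IRI) is the duration of a stationary epoch lying
    between two consecutive running epochs.  With no running epochs the
    proportion is 0 and the other fields are reported missing (NaN).
    """
    total = e.duration
    run_time = e.total_duration("running")
    proportion = run_time / total if total > 0 else 0.0
    is_run = e.labels == "running"
    if not is_run.any():
        return {
            "proportion_running": 0.0,
            "mean_run_velocity": float("nan"),
            "mean_inter_run_interval": float("nan"),
        }
    run_mask = e.mask_at(v.time + v.step / 2, "running")
    mean_vel = float(np.mean(np.abs(v.velocity[run_mask]))) if run_mask.any() else float("nan")
    run_pos = np.flatnonzero(is_run)
    iris = []
    for k in range(len(e.starts)):
        if e.labels[k] == "stationary" and run_pos.size and run_pos.min() < k < run_pos.max():
            iris.append(e.ends[k] - e.starts[k])
    mean_iri = float(np.mean(iris)) if iris else float("nan")
    return {
        "proportion_running": float(proportion),
        "mean_run_velocity": mean_vel,
        "mean_inter_run_interval": mean_iri,
    }
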