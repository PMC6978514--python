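"""Independent and pairwise maximum-entropy (Ising) models of binary patterns.

The pairwise model assigns each joint state sigma in {0,1}^N the probability

    P(sigma) = exp( sum_i h_i sigma_i + (1/2) sum_{i != j} J_ij sigma_i sigma_j ) / Z

with symmetric couplings J (zero diagonal) and partition function Z.  The
independent (first-order) model is the J = 0 special case, whose biases have
the closed form h_i = logit(m_i) for marginal spike probabilities m_i.

All computations are exact: for the ensemble sizes used here (N <= 20) the
2**N states are enumerated directly, so there is no sampling error in the
partition function, the model moments, or the fitting gradients.  Fitting the
pairwise model maximizes likelihood (equivalently, minimizes
D(empirical || model)), which is a smooth convex problem whose gradient is the
difference between model and empirical first/second moments; we polish an
L-BFGS solution with damped Newton steps on the exact Fisher information until
the maximum moment mismatch falls below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .core import BinaryRaster, PatternDistribution, pattern_bits

__all__ = [
    "MaxEntModel",
    "FitReport",
    "fit_independent",
    "fit_pairwise",
    "model_pattern_probs",
    "kld",
    "coactivity_spectrum",
    "sample_model",
    "model_entropy",
]

_MAX_N = 20


@dataclass
class MaxEntModel:
    """Order-1 or order-2 maximum-entropy model over N binary units."""

    N: int
    order: int
    h: np.ndarray
    J: np.ndarray
    logZ: float

    def __post_init__(self) -> None:
        if self.N < 1 or self.N > _MAX_N:
            raise ValueError(f"N must be in 1..{_MAX_N} (exact enumeration bound)")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.shape != (self.N,):
            raise ValueError("h must have shape (N,)")
        if self.J.shape != (self.N, self.N):
            raise ValueError("J must have shape (N, N)")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have zero diagonal")
        if self.order == 1 and np.any(self.J != 0):
            raise ValueError("order-1 model must have J = 0")

    @classmethod
    def from_params(cls, h: np.ndarray, J: np.ndarray | None = None) -> "MaxEntModel":
        """Build a model from (h, J), computing logZ by enumeration."""
        h = np.asarray(h, dtype=float)
        n = len(h)
        if J is None:
            J = np.zeros((n, n))
        J = np.asarray(J, dtype=float)
        order = 1 if not np.any(J) else 2
        logZ = _log_partition(h, J)
        return cls(N=n, order=order, h=h, J=J, logZ=logZ)


@dataclass
class FitReport:
    iterations: int
    moment_mismatch: float
    converged: bool
    tol: float


def _energies(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """log of unnormalized pattern probabilities for all 2**N states."""
    bits = pattern_bits(len(h))
    e = bits @ h
    if np.any(J):
        # (1/2) sum_{i != j} J_ij s_i s_j == sum_{i<j} J_ij s_i s_j
        e = e + 0.5 * np.einsum("ki,ij,kj->k", bits, J, bits)
    return e


def _log_partition(h: np.ndarray, J: np.ndarray) -> float:
    return float(logsumexp(_energies(h, J)))


def model_pattern_probs(m: MaxEntModel) -> PatternDistribution:
    """Exact pattern probabilities of the model by full state enumeration."""
    logp = _energies(m.h, m.J) - m.logZ
    p = np.exp(logp)
    p /= p.sum()  # guard residual rounding; already 1 within 1e-12
    return PatternDistribution(N=m.N, p=p)


def model_entropy(m: MaxEntModel) -> float:
    """Shannon entropy of the model distribution in bits."""
    p = model_pattern_probs(m).p
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def fit_independent(
    d: PatternDistribution, eps: float | None = None
) -> tuple[MaxEntModel, FitReport]:
    """Closed-form first-order fit: h_i = logit of the empirical marginal.

    Marginals are clipped to ``[eps, 1-eps]`` before the logit; ``eps``
    defaults to ``1/(2 n_samples)`` when the sample count is known.
    """
    m = d.marginals()
    if eps is None:
        if d.n_samples:
            eps = 1.0 / (2.0 * d.n_samples)
        else:
            eps = 1e-6
            if np.any(m <= 0) or np.any(m >= 1):
                warnings.warn(
                    "marginal at 0 or 1 with unknown sample count; clipping at 1e-6",
                    stacklevel=2,
                )
    mc = np.clip(m, eps, 1.0 - eps)
    h = np.log(mc / (1.0 - mc))
    model = MaxEntModel.from_params(h)
    mismatch = float(np.max(np.abs(model_pattern_probs(model).marginals() - mc)))
    return model, FitReport(iterations=0, moment_mismatch=mismatch, converged=True, tol=0.0)


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _suff_stats(d: PatternDistribution) -> np.ndarray:
    """Empirical moment vector (marginals, upper-triangle pair moments)."""
    iu, ju = _pair_index(d.N)
    return np.concatenate([d.marginals(), d.second_moments()[iu, ju]])


def _unpack(theta: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    h = theta[:n]
    J = np.zeros((n, n))
    iu, ju = _pair_index(n)
    J[iu, ju] = theta[n:]
    J = J + J.T
    return h, J


def _model_moments(h: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, float]:
    bits = pattern_bits(len(h))
    e = _energies(h, J)
    logZ = logsumexp(e)
    p = np.exp(e - logZ)
    iu, ju = _pair_index(len(h))
    first = p @ bits
    pair = (bits[:, iu] * bits[:, ju] * p[:, None]).sum(axis=0)
    return np.concatenate([first, pair]), float(logZ)


def fit_pairwise(
    d: PatternDistribution, tol: float = 1e-6, max_iter: int = 10_000
) -> tuple[MaxEntModel, FitReport]:
    """Fit the pairwise model by exact maximum likelihood.

    Convergence is declared on the sufficient statistics: the maximum absolute
    difference between model and empirical first/second moments must fall
    below ``tol``.  The objective per sample is ``logZ(theta) - <theta, T>``
    (T = empirical moments), whose gradient is exactly that moment mismatch.
    """
    n = d.N
    target = _suff_stats(d)
    iu, ju = _pair_index(n)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        h, J = _unpack(theta, n)
        moments, logZ = _model_moments(h, J)
        f = logZ - float(theta @ target)
        return f, moments - target

    # warm start from the independent fit
    m0 = np.clip(d.marginals(), 1e-4, 1 - 1e-4)
    theta0 = np.concatenate([np.log(m0 / (1 - m0)), np.zeros(len(iu))])

    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * 1e-3, "ftol": 1e-16},
    )
    theta = res.x
    n_iter = int(res.nit)

    # Newton polish on the exact Fisher information (covariance of the
    # sufficient statistics under the model); quadratic convergence to the
    # moment-matching point whenever the empirical moments are attainable.
    bits = pattern_bits(n)
    stats = np.concatenate([bits, bits[:, iu] * bits[:, ju]], axis=1)
    for _ in range(60):
        h, J = _unpack(theta, n)
        moments, _ = _model_moments(h, J)
        grad = moments - target
        gmax = float(np.max(np.abs(grad)))
        if gmax <= tol * 1e-3:
            break
        e = _energies(h, J)
        p = np.exp(e - logsumexp(e))
        centered = stats - moments
        fisher = (centered * p[:, None]).T @ centered
        fisher[np.diag_indices_from(fisher)] += 1e-12
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking on the convex objective
        f0 = _log_partition(h, J) - float(theta @ target)
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            hc, Jc = _unpack(cand, n)
            if _log_partition(hc, Jc) - float(cand @ target) < f0:
                theta = cand
                break
            scale *= 0.5
        else:
            break
        n_iter += 1

    h, J = _unpack(theta, n)
    moments, logZ = _model_moments(h, J)
    mismatch = float(np.max(np.abs(moments - target)))
    model = MaxEntModel(N=n, order=2, h=h, J=J, logZ=logZ)
    report = FitReport(
        iterations=n_iter,
        moment_mismatch=mismatch,
        converged=bool(mismatch <= tol),
        tol=tol,
    )
    return model, report


def kld(empirical: PatternDistribution, model: PatternDistribution) -> float:
    """Kullback-Leibler divergence D(empirical || model) in bits.

    Terms with zero empirical probability contribute nothing; a zero model
    probability where the empirical mass is positive yields ``inf`` (cannot
    occur for maximum-entropy models, whose probabilities are strictly
    positive).
    """
    if empirical.N != model.N:
        raise ValueError("distributions must share N")
    pe, pm = empirical.p, model.p
    nz = pe > 0
    if np.any(pm[nz] == 0):
        warnings.warn("model assigns zero probability to observed pattern", stacklevel=2)
        return float("inf")
    return float(np.sum(pe[nz] * np.log2(pe[nz] / pm[nz])))


def coactivity_spectrum(d: PatternDistribution) -> np.ndarray:
    """P(exactly k units active), k = 0..N, from the pattern distribution."""
    counts = pattern_bits(d.N).sum(axis=1).astype(int)
    return np.bincount(counts, weights=d.p, minlength=d.N + 1)


def sample_model(
    m: MaxEntModel, n_bins: int, seed: int | np.random.Generator
) -> BinaryRaster:
    """Draw i.i.d. bins from the model's exact pattern distribution."""
    rng = np.random.default_rng(seed)
    p = model_pattern_probs(m).p
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    codes = np.searchsorted(cdf, rng.random(n_bins), side="right")
    bits = ((codes[:, None] >> np.arange(m.N)) & 1).astype(np.uint8)
    return BinaryRaster(matrix=bits.T)


def observed_fisher_se(m: MaxEntModel, n_samples: int) -> np.ndarray:
    """Asymptotic standard errors of (h, J_upper) from the exact Fisher matrix."""
    bits = pattern_bits(m.N)
    iu, ju = _pair_index(m.N)
    stats = np.concatenate([bits, bits[:, iu] * bits[:, ju]], axis=1)
    p = model_pattern_probs(m).p
    mean = p @ stats
    centered = stats - mean
    fisher = (centered * p[:, None]).T @ centered
    cov = np.linalg.inv(fisher + 1e-12 * np.eye(len(mean)))
    return np.sqrt(np.diag(cov) / n_samples)
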