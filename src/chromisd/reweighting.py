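"""Multiple-histogram reweighting across replicas.

Replica-exchange runs sample a family of tempered distributions
``p_k propto prior * exp(lambda_k * l(x))`` where ``l`` is the data
log-likelihood (model-evidence estimation) or ``-R_g`` (density-of-states
estimation).  A binless self-consistent estimator (MBAR-style) combines all
replicas into relative free energies ``f(lambda) = -log Z(lambda)``; the
model evidence is ``log Pr(D|I) = log Z(1) - log Z(0)``.  A binned variant
over R_g recovers the density of states (microcanonical entropy) of the
conformational prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EvidenceResult",
    "DensityOfStates",
    "estimate_log_evidence",
    "estimate_density_of_states",
]


class ReweightingError(RuntimeError):
    """Raised when the self-consistent iteration fails to converge."""


@dataclass
class EvidenceResult:
    """log Z on the tempering schedule, normalized so log Z(0) = 0."""

    lambdas: np.ndarray
    log_Z: np.ndarray
    log_evidence: float  # log Z(1) - log Z(0)
    n_iterations: int

    def interpolate(self, lam: float) -> float:
        return float(np.interp(lam, self.lambdas, self.log_Z))


def _mbar_free_energies(
    lambdas: np.ndarray,
    log_like: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Self-consistent free energies of the tempered states.

    ``log_like`` has shape (K, T): T draws of the tempered term from each
    of the K states.  Returns (f_k, pooled log-denominators, iterations);
    f is defined by exp(-f_k) = sum_n exp(lambda_k l_n) / D_n with
    D_n = sum_j N_j exp(lambda_j l_n - f_j).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    log_like = np.asarray(log_like, dtype=float)
    K, T = log_like.shape
    if K != len(lambdas):
        raise ValueError("log_like must have one row per lambda")
    l_pool = log_like.ravel()  # pooled samples, N_j = T for every state
    logN = np.log(T)
    f = np.zeros(K)
    A = lambdas[:, None] * l_pool[None, :]  # (K, N_tot)
    for it in range(max_iter):
        # D_n = sum_j N_j exp(lambda_j l_n + f_j) with f_j = -log Z_j
        log_D = logsumexp(logN + A + f[:, None], axis=0)  # (N_tot,)
        f_new = -logsumexp(A - log_D[None, :], axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            log_D = logsumexp(logN + A + f[:, None], axis=0)
            return f, log_D, it + 1
    raise ReweightingError(
        f"free-energy iteration did not converge (last change {delta:.2e}); "
        "adjacent tempered distributions may not overlap"
    )


def _check_neighbor_overlap(
    lambdas: np.ndarray, log_like: np.ndarray, min_ess: float = 2.0
) -> None:
    """Diagnose non-overlapping neighbors before the iteration runs.

    Reweights each state's samples to its neighbor and computes the
    effective sample size of the importance weights; an ESS below
    ``min_ess`` in both directions means the free-energy chain is broken.
    """
    K = len(lambdas)
    for k in range(K - 1):
        ess = []
        for src, dst in ((k, k + 1), (k + 1, k)):
            logw = (lambdas[dst] - lambdas[src]) * log_like[src]
            logw = logw - logsumexp(logw)
            ess.append(float(np.exp(-logsumexp(2.0 * logw))))
        if max(ess) < min_ess:
            raise ReweightingError(
                f"tempered states at lambda = {lambdas[k]:.4g} and "
                f"{lambdas[k + 1]:.4g} do not overlap (ESS "
                f"{max(ess):.2f} < {min_ess}); refine the schedule"
            )


def estimate_log_evidence(
    lambdas: np.ndarray,
    log_like: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> EvidenceResult:
    """Estimate log Z(lambda) from tempered samples of the log-likelihood.

    The schedule need not contain lambda = 0 or 1: free energies at those
    endpoints are obtained by reweighting the pooled samples.  Requires
    overlapping neighbor distributions (nonzero swap acceptance); a
    convergence failure raises :class:`ReweightingError`.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    log_like = np.asarray(log_like, dtype=float)
    _check_neighbor_overlap(lambdas, log_like)
    f, log_D, n_iter = _mbar_free_energies(lambdas, log_like, tol, max_iter)
    l_pool = log_like.ravel()

    def f_at(lam: float) -> float:
        return float(-logsumexp(lam * l_pool - log_D))

    f0 = f_at(0.0)
    eval_lams = np.unique(np.concatenate([[0.0, 1.0], lambdas]))
    log_Z = np.array([f0 - f_at(lam) for lam in eval_lams])  # logZ - logZ(0)
    log_ev = float(f0 - f_at(1.0))
    return EvidenceResult(eval_lams, log_Z, log_ev, n_iter)


@dataclass
class DensityOfStates:
    """Log density of states (entropy up to a constant) on an R_g grid."""

    rg_grid: np.ndarray  # bin centers, strictly increasing
    log_g: np.ndarray  # normalized so logsumexp(log_g) = 0
    counts: np.ndarray  # pooled histogram counts per bin
    empty_interior_bins: np.ndarray  # flagged bins inside the support

    def mean_rg(self) -> float:
        """Mean R_g under the unbiased conformational prior."""
        w = np.exp(self.log_g - logsumexp(self.log_g))
        return float(np.sum(w * self.rg_grid))

    def tail_fraction(self, rg_threshold: float) -> float:
        """Pr(R_g < threshold) under the unbiased prior."""
        mask = self.rg_grid < rg_threshold
        if not np.any(mask):
            return 0.0
        return float(np.exp(logsumexp(self.log_g[mask]) - logsumexp(self.log_g)))


def estimate_density_of_states(
    bias_lambdas: np.ndarray,
    rg_samples: np.ndarray,
    bin_width: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> DensityOfStates:
    """Binned WHAM over R_g for samples of exp(-lambda R_g) * prior.

    ``rg_samples`` has shape (K, T).  A single unbiased replica (K = 1,
    lambda = 0) reduces to the plain R_g histogram.  Interior bins with no
    samples are flagged in the result.
    """
    bias_lambdas = np.asarray(bias_lambdas, dtype=float)
    rg_samples = np.asarray(rg_samples, dtype=float)
    if rg_samples.ndim == 1:
        rg_samples = rg_samples[None, :]
    K, T = rg_samples.shape
    if K != len(bias_lambdas):
        raise ValueError("one row of samples per bias strength required")

    lo, hi = rg_samples.min(), rg_samples.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    H = np.zeros((K, n_bins))
    for k in range(K):
        H[k], _ = np.histogram(rg_samples[k], bins=edges)
    pooled = H.sum(axis=0)
    occupied = pooled > 0
    interior = np.zeros(n_bins, dtype=bool)
    if occupied.any():
        first, last = np.argmax(occupied), n_bins - 1 - np.argmax(occupied[::-1])
        interior[first : last + 1] = ~occupied[first : last + 1]

    # WHAM: log g_b = log(sum_k H_kb) - logsumexp_k(log N_k + f_k - lambda_k Rg_b)
    with np.errstate(divide="ignore"):
        log_pooled = np.where(occupied, np.log(np.maximum(pooled, 1)), -np.inf)
    logN = np.log(T)
    f = np.zeros(K)
    bias = -bias_lambdas[:, None] * centers[None, :]  # (K, B)
    for _ in range(max_iter):
        log_g = log_pooled - logsumexp(logN + f[:, None] + bias, axis=0)
        f_new = -logsumexp(log_g[None, :] + bias, axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise ReweightingError("WHAM iteration did not converge")
    log_g = log_g - logsumexp(log_g[occupied])
    return DensityOfStates(centers, log_g, pooled, interior)
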