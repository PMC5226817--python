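"""Data models for single-cell Hi-C contacts and FISH size measurements.

Three likelihoods measure the compatibility of a conformation with a list of
contacts: a logistic contact probability (steepness ``alpha``, cutoff
``d_c``), and two distance-restraint error models — a Gaussian with a flat
plateau and a lognormal — that interpret a contact as a noisy measurement of
an unknown distance ``delta = a / gamma``.  A Gaussian error model restrains
the chromosome size inferred from FISH imaging.  For diploid chromosomes,
ambiguous distance restraints combine the two per-copy distances by r^-6
averaging (a soft logical OR) before entering the logistic model.

Multiplicities ``n_ij > 1`` duplicate a restraint ``n_ij`` times in every
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import radius_of_gyration, SizeModel, size_from_rg

__all__ = [
    "ContactData",
    "FishData",
    "NuisanceParams",
    "logistic_log_likelihood",
    "logistic_gradient",
    "gaussian_plateau_log_likelihood",
    "gaussian_plateau_gradient",
    "lognormal_log_likelihood",
    "lognormal_gradient",
    "fish_log_likelihood",
    "fish_gradient",
    "ambiguous_distance",
    "diploid_logistic_log_likelihood",
    "diploid_logistic_gradient",
    "classify_diploid_contacts",
]

#: Fixed restraint weights w = 1/sigma^2 used in the headline distance runs.
DEFAULT_WEIGHT_PLATEAU = 100.0
DEFAULT_WEIGHT_LOGNORMAL = 500.0


@dataclass
class ContactData:
    """Unique unordered bead pairs with multiplicities.

    ``i``, ``j`` are 0-based bead indices with ``i < j``; ``counts`` holds
    the multiplicity n_ij >= 1 of each pair.  Self-contacts are rejected.
    """

    i: np.ndarray
    j: np.ndarray
    counts: np.ndarray
    n_beads: int

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.counts)):
            raise ValueError("index and count arrays must have equal length")
        lo = np.minimum(self.i, self.j)
        hi = np.maximum(self.i, self.j)
        if np.any(lo == hi):
            raise ValueError("self-contacts (i == j) are not allowed")
        if len(lo) and (lo.min() < 0 or hi.max() >= self.n_beads):
            raise ValueError("bead index out of range")
        self.i, self.j = lo, hi
        key = self.i * self.n_beads + self.j
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate pairs; merge multiplicities first")
        if np.any(self.counts < 1):
            raise ValueError("multiplicities must be >= 1")

    @classmethod
    def from_pairs(cls, pairs, n_beads: int, counts=None) -> "ContactData":
        """Build from possibly unsorted/duplicated pairs, merging counts."""
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        if counts is None:
            counts = np.ones(len(pairs))
        counts = np.asarray(counts, dtype=float)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        if len(lo) and (lo.min() < 0 or hi.max() >= n_beads):
            raise ValueError("bead index out of range")
        keep = lo != hi
        lo, hi, counts = lo[keep], hi[keep], counts[keep]
        key = lo * n_beads + hi
        uniq, inv = np.unique(key, return_inverse=True)
        merged = np.zeros(len(uniq))
        np.add.at(merged, inv, counts)
        return cls(uniq // n_beads, uniq % n_beads, merged, n_beads)

    def __len__(self) -> int:
        return len(self.i)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    def distances(self, X: np.ndarray) -> np.ndarray:
        return np.linalg.norm(X[self.i] - X[self.j], axis=1)


@dataclass
class FishData:
    """Summary of M chromosome-size measurements from FISH imaging (um)."""

    s_bar: float = 3.7
    delta_s: float = 0.3
    M: int = 1
    sigma_fish: float | None = None  # defaults to delta_s

    def __post_init__(self) -> None:
        if self.sigma_fish is None:
            self.sigma_fish = self.delta_s
        if self.s_bar <= 0 or self.delta_s < 0 or self.M < 1 or self.sigma_fish <= 0:
            raise ValueError("invalid FISH data")


@dataclass
class NuisanceParams:
    """Distance scale gamma (delta = a/gamma) and error sigma (w = 1/sigma^2)."""

    gamma: float = 1.0
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.sigma <= 0:
            raise ValueError("gamma and sigma must be positive")

    @property
    def w(self) -> float:
        return 1.0 / self.sigma**2


# ---------------------------------------------------------------------------
# logistic contact model
# ---------------------------------------------------------------------------

def _logistic_terms(d: np.ndarray, alpha: float, d_c: float) -> np.ndarray:
    # log(1 / (1 + exp(alpha (d - d_c)))) = -log1p(exp(z)), overflow-safe
    z = alpha * (d - d_c)
    return -np.logaddexp(0.0, z)


def logistic_log_likelihood(
    X: np.ndarray, contacts: ContactData, alpha: float, d_c: float
) -> float:
    """Sum over contacts of n_ij * log sigmoid(-alpha (d_ij - d_c))."""
    if alpha <= 0 or d_c <= 0:
        raise ValueError("alpha and d_c must be positive")
    d = contacts.distances(np.asarray(X, dtype=float))
    return float(np.sum(contacts.counts * _logistic_terms(d, alpha, d_c)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _scatter_pair_gradient(
    X: np.ndarray, contacts: ContactData, dlogL_dd: np.ndarray
) -> np.ndarray:
    """Distribute per-contact d(logL)/d(d_ij) onto bead coordinates."""
    vec = X[contacts.i] - X[contacts.j]
    d = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = vec / np.where(d > 0, d, 1.0)[:, None]
    grad = np.zeros_like(X)
    contrib = dlogL_dd[:, None] * unit
    np.add.at(grad, contacts.i, contrib)
    np.subtract.at(grad, contacts.j, contrib)
    return grad


def logistic_gradient(
    X: np.ndarray, contacts: ContactData, alpha: float, d_c: float
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    d = contacts.distances(X)
    dlogL_dd = -contacts.counts * alpha * _sigmoid(alpha * (d - d_c))
    return _scatter_pair_gradient(X, contacts, dlogL_dd)


# ---------------------------------------------------------------------------
# distance-restraint error models
# ---------------------------------------------------------------------------

def _plateau_residual(gd: np.ndarray, a: float) -> np.ndarray:
    """Signed distance of gamma*d to the plateau [0.8a, 1.2a] (0 inside)."""
    return np.where(gd < 0.8 * a, gd - 0.8 * a, np.where(gd > 1.2 * a, gd - 1.2 * a, 0.0))


def gaussian_plateau_log_likelihood(
    X: np.ndarray, contacts: ContactData, gamma: float, sigma: float, a: float = 1.0
) -> float:
    """Gaussian error model with a flat plateau for gamma*d in [0.8a, 1.2a]."""
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be positive")
    d = contacts.distances(np.asarray(X, dtype=float))
    res = _plateau_residual(gamma * d, a)
    log_norm = -np.log(np.sqrt(2.0 * np.pi) * sigma + 0.4 * a)
    terms = log_norm - res**2 / (2.0 * sigma**2)
    return float(np.sum(contacts.counts * terms))


def gaussian_plateau_gradient(
    X: np.ndarray, contacts: ContactData, gamma: float, sigma: float, a: float = 1.0
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    d = contacts.distances(X)
    res = _plateau_residual(gamma * d, a)
    dlogL_dd = -contacts.counts * res * gamma / sigma**2
    return _scatter_pair_gradient(X, contacts, dlogL_dd)


def lognormal_log_likelihood(
    X: np.ndarray, contacts: ContactData, gamma: float, sigma: float, a: float = 1.0
) -> float:
    """Lognormal error model: -log(sqrt(2 pi) sigma a) - log^2(a/(gamma d))/(2 sigma^2)."""
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be positive")
    d = contacts.distances(np.asarray(X, dtype=float))
    if np.any(d <= 0):
        raise ValueError("lognormal model requires strictly positive distances")
    r = np.log(a / (gamma * d))
    terms = -np.log(np.sqrt(2.0 * np.pi) * sigma * a) - r**2 / (2.0 * sigma**2)
    return float(np.sum(contacts.counts * terms))


def lognormal_gradient(
    X: np.ndarray, contacts: ContactData, gamma: float, sigma: float, a: float = 1.0
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    d = contacts.distances(X)
    r = np.log(a / (gamma * d))
    dlogL_dd = contacts.counts * r / (sigma**2 * d)
    return _scatter_pair_gradient(X, contacts, dlogL_dd)


# ---------------------------------------------------------------------------
# FISH size restraint
# ---------------------------------------------------------------------------

def fish_log_likelihood(
    X: np.ndarray,
    fish: FishData,
    size_model: SizeModel | None = None,
    length_unit_um: float = 1.0,
) -> float:
    """Gaussian size restraint from M FISH measurements with mean s_bar, sd delta_s.

    ``length_unit_um`` converts internal coordinates (units of a) to um.
    The delta_s^2 term is constant in X but kept so evidence comparisons see
    the complete log-density.
    """
    rg_um = radius_of_gyration(X) * length_unit_um
    size = size_from_rg(rg_um, size_model)
    norm = -fish.M * np.log(np.sqrt(2.0 * np.pi) * fish.sigma_fish)
    return float(
        norm
        - fish.M
        / (2.0 * fish.sigma_fish**2)
        * ((fish.s_bar - size) ** 2 + fish.delta_s**2)
    )


def fish_gradient(
    X: np.ndarray,
    fish: FishData,
    size_model: SizeModel | None = None,
    length_unit_um: float = 1.0,
) -> np.ndarray:
    from .model import radius_of_gyration_gradient

    if size_model is None:
        size_model = SizeModel()
    X = np.asarray(X, dtype=float)
    rg = radius_of_gyration(X)
    rg_um = rg * length_unit_um
    size = size_from_rg(rg_um, size_model)
    if size_model.kind == "linear":
        dsize_drg_um = size_model.linear_factor
    else:
        c, p = size_model.powerlaw
        dsize_drg_um = c * p * rg_um ** (p - 1.0) if rg_um > 0 else 0.0
    dlogL_dsize = fish.M / fish.sigma_fish**2 * (fish.s_bar - size)
    return dlogL_dsize * dsize_drg_um * length_unit_um * radius_of_gyration_gradient(X)


# ---------------------------------------------------------------------------
# ambiguous restraints for diploid chromosomes
# ---------------------------------------------------------------------------

def ambiguous_distance(d1, d2):
    """r^-6 average (d1^-6 + d2^-6)^(-1/6); always <= min(d1, d2)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("distances must be positive")
    out = (d1**-6 + d2**-6) ** (-1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def _check_diploid(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape != X2.shape:
        raise ValueError("the two chromosome copies must have equal bead counts")
    return X1, X2


def diploid_logistic_log_likelihood(
    X1: np.ndarray, X2: np.ndarray, contacts: ContactData, alpha: float, d_c: float
) -> float:
    """Logistic contact model on the r^-6-averaged per-copy distances."""
    X1, X2 = _check_diploid(X1, X2)
    dbar = ambiguous_distance(contacts.distances(X1), contacts.distances(X2))
    return float(np.sum(contacts.counts * _logistic_terms(dbar, alpha, d_c)))


def diploid_logistic_gradient(
    X1: np.ndarray, X2: np.ndarray, contacts: ContactData, alpha: float, d_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients with respect to both copies (chain rule through the ADR)."""
    X1, X2 = _check_diploid(X1, X2)
    d1 = contacts.distances(X1)
    d2 = contacts.distances(X2)
    dbar = ambiguous_distance(d1, d2)
    dlogL_ddbar = -contacts.counts * alpha * _sigmoid(alpha * (dbar - d_c))
    # d dbar / d d_k = (dbar / d_k)^7
    g1 = _scatter_pair_gradient(X1, contacts, dlogL_ddbar * (dbar / d1) ** 7)
    g2 = _scatter_pair_gradient(X2, contacts, dlogL_ddbar * (dbar / d2) ** 7)
    return g1, g2


def classify_diploid_contacts(
    ensemble1: np.ndarray,
    ensemble2: np.ndarray,
    contacts: ContactData,
    d_c: float,
    align_copies: bool = True,
) -> np.ndarray:
    """Label each contact by which copy satisfies it in the posterior mean.

    ``ensemble1``/``ensemble2`` are (M, N, 3) stacks of posterior draws for
    the two copies.  A contact is ``both`` when the ensemble-mean distance is
    below ``d_c`` in both copies, ``copy1``/``copy2`` when only one copy
    satisfies it, and ``violated`` when neither does.

    The diploid posterior is symmetric under exchanging the copies, so a
    well-mixed sampler switches the labels along the chain.  With
    ``align_copies`` (default) each draw's copies are relabeled to match the
    running per-copy mean of the restrained distances before averaging —
    the usual relabeling treatment for label switching in mixture models.
    """
    ensemble1 = np.asarray(ensemble1, dtype=float)
    ensemble2 = np.asarray(ensemble2, dtype=float)
    if ensemble1.ndim == 2:
        ensemble1 = ensemble1[None]
    if ensemble2.ndim == 2:
        ensemble2 = ensemble2[None]
    D1 = np.linalg.norm(ensemble1[:, contacts.i] - ensemble1[:, contacts.j], axis=-1)
    D2 = np.linalg.norm(ensemble2[:, contacts.i] - ensemble2[:, contacts.j], axis=-1)
    if align_copies and len(D1) > 1:
        ref1, ref2 = D1[0].copy(), D2[0].copy()
        for t in range(1, len(D1)):
            keep = np.sum((D1[t] - ref1) ** 2 + (D2[t] - ref2) ** 2)
            swap = np.sum((D2[t] - ref1) ** 2 + (D1[t] - ref2) ** 2)
            if swap < keep:
                D1[t], D2[t] = D2[t].copy(), D1[t].copy()
            w = 1.0 / (t + 1)
            ref1 = (1 - w) * ref1 + w * D1[t]
            ref2 = (1 - w) * ref2 + w * D2[t]
    d1 = D1.mean(axis=0)
    d2 = D2.mean(axis=0)
    labels = np.full(len(contacts), "violated", dtype=object)
    labels[(d1 < d_c) & (d2 < d_c)] = "both"
    labels[(d1 < d_c) & (d2 >= d_c)] = "copy1"
    labels[(d1 >= d_c) & (d2 < d_c)] = "copy2"
    return labels
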