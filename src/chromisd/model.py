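"""Coarse-grained bead-polymer model of the chromatin fiber.

A chromosome is represented as a linear chain of ``N`` spherical beads of
diameter ``a``.  Internally all lengths are measured in units of ``a``
(``a = 1``); conversion to physical units happens only at I/O, through
:func:`bead_radius_from_resolution`.

The conformational prior is a canonical ensemble

    Pr(X | I)  propto  exp( -k_nb * E_nb(X) - k_bb * E_bb(X) )

with a harmonic upper-limit backbone term ``E_bb`` that penalizes
consecutive-bead distances exceeding ``a``, and one of two excluded-volume
terms ``E_nb``: a soft quartic repulsion, or a Lennard-Jones potential with
linear asymptotes (attractive well of unit depth at ``d = a``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolymerSpec",
    "SizeModel",
    "bead_radius_from_resolution",
    "backbone_energy",
    "backbone_gradient",
    "quartic_repulsion_energy",
    "quartic_repulsion_gradient",
    "lennard_jones_energy",
    "lennard_jones_gradient",
    "prior_log_density",
    "prior_gradient",
    "radius_of_gyration",
    "radius_of_gyration_gradient",
    "chromosome_size",
]

#: Default chromatin density used to size beads, in base pairs per cubic micron.
DEFAULT_DENSITY_BP_PER_UM3 = 12e6


@dataclass
class PolymerSpec:
    """Parameters of the bead-polymer model.

    Force constants are given in powers of the bead diameter ``a``:
    ``k_bb = 250 / a**2`` for the backbone and ``k_nb = 5 / a**4`` for the
    quartic repulsion.  The Lennard-Jones term carries no explicit force
    constant (weight 1).
    """

    n_beads: int
    bead_diameter: float = 1.0
    resolution_bp: float = 500_000.0
    k_bb: float = field(default=None)  # type: ignore[assignment]
    k_nb: float = field(default=None)  # type: ignore[assignment]
    ev_kind: str = "quartic_repulsion"  # or "lennard_jones"
    lj_s: float = 0.6
    lj_l: float = 1.25
    lj_dcut: float = field(default=None)  # type: ignore[assignment]
    contact_cutoff: float = field(default=None)  # type: ignore[assignment]
    logistic_steepness: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = self.bead_diameter
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if a <= 0:
            raise ValueError("bead_diameter must be positive")
        if self.k_bb is None:
            self.k_bb = 250.0 / a**2
        if self.k_nb is None:
            self.k_nb = 5.0 / a**4
        if self.lj_dcut is None:
            self.lj_dcut = 1.375 * a
        if self.contact_cutoff is None:
            self.contact_cutoff = 1.5 * a
        if self.logistic_steepness is None:
            self.logistic_steepness = 200.0 / a
        if self.ev_kind not in ("quartic_repulsion", "lennard_jones"):
            raise ValueError(f"unknown ev_kind: {self.ev_kind!r}")
        if not (0 < self.lj_s < 1 < self.lj_l < self.lj_dcut / a):
            raise ValueError("require 0 < s < 1 < l < d_cut/a")
        if min(self.k_bb, self.k_nb, self.contact_cutoff, self.logistic_steepness) <= 0:
            raise ValueError("force constants and cutoffs must be positive")


@dataclass
class SizeModel:
    """Maps the radius of gyration to a chromosome-territory size.

    The default is the linear relation ``size = 2.58 * R_g``; the power law
    ``1.21 * R_g**1.11`` is an alternative for relatively compact structures.
    """

    linear_factor: float = 2.58
    powerlaw: tuple[float, float] = (1.21, 1.11)
    kind: str = "linear"  # or "powerlaw"

    def __post_init__(self) -> None:
        if self.linear_factor <= 0 or min(self.powerlaw) <= 0:
            raise ValueError("size-model factors must be positive")
        if self.kind not in ("linear", "powerlaw"):
            raise ValueError(f"unknown size-model kind: {self.kind!r}")


def bead_radius_from_resolution(
    resolution_bp: float, density_bp_per_um3: float = DEFAULT_DENSITY_BP_PER_UM3
) -> float:
    """Radius (um) of a sphere holding ``resolution_bp`` of chromatin.

    The bead volume is resolution / density; at the typical chromatin
    density of 12 Mb/um^3 a 500 kb bead has radius ~0.215 um and a 50 kb
    bead ~0.100 um.
    """
    if resolution_bp <= 0 or density_bp_per_um3 <= 0:
        raise ValueError("resolution and density must be positive")
    volume = resolution_bp / density_bp_per_um3
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def _check_conformation(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("conformation must be an (N, 3) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("conformation contains non-finite coordinates")
    return X


def _bond_vectors(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vec = X[1:] - X[:-1]
    return vec, np.linalg.norm(vec, axis=1)


def backbone_energy(X: np.ndarray, a: float = 1.0) -> float:
    """Harmonic upper-limit restraint on consecutive-bead distances.

    E_bb = sum_i theta(d_{i,i+1} - a) (d_{i,i+1} - a)^2 ; distances at or
    below the bead diameter cost nothing.
    """
    X = _check_conformation(X)
    _, d = _bond_vectors(X)
    excess = np.maximum(d - a, 0.0)
    return float(np.sum(excess**2))


def backbone_gradient(X: np.ndarray, a: float = 1.0) -> np.ndarray:
    X = _check_conformation(X)
    vec, d = _bond_vectors(X)
    excess = np.maximum(d - a, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(d > 0, 2.0 * excess / np.where(d > 0, d, 1.0), 0.0)
    force = coef[:, None] * vec  # dE/d(x_{i+1})
    grad = np.zeros_like(X)
    np.add.at(grad, np.arange(1, len(X)), force)
    np.subtract.at(grad, np.arange(0, len(X) - 1), force)
    return grad


def _pair_distances(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs displacement tensor and distance matrix (diagonal zero)."""
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    return diff, d


def quartic_repulsion_energy(X: np.ndarray, a: float = 1.0) -> float:
    """Soft excluded volume: sum_{i<j} theta(a - d_ij) (a - d_ij)^4."""
    X = _check_conformation(X)
    _, d = _pair_distances(X)
    overlap = np.maximum(a - d, 0.0)
    np.fill_diagonal(overlap, 0.0)
    return float(np.sum(np.triu(overlap**4, k=1)))


def quartic_repulsion_gradient(X: np.ndarray, a: float = 1.0) -> np.ndarray:
    X = _check_conformation(X)
    diff, d = _pair_distances(X)
    overlap = np.maximum(a - d, 0.0)
    np.fill_diagonal(overlap, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(d > 0, -4.0 * overlap**3 / np.where(d > 0, d, 1.0), 0.0)
    # dE/dx_i = sum_j coef_ij * (x_i - x_j)
    return np.einsum("ij,ijk->ik", coef, diff)


def _lj_branch_constants(s: float, l: float) -> tuple[float, float, float]:
    """Constants of the linear core and tail of the piecewise LJ potential."""
    core_slope = -12.0 * (1.0 - s**6) / s**13
    core_offset = (13.0 - 14.0 * s**6) / s**12
    tail_value = (1.0 - 2.0 * l**6) / l**12  # LJ value at d = l*a
    return core_offset, core_slope, tail_value


def lennard_jones_energy(
    X: np.ndarray,
    a: float = 1.0,
    s: float = 0.6,
    l: float = 1.25,
    d_cut: float | None = None,
) -> float:
    """Piecewise 12-6 Lennard-Jones with linear core and linear tail.

    Per pair, with x = d/a: linear core for x < s (continuing the LJ value
    and slope at s), plain ``x**-12 - 2 x**-6`` for s < x <= l, a linear
    ramp from the LJ value at l down to zero at d_cut, and zero beyond.
    The minimum is -1 at ``d = a``.
    """
    X = _check_conformation(X)
    if d_cut is None:
        d_cut = 1.375 * a
    _, d = _pair_distances(X)
    iu = np.triu_indices(len(X), k=1)
    return float(np.sum(_lj_pair_energy(d[iu], a, s, l, d_cut)))


def _lj_pair_energy(d: np.ndarray, a: float, s: float, l: float, d_cut: float) -> np.ndarray:
    x = d / a
    core_offset, core_slope, tail_value = _lj_branch_constants(s, l)
    out = np.zeros_like(x)
    core = x < s
    mid = (x >= s) & (x <= l)
    tail = (x > l) & (d <= d_cut)
    out[core] = core_offset + core_slope * x[core]
    xm = np.maximum(x[mid], 1e-300)
    out[mid] = xm**-12 - 2.0 * xm**-6
    out[tail] = tail_value * (d_cut - d[tail]) / (d_cut - l * a)
    return out


def _lj_pair_dEdd(d: np.ndarray, a: float, s: float, l: float, d_cut: float) -> np.ndarray:
    x = d / a
    _, core_slope, tail_value = _lj_branch_constants(s, l)
    out = np.zeros_like(x)
    core = x < s
    mid = (x >= s) & (x <= l)
    tail = (x > l) & (d <= d_cut)
    out[core] = core_slope / a
    xm = np.maximum(x[mid], 1e-300)
    out[mid] = (-12.0 * xm**-13 + 12.0 * xm**-7) / a
    out[tail] = -tail_value / (d_cut - l * a)
    return out


def lennard_jones_gradient(
    X: np.ndarray,
    a: float = 1.0,
    s: float = 0.6,
    l: float = 1.25,
    d_cut: float | None = None,
) -> np.ndarray:
    X = _check_conformation(X)
    if d_cut is None:
        d_cut = 1.375 * a
    diff, d = _pair_distances(X)
    mask = ~np.eye(len(X), dtype=bool)
    dEdd = np.zeros_like(d)
    dEdd[mask] = _lj_pair_dEdd(d[mask], a, s, l, d_cut)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(mask & (d > 0), dEdd / np.where(d > 0, d, 1.0), 0.0)
    return np.einsum("ij,ijk->ik", coef, diff)


def nonbonded_energy(X: np.ndarray, spec: PolymerSpec) -> float:
    """Excluded-volume energy selected by ``spec.ev_kind`` (unweighted)."""
    a = spec.bead_diameter
    if spec.ev_kind == "quartic_repulsion":
        return quartic_repulsion_energy(X, a)
    return lennard_jones_energy(X, a, spec.lj_s, spec.lj_l, spec.lj_dcut)


def _nonbonded_weight(spec: PolymerSpec) -> float:
    # The quartic term carries k_nb = 5/a^4; the LJ term has unit weight.
    return spec.k_nb if spec.ev_kind == "quartic_repulsion" else 1.0


def prior_log_density(X: np.ndarray, spec: PolymerSpec) -> float:
    """log Pr(X | I) up to an additive constant: -k_nb E_nb - k_bb E_bb."""
    X = _check_conformation(X)
    if len(X) != spec.n_beads:
        raise ValueError("conformation length does not match spec.n_beads")
    a = spec.bead_diameter
    return float(
        -_nonbonded_weight(spec) * nonbonded_energy(X, spec)
        - spec.k_bb * backbone_energy(X, a)
    )


def prior_gradient(X: np.ndarray, spec: PolymerSpec) -> np.ndarray:
    """Gradient of :func:`prior_log_density` with respect to bead positions."""
    X = _check_conformation(X)
    a = spec.bead_diameter
    if spec.ev_kind == "quartic_repulsion":
        g_nb = quartic_repulsion_gradient(X, a)
    else:
        g_nb = lennard_jones_gradient(X, a, spec.lj_s, spec.lj_l, spec.lj_dcut)
    return -_nonbonded_weight(spec) * g_nb - spec.k_bb * backbone_gradient(X, a)


def radius_of_gyration(X: np.ndarray) -> float:
    """RMS distance of the beads from their center of mass."""
    X = _check_conformation(X)
    centered = X - X.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def radius_of_gyration_gradient(X: np.ndarray) -> np.ndarray:
    """d R_g / d x_n = (x_n - xbar) / (N * R_g); zero for a collapsed chain."""
    X = _check_conformation(X)
    centered = X - X.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
    if rg == 0.0:
        return np.zeros_like(X)
    return centered / (len(X) * rg)


# ---------------------------------------------------------------------------
# fused energy/gradient kernels (numba-accelerated when available)
# ---------------------------------------------------------------------------
# The samplers evaluate the prior and its gradient once per leapfrog step,
# so the O(N^2) pair loop dominates the run time.  The jitted kernels below
# are required to agree with the vectorized reference implementations above
# to floating-point tolerance (asserted in the test suite).

try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@_njit(fastmath=False)
def _bb_energy_grad(X: np.ndarray, a: float):
    n = X.shape[0]
    e = 0.0
    grad = np.zeros_like(X)
    for i in range(n - 1):
        dx = X[i + 1, 0] - X[i, 0]
        dy = X[i + 1, 1] - X[i, 1]
        dz = X[i + 1, 2] - X[i, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d > a:
            exc = d - a
            e += exc * exc
            c = 2.0 * exc / d
            grad[i + 1, 0] += c * dx
            grad[i + 1, 1] += c * dy
            grad[i + 1, 2] += c * dz
            grad[i, 0] -= c * dx
            grad[i, 1] -= c * dy
            grad[i, 2] -= c * dz
    return e, grad


@_njit(fastmath=False)
def _quartic_energy_grad(X: np.ndarray, a: float):
    n = X.shape[0]
    e = 0.0
    grad = np.zeros_like(X)
    for i in range(n):
        for j in range(i + 1, n):
            dx = X[i, 0] - X[j, 0]
            dy = X[i, 1] - X[j, 1]
            dz = X[i, 2] - X[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < a * a:
                d = d2**0.5
                if d > 0.0:
                    ov = a - d
                    ov3 = ov * ov * ov
                    e += ov3 * ov
                    c = -4.0 * ov3 / d
                    grad[i, 0] += c * dx
                    grad[i, 1] += c * dy
                    grad[i, 2] += c * dz
                    grad[j, 0] -= c * dx
                    grad[j, 1] -= c * dy
                    grad[j, 2] -= c * dz
                else:
                    e += a**4
    return e, grad


@_njit(fastmath=False)
def _lj_energy_grad(X: np.ndarray, a: float, s: float, l: float, d_cut: float):
    n = X.shape[0]
    e = 0.0
    grad = np.zeros_like(X)
    core_slope = -12.0 * (1.0 - s**6) / s**13
    core_offset = (13.0 - 14.0 * s**6) / s**12
    tail_value = (1.0 - 2.0 * l**6) / l**12
    for i in range(n):
        for j in range(i + 1, n):
            dx = X[i, 0] - X[j, 0]
            dy = X[i, 1] - X[j, 1]
            dz = X[i, 2] - X[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > d_cut * d_cut:
                continue
            d = d2**0.5
            x = d / a
            if x < s:
                e += core_offset + core_slope * x
                dEdd = core_slope / a
            elif x <= l:
                x6 = x**-6
                e += x6 * x6 - 2.0 * x6
                dEdd = (-12.0 * x**-13 + 12.0 * x**-7) / a
            else:
                e += tail_value * (d_cut - d) / (d_cut - l * a)
                dEdd = -tail_value / (d_cut - l * a)
            if d > 0.0:
                c = dEdd / d
                grad[i, 0] += c * dx
                grad[i, 1] += c * dy
                grad[i, 2] += c * dz
                grad[j, 0] -= c * dx
                grad[j, 1] -= c * dy
                grad[j, 2] -= c * dz
    return e, grad


def prior_logp_and_grad(X: np.ndarray, spec: PolymerSpec) -> tuple[float, np.ndarray]:
    """Fused (log prior, gradient) evaluation used by the samplers."""
    X = np.ascontiguousarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        return -np.inf, np.zeros_like(X)
    a = spec.bead_diameter
    e_bb, g_bb = _bb_energy_grad(X, a)
    if spec.ev_kind == "quartic_repulsion":
        e_nb, g_nb = _quartic_energy_grad(X, a)
        w = spec.k_nb
    else:
        e_nb, g_nb = _lj_energy_grad(X, a, spec.lj_s, spec.lj_l, spec.lj_dcut)
        w = 1.0
    logp = -w * e_nb - spec.k_bb * e_bb
    grad = -w * g_nb - spec.k_bb * g_bb
    return float(logp), grad


def chromosome_size(X: np.ndarray, size_model: SizeModel | None = None) -> float:
    """Chromosome-territory size predicted from the radius of gyration."""
    if size_model is None:
        size_model = SizeModel()
    rg = radius_of_gyration(X)
    return size_from_rg(rg, size_model)


def size_from_rg(rg: float, size_model: SizeModel | None = None) -> float:
    if size_model is None:
        size_model = SizeModel()
    if size_model.kind == "linear":
        return float(size_model.linear_factor * rg)
    c, p = size_model.powerlaw
    return float(c * rg**p)
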