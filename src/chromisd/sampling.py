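"""Posterior sampling: HMC, Gibbs sweeps and replica exchange.

Coordinates are sampled with Hamiltonian Monte Carlo (unit mass matrix,
250 leapfrog steps by default, timestep adapted toward 50% acceptance
during burn-in).  Nuisance parameters (distance scale gamma, error sigma)
are drawn from their conditional distributions inside a Gibbs sweep.  To
cross the barriers of the multimodal posterior, the Gibbs sampler is
embedded in a replica-exchange scheme over a family of tempered targets

    p_lambda(X, theta)  propto  Pr(D | X, theta)^lambda Pr(X) Pr(theta)

with lambda from ~0 (prior) to 1 (posterior).  The same machinery drives
the radius-of-gyration-biased prior exploration, where the tempered term
is -lambda * R_g(X) instead of the log-likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    PolymerSpec,
    SizeModel,
    prior_gradient,
    prior_log_density,
    prior_logp_and_grad,
    radius_of_gyration,
    radius_of_gyration_gradient,
)
from .likelihoods import (
    ContactData,
    FishData,
    NuisanceParams,
    DEFAULT_WEIGHT_PLATEAU,
    DEFAULT_WEIGHT_LOGNORMAL,
    diploid_logistic_gradient,
    diploid_logistic_log_likelihood,
    fish_gradient,
    fish_log_likelihood,
    gaussian_plateau_gradient,
    gaussian_plateau_log_likelihood,
    logistic_gradient,
    logistic_log_likelihood,
    lognormal_gradient,
    lognormal_log_likelihood,
)

logger = logging.getLogger("chromisd")

__all__ = [
    "HmcSettings",
    "ReplicaSchedule",
    "ChainState",
    "ISDModel",
    "hmc_step",
    "TimestepAdapter",
    "sample_gamma",
    "sample_weight",
    "gibbs_sweep",
    "replica_exchange_run",
    "rg_biased_prior_run",
    "extended_chain",
    "random_walk_chain",
    "geometric_lambdas",
]


@dataclass
class HmcSettings:
    """Knobs of the Hamiltonian Monte Carlo coordinate sampler."""

    n_leapfrog: int = 250
    timestep: float = 1e-3
    target_acceptance: float = 0.5
    adapt_gain: float = 1.0
    adapt_decay: float = 0.6

    def __post_init__(self) -> None:
        if self.n_leapfrog < 1 or self.timestep <= 0:
            raise ValueError("n_leapfrog >= 1 and timestep > 0 required")


@dataclass
class ReplicaSchedule:
    """Ordered tempering parameters, one per replica."""

    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.lambdas) < 1 or np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambdas must be strictly increasing, K >= 1")

    def __len__(self) -> int:
        return len(self.lambdas)


def geometric_lambdas(lam_min: float = 1e-4, lam_max: float = 1.0, K: int = 50) -> np.ndarray:
    """Geometrically spaced tempering schedule (default 1e-4 .. 1, K = 50)."""
    return np.geomspace(lam_min, lam_max, K)


@dataclass
class ChainState:
    """State of one replica: coordinates, nuisance values, cached energies."""

    X: np.ndarray
    X2: np.ndarray | None = None
    params: NuisanceParams = field(default_factory=NuisanceParams)
    log_prior: float = np.nan
    log_like: float = np.nan
    replica_index: int = 0

    def copy(self) -> "ChainState":
        return ChainState(
            self.X.copy(),
            None if self.X2 is None else self.X2.copy(),
            NuisanceParams(self.params.gamma, self.params.sigma),
            self.log_prior,
            self.log_like,
            self.replica_index,
        )


def extended_chain(n_beads: int, a: float = 1.0) -> np.ndarray:
    """Fully extended chain along x with consecutive beads at distance a."""
    X = np.zeros((n_beads, 3))
    X[:, 0] = np.arange(n_beads) * a
    return X


def random_walk_chain(
    n_beads: int, a: float = 1.0, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Freely-jointed chain with bond length a (random uniform directions).

    A useful initialization for prior-equilibrium studies: it starts the
    sampler near typical prior configurations instead of the fully extended
    state, which is ~10 standard deviations into the tail of R_g.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    steps = rng.standard_normal((n_beads - 1, 3))
    steps *= a / np.linalg.norm(steps, axis=1)[:, None]
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


class ISDModel:
    """Bundles prior, likelihood and nuisance handling for the samplers.

    ``likelihood`` is one of ``logistic``, ``gaussian_plateau``,
    ``lognormal`` or ``none`` (prior-only).  With ``rg_bias=True`` the
    tempered term is ``-R_g(X)`` (prior exploration); otherwise it is the
    data log-likelihood.  ``diploid=True`` samples two copies restrained by
    ambiguous r^-6-averaged distances (logistic model only); by default the
    copies do not share an excluded-volume term (separate territories) —
    set ``inter_copy_ev=True`` to enable inter-copy repulsion.
    """

    def __init__(
        self,
        spec: PolymerSpec,
        contacts: ContactData | None = None,
        likelihood: str = "logistic",
        diploid: bool = False,
        fish: FishData | None = None,
        size_model: SizeModel | None = None,
        length_unit_um: float = 1.0,
        rg_bias: bool = False,
        sample_gamma_flag: bool = False,
        sample_weight_flag: bool = False,
        inter_copy_ev: bool = False,
    ) -> None:
        if likelihood not in ("logistic", "gaussian_plateau", "lognormal", "none"):
            raise ValueError(f"unknown likelihood: {likelihood!r}")
        if rg_bias and likelihood != "none":
            raise ValueError("rg_bias applies to the prior-only model")
        if diploid and likelihood not in ("logistic", "none"):
            raise ValueError("diploid inference uses the logistic contact model")
        if likelihood != "none" and contacts is None:
            raise ValueError("contacts required for a data likelihood")
        self.spec = spec
        self.contacts = contacts
        self.likelihood = likelihood
        self.diploid = diploid
        self.fish = fish
        self.size_model = size_model
        self.length_unit_um = length_unit_um
        self.rg_bias = rg_bias
        self.sample_gamma_flag = sample_gamma_flag and likelihood in (
            "gaussian_plateau",
            "lognormal",
        )
        self.sample_weight_flag = sample_weight_flag and likelihood in (
            "gaussian_plateau",
            "lognormal",
        )
        self.inter_copy_ev = inter_copy_ev

    # -- nuisance defaults ------------------------------------------------
    def default_params(self) -> NuisanceParams:
        if self.likelihood == "gaussian_plateau":
            return NuisanceParams(1.0, DEFAULT_WEIGHT_PLATEAU**-0.5)
        if self.likelihood == "lognormal":
            return NuisanceParams(1.0, DEFAULT_WEIGHT_LOGNORMAL**-0.5)
        return NuisanceParams(1.0, 0.1)

    def initial_state(self) -> ChainState:
        X = extended_chain(self.spec.n_beads, self.spec.bead_diameter)
        X2 = None
        if self.diploid:
            X2 = X.copy()
            X2[:, 1] += 2.0 * self.spec.bead_diameter
        state = ChainState(X, X2, self.default_params())
        state.log_prior = self.log_prior(X, X2)
        state.log_like = self.log_tempered_term(X, X2, state.params)
        return state

    # -- densities ---------------------------------------------------------
    def log_prior(self, X: np.ndarray, X2: np.ndarray | None = None) -> float:
        lp = prior_log_density(X, self.spec)
        if X2 is not None:
            lp += prior_log_density(X2, self.spec)
            if self.inter_copy_ev:
                lp += self._inter_copy_log_prior(X, X2)
        return lp

    def _inter_copy_log_prior(self, X: np.ndarray, X2: np.ndarray) -> float:
        from .model import _lj_pair_energy  # quartic cross term kept simple

        a = self.spec.bead_diameter
        d = np.linalg.norm(X[:, None, :] - X2[None, :, :], axis=-1)
        if self.spec.ev_kind == "quartic_repulsion":
            overlap = np.maximum(a - d, 0.0)
            return float(-self.spec.k_nb * np.sum(overlap**4))
        return float(
            -np.sum(_lj_pair_energy(d.ravel(), a, self.spec.lj_s, self.spec.lj_l, self.spec.lj_dcut))
        )

    def prior_grad(
        self, X: np.ndarray, X2: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        g1 = prior_gradient(X, self.spec)
        if X2 is None:
            return g1, None
        g2 = prior_gradient(X2, self.spec)
        if self.inter_copy_ev:
            g1c, g2c = self._inter_copy_grad(X, X2)
            g1 = g1 + g1c
            g2 = g2 + g2c
        return g1, g2

    def _inter_copy_grad(self, X: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from .model import _lj_pair_dEdd

        a = self.spec.bead_diameter
        diff = X[:, None, :] - X2[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        d_safe = np.where(d > 0, d, 1.0)
        if self.spec.ev_kind == "quartic_repulsion":
            overlap = np.maximum(a - d, 0.0)
            dEdd = -4.0 * overlap**3
            coef = self.spec.k_nb * dEdd / d_safe
        else:
            coef = _lj_pair_dEdd(d.ravel(), a, self.spec.lj_s, self.spec.lj_l, self.spec.lj_dcut)
            coef = coef.reshape(d.shape) / d_safe
        g1 = -np.einsum("ij,ijk->ik", coef, diff)
        g2 = np.einsum("ij,ijk->ik", coef, diff)
        return g1, g2

    def log_tempered_term(
        self, X: np.ndarray, X2: np.ndarray | None, params: NuisanceParams
    ) -> float:
        """Value of the term that gets multiplied by lambda."""
        if self.rg_bias:
            return -radius_of_gyration(X)
        if self.likelihood == "none":
            return 0.0
        spec = self.spec
        if self.diploid:
            ll = diploid_logistic_log_likelihood(
                X, X2, self.contacts, spec.logistic_steepness, spec.contact_cutoff
            )
        elif self.likelihood == "logistic":
            ll = logistic_log_likelihood(
                X, self.contacts, spec.logistic_steepness, spec.contact_cutoff
            )
        elif self.likelihood == "gaussian_plateau":
            ll = gaussian_plateau_log_likelihood(
                X, self.contacts, params.gamma, params.sigma, spec.bead_diameter
            )
        else:
            ll = lognormal_log_likelihood(
                X, self.contacts, params.gamma, params.sigma, spec.bead_diameter
            )
        if self.fish is not None:
            ll += fish_log_likelihood(X, self.fish, self.size_model, self.length_unit_um)
            if X2 is not None:
                ll += fish_log_likelihood(X2, self.fish, self.size_model, self.length_unit_um)
        return ll

    def tempered_grad(
        self, X: np.ndarray, X2: np.ndarray | None, params: NuisanceParams
    ) -> tuple[np.ndarray, np.ndarray | None]:
        if self.rg_bias:
            return -radius_of_gyration_gradient(X), None
        if self.likelihood == "none":
            return np.zeros_like(X), None if X2 is None else np.zeros_like(X2)
        spec = self.spec
        g2 = None
        if self.diploid:
            g1, g2 = diploid_logistic_gradient(
                X, X2, self.contacts, spec.logistic_steepness, spec.contact_cutoff
            )
        elif self.likelihood == "logistic":
            g1 = logistic_gradient(
                X, self.contacts, spec.logistic_steepness, spec.contact_cutoff
            )
        elif self.likelihood == "gaussian_plateau":
            g1 = gaussian_plateau_gradient(
                X, self.contacts, params.gamma, params.sigma, spec.bead_diameter
            )
        else:
            g1 = lognormal_gradient(
                X, self.contacts, params.gamma, params.sigma, spec.bead_diameter
            )
        if self.fish is not None:
            g1 = g1 + fish_gradient(X, self.fish, self.size_model, self.length_unit_um)
            if X2 is not None:
                g2 = g2 + fish_gradient(X2, self.fish, self.size_model, self.length_unit_um)
        return g1, g2

    # -- flat-coordinate interface for HMC ---------------------------------
    def pack(self, X: np.ndarray, X2: np.ndarray | None) -> np.ndarray:
        return X.ravel() if X2 is None else np.concatenate([X.ravel(), X2.ravel()])

    def unpack(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        n = self.spec.n_beads
        if self.diploid:
            return q[: 3 * n].reshape(n, 3), q[3 * n :].reshape(n, 3)
        return q.reshape(n, 3), None

    def logp_and_grad(self, lam: float, params: NuisanceParams):
        """(log density, gradient) of coordinates at tempering lambda."""

        def fn(q: np.ndarray) -> tuple[float, np.ndarray]:
            X, X2 = self.unpack(q)
            lp1, gp1 = prior_logp_and_grad(X, self.spec)
            lp = lp1
            gp2 = None
            if X2 is not None:
                lp2, gp2 = prior_logp_and_grad(X2, self.spec)
                lp += lp2
                if self.inter_copy_ev:
                    lp += self._inter_copy_log_prior(X, X2)
                    g1c, g2c = self._inter_copy_grad(X, X2)
                    gp1 = gp1 + g1c
                    gp2 = gp2 + g2c
            if not np.isfinite(lp):
                return -np.inf, np.zeros_like(q)
            lp += lam * self.log_tempered_term(X, X2, params)
            gl1, gl2 = self.tempered_grad(X, X2, params)
            g1 = gp1 + lam * gl1
            if X2 is None:
                return lp, g1.ravel()
            g2 = gp2 + lam * (gl2 if gl2 is not None else 0.0)
            return lp, np.concatenate([g1.ravel(), g2.ravel()])

        return fn


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

def hmc_step(
    q: np.ndarray,
    logp_and_grad,
    timestep: float,
    n_leapfrog: int,
    rng: np.random.Generator,
    logp: float | None = None,
    grad: np.ndarray | None = None,
):
    """One HMC transition with unit masses and a leapfrog trajectory.

    Returns ``(q, logp, grad, accepted)``; the position is unchanged on
    rejection.  Non-finite trajectory energies reject automatically.
    """
    if logp is None or grad is None:
        logp, grad = logp_and_grad(q)
    p = rng.standard_normal(q.shape)
    h0 = -logp + 0.5 * np.dot(p, p)

    q_new, g = q.copy(), grad
    p = p + 0.5 * timestep * g
    ok = True
    lp_new = logp
    for step in range(n_leapfrog):
        q_new = q_new + timestep * p
        lp_new, g = logp_and_grad(q_new)
        if not np.all(np.isfinite(g)) or not np.isfinite(lp_new):
            ok = False
            break
        p = p + (timestep if step < n_leapfrog - 1 else 0.5 * timestep) * g
    if ok:
        h1 = -lp_new + 0.5 * np.dot(p, p)
        if np.isfinite(h1) and np.log(rng.uniform()) < h0 - h1:
            return q_new, lp_new, g, True
    else:
        logger.warning("non-finite energy in leapfrog trajectory; proposal rejected")
    return q, logp, grad, False


class TimestepAdapter:
    """Robbins-Monro adaptation of log-timestep toward a target acceptance.

    Updates are applied only during burn-in; afterwards the timestep is
    frozen at its current value.
    """

    def __init__(self, settings: HmcSettings, n_burnin: int):
        self.log_eps = float(np.log(settings.timestep))
        self.target = settings.target_acceptance
        self.gain = settings.adapt_gain
        self.decay = settings.adapt_decay
        self.n_burnin = n_burnin
        self.t = 0

    @property
    def timestep(self) -> float:
        return float(np.exp(self.log_eps))

    def update(self, accepted: bool) -> float:
        if self.t < self.n_burnin:
            eta = self.gain / (1.0 + self.t) ** self.decay
            self.log_eps += eta * ((1.0 if accepted else 0.0) - self.target)
        self.t += 1
        return self.timestep


# ---------------------------------------------------------------------------
# conditional samplers for nuisance parameters
# ---------------------------------------------------------------------------

def sample_gamma(
    model_kind: str,
    distances: np.ndarray,
    counts: np.ndarray,
    sigma: float,
    a: float,
    rng: np.random.Generator,
    gamma_current: float = 1.0,
    lam: float = 1.0,
    n_mh_steps: int = 10,
    mh_step: float = 0.05,
) -> float:
    """Draw the distance scale gamma from its conditional posterior.

    Jeffreys prior (flat in log gamma).  For the lognormal error model the
    conditional of log gamma is Gaussian and drawn exactly; for the plateau
    model a Metropolis random walk on log gamma is used.
    """
    distances = np.asarray(distances, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n_tot = counts.sum()
    if n_tot < 1:
        raise ValueError("need at least one restrained distance")
    if model_kind == "lognormal":
        logr = np.log(a / distances)
        mean = float(np.sum(counts * logr) / n_tot)
        sd = sigma / np.sqrt(lam * n_tot)
        return float(np.exp(rng.normal(mean, sd)))
    if model_kind != "gaussian_plateau":
        raise ValueError(f"no gamma sampler for model {model_kind!r}")

    def loglik(gamma: float) -> float:
        from .likelihoods import _plateau_residual

        res = _plateau_residual(gamma * distances, a)
        return float(-lam * np.sum(counts * res**2) / (2.0 * sigma**2))

    lg = np.log(gamma_current)
    ll = loglik(np.exp(lg))
    for _ in range(n_mh_steps):
        lg_prop = lg + mh_step * rng.standard_normal()
        ll_prop = loglik(np.exp(lg_prop))
        if np.log(rng.uniform()) < ll_prop - ll:
            lg, ll = lg_prop, ll_prop
    return float(np.exp(lg))


def sample_weight(
    model_kind: str,
    residuals: np.ndarray,
    counts: np.ndarray,
    a: float,
    rng: np.random.Generator,
    sigma_current: float = 0.1,
    lam: float = 1.0,
    n_mh_steps: int = 10,
    mh_step: float = 0.1,
) -> tuple[float, float]:
    """Draw (sigma, w = sigma^-2) from the conditional posterior.

    Lognormal model: w is Gamma with shape lam*n/2 (Jeffreys prior) and
    rate lam/2 * sum n_ij r_ij^2 of the squared log-residuals.  Plateau
    model: Metropolis random walk on log sigma (the plateau normalizer
    depends on sigma, so no conjugate form exists).
    """
    residuals = np.asarray(residuals, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n_tot = counts.sum()
    if model_kind == "lognormal":
        rate = 0.5 * lam * float(np.sum(counts * residuals**2))
        if rate <= 0.0:
            warnings.warn("all residuals zero; keeping current weight")
            return sigma_current, 1.0 / sigma_current**2
        w = rng.gamma(shape=0.5 * lam * n_tot, scale=1.0 / rate)
        return float(w**-0.5), float(w)
    if model_kind != "gaussian_plateau":
        raise ValueError(f"no weight sampler for model {model_kind!r}")

    def loglik(sigma: float) -> float:
        return float(
            -lam * n_tot * np.log(np.sqrt(2.0 * np.pi) * sigma + 0.4 * a)
            - lam * np.sum(counts * residuals**2) / (2.0 * sigma**2)
        )

    ls = np.log(sigma_current)
    ll = loglik(np.exp(ls))
    for _ in range(n_mh_steps):
        ls_prop = ls + mh_step * rng.standard_normal()
        ll_prop = loglik(np.exp(ls_prop))
        if np.log(rng.uniform()) < ll_prop - ll:
            ls, ll = ls_prop, ll_prop
    sigma = float(np.exp(ls))
    return sigma, 1.0 / sigma**2


def gibbs_sweep(
    state: ChainState,
    model: ISDModel,
    settings: HmcSettings,
    rng: np.random.Generator,
    lam: float = 1.0,
    timestep: float | None = None,
) -> tuple[ChainState, bool]:
    """One Gibbs cycle: HMC block for coordinates, then nuisance draws."""
    eps = settings.timestep if timestep is None else timestep
    fn = model.logp_and_grad(lam, state.params)
    q = model.pack(state.X, state.X2)
    q, _, _, accepted = hmc_step(q, fn, eps, settings.n_leapfrog, rng)
    X, X2 = model.unpack(q)
    state.X, state.X2 = X, X2

    if model.sample_gamma_flag or model.sample_weight_flag:
        d = model.contacts.distances(X)
        counts = model.contacts.counts
        a = model.spec.bead_diameter
        if model.sample_gamma_flag:
            state.params.gamma = sample_gamma(
                model.likelihood, d, counts, state.params.sigma, a, rng,
                gamma_current=state.params.gamma, lam=lam,
            )
        if model.sample_weight_flag:
            if model.likelihood == "lognormal":
                residuals = np.log(a / (state.params.gamma * d))
            else:
                from .likelihoods import _plateau_residual

                residuals = _plateau_residual(state.params.gamma * d, a)
            state.params.sigma, _ = sample_weight(
                model.likelihood, residuals, counts, a, rng,
                sigma_current=state.params.sigma, lam=lam,
            )
    state.log_prior = model.log_prior(state.X, state.X2)
    state.log_like = model.log_tempered_term(state.X, state.X2, state.params)
    return state, accepted


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

@dataclass
class ReplicaRunResult:
    """Sample streams and diagnostics of a replica-exchange run."""

    lambdas: np.ndarray
    log_like: np.ndarray  # (K, T) tempered-term values per transition
    log_prior: np.ndarray  # (K, T)
    positions: np.ndarray | None  # (T, N, 3) posterior-replica draws
    positions2: np.ndarray | None
    all_positions: list | None  # per-replica (T, N, 3) when requested
    gammas: np.ndarray  # (K, T)
    sigmas: np.ndarray  # (K, T)
    swap_acceptance: np.ndarray  # (K-1,) per adjacent pair
    hmc_acceptance: np.ndarray  # (K,)
    timesteps: np.ndarray  # (K,) final adapted timesteps
    n_burnin: int

    @property
    def posterior_positions(self) -> np.ndarray:
        """Draws of the lambda = 1 (or largest-lambda) replica, post burn-in."""
        return self.positions[self.n_burnin:]

    @property
    def posterior_positions2(self) -> np.ndarray:
        return self.positions2[self.n_burnin:]


def replica_exchange_run(
    model: ISDModel,
    schedule: ReplicaSchedule,
    n_transitions: int,
    hmc_steps_per_transition: int = 10,
    settings: HmcSettings | None = None,
    rng: np.random.Generator | int | None = None,
    burnin_fraction: float = 0.1,
    n_burnin: int | None = None,
    save_all_positions: bool = False,
    initial_states: list[ChainState] | None = None,
) -> ReplicaRunResult:
    """Run K tempered Gibbs samplers with even/odd adjacent swap proposals.

    Every transition consists of ``hmc_steps_per_transition`` Gibbs sweeps
    per replica followed by one round of Metropolis swap proposals on
    adjacent pairs (even pairs on even transitions, odd pairs on odd ones).
    Timesteps adapt per replica toward 50% acceptance during burn-in.
    K = 1 degrades to plain HMC/Gibbs sampling.
    """
    if settings is None:
        settings = HmcSettings()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    K = len(schedule)
    if n_burnin is None:
        n_burnin = max(1, int(burnin_fraction * n_transitions))
    # deterministic per-replica streams, independent of execution order
    seeds = rng.integers(0, 2**31 - 1, size=K + 1)
    rngs = [np.random.default_rng(int(s)) for s in seeds[:K]]
    swap_rng = np.random.default_rng(int(seeds[K]))

    if initial_states is None:
        states = [model.initial_state() for _ in range(K)]
    else:
        states = [s.copy() for s in initial_states]
    for k, s in enumerate(states):
        s.replica_index = k
    adapters = [TimestepAdapter(settings, n_burnin * hmc_steps_per_transition) for _ in range(K)]

    n = model.spec.n_beads
    log_like = np.zeros((K, n_transitions))
    log_prior_arr = np.zeros((K, n_transitions))
    gammas = np.zeros((K, n_transitions))
    sigmas = np.zeros((K, n_transitions))
    positions = np.zeros((n_transitions, n, 3))
    positions2 = np.zeros((n_transitions, n, 3)) if model.diploid else None
    all_positions = [np.zeros((n_transitions, n, 3)) for _ in range(K)] if save_all_positions else None
    swap_att = np.zeros(max(K - 1, 1))
    swap_acc = np.zeros(max(K - 1, 1))
    hmc_acc = np.zeros(K)

    for t in range(n_transitions):
        for k in range(K):
            lam = schedule.lambdas[k]
            for _ in range(hmc_steps_per_transition):
                states[k], accepted = gibbs_sweep(
                    states[k], model, settings, rngs[k], lam=lam,
                    timestep=adapters[k].timestep,
                )
                adapters[k].update(accepted)
                hmc_acc[k] += accepted
        # even/odd alternating adjacent swaps on the tempered term
        for k in range(t % 2, K - 1, 2):
            swap_att[k] += 1
            dlam = schedule.lambdas[k] - schedule.lambdas[k + 1]
            delta = dlam * (states[k + 1].log_like - states[k].log_like)
            if np.log(swap_rng.uniform()) < delta:
                states[k], states[k + 1] = states[k + 1], states[k]
                swap_acc[k] += 1
        for k in range(K):
            log_like[k, t] = states[k].log_like
            log_prior_arr[k, t] = states[k].log_prior
            gammas[k, t] = states[k].params.gamma
            sigmas[k, t] = states[k].params.sigma
            if save_all_positions:
                all_positions[k][t] = states[k].X
        positions[t] = states[K - 1].X
        if model.diploid:
            positions2[t] = states[K - 1].X2

    with np.errstate(invalid="ignore"):
        swap_rate = np.where(swap_att > 0, swap_acc / np.maximum(swap_att, 1), np.nan)
    return ReplicaRunResult(
        lambdas=schedule.lambdas.copy(),
        log_like=log_like,
        log_prior=log_prior_arr,
        positions=positions,
        positions2=positions2,
        all_positions=all_positions,
        gammas=gammas,
        sigmas=sigmas,
        swap_acceptance=swap_rate,
        hmc_acceptance=hmc_acc / (n_transitions * hmc_steps_per_transition),
        timesteps=np.array([ad.timestep for ad in adapters]),
        n_burnin=n_burnin,
    )


def rg_biased_prior_run(
    spec: PolymerSpec,
    bias_lambdas: np.ndarray | None = None,
    n_transitions: int = 200,
    hmc_steps_per_transition: int = 10,
    settings: HmcSettings | None = None,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> tuple[ReplicaRunResult, np.ndarray]:
    """Replica exchange over exp(-lambda R_g - k_bb E_bb - k_nb E_nb).

    ``bias_lambdas`` defaults to 64 values spanning 0..500.  Returns the run
    plus the (K, T) array of sampled R_g values (the negated tempered term),
    ready for density-of-states estimation.
    """
    if bias_lambdas is None:
        bias_lambdas = np.concatenate([[0.0], np.geomspace(0.5, 500.0, 63)])
    bias_lambdas = np.asarray(bias_lambdas, dtype=float)
    if bias_lambdas[0] == 0.0:
        # shift zero slightly off to keep the schedule strictly increasing
        lams = bias_lambdas.copy()
    else:
        lams = bias_lambdas
    model = ISDModel(spec, likelihood="none", rg_bias=True)
    schedule = ReplicaSchedule(lams)
    run = replica_exchange_run(
        model,
        schedule,
        n_transitions,
        hmc_steps_per_transition,
        settings,
        rng,
        save_all_positions=False,
        **kwargs,
    )
    rg_values = -run.log_like  # tempered term is -R_g
    return run, rg_values
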