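"""Likelihood-free inference of the colony growth parameters.

The five growth parameters ``theta = (n*, p_a, p_sp, p_ps, gamma)`` enter
the model only through the stochastic simulator, so the likelihood is
intractable.  We sample an approximate posterior with ABC-MCMC: a
Metropolis-Hastings chain whose acceptance probability replaces the
likelihood ratio with an indicator that the simulated colony's summary
statistics lie within a tolerance ``epsilon`` of the observed ones,

    alpha = min{1, pi(theta*) / pi(theta_i) * 1[rho(S(x), S_bar) <= eps]},

with a symmetric multivariate Gaussian proposal (whose densities cancel).
``S`` is the normalised statistic vector (I_B, I_F, I_R): each statistic
is min-max scaled against the vector of replicate observations so the
three contribute comparably, and ``S_bar`` is the normalised replicate
mean.  The distance is the normalised Euclidean metric

    rho(S, S_bar) = (1/3) * sqrt(sum_i ((S_i - S_bar_i) / (1 + S_bar_i))^2).

Priors are independent Beta distributions on [0, 1] for each parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .morphometry import SummaryStats, summarise
from .simulate import ColonyStallError, SimParams, rasterise_ellipses

__all__ = [
    "ReplicateStats",
    "Chain",
    "AbcMcmc",
    "DEFAULT_PRIORS",
    "normalise_stats",
    "reference_stats",
    "distance",
    "prior_log_density",
    "abc_mh_step",
    "run_abc",
    "effective_sample_size",
]

PARAM_NAMES = ("n_star", "p_a", "p_sp", "p_ps", "gamma")

#: Default Beta(shape1, shape2) priors in theta order (n*, p_a, p_sp,
#: p_ps, gamma): weakly informative for n* (expected large), p_a and
#: gamma (expected small); uninformative for p_sp and p_ps.
DEFAULT_PRIORS = ((5.0, 2.0), (2.0, 5.0), (2.0, 2.0), (2.0, 2.0), (2.0, 5.0))


@dataclass
class ReplicateStats:
    """Summary-statistic vectors over the replicates of one condition.

    These vectors define the min-max normalisation basis for both the
    observations and every simulated colony compared against them.
    """

    I_B_vec: np.ndarray
    I_F_vec: np.ndarray
    I_R_vec: np.ndarray

    def __post_init__(self) -> None:
        self.I_B_vec = np.asarray(self.I_B_vec, dtype=float)
        self.I_F_vec = np.asarray(self.I_F_vec, dtype=float)
        self.I_R_vec = np.asarray(self.I_R_vec, dtype=float)
        n = len(self.I_B_vec)
        if n < 2 or len(self.I_F_vec) != n or len(self.I_R_vec) != n:
            raise ValueError("need >= 2 replicates with equal-length vectors")
        if (self.maxs - self.mins <= 0).any():
            raise ValueError(
                "degenerate replicate statistics: max == min for some "
                "statistic, min-max normalisation undefined"
            )

    @classmethod
    def from_summaries(cls, summaries: "list[SummaryStats]") -> "ReplicateStats":
        arr = np.array([s.as_vector() for s in summaries])
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])

    @classmethod
    def from_array(cls, raw: np.ndarray) -> "ReplicateStats":
        """From an (n_rep, 3) array with columns (I_B, I_F, I_R)."""
        raw = np.asarray(raw, dtype=float)
        return cls(raw[:, 0], raw[:, 1], raw[:, 2])

    @property
    def n_rep(self) -> int:
        return len(self.I_B_vec)

    @property
    def _stack(self) -> np.ndarray:
        return np.stack([self.I_B_vec, self.I_F_vec, self.I_R_vec])

    @property
    def mins(self) -> np.ndarray:
        return self._stack.min(axis=1)

    @property
    def maxs(self) -> np.ndarray:
        return self._stack.max(axis=1)

    @property
    def means(self) -> np.ndarray:
        return self._stack.mean(axis=1)


def _as_raw_vector(raw) -> np.ndarray:
    if isinstance(raw, SummaryStats):
        return raw.as_vector()
    return np.asarray(raw, dtype=float)


def normalise_stats(raw, ref: ReplicateStats) -> np.ndarray:
    """Min-max scale a raw (I_B, I_F, I_R) triple against the replicates.

    Simulated colonies may fall slightly outside [0, 1]; that is expected
    and harmless.
    """
    return (_as_raw_vector(raw) - ref.mins) / (ref.maxs - ref.mins)


def reference_stats(ref: ReplicateStats) -> np.ndarray:
    """``S_bar``: the normalised replicate means."""
    return (ref.means - ref.mins) / (ref.maxs - ref.mins)


def distance(s_x, s_bar, prefactor: str = "third") -> float:
    """Normalised Euclidean distance between statistic vectors.

    ``prefactor="third"`` applies the printed form ``(1/3) sqrt(sum ...)``;
    ``"rms"`` gives the root-mean-square alternative ``sqrt(sum/3)`` for
    sensitivity checks.
    """
    s_x = np.asarray(s_x, dtype=float)
    s_bar = np.asarray(s_bar, dtype=float)
    q = float(np.sum(((s_x - s_bar) / (1.0 + s_bar)) ** 2))
    if prefactor == "third":
        return math.sqrt(q) / 3.0
    if prefactor == "rms":
        return math.sqrt(q / 3.0)
    raise ValueError(f"unknown prefactor {prefactor!r}")


def prior_log_density(theta, priors=DEFAULT_PRIORS) -> float:
    """Sum of independent Beta log densities; -inf outside (0, 1)^5."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) != len(priors):
        raise ValueError("theta and priors length mismatch")
    if ((theta <= 0.0) | (theta >= 1.0)).any():
        return -np.inf
    ab = np.asarray(priors, dtype=float)
    a, b = ab[:, 0], ab[:, 1]
    return float(
        np.sum(
            (a - 1) * np.log(theta)
            + (b - 1) * np.log1p(-theta)
            - special.betaln(a, b)
        )
    )


@dataclass
class Chain:
    """One ABC-MCMC trace."""

    samples: np.ndarray  # (chain_length, 5)
    accepted: np.ndarray  # bool per iteration
    distances: np.ndarray  # rho per proposal (nan where not simulated)
    chain_id: int = 0

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def ess(self) -> np.ndarray:
        return np.array(
            [effective_sample_size(self.samples[:, j]) for j in range(5)]
        )


def abc_mh_step(
    theta: np.ndarray,
    log_prior: float,
    simulate_distance,
    epsilon: float,
    proposal_chol: np.ndarray,
    rng: np.random.Generator,
    priors=DEFAULT_PRIORS,
):
    """One ABC Metropolis-Hastings step.

    ``simulate_distance(theta, rng) -> rho`` runs one colony simulation
    and returns its distance to the observed statistics; it is never
    called for proposals outside the prior support, nor when ``epsilon``
    is infinite (prior sampling short-circuit).  A simulator stall is
    treated as a rejection.

    Returns ``(theta_next, log_prior_next, accepted, rho)``; ``rho`` is
    nan when no simulation ran.
    """
    prop = theta + proposal_chol @ rng.standard_normal(len(theta))
    lp = prior_log_density(prop, priors)
    if not np.isfinite(lp):
        return theta, log_prior, False, np.nan
    rho = np.nan
    if not math.isinf(epsilon):
        try:
            rho = simulate_distance(prop, rng)
        except ColonyStallError as err:
            warnings.warn(f"simulator stall treated as rejection: {err}")
            return theta, log_prior, False, np.nan
        if rho > epsilon:
            return theta, log_prior, False, rho
    if math.log(rng.random()) < lp - log_prior:
        return prop, lp, True, rho
    return theta, log_prior, False, rho


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a scalar chain, ``M / (1 + 2 sum_k rho_k)``.

    Autocorrelations are summed using Geyer's initial-positive-sequence
    rule: consecutive lag pairs ``rho_{2k} + rho_{2k+1}`` are accumulated
    until the first non-positive pair.
    """
    x = np.asarray(x, dtype=float)
    m = len(x)
    if m < 10:
        raise ValueError("chain too short for an ESS estimate")
    x = x - x.mean()
    var = float(np.dot(x, x)) / m
    if var == 0.0:
        return 1.0
    # FFT autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * m)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:m].real / m
    rho = acov / var
    tau = 0.0
    for k in range(1, m - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0.0:
            break
        tau += pair
    ess = m / (1.0 + 2.0 * tau)
    return float(min(max(ess, 1.0), m))


class AbcMcmc:
    """ABC-MCMC sampler for the five colony growth parameters.

    Scikit-learn-style estimator: configure with hyperparameters, call
    :meth:`fit` on the observed replicate statistics, then read the
    fitted attributes (``samples_``, ``chains_``, ``acceptance_rate_``,
    ``ess_``, ...).

    Parameters
    ----------
    priors : tuple of (shape1, shape2)
        Independent Beta priors in theta order (n*, p_a, p_sp, p_ps,
        gamma).
    epsilon : float
        ABC tolerance.  ``np.inf`` short-circuits the simulator and the
        chain samples the prior; ``None`` requires :meth:`fit` with
        ``tune=True`` (the default) to choose it.
    chain_length, n_chains : int
        Iterations per chain, and number of independent chains whose
        samples are concatenated.
    proposal_cov : (5, 5) array or None
        Gaussian proposal covariance; estimated from a pilot chain when
        None.
    proposal_scale : float
        Multiplier applied to the pilot sample covariance (the usual
        optimal-scaling factor 2.38^2/5 by default).
    n_max : int
        Cell-count stopping rule for each simulated colony.
    target_area : float or None
        Area stopping rule (occupied pixels, matched to 5%); overrides
        counting when set.
    px_per_um : float
        Rasterisation resolution of simulated colonies.
    init_scale : float
        The chain starts at the prior mean plus Gaussian noise of this
        scale per coordinate.
    random_state : int
        Seed for all sampler and simulator randomness.
    """

    def __init__(
        self,
        priors=DEFAULT_PRIORS,
        epsilon: float | None = None,
        chain_length: int = 2000,
        n_chains: int = 3,
        proposal_cov=None,
        proposal_scale: float = 2.38**2 / 5,
        n_max: int = 1000,
        target_area: float | None = None,
        area_tol: float = 0.05,
        px_per_um: float = 1.0,
        domain: tuple[float, float] = (4000.0, 4000.0),
        engine: str = "auto",
        init_scale: float = 0.02,
        distance_prefactor: str = "third",
        random_state: int | None = None,
    ):
        self.priors = priors
        self.epsilon = epsilon
        self.chain_length = chain_length
        self.n_chains = n_chains
        self.proposal_cov = proposal_cov
        self.proposal_scale = proposal_scale
        self.n_max = n_max
        self.target_area = target_area
        self.area_tol = area_tol
        self.px_per_um = px_per_um
        self.domain = domain
        self.engine = engine
        self.init_scale = init_scale
        self.distance_prefactor = distance_prefactor
        self.random_state = random_state

    _param_names = (
        "priors", "epsilon", "chain_length", "n_chains", "proposal_cov",
        "proposal_scale", "n_max", "target_area", "area_tol", "px_per_um",
        "domain", "engine", "init_scale", "distance_prefactor",
        "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "AbcMcmc":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if len(self.priors) != 5 or any(
            a <= 0 or b <= 0 for a, b in self.priors
        ):
            raise ValueError("priors must be five Beta (shape1, shape2) pairs")
        if self.chain_length < 1 or self.n_chains < 1:
            raise ValueError("chain_length and n_chains must be >= 1")
        if self.epsilon is not None and not self.epsilon > 0:
            raise ValueError("epsilon must be positive (or None to tune)")

    def _prior_mean(self) -> np.ndarray:
        return np.array([a / (a + b) for a, b in self.priors])

    def _chol(self, cov) -> np.ndarray:
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (5, 5) or not np.allclose(cov, cov.T):
            raise ValueError("proposal_cov must be a symmetric 5x5 matrix")
        jitter = 1e-12
        for _ in range(8):
            try:
                return np.linalg.cholesky(cov + jitter * np.eye(5))
            except np.linalg.LinAlgError:
                jitter *= 100
        raise ValueError("proposal_cov is not positive definite")

    def _default_cov(self) -> np.ndarray:
        return np.diag(np.full(5, 0.05**2))

    def _ref(self, X) -> ReplicateStats:
        if isinstance(X, ReplicateStats):
            return X
        X = list(X)
        if X and isinstance(X[0], SummaryStats):
            return ReplicateStats.from_summaries(X)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 3:
            return ReplicateStats.from_array(arr)
        # fall back: a sequence of masks
        return ReplicateStats.from_summaries([summarise(m) for m in X])

    def _make_simulate_distance(self, ref: ReplicateStats, s_bar: np.ndarray):
        use_kernel = self.engine in ("auto", "numba")
        if use_kernel:
            from . import _kernel

        def simulate_distance(theta, rng: np.random.Generator) -> float:
            seed = int(rng.integers(2**31))
            params = SimParams(
                n_star=float(theta[0]), p_a=float(theta[1]),
                p_sp=float(theta[2]), p_ps=float(theta[3]),
                gamma=float(theta[4]), n_max=self.n_max,
                target_area=self.target_area, area_tol=self.area_tol,
                px_per_um=self.px_per_um, domain=self.domain, seed=seed,
            )
            if use_kernel:
                cx, cy, ct, st, a, b, _, _ = _kernel.grow_arrays(params)
                mask = rasterise_ellipses(cx, cy, ct, st, a, b, self.px_per_um)
            else:
                from .simulate import colony_to_mask, run_simulation

                mask = colony_to_mask(
                    run_simulation(params, engine="python"), self.px_per_um
                ).pixels
            s_x = normalise_stats(summarise(mask), ref)
            return distance(s_x, s_bar, prefactor=self.distance_prefactor)

        return simulate_distance

    def _run_chain(
        self, simulate_distance, epsilon, chol, rng, chain_id, length
    ) -> Chain:
        theta = np.clip(
            self._prior_mean() + self.init_scale * rng.standard_normal(5),
            1e-6, 1 - 1e-6,
        )
        lp = prior_log_density(theta, self.priors)
        samples = np.empty((length, 5))
        accepted = np.zeros(length, dtype=bool)
        distances = np.full(length, np.nan)
        for i in range(length):
            theta, lp, acc, rho = abc_mh_step(
                theta, lp, simulate_distance, epsilon, chol, rng, self.priors
            )
            samples[i] = theta
            accepted[i] = acc
            distances[i] = rho
        return Chain(samples, accepted, distances, chain_id)

    # ------------------------------------------------------------------
    def tune(
        self,
        X,
        pilot_iters: int = 300,
        n_warm_sims: int = 30,
        accept_band: tuple[float, float] = (0.05, 0.10),
        shrink: float = 0.75,
        max_rounds: int = 12,
    ) -> "AbcMcmc":
        """Choose the proposal covariance and tolerance from pilot runs.

        A warm-up of prior-predictive simulations sets a generous initial
        ``epsilon``; a pilot chain at that tolerance provides the sample
        covariance for the Gaussian proposal (scaled by
        ``proposal_scale``); ``epsilon`` is then shrunk geometrically
        until a short pilot chain accepts within ``accept_band``.  Sets
        ``proposal_cov`` and ``epsilon`` in place and records the pilot
        acceptance in ``tuning_report_``.
        """
        if pilot_iters < 100:
            raise ValueError("pilot_iters must be >= 100")
        self._validate()
        ref = self._ref(X)
        s_bar = reference_stats(ref)
        simulate_distance = self._make_simulate_distance(ref, s_bar)
        rng = np.random.default_rng(self.random_state)

        # Warm-up: distances of prior draws give the starting tolerance.
        rhos = []
        for _ in range(n_warm_sims):
            theta = np.array(
                [rng.beta(a, b) for a, b in self.priors]
            )
            try:
                rhos.append(simulate_distance(theta, rng))
            except ColonyStallError:
                continue
        if not rhos:
            raise RuntimeError("all warm-up simulations stalled")
        eps = float(np.quantile(rhos, 0.8))

        # Pilot chain at the loose tolerance -> proposal covariance.
        chol0 = self._chol(
            self.proposal_cov if self.proposal_cov is not None
            else self._default_cov()
        )
        pilot = self._run_chain(
            simulate_distance, eps, chol0, rng, chain_id=-1, length=pilot_iters
        )
        cov = np.cov(pilot.samples.T)
        if not np.all(np.isfinite(cov)) or np.trace(cov) < 1e-10:
            warnings.warn("degenerate pilot chain; keeping default proposal")
            cov = self._default_cov()
        else:
            cov = self.proposal_scale * cov + 1e-8 * np.eye(5)
        self.proposal_cov = cov
        chol = self._chol(cov)

        # Geometric tolerance decrease until acceptance is in band.
        lo, hi = accept_band
        history = []
        best = (eps, np.inf)
        for _ in range(max_rounds):
            pilot = self._run_chain(
                simulate_distance, eps, chol, rng, chain_id=-1,
                length=pilot_iters,
            )
            acc = pilot.acceptance_rate
            history.append((eps, acc))
            mid = 0.5 * (lo + hi)
            if abs(acc - mid) < best[1]:
                best = (eps, abs(acc - mid))
            if lo <= acc <= hi:
                break
            if acc > hi:
                eps *= shrink
            else:
                # overshot: step back part-way and stop shrinking further
                eps /= math.sqrt(shrink)
        else:
            warnings.warn(
                "tuning budget exhausted before acceptance reached "
                f"[{lo}, {hi}]; using best epsilon {best[0]:.4g}"
            )
            eps = best[0]
        self.epsilon = eps
        self.tuning_report_ = {
            "epsilon": eps,
            "history": history,
            "acceptance": history[-1][1],
        }
        return self

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "AbcMcmc":
        """Sample the approximate posterior given observed statistics.

        ``X`` may be a :class:`ReplicateStats`, an ``(n_rep, 3)`` array of
        raw ``(I_B, I_F, I_R)`` rows, a list of :class:`SummaryStats`, or
        a list of masks.  When ``epsilon`` is None, :meth:`tune` runs
        first.
        """
        self._validate()
        ref = self._ref(X)
        s_bar = reference_stats(ref)
        if self.epsilon is None:
            self.tune(ref)
        simulate_distance = self._make_simulate_distance(ref, s_bar)
        cov = (
            self.proposal_cov if self.proposal_cov is not None
            else self._default_cov()
        )
        chol = self._chol(cov)
        ss = np.random.SeedSequence(self.random_state)
        chains = []
        for cid, child in enumerate(ss.spawn(self.n_chains)):
            rng = np.random.default_rng(child)
            chains.append(
                self._run_chain(
                    simulate_distance, self.epsilon, chol, rng, cid,
                    self.chain_length,
                )
            )
        self.ref_ = ref
        self.s_bar_ = s_bar
        self.chains_ = chains
        self.samples_ = np.vstack([c.samples for c in chains])
        self.acceptance_rate_ = float(
            np.mean([c.acceptance_rate for c in chains])
        )
        self.ess_ = np.sum([c.ess() for c in chains], axis=0)
        self.posterior_mean_ = self.samples_.mean(axis=0)
        return self

    def credible_interval(self, level: float = 0.90) -> np.ndarray:
        """Central credible intervals, one (lo, hi) row per parameter."""
        if not hasattr(self, "samples_"):
            raise AttributeError("call fit() first")
        alpha = (1.0 - level) / 2.0
        return np.quantile(
            self.samples_, [alpha, 1.0 - alpha], axis=0
        ).T


def run_abc(X, **kwargs) -> AbcMcmc:
    """Convenience wrapper: fit an :class:`AbcMcmc` on observed statistics."""
    return AbcMcmc(**kwargs).fit(X)
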