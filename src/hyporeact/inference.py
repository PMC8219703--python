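"""Bayesian inference of transport parameters from breakthrough curves.

The sampler is a DREAM-style differential-evolution adaptive Metropolis
scheme: multiple chains evolve jointly, each proposal being the current
state plus a scaled difference of randomly chosen pairs of other chains,
restricted to a random parameter subspace (crossover), with occasional
unit-jump generations for mode switching and outlier-chain correction
during burn-in.

The likelihood treats residuals between observed and modelled porewater
concentrations as independent Gaussians.  By default a single homoscedastic
error scale sigma is integrated out analytically under a Jeffreys prior
(marginal likelihood ~ SSR^(-n/2)); alternatives are a fixed absolute scale,
or a heteroscedastic scale set by the relative measurement precision
(sigma_i = rel_sd * observed_i, matching how LC-MS/MS uncertainty behaves).  Left-censored
observations enter through their substituted values (LOQ / sqrt(2)),
mirroring how the measured data are prepared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .priors import (
    PARAM_NAMES,
    FlowpathGeometry,
    PriorSet,
    build_prior_set,
    flowpath_by_id,
)
from .transport import (
    BoundarySeries,
    PecletWarning,
    SpatialGrid,
    TransportParameters,
    TransportSolverError,
    solve_ade,
)

__all__ = [
    "LOQ_SUBSTITUTION_FACTOR",
    "ObservationSet",
    "DreamSettings",
    "ChainEnsemble",
    "PosteriorSummary",
    "TwoStageResult",
    "ConfigurationError",
    "log_posterior",
    "dream_sample",
    "gelman_rubin",
    "summarize_posterior",
    "two_stage_calibration",
    "TransportCurveFitter",
]

logger = logging.getLogger(__name__)

#: left-censored values are replaced by LOQ times this factor (= 2^-0.5)
LOQ_SUBSTITUTION_FACTOR = 2.0 ** -0.5

#: residual floor per observation so the noise-free limit stays finite
_SSR_FLOOR_PER_POINT = 1e-12 ** 2


class ConfigurationError(ValueError):
    """Invalid inference configuration (chain count, missing reference, ...)."""


@dataclass(frozen=True)
class ObservationSet:
    """LOQ-substituted porewater concentrations for one compound on one flowpath."""

    compound: str
    flowpath: str
    times: np.ndarray
    concentrations: np.ndarray
    loq: float = 0.0
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or t.size == 0:
            raise ValueError("times and concentrations must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("observation times must be sorted, unique and >= 0")
        if np.any(c <= 0):
            raise ValueError(
                "observed concentrations must be positive after LOQ substitution"
            )
        if self.loq < 0:
            raise ValueError("LOQ must be >= 0")
        flags = (np.zeros(t.size, dtype=bool) if self.censored is None
                 else np.asarray(self.censored, dtype=bool))
        if flags.shape != t.shape:
            raise ValueError("censored flags must align with observations")
        if flags.any():
            sub = self.loq * LOQ_SUBSTITUTION_FACTOR
            if not np.allclose(c[flags], sub, rtol=1e-6, atol=0.0):
                raise ValueError(
                    "censored observations must carry the substituted value LOQ/sqrt(2)"
                )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "censored", flags)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DreamSettings:
    """Sampler configuration.

    The defaults mirror the study-scale setup: 20 chains, 4004 generations
    with the first half discarded as burn-in, leaving 2002 retained samples
    per chain (40,040 pooled posterior draws).  Tests and quick looks run
    with fewer generations.
    """

    n_chains: int = 20
    n_generations: int = 4004
    burn_in: float = 0.5
    n_pairs_max: int = 3
    n_crossover: int = 3
    gamma_unit_prob: float = 0.1
    snooker_prob: float = 0.1
    jitter: float = 1e-6
    outlier_correction: bool = True
    #: fraction of the run over which the likelihood is annealed in
    #: (quadratic beta ramp 0 -> 1); confined to the first half of burn-in,
    #: so retained samples always target the exact posterior.  Annealing
    #: lets the chains contract gradually from the prior onto sharply
    #: peaked posteriors instead of having to hit them by chance.
    anneal_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ConfigurationError("need at least 2 chains")
        if not 0 <= self.burn_in < 1:
            raise ConfigurationError("burn_in must be a fraction in [0, 1)")
        if self.n_generations < 10:
            raise ConfigurationError("n_generations must be >= 10")

    @property
    def n_burn(self) -> int:
        return int(self.burn_in * self.n_generations)


@dataclass(frozen=True)
class ChainEnsemble:
    """Full multi-chain trajectories plus bookkeeping.

    ``params`` has shape (n_chains, n_generations + 1, n_params) including
    the initial states; post-burn-in samples form the posterior.
    """

    params: np.ndarray
    logp: np.ndarray
    n_burn: int
    param_names: tuple[str, ...]
    seed: int | None
    acceptance_rate: float
    n_outlier_resets: int = 0

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    def retained(self) -> np.ndarray:
        """Post-burn-in samples, shape (n_chains, n_kept, n_params)."""
        return self.params[:, self.n_burn + 1:, :]

    def pooled(self) -> np.ndarray:
        """Posterior draws pooled across chains, shape (n, n_params)."""
        r = self.retained()
        return r.reshape(-1, r.shape[-1])

    def pooled_param(self, name: str) -> np.ndarray:
        return self.pooled()[:, self.param_names.index(name)]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter median and quartiles of the pooled posterior."""

    median: dict[str, float]
    q25: dict[str, float]
    q75: dict[str, float]
    n_samples: int
    rhat: dict[str, float]
    acceptance_rate: float

    def iqr(self, name: str) -> float:
        return self.q75[name] - self.q25[name]

    def median_params(self) -> TransportParameters:
        return TransportParameters(**{n: self.median[n] for n in PARAM_NAMES})

    @property
    def converged(self) -> bool:
        finite = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(finite) and max(finite) < 1.2


class _LogPosterior:
    """Fast callable: parameter vector (sampler order) -> log posterior."""

    def __init__(self, obs: ObservationSet | None, priors: PriorSet,
                 boundary: BoundarySeries | None, grid: SpatialGrid,
                 sigma_mode: str = "jeffreys", sigma: float | None = None):
        if sigma_mode not in ("relative", "jeffreys", "fixed"):
            raise ConfigurationError(f"unknown sigma_mode {sigma_mode!r}")
        if sigma_mode in ("fixed", "relative") and (sigma is None or sigma <= 0):
            raise ConfigurationError(
                f"sigma_mode={sigma_mode!r} requires sigma > 0 "
                "(an absolute ug/L scale, or the relative measurement SD)")
        if obs is not None and boundary is None:
            raise ConfigurationError("observations require a boundary series")
        self.obs = obs
        self.priors = priors
        self.boundary = boundary
        self.grid = grid
        self.sigma_mode = sigma_mode
        self.sigma = sigma
        if obs is not None and sigma_mode == "relative":
            # heteroscedastic Gaussian with known relative precision:
            # sigma_i = rel_sd * observed_i (floored at the substituted LOQ
            # value so censored points keep a finite scale)
            floor = max(obs.loq * LOQ_SUBSTITUTION_FACTOR, 1e-6)
            self._sigmas = sigma * np.maximum(obs.concentrations, floor)
            self._lognorm = -0.5 * np.sum(np.log(2.0 * np.pi * self._sigmas ** 2))

    def log_likelihood(self, theta: np.ndarray) -> float:
        if self.obs is None:
            return 0.0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", PecletWarning)
                curve = solve_ade(TransportParameters.from_array(theta),
                                  self.boundary, self.grid)
        except TransportSolverError as exc:
            logger.warning("forward solver failed at theta=%s: %s", theta, exc)
            return -np.inf
        model = np.interp(self.obs.times, curve.times, curve.concentrations)
        resid = self.obs.concentrations - model
        n = resid.size
        if self.sigma_mode == "relative":
            z = resid / self._sigmas
            return self._lognorm - 0.5 * float(z @ z)
        ssr = float(resid @ resid)
        if self.sigma_mode == "fixed":
            s2 = self.sigma ** 2
            return -0.5 * n * np.log(2.0 * np.pi * s2) - ssr / (2.0 * s2)
        ssr = max(ssr, n * _SSR_FLOOR_PER_POINT)
        return -0.5 * n * np.log(ssr)

    def __call__(self, theta: np.ndarray) -> float:
        lp = self.priors.logpdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.log_likelihood(theta)
        if not np.isfinite(ll):
            return -np.inf if ll < 0 else ll
        return lp + ll


def log_posterior(
    params: TransportParameters | np.ndarray,
    obs: ObservationSet | None,
    priors: PriorSet,
    boundary: BoundarySeries | None,
    grid: SpatialGrid | None = None,
    sigma_mode: str = "jeffreys",
    sigma: float | None = None,
) -> float:
    """Log posterior density (up to a constant) of one parameter vector.

    Outside the prior support this returns ``-inf`` (never raises); a
    forward-solver failure likewise maps to ``-inf`` with a logged warning.
    """
    theta = params.as_array() if isinstance(params, TransportParameters) else np.asarray(params, float)
    fn = _LogPosterior(obs, priors, boundary, grid or SpatialGrid.for_inference(),
                       sigma_mode, sigma)
    return fn(theta)


def _dream_core(fn: "_LogPosterior", priors: PriorSet, settings: DreamSettings,
                rng: np.random.Generator, seed: int | None) -> ChainEnsemble:
    d = len(priors.names)
    N = settings.n_chains
    if N < 2 * d + 1:
        raise ConfigurationError(
            f"DREAM needs at least 2*d+1 = {2 * d + 1} chains for dimension {d}, got {N}"
        )
    G = settings.n_generations
    n_burn = settings.n_burn
    jitter_sd = settings.jitter * priors.reference_scales()

    # Likelihood annealing schedule: quadratic ramp over the first
    # anneal_fraction of the run, never extending past half of burn-in.
    n_anneal = min(int(settings.anneal_fraction * G), n_burn // 2)

    def beta_at(gen: int) -> float:
        if n_anneal <= 0 or gen >= n_anneal:
            return 1.0
        return (gen / n_anneal) ** 2

    # Chains evolve in sampling coordinates (scale parameters on the log
    # axis); the Metropolis target includes the Jacobian so that recorded
    # natural-unit samples follow the exact posterior.  Prior and likelihood
    # parts are kept separate so a change of beta costs no re-evaluation.
    def eval_parts(phi: np.ndarray) -> tuple[float, float]:
        theta = priors.from_sampling(phi)
        lp = priors.logpdf(theta)
        if not np.isfinite(lp):
            return -np.inf, 0.0
        lp += priors.log_jacobian(phi)
        ll = fn.log_likelihood(theta)
        if not np.isfinite(ll):
            return -np.inf, 0.0
        return lp, ll

    X = priors.to_sampling(priors.sample(rng, N))
    parts = np.array([eval_parts(x) for x in X])
    for i in np.flatnonzero(~np.isfinite(parts[:, 0])):
        for _ in range(100):
            X[i] = priors.to_sampling(priors.sample(rng, 1)[0])
            parts[i] = eval_parts(X[i])
            if np.isfinite(parts[i, 0]):
                break
        else:
            raise ConfigurationError("could not find a finite-density start point")
    logprior = parts[:, 0]
    loglik = parts[:, 1]

    traj = np.empty((N, G + 1, d))
    traj_logp = np.empty((N, G + 1))
    traj[:, 0] = priors.from_sampling(X)
    traj_logp[:, 0] = logprior + loglik

    n_accept = 0
    n_resets = 0
    check_every = min(25, max(10, n_burn // 10)) if n_burn else 0
    others = {i: np.array([j for j in range(N) if j != i]) for i in range(N)}

    for gen in range(1, G + 1):
        beta = beta_at(gen)
        unit_gamma = rng.random() < settings.gamma_unit_prob
        for i in range(N):
            log_metropolis_corr = 0.0
            if not unit_gamma and rng.random() < settings.snooker_prob:
                # snooker move: jump along the line towards another chain,
                # scaled by the difference of two further chains projected
                # onto that line; strongly improves mixing along posterior
                # ridges.  The (d-1)-power correction keeps detailed balance.
                pick = rng.choice(others[i], size=3, replace=False)
                anchor = X[pick[0]]
                line = X[i] - anchor
                norm2 = float(line @ line)
                if norm2 <= 0:
                    continue
                proj = ((X[pick[1]] - X[pick[2]]) @ line) / norm2
                gamma_s = rng.uniform(1.2, 2.2)
                z = X[i] + gamma_s * proj * line
                znorm2 = float((z - anchor) @ (z - anchor))
                if znorm2 <= 0:
                    continue
                log_metropolis_corr = 0.5 * (d - 1) * np.log(znorm2 / norm2)
            else:
                delta = int(rng.integers(1, settings.n_pairs_max + 1))
                pick = rng.choice(others[i], size=2 * delta, replace=False)
                diff = X[pick[:delta]].sum(axis=0) - X[pick[delta:]].sum(axis=0)
                cr = (int(rng.integers(1, settings.n_crossover + 1))
                      / settings.n_crossover)
                if unit_gamma:
                    # mode-jump generations propose in the full space so a
                    # chain can swap basins in one move
                    mask = np.ones(d, dtype=bool)
                else:
                    mask = rng.random(d) < cr
                    if not mask.any():
                        mask[rng.integers(d)] = True
                dprime = int(mask.sum())
                gamma = 1.0 if unit_gamma else 2.38 / np.sqrt(2.0 * delta * dprime)
                lam = rng.uniform(-0.1, 0.1, d)
                zeta = rng.normal(0.0, 1.0, d) * jitter_sd
                z = X[i].copy()
                z[mask] = (X[i, mask] + (1.0 + lam[mask]) * gamma * diff[mask]
                           + zeta[mask])
            lp_z, ll_z = eval_parts(z)
            delta_eff = (lp_z + beta * ll_z) - (logprior[i] + beta * loglik[i])
            if np.log(rng.random()) < delta_eff + log_metropolis_corr:
                X[i] = z
                logprior[i] = lp_z
                loglik[i] = ll_z
                n_accept += 1
        traj[:, gen] = priors.from_sampling(X)
        traj_logp[:, gen] = logprior + loglik

        if (settings.outlier_correction and gen < n_burn and check_every
                and gen % check_every == 0 and gen >= max(20, n_anneal + 10)):
            window = max(gen // 2, gen - 100, n_anneal)
            means = traj_logp[:, window: gen + 1].mean(axis=1)
            q1, q3 = np.percentile(means, [25, 75])
            outliers = np.flatnonzero(means < q1 - 2.0 * (q3 - q1))
            if outliers.size:
                best = int(np.argmax(logprior + loglik))
                for i in outliers:
                    if i == best:
                        continue
                    X[i] = X[best]
                    logprior[i] = logprior[best]
                    loglik[i] = loglik[best]
                    n_resets += 1

    return ChainEnsemble(
        params=traj,
        logp=traj_logp,
        n_burn=n_burn,
        param_names=tuple(priors.names),
        seed=seed,
        acceptance_rate=n_accept / (N * G),
        n_outlier_resets=n_resets,
    )


def dream_sample(
    obs: ObservationSet | None,
    priors: PriorSet,
    boundary: BoundarySeries | None = None,
    settings: DreamSettings | None = None,
    grid: SpatialGrid | None = None,
    seed: int | None = 0,
    sigma_mode: str = "jeffreys",
    sigma: float | None = None,
) -> ChainEnsemble:
    """Run the multi-chain sampler for one compound on one flowpath.

    With ``obs=None`` the likelihood is constant and the sampler targets the
    prior — the standard correctness check for proposal and acceptance
    mechanics.
    """
    settings = settings or DreamSettings()
    grid = grid or SpatialGrid.for_inference()
    fn = _LogPosterior(obs, priors, boundary, grid, sigma_mode, sigma)
    rng = np.random.default_rng(seed)
    return _dream_core(fn, priors, settings, rng, seed)


def gelman_rubin(ensemble: ChainEnsemble) -> dict[str, float]:
    """Potential scale reduction factor per parameter over retained samples.

    Values near 1 indicate the between-chain spread has collapsed onto the
    within-chain spread; convergence is conventionally declared below 1.2.
    Degenerate (zero-variance) chains yield NaN with a warning.
    """
    r = ensemble.retained()
    m, n, d = r.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains and >= 10 retained samples per chain")
    out: dict[str, float] = {}
    for j, name in enumerate(ensemble.param_names):
        chains = r[:, :, j]
        w = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        if w <= 0:
            warnings.warn(f"zero within-chain variance for {name!r}; "
                          "diagnostic undefined", UserWarning, stacklevel=2)
            out[name] = np.nan
            continue
        var_plus = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(var_plus / w))
    return out


def summarize_posterior(ensemble: ChainEnsemble) -> PosteriorSummary:
    """Median and quartiles of the pooled post-burn-in samples."""
    pooled = ensemble.pooled()
    if pooled.size == 0:
        raise ValueError("no retained samples to summarize")
    q25, med, q75 = np.percentile(pooled, [25, 50, 75], axis=0)
    names = ensemble.param_names
    return PosteriorSummary(
        median=dict(zip(names, med)),
        q25=dict(zip(names, q25)),
        q75=dict(zip(names, q75)),
        n_samples=pooled.shape[0],
        rhat=gelman_rubin(ensemble),
        acceptance_rate=ensemble.acceptance_rate,
    )


@dataclass(frozen=True)
class TwoStageResult:
    """Output of the chained calibration: summaries plus the priors used."""

    summaries: dict[tuple[str, str], PosteriorSummary]
    stage1_dh: dict[str, tuple[float, float]]
    priors_used: dict[tuple[str, str], PriorSet]
    ensembles: dict[tuple[str, str], ChainEnsemble] | None = None


def two_stage_calibration(
    dataset: Sequence[ObservationSet],
    boundaries: Mapping[str, BoundarySeries],
    reference_compound: str,
    settings: DreamSettings | None = None,
    grid: SpatialGrid | None = None,
    seed: int = 0,
    geometries: Mapping[str, FlowpathGeometry] | None = None,
    relative_sd: float = 0.2,
    sigma_mode: str = "jeffreys",
    sigma: float | None = None,
    return_ensembles: bool = False,
) -> TwoStageResult:
    """Chained dispersion calibration across compounds, per flowpath.

    Stage 1 fits the designated conservative reference compound on each
    flowpath under a wide log-uniform dispersion prior; stage 2 replaces the
    dispersion prior with a Gaussian matched to the stage-1 posterior
    (median, IQR/1.349) and fits every other compound independently.
    """
    settings = settings or DreamSettings()
    grid = grid or SpatialGrid.for_inference()
    by_key = {(o.compound, o.flowpath): o for o in dataset}
    flowpaths = sorted({o.flowpath for o in dataset})
    compounds = sorted({o.compound for o in dataset})
    missing = [fp for fp in flowpaths if (reference_compound, fp) not in by_key]
    if reference_compound not in compounds or missing:
        raise ConfigurationError(
            f"two-stage calibration requires the reference compound "
            f"{reference_compound!r} on every flowpath (missing on: "
            f"{missing or flowpaths}); its dispersion posterior seeds the "
            f"stage-2 priors"
        )
    if geometries is None:
        geometries = {fp: flowpath_by_id(fp) for fp in flowpaths}

    n_fits = len(by_key)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n_fits)]
    seed_iter = iter(child_seeds)

    summaries: dict[tuple[str, str], PosteriorSummary] = {}
    priors_used: dict[tuple[str, str], PriorSet] = {}
    stage1_dh: dict[str, tuple[float, float]] = {}
    ensembles: dict[tuple[str, str], ChainEnsemble] = {}

    def _fit(key: tuple[str, str], priors: PriorSet) -> PosteriorSummary:
        obs = by_key[key]
        ens = dream_sample(obs, priors, boundaries[obs.compound], settings,
                           grid=grid, seed=next(seed_iter),
                           sigma_mode=sigma_mode, sigma=sigma)
        if return_ensembles:
            ensembles[key] = ens
        return summarize_posterior(ens)

    for fp in flowpaths:
        key = (reference_compound, fp)
        priors = build_prior_set(geometries[fp], dh_prior=None,
                                 relative_sd=relative_sd,
                                 domain_length=grid.domain_length)
        summary = _fit(key, priors)
        summaries[key] = summary
        priors_used[key] = priors
        stage1_dh[fp] = (summary.median["D"], summary.iqr("D"))

    for compound in compounds:
        if compound == reference_compound:
            continue
        for fp in flowpaths:
            key = (compound, fp)
            if key not in by_key:
                continue
            priors = build_prior_set(geometries[fp], dh_prior=stage1_dh[fp],
                                     relative_sd=relative_sd,
                                     domain_length=grid.domain_length)
            summaries[key] = _fit(key, priors)
            priors_used[key] = priors

    return TwoStageResult(summaries=summaries, stage1_dh=stage1_dh,
                          priors_used=priors_used,
                          ensembles=ensembles if return_ensembles else None)


class TransportCurveFitter(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator fitting one breakthrough curve.

    ``fit(X, y)`` takes observation times (hours, shape (n,) or (n, 1)) and
    concentrations (ug/L) and runs the DREAM sampler against the configured
    priors and boundary series; ``predict(X)`` evaluates the forward model at
    the posterior-median parameters.

    Examples
    --------
    >>> from hyporeact import priors as hp
    >>> geom = hp.flowpath_by_id("b")
    >>> fitter = TransportCurveFitter(
    ...     priors=hp.build_prior_set(geom, hp.DEFAULT_DH_POSTERIORS["b"]),
    ...     boundary=BoundarySeries.constant(11.5, 504.0),
    ...     n_generations=200)   # doctest: +SKIP
    """

    def __init__(self, priors=None, boundary=None, grid=None,
                 n_chains=20, n_generations=4004, burn_in=0.5,
                 sigma_mode="jeffreys", sigma=None, random_state=0):
        self.priors = priors
        self.boundary = boundary
        self.grid = grid
        self.n_chains = n_chains
        self.n_generations = n_generations
        self.burn_in = burn_in
        self.sigma_mode = sigma_mode
        self.sigma = sigma
        self.random_state = random_state

    def _validate_times(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be observation times, shape (n,) or (n, 1)")
        return X

    def fit(self, X, y):
        if self.priors is None or self.boundary is None:
            raise ConfigurationError("fitting requires `priors` and `boundary`")
        times = self._validate_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != times.shape:
            raise ValueError("y must match X in length")
        obs = ObservationSet("curve", "?", times, y)
        settings = DreamSettings(n_chains=self.n_chains,
                                 n_generations=self.n_generations,
                                 burn_in=self.burn_in)
        grid = self.grid or SpatialGrid.for_inference()
        self.ensemble_ = dream_sample(obs, self.priors, self.boundary, settings,
                                      grid=grid, seed=self.random_state,
                                      sigma_mode=self.sigma_mode, sigma=self.sigma)
        self.summary_ = summarize_posterior(self.ensemble_)
        self.rhat_ = self.summary_.rhat
        self.acceptance_rate_ = self.summary_.acceptance_rate
        self.median_params_ = self.summary_.median_params()
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "summary_"):
            raise AttributeError("this TransportCurveFitter is not fitted yet")
        times = self._validate_times(X)
        grid = self.grid or SpatialGrid.for_inference()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PecletWarning)
            curve = solve_ade(self.median_params_, self.boundary, grid)
        return curve.at(times)
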