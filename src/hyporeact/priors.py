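"""Flowpath geometry and prior distributions for transport-parameter inference.

Default geometries are the median flowpath lengths and travel times of the
four porewater samplers (a--d) from the bedform hydrodynamic model; default
dispersion priors are the per-flowpath posteriors obtained by fitting the
most conservative compound (hydrochlorothiazide) in a calibration pre-run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FlowpathGeometry",
    "PriorSpec",
    "PriorSet",
    "PARAM_NAMES",
    "IQR_TO_SD",
    "default_flowpaths",
    "flowpath_by_id",
    "build_prior_set",
    "DEFAULT_DH_POSTERIORS",
]

#: canonical parameter ordering used by the sampler
PARAM_NAMES = ("k", "R", "v", "L", "D")

#: interquartile range of a normal distribution = 1.349 standard deviations
IQR_TO_SD = 1.0 / 1.349

#: per-flowpath (median, IQR) of the dispersion coefficient D, m^2/h, from
#: the conservative-compound calibration reported for the flume experiment
DEFAULT_DH_POSTERIORS: dict[str, tuple[float, float]] = {
    "a": (0.0015, 0.0008),
    "b": (1.1e-4, 5.1e-5),
    "c": (5.3e-5, 6.7e-6),
    "d": (2.4e-5, 1.4e-5),
}

DEFAULT_K_BOUNDS = (1e-5, 4.0)
DEFAULT_R_BOUNDS = (1.0, 49.0)
STAGE1_DH_BOUNDS = (1e-6, 1e-2)


@dataclass(frozen=True)
class FlowpathGeometry:
    """Median length (m) and travel time (h) of one hyporheic flowpath."""

    id: str
    median_length: float
    median_travel_time: float

    def __post_init__(self) -> None:
        if self.median_length <= 0 or self.median_travel_time <= 0:
            raise ValueError("flowpath length and travel time must be positive")

    @property
    def median_velocity(self) -> float:
        """Median porewater velocity, m/h, consistent with length/time."""
        return self.median_length / self.median_travel_time


def default_flowpaths() -> list[FlowpathGeometry]:
    """The four sampler flowpaths with their hydrodynamic-model medians."""
    return [
        FlowpathGeometry("a", 0.05, 11.5),
        FlowpathGeometry("b", 0.111, 24.3),
        FlowpathGeometry("c", 0.166, 43.3),
        FlowpathGeometry("d", 0.092, 20.1),
    ]


def flowpath_by_id(flowpath_id: str) -> FlowpathGeometry:
    for geom in default_flowpaths():
        if geom.id == flowpath_id:
            return geom
    raise KeyError(f"unknown flowpath id {flowpath_id!r}; expected one of a, b, c, d")


@dataclass(frozen=True)
class PriorSpec:
    """One named prior: family, parameters and hard support bounds.

    Families
    --------
    - ``uniform``: flat on [lower, upper] (= bounds).
    - ``gaussian``: N(loc, scale) truncated to the hard bounds.
    - ``loguniform``: flat in log x on [lower, upper]; used for the wide
      stage-1 dispersion prior of the calibration pre-run.
    """

    name: str
    family: str
    loc: float | None = None
    scale: float | None = None
    lower: float | None = None
    upper: float | None = None
    bounds: tuple[float, float] = (-math.inf, math.inf)
    #: sample this parameter on the log scale (with Jacobian correction);
    #: the target density is unchanged, but proposals become multiplicative,
    #: which mixes far better for scale-like parameters spanning decades.
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform", "loguniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "gaussian":
            if self.loc is None or self.scale is None or self.scale <= 0:
                raise ValueError(f"gaussian prior {self.name!r} needs loc and scale > 0")
        else:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"{self.family} prior {self.name!r} needs lower < upper")
            if self.family == "loguniform" and self.lower <= 0:
                raise ValueError("loguniform prior requires lower > 0")
            object.__setattr__(self, "bounds", (self.lower, self.upper))
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"hard bounds must satisfy lo < hi, got {self.bounds}")
        if self.log_scale and lo <= 0:
            raise ValueError(
                f"log-scale sampling of {self.name!r} requires a positive lower bound"
            )

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.bounds
        return (x >= lo) & (x <= hi)

    def logpdf(self, x) -> np.ndarray:
        """Log density up to an additive constant; -inf outside the bounds."""
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        inside = self.contains(x)
        if self.family == "gaussian":
            out = np.where(inside, -0.5 * ((x - self.loc) / self.scale) ** 2, out)
        elif self.family == "uniform":
            out = np.where(inside, 0.0, out)
        else:  # loguniform
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(inside, -np.log(np.where(inside, x, 1.0)), out)
        return out

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.lower, self.upper, size)
        if self.family == "loguniform":
            return np.exp(rng.uniform(np.log(self.lower), np.log(self.upper), size))
        lo, hi = self.bounds
        a = (lo - self.loc) / self.scale
        b = (hi - self.loc) / self.scale
        return stats.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale,
                                   size=size, random_state=rng)

    def reference_scale(self) -> float:
        """A characteristic width in sampling coordinates (jitter scaling)."""
        if self.log_scale:
            lo, hi = self.bounds
            if math.isfinite(hi):
                return float(math.log(hi / lo))
            return float(self.scale / self.loc) if self.family == "gaussian" else 1.0
        if self.family == "gaussian":
            return float(self.scale)
        return float(self.upper - self.lower)

    @classmethod
    def gaussian_from_iqr(cls, name: str, median: float, iqr: float,
                          bounds: tuple[float, float]) -> "PriorSpec":
        """Gaussian prior matched to a printed median and interquartile range."""
        if iqr <= 0:
            raise ValueError("IQR must be positive")
        return cls(name=name, family="gaussian", loc=median,
                   scale=iqr * IQR_TO_SD, bounds=bounds)


@dataclass(frozen=True)
class PriorSet:
    """One prior per inferred transport parameter, in sampler order."""

    specs: tuple[PriorSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if sorted(names) != sorted(PARAM_NAMES) or len(set(names)) != len(names):
            raise ValueError(
                f"PriorSet needs exactly one spec per parameter {PARAM_NAMES}, got {names}"
            )
        ordered = tuple(sorted(self.specs, key=lambda s: PARAM_NAMES.index(s.name)))
        object.__setattr__(self, "specs", ordered)

    def __getitem__(self, name: str) -> PriorSpec:
        for spec in self.specs:
            if spec.name == name:
                return spec
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([s.bounds for s in self.specs])

    def reference_scales(self) -> np.ndarray:
        return np.array([s.reference_scale() for s in self.specs])

    def logpdf(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        total = 0.0
        for spec, x in zip(self.specs, theta):
            lp = float(spec.logpdf(x))
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` parameter vectors, shape (size, 5), in sampler order."""
        return np.column_stack([s.sample(rng, size) for s in self.specs])

    def replace_spec(self, spec: PriorSpec) -> "PriorSet":
        return PriorSet(tuple(spec if s.name == spec.name else s for s in self.specs))

    # -- sampling-coordinate helpers -------------------------------------
    # Scale-like parameters are proposed on the log axis; the density is
    # corrected by the Jacobian so the posterior in natural units is exact.

    @property
    def log_mask(self) -> np.ndarray:
        return np.array([s.log_scale for s in self.specs])

    def to_sampling(self, theta: np.ndarray) -> np.ndarray:
        phi = np.array(theta, dtype=float, copy=True)
        m = self.log_mask
        phi[..., m] = np.log(phi[..., m])
        return phi

    def from_sampling(self, phi: np.ndarray) -> np.ndarray:
        theta = np.array(phi, dtype=float, copy=True)
        m = self.log_mask
        theta[..., m] = np.exp(theta[..., m])
        return theta

    def log_jacobian(self, phi: np.ndarray) -> float:
        """log |d theta / d phi| at a sampling-space point."""
        return float(np.sum(phi[self.log_mask]))


def build_prior_set(
    geom: FlowpathGeometry,
    dh_prior: tuple[float, float] | None = None,
    relative_sd: float = 0.2,
    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS,
    r_bounds: tuple[float, float] = DEFAULT_R_BOUNDS,
    stage1_dh_bounds: tuple[float, float] = STAGE1_DH_BOUNDS,
    domain_length: float = 0.25,
) -> PriorSet:
    """Assemble the prior set for one flowpath.

    Parameters
    ----------
    geom : FlowpathGeometry
        Supplies the Gaussian prior centres for length and velocity.
    dh_prior : (median, iqr) or None
        Dispersion prior.  When given (stage 2, or the tabulated defaults in
        :data:`DEFAULT_DH_POSTERIORS`), a Gaussian matched via sd = IQR/1.349;
        when None, the wide log-uniform stage-1 prior used for the
        conservative-compound calibration pre-run.
    relative_sd : float
        Relative standard deviation of the Gaussian length and velocity
        priors (their spreads are not tabulated; the flowpath distributions
        are broad but unimodal, and 20% is the package default).
    """
    if not 0 < relative_sd < 1:
        raise ValueError("relative_sd must be in (0, 1)")
    eps = 1e-4
    specs = [
        PriorSpec("k", "uniform", lower=k_bounds[0], upper=k_bounds[1],
                  log_scale=True),
        PriorSpec("R", "uniform", lower=r_bounds[0], upper=r_bounds[1]),
        PriorSpec("v", "gaussian", loc=geom.median_velocity,
                  scale=relative_sd * geom.median_velocity,
                  bounds=(1e-6, math.inf)),
        PriorSpec("L", "gaussian", loc=geom.median_length,
                  scale=relative_sd * geom.median_length,
                  bounds=(eps, domain_length - eps)),
    ]
    if dh_prior is None:
        specs.append(PriorSpec("D", "loguniform",
                               lower=stage1_dh_bounds[0], upper=stage1_dh_bounds[1],
                               log_scale=True))
    else:
        median, iqr = dh_prior
        spec = PriorSpec.gaussian_from_iqr(
            "D", median, iqr, bounds=(stage1_dh_bounds[0] / 10, stage1_dh_bounds[1] * 10))
        specs.append(PriorSpec(spec.name, spec.family, loc=spec.loc,
                               scale=spec.scale, bounds=spec.bounds,
                               log_scale=True))
    return PriorSet(tuple(specs))
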