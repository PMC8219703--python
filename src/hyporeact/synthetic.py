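"""Synthetic flume datasets with known ground truth.

Emulates the recirculating-flume injection experiment: all compounds start
at a common surface-water concentration (11.5 ug/L), decline roughly
exponentially as they degrade in the recirculating water, and break through
at the porewater samplers according to the 1-D reactive transport model.
Porewater observations carry multiplicative lognormal measurement noise and
are left-censored at the limit of quantification, with censored values
substituted by LOQ / sqrt(2) exactly as the measured data are prepared.

Because every stage of the fitting pipeline can be run against these
datasets, parameter recovery is testable end to end without the (not
deposited) measured concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import LOQ_SUBSTITUTION_FACTOR, ObservationSet
from .priors import DEFAULT_DH_POSTERIORS, default_flowpaths
from .transport import (
    BoundarySeries,
    PecletWarning,
    SpatialGrid,
    TransportParameters,
    solve_ade,
)

__all__ = [
    "CompoundSpec",
    "ScenarioSpec",
    "SyntheticDataset",
    "DEFAULT_SAMPLING_DAYS",
    "gen_sw_series",
    "simulate_observations",
    "loq_substitute",
    "gen_benchmark_scenario",
    "generate_dataset",
]

#: porewater/surface-water sampling schedule within the 21-day fit window (days)
DEFAULT_SAMPLING_DAYS = (0, 1, 2, 3, 7, 14, 21)

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class CompoundSpec:
    """Ground truth for one compound: per-flowpath transport parameters plus
    its surface-water decay rate and limit of quantification."""

    name: str
    truth: dict[str, TransportParameters]
    sw_decay_rate: float  # 1/h, first-order decline of the recirculating SW
    loq: float = 0.1      # ug/L
    reference: bool = False

    def __post_init__(self) -> None:
        if self.sw_decay_rate < 0:
            raise ValueError("surface-water decay rate must be >= 0")
        if self.loq < 0:
            raise ValueError("LOQ must be >= 0")
        if not self.truth:
            raise ValueError("compound needs truth parameters for at least one flowpath")


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete specification of a synthetic experiment."""

    compounds: tuple[CompoundSpec, ...]
    c0: float = 11.5                     # injected SW concentration, ug/L
    sampling_days: tuple = DEFAULT_SAMPLING_DAYS
    noise_rel_sd: float = 0.05           # relative SD of measurement noise
    #: optional refill dilutions: (day, fraction) step drops of the SW
    #: concentration, mimicking top-ups with deionized water; off by default
    #: because the experiment's refill timing is unpublished
    dilution_events: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("initial concentration must be positive")
        for day, frac in self.dilution_events:
            if day < 0 or not 0.0 < frac < 1.0:
                raise ValueError(
                    "dilution events must be (day >= 0, 0 < fraction < 1)")
        if list(self.sampling_days) != sorted(set(self.sampling_days)):
            raise ValueError("sampling days must be sorted and unique")
        if self.noise_rel_sd < 0:
            raise ValueError("noise relative SD must be >= 0")
        names = [c.name for c in self.compounds]
        if len(names) != len(set(names)):
            raise ValueError("compound names must be unique")

    @property
    def sampling_times(self) -> np.ndarray:
        return np.asarray(self.sampling_days, dtype=float) * HOURS_PER_DAY

    def compound(self, name: str) -> CompoundSpec:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def reference_compound(self) -> str | None:
        for c in self.compounds:
            if c.reference:
                return c.name
        return None


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated boundary series, observations and the truth they came from."""

    scenario: ScenarioSpec
    boundaries: dict[str, BoundarySeries]
    observations: tuple[ObservationSet, ...]

    def truth(self, compound: str, flowpath: str) -> TransportParameters:
        return self.scenario.compound(compound).truth[flowpath]


def gen_sw_series(spec: ScenarioSpec, compound: str) -> BoundarySeries:
    """Surface-water record at the sampling days: c0 * exp(-k_sw t).

    Only the sampling-day values are emitted (as measured), so downstream
    code must interpolate — the same situation the real data present.
    """
    comp = spec.compound(compound)
    t = spec.sampling_times
    c = spec.c0 * np.exp(-comp.sw_decay_rate * t)
    for day, frac in spec.dilution_events:
        c = np.where(t >= day * HOURS_PER_DAY, c * (1.0 - frac), c)
    return BoundarySeries(t, c)


def loq_substitute(value, loq: float):
    """Left-censoring rule: values below LOQ are replaced by LOQ / sqrt(2).

    Values at or above the LOQ (including exactly at it) pass unchanged.
    """
    if loq < 0:
        raise ValueError("LOQ must be >= 0")
    value = np.asarray(value, dtype=float)
    out = np.where(value < loq, loq * LOQ_SUBSTITUTION_FACTOR, value)
    return float(out) if out.ndim == 0 else out


def _noise_sigma(rel_sd: float) -> float:
    # lognormal log-sd giving the requested coefficient of variation
    return np.sqrt(np.log1p(rel_sd ** 2))


def simulate_observations(
    spec: ScenarioSpec,
    compound: str,
    flowpath: str,
    rng: np.random.Generator | None = None,
    grid: SpatialGrid | None = None,
) -> ObservationSet:
    """Noisy, LOQ-censored porewater observations for one compound/flowpath.

    Runs the forward model with the truth parameters and the sparse
    surface-water boundary, samples the breakthrough curve at the sampling
    days, applies multiplicative lognormal noise (median-unbiased, with the
    requested coefficient of variation) and censors below the LOQ.
    """
    comp = spec.compound(compound)
    if flowpath not in comp.truth:
        raise KeyError(f"no truth parameters for {compound!r} on flowpath {flowpath!r}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    grid = grid or SpatialGrid(duration=float(spec.sampling_times[-1]))
    boundary = gen_sw_series(spec, compound)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PecletWarning)
        curve = solve_ade(comp.truth[flowpath], boundary, grid)
    clean = curve.at(spec.sampling_times)
    if spec.noise_rel_sd > 0:
        noisy = clean * rng.lognormal(0.0, _noise_sigma(spec.noise_rel_sd),
                                      clean.shape)
    else:
        noisy = clean.copy()
    censored = noisy < comp.loq
    values = loq_substitute(noisy, comp.loq)
    if comp.loq == 0:
        # keep strictly positive observations even in the noise/LOQ-free case
        values = np.maximum(values, 1e-12)
        censored = np.zeros_like(censored)
    return ObservationSet(
        compound=compound,
        flowpath=flowpath,
        times=spec.sampling_times,
        concentrations=values,
        loq=comp.loq,
        censored=censored,
    )


def generate_dataset(spec: ScenarioSpec, grid: SpatialGrid | None = None) -> SyntheticDataset:
    """All boundaries and observation sets of a scenario, reproducible by seed.

    A single generator seeded with the scenario seed drives all noise, drawn
    in the deterministic (compound, flowpath) iteration order.
    """
    rng = np.random.default_rng(spec.seed)
    boundaries = {c.name: gen_sw_series(spec, c.name) for c in spec.compounds}
    observations = []
    for comp in spec.compounds:
        for fp in sorted(comp.truth):
            observations.append(
                simulate_observations(spec, comp.name, fp, rng=rng, grid=grid)
            )
    return SyntheticDataset(scenario=spec, boundaries=boundaries,
                            observations=tuple(observations))


def gen_benchmark_scenario(
    seed: int = 0,
    flowpaths: tuple[str, ...] = ("a", "b", "c", "d"),
    compounds: tuple[str, ...] = ("hydrochlorothiazide", "sotalol", "metformin"),
    noise_rel_sd: float = 0.05,
) -> ScenarioSpec:
    """Canonical three-compound test scenario with known truth.

    Compounds emulate the behavioural archetypes seen in the flumes:

    - ``hydrochlorothiazide`` — conservative reference (k = 0, R = 1.2),
      slow decline in the recirculating surface water;
    - ``sotalol`` — fast degrader (k = 1 /h, R = 3);
    - ``metformin`` — moderate degrader with strong retardation
      (k = 0.02 /h, R = 8).

    Velocities are the flowpath median length / median travel time, and the
    dispersion truth is the per-flowpath calibrated median.
    """
    geoms = {g.id: g for g in default_flowpaths()}
    archetypes = {
        # name: (k 1/h, R -, sw decay 1/h)
        "hydrochlorothiazide": (0.0, 1.2, 0.0013),
        "sotalol": (1.0, 3.0, 0.0144),
        "metformin": (0.02, 8.0, 0.0069),
    }
    specs = []
    for name in compounds:
        if name not in archetypes:
            raise KeyError(f"unknown benchmark compound {name!r}")
        k, R, sw_rate = archetypes[name]
        truth = {}
        for fp in flowpaths:
            geom = geoms[fp]
            truth[fp] = TransportParameters(
                k=k, R=R, v=geom.median_velocity, L=geom.median_length,
                D=DEFAULT_DH_POSTERIORS[fp][0],
            )
        specs.append(CompoundSpec(
            name=name, truth=truth, sw_decay_rate=sw_rate, loq=0.1,
            reference=(name == "hydrochlorothiazide"),
        ))
    return ScenarioSpec(compounds=tuple(specs), seed=seed,
                        noise_rel_sd=noise_rel_sd)
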