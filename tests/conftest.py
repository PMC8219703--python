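import numpy as np
import pytest

from hyporeact.priors import DEFAULT_DH_POSTERIORS, flowpath_by_id, build_prior_set
from hyporeact.synthetic import CompoundSpec, ScenarioSpec, generate_dataset
from hyporeact.transport import BoundarySeries, SpatialGrid, TransportParameters


@pytest.fixture(scope="session")
def flowpath_b():
    return flowpath_by_id("b")


@pytest.fixture(scope="session")
def priors_b(flowpath_b):
    return build_prior_set(flowpath_b, DEFAULT_DH_POSTERIORS["b"])


@pytest.fixture(scope="session")
def recovery_dataset(flowpath_b):
    """One-compound synthetic dataset on flowpath b with known truth."""
    truth = TransportParameters(k=0.03, R=1.5, v=flowpath_b.median_velocity,
                                L=flowpath_b.median_length, D=1.1e-4)
    spec = ScenarioSpec(
        compounds=(CompoundSpec("solute", {"b": truth}, sw_decay_rate=0.008,
                                loq=0.1),),
        seed=3,
    )
    return generate_dataset(spec), truth


@pytest.fixture(scope="session")
def constant_boundary():
    return BoundarySeries.constant(11.5, 504.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return SpatialGrid.for_inference()
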