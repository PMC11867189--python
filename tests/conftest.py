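import numpy as np
import pytest

from mmcoal.genealogy import CoalescentData, SamplingSchedule
from mmcoal.measures import RateTable, beta_measure
from mmcoal.simulate import PiecewiseNe, SimulationSpec, simulate


@pytest.fixture(scope="session")
def beta15_table():
    return RateTable(beta_measure(1.5), 100)


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic heterochronous multifurcating dataset (hand-built)."""
    sched = SamplingSchedule(np.array([0.0, 0.3]), np.array([4, 3]))
    t = np.array([0.2, 0.5, 0.9, 1.4])
    m = np.array([2, 3, 2, 3])
    return CoalescentData(sched, t, m)


@pytest.fixture(scope="session")
def sim_dataset(beta15_table):
    """A simulated Beta(1.5) genealogy with 30 tips, constant Ne."""
    sched = SamplingSchedule.isochronous(30)
    spec = SimulationSpec(beta_measure(1.5), PiecewiseNe.constant(50.0), sched, 42)
    tree, data = simulate(spec, rate_table=beta15_table)
    return tree, data
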