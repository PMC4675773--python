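"""Shared fixtures.

Reduced 10-compartment lungs (each compartment lumping ten alveolar units
of the reference lung) keep the suite fast; the lump scaling preserves
aggregate mechanics, so the physiology under test is the same.
"""

import numpy as np
import pytest

from ardsim import (GAConfig, VentilatorSettings, run_ga, table_fixtures)
from ardsim.mechanics import CompartmentSet

N_REDUCED = 10

#: matching configuration used throughout the suite: termination threshold
#: well inside the E_T <= 0.02 contract so per-output errors settle too
MATCH_CONFIG = dict(population=64, generations=200, seed=11, threshold=0.002)


@pytest.fixture(scope="session")
def fixtures():
    return table_fixtures()


@pytest.fixture(scope="session")
def datasets(fixtures):
    return fixtures["datasets"]


@pytest.fixture(scope="session")
def matched_patients(datasets):
    """GA fits of the three printed patient datasets on reduced lungs."""
    out = {}
    for pid in "ABC":
        out[pid] = run_ga(datasets[pid], GAConfig(**MATCH_CONFIG),
                          n_compartments=N_REDUCED)
    return out


@pytest.fixture
def baseline_vent():
    return VentilatorSettings(V_T=560.0, RR=12.5, DC=0.33, PEEP=5.0, FiO2=0.21)


@pytest.fixture
def homogeneous_lung():
    """Aerated homogeneous reduced lung, equilibrated at PEEP 5."""
    c = CompartmentSet.homogeneous(N_REDUCED, TOP=5.0, S=0.05, P_ext=0.0)
    c.equilibrate(5.0)
    return c


def random_lung(seed: int, n: int = 12) -> CompartmentSet:
    """A lung with parameters drawn uniformly from the allowed box."""
    r = np.random.default_rng(seed)
    c = CompartmentSet.from_parameters(r.uniform(5, 60, n),
                                       r.uniform(0.005, 0.5, n),
                                       r.uniform(-20, 28.8, n))
    c.equilibrate(5.0)
    return c
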