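"""Shared fixtures: physics tables and the scaled-down reference runs.

The stochastic-reproduction tests share a few session-scoped transport
runs so the suite stays within a desk-scale time budget; all runs are
fully seeded and deterministic.
"""

import numpy as np
import pytest

from tg43mc.pipeline import (run_air_kerma, run_water_dose_table,
                             extract_parameters)
from tg43mc.transport import PhysicsData


@pytest.fixture(scope="session")
def physics():
    return PhysicsData()


@pytest.fixture(scope="session")
def air_nndc(physics):
    return run_air_kerma("NNDC", histories=50_000, batches=4, seed=101,
                         physics=physics)


@pytest.fixture(scope="session")
def air_dc(physics):
    return run_air_kerma("DuchemCoursol", histories=50_000, batches=4,
                         seed=102, physics=physics)


@pytest.fixture(scope="session")
def water_nndc(physics):
    """NNDC water run: 4.8e6 histories on the targeted (1 cm, 3 cm)
    grid -- the polar anisotropy cells need the statistics."""
    return run_water_dose_table("NNDC", histories=1_200_000, batches=4,
                                seed=103, physics=physics)


@pytest.fixture(scope="session")
def water_dc(physics):
    """Duchemin-Coursol water run (dose-rate-constant check only)."""
    return run_water_dose_table("DuchemCoursol", histories=250_000,
                                batches=4, seed=104, physics=physics)


@pytest.fixture(scope="session")
def params_nndc(water_nndc, air_nndc):
    table, _res = water_nndc
    return extract_parameters(table, air_nndc)


@pytest.fixture(scope="session")
def params_dc(water_dc, air_dc):
    table, _res = water_dc
    return extract_parameters(table, air_dc)
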