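"""Shared fixtures: reference molecules, tissue, and pre-solved profiles.

The PDE solves are session-scoped so the suite pays for each infusion
simulation once.
"""

import pytest

from cedsim.experiments import run_rate_comparison, run_tracer_comparison
from cedsim.solver import InfusionProtocol, SolverSettings, TissueModel, solve_infusion
from cedsim.transport import get_molecule


@pytest.fixture(scope="session")
def gdnf():
    return get_molecule("r-metHuGDNF")


@pytest.fixture(scope="session")
def gd_dtpa():
    return get_molecule("Gd-DTPA")


@pytest.fixture(scope="session")
def tissue():
    return TissueModel()


@pytest.fixture(scope="session")
def tissue_no_elim():
    return TissueModel(elimination_rate=0.0)


@pytest.fixture(scope="session")
def protocol_5():
    return InfusionProtocol(rate=5.0, infusion_volume=0.105)


@pytest.fixture(scope="session")
def rate_comparison(tissue, gdnf):
    """End-of-infusion profiles and summary table at 0.1/1/3/5 uL/min."""
    return run_rate_comparison(tissue=tissue, molecule=gdnf)


@pytest.fixture(scope="session")
def profile_5_no_elim(protocol_5, tissue_no_elim, gdnf):
    """5 uL/min end-of-infusion GDNF profile with clearance off."""
    return solve_infusion(protocol_5, tissue_no_elim, gdnf)


@pytest.fixture(scope="session")
def tracer_comparison(tissue):
    """Drug-vs-tracer Vd at T=0 and T=2 h after a 5 uL/min infusion."""
    return run_tracer_comparison(tissue=tissue)


@pytest.fixture(scope="session")
def default_settings():
    return SolverSettings()
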