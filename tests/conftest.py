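"""Shared fixtures: the calibrated reference model and cached trajectories.

Everything is generated programmatically from the bundled YAML fixture;
session scope keeps the stiff integrations from being re-run per test.
"""

import pytest

from lateralwall.calibration import calibrate_system
from lateralwall.engine import Perturbation, integrate
from lateralwall.io_cli import load_default_config


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def model(config):
    return calibrate_system(config)


@pytest.fixture(scope="session")
def settled(model):
    """600-s unperturbed settle run from the fixture's initial values."""
    return integrate(model.system, model.state, 600.0)


@pytest.fixture(scope="session")
def blockade(model, settled):
    """40-min trajectory under the published pump blockade (kappa=0.46)."""
    pert = Perturbation("SB", "nak_atpase", factor=0.46, onset=0.0)
    return integrate(model.system, settled.final_state(), 2400.0, [pert])
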