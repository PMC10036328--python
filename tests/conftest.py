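"""Shared fixtures: simulated embryos for the three experimental conditions.

Session-scoped so the (relatively) expensive renders happen once.  The
``*_short`` configs truncate the acquisition to 10 min — every preset has
fully closed by then — to keep per-test cost low where the late frames
carry no information.
"""

import numpy as np
import pytest

from woundrepair.geometry import segment_wound
from woundrepair.simulate import WoundSimConfig, preset, simulate_stack

SHORT_TIMES = np.arange(0.0, 601.0, 30.0)


def short_preset(name: str, **overrides) -> WoundSimConfig:
    overrides.setdefault("frame_times", SHORT_TIMES.copy())
    return preset(name, **overrides)


@pytest.fixture(scope="session")
def control_sim():
    return simulate_stack(short_preset("control", seed=42))


@pytest.fixture(scope="session")
def rac_sim():
    return simulate_stack(short_preset("rac_inhibited", seed=43))


@pytest.fixture(scope="session")
def scar_sim():
    return simulate_stack(short_preset("scar_rnai", seed=44))


@pytest.fixture(scope="session")
def control_traj(control_sim):
    return segment_wound(control_sim.stack)


@pytest.fixture(scope="session")
def rac_traj(rac_sim):
    return segment_wound(rac_sim.stack)


@pytest.fixture(scope="session")
def scar_traj(scar_sim):
    return segment_wound(scar_sim.stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
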