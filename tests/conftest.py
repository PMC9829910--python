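import numpy as np
import pytest
from hypothesis import settings

from rivalscreen.core import DEFAULT_LADDER
from rivalscreen.observers import ObserverProfile, make_archetype
from rivalscreen.staircase import StaircaseConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def config():
    return StaircaseConfig()


@pytest.fixture
def ladder():
    return DEFAULT_LADDER


@pytest.fixture
def normal_observer():
    return make_archetype("normal")


@pytest.fixture
def amblyope_observer():
    """The undetected unilateral amblyope: 0.6 log-unit OS attenuation,
    pinhole-resistant 20/40 OS, acquired tritan defect OS."""
    return make_archetype("amblyope", delta=0.6, neural=0.3, tritan=True)


@pytest.fixture
def refractive_observer():
    return make_archetype("refractive", refractive=0.3)


def grid_deltas(step=0.3, max_disparity=1.8):
    k = round(max_disparity / step)
    return [round(i * step, 10) for i in range(-k, k + 1)]


def observer_with_attenuation(delta, noise=0.0):
    """Observer whose interocular attenuation (OS - OD) equals ``delta``."""
    eye = "OS" if delta >= 0 else "OD"
    obs = make_archetype("amblyope", delta=abs(delta), neural=0.0, eye=eye)
    obs.decision_noise = noise
    return obs
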