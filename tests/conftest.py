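import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from rsvphase import RsvSegment, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def spring_config():
    """Baseline spring-transition world: fully social-clock-driven rhythm."""
    return SimulationConfig(season="spring", transition_year=2018, seed=42)


def make_segment(values, start="2018-03-10 00:00", term="insomnia", geo="IT"):
    return RsvSegment(term=term, geo=geo, start=start, values=np.asarray(values))


def cosine_day(mesor=10.0, amplitude=3.0, acrophase=5.0, noise_sd=0.0, rng=None):
    t = np.arange(24.0)
    y = mesor + amplitude * np.cos(2.0 * np.pi * (t - acrophase) / 24.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=24)
    return y
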