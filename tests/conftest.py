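from datetime import date

import pytest

from appersist.exposure import DispensingClaim, EpisodeRules
from appersist.simulate import SimulationConfig

D0 = date(2011, 6, 1)  # a convenient index date inside the study window


def day(n: int) -> date:
    """Day-offset helper anchored at D0."""
    return date.fromordinal(D0.toordinal() + n)


def claim(offset: int, supply: int, drug: str = "AP01", pid: str = "p1") -> DispensingClaim:
    return DispensingClaim(pid, day(offset), drug, supply)


@pytest.fixture
def rules() -> EpisodeRules:
    return EpisodeRules()


@pytest.fixture
def small_config() -> SimulationConfig:
    """A small but fully featured synthetic world."""
    return SimulationConfig(seed=42, n_residents=800, n_facilities=40)
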