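import numpy as np
import pytest

from allohex.simulate import HEEvent, SimConfig, simulate_progenitors
from allohex.synteny import LiftoverChain


PLANTED_EVENTS = [
    HEEvent("replacement", "S", 1, 200_000, 100_000),
    HEEvent("replacement", "D", 1, 600_000, 200_000),
    HEEvent("replacement", "S", 2, 100_000, 60_000),
    # sub-threshold events: must never be called
    HEEvent("replacement", "S", 2, 400_000, 30_000),
    HEEvent("replacement", "D", 2, 800_000, 50_000),
]


@pytest.fixture(scope="session")
def planted_config() -> SimConfig:
    """Two subgenomes x two 2 Mb chromosomes with five planted events."""
    return SimConfig(seed=20_260_922, he_events=list(PLANTED_EVENTS))


@pytest.fixture(scope="session")
def progenitor_chain(planted_config) -> LiftoverChain:
    prog = simulate_progenitors(planted_config)
    return LiftoverChain.from_anchors(prog.anchors)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
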