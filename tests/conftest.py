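import pytest

from prfmap import (
    CarrierConfig,
    HRFParams,
    StimulusDesign,
    bar_sequence,
    photic_sequence,
    wedge_ring_sequence,
)


@pytest.fixture(scope="session")
def cfg9() -> CarrierConfig:
    """Small-display config at modest resolution, shared across tests."""
    return CarrierConfig(max_eccentricity_deg=9.0, pixels_per_degree=2.0)


@pytest.fixture(scope="session")
def design() -> StimulusDesign:
    return StimulusDesign()


@pytest.fixture(scope="session")
def hrf() -> HRFParams:
    return HRFParams(dt=2.55)


@pytest.fixture(scope="session")
def bar_run(cfg9, design):
    return bar_sequence(0, 1, False, design, cfg9)


@pytest.fixture(scope="session")
def bar_runs(cfg9, design):
    return [bar_sequence(0, 1, False, design, cfg9), bar_sequence(45, 1, False, design, cfg9)]


@pytest.fixture(scope="session")
def wedge_ring_runs(cfg9, design):
    return [
        wedge_ring_sequence("cw_expand", design, cfg9),
        wedge_ring_sequence("ccw_contract", design, cfg9),
    ]


@pytest.fixture(scope="session")
def photic_run_seq(cfg9):
    return photic_sequence(cfg9)
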