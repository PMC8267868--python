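import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vwisim.bloch import CSF, VESSEL_WALL
from vwisim.presets import load_presets
from vwisim.sequence import simulate_preset_suite


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def steady_table():
    """Steady-state (10-rep) signal table of the three T2-weighted presets
    for CSF and vessel wall; shared because schedule design dominates cost."""
    return simulate_preset_suite(n_reps=10)


@pytest.fixture(scope="session")
def signal(steady_table):
    def look(sequence: str, tissue: str) -> float:
        row = steady_table[
            (steady_table["sequence"] == sequence) & (steady_table["tissue"] == tissue)
        ]
        assert len(row) == 1
        return float(row["signal"].iloc[0])

    return look


@pytest.fixture
def csf():
    return CSF


@pytest.fixture
def vessel_wall():
    return VESSEL_WALL
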