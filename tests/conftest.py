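import numpy as np
import pytest

from pitcalc.protocol import build_protocol, default_protocol
from pitcalc.scenarios import (
    TUMOR2_FRACTIONS,
    TUMOR4_FRACTIONS,
    TUMOR8_FRACTIONS,
    make_scenario_spec,
    run_recovery,
)


@pytest.fixture(scope="session")
def compressed_protocol():
    """Reference protocol with washes compressed 10x (fast experiments)."""
    return default_protocol(compress=10)


@pytest.fixture(scope="session")
def tiny_protocol():
    """Minimal two-stimulus protocol for cheap unit tests."""
    return build_protocol(["GnRH", "TRH"], baseline_s=60.0, pulse_s=10.0, wash_s=20.0, frame_interval_s=0.2)


@pytest.fixture(scope="session")
def tumor2_recovery():
    """Full-pipeline recovery on the tumor-2-like scenario (500 viable cells)."""
    return run_recovery(make_scenario_spec(TUMOR2_FRACTIONS, n_cells=500, seed=1), tumor_id="tumor2_like")


@pytest.fixture(scope="session")
def tumor8_recovery():
    return run_recovery(make_scenario_spec(TUMOR8_FRACTIONS, n_cells=500, seed=1), tumor_id="tumor8_like")


@pytest.fixture(scope="session")
def tumor4_recovery():
    return run_recovery(make_scenario_spec(TUMOR4_FRACTIONS, n_cells=500, seed=1), tumor_id="tumor4_like")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
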