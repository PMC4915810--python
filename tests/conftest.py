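import numpy as np
import pytest
from hypothesis import settings

from vmtask import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gp_session():
    """One short trained-mouse session shared by read-only tests."""
    cfg = sd.preset_config("good_performer", "S2-p",
                           session_duration_s=120.0)
    session, truth = sd.generate_session(
        cfg, 7, meta={"mouse_id": "m00", "cell_id": "c00",
                      "projection_target": "S2-p",
                      "group": "good_performer"})
    return session, truth, cfg
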