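import numpy as np
import pytest

from ratplm import GroupPreset, Hypnogram


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_hypnogram(stages, epoch_s=10.0, **kw):
    return Hypnogram(epoch_length=epoch_s, stages=np.array(stages, dtype=object), **kw)


@pytest.fixture
def tiny_hypnogram():
    return make_hypnogram(["QW", "QW", "SWS", "SWS", "SWS", "REM"])


def small_preset(**overrides):
    """A fast low-rate preset for unit tests (2-h recordings by default)."""
    base = dict(
        name="test",
        group="T",
        hct_mean=45.0,
        hct_sd=1.0,
        stage_percent={"Wake": 49.7, "SWS": 45.6, "REM": 4.7},
        bout_min={"Wake": 1.41, "SWS": 1.28, "REM": 1.21},
        plms_rate=30.0,
        ilms_rate=10.0,
        plmw_prob_nonzero=0.0,
        plmw_nonzero_mean=0.0,
        plmw_nonzero_sd=0.0,
        duration_h=2.0,
    )
    base.update(overrides)
    return GroupPreset(**base)
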