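import numpy as np
import pytest

from abneuro.calcium_traces import DualChannelTrace, RatioTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ratio_trace(ratio, frame_rate_hz=10.0, **kw):
    """RatioTrace from raw values with uniform sampling."""
    ratio = np.asarray(ratio, dtype=float)
    t = np.arange(len(ratio)) / frame_rate_hz
    return RatioTrace(t=t, ratio=ratio, frame_rate_hz=frame_rate_hz, **kw)


def make_dual_trace(ratio, frame_rate_hz=10.0, cer_corr=100.0, cer_bg=30.0, ven_bg=25.0):
    """Two-channel trace whose computed ratio equals ``ratio`` exactly."""
    ratio = np.asarray(ratio, dtype=float)
    t = np.arange(len(ratio)) / frame_rate_hz
    n = len(ratio)
    return DualChannelTrace(
        t=t,
        F_ven_soma=np.full(n, ven_bg) + ratio * cer_corr,
        F_ven_bg=np.full(n, ven_bg),
        F_cer_soma=np.full(n, cer_bg + cer_corr),
        F_cer_bg=np.full(n, cer_bg),
        frame_rate_hz=frame_rate_hz,
    )
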