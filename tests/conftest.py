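import numpy as np
import pytest

from balancemocap.sync_io import RawStream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_imu_stream(device_id: str, t: np.ndarray, **overrides) -> RawStream:
    """IMU stream at rest (gravity on z, field on y) unless overridden."""
    n = t.size
    ch = {
        "ax": np.zeros(n), "ay": np.zeros(n), "az": np.full(n, 9.81),
        "gx": np.zeros(n), "gy": np.zeros(n), "gz": np.zeros(n),
        "mx": np.zeros(n), "my": np.ones(n), "mz": np.zeros(n),
    }
    ch.update(overrides)
    return RawStream(device_id, t, ch)
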