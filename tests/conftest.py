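import numpy as np
import pytest

from adlhub import (
    CHANNELS,
    MultiChannelSeries,
    default_catalog,
    default_ranges,
    default_signatures,
    default_thresholds,
    default_weight_table,
)


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def ranges():
    return default_ranges()


@pytest.fixture(scope="session")
def weight_table():
    return default_weight_table()


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


def make_series(t, value_fn=None, sampling_interval=1.0):
    """Series with identical timestamps on every channel.

    ``value_fn(channel_index, t_array) -> values``; defaults to t itself.
    """
    t = np.asarray(t, dtype=float)
    data = {}
    for k, ch in enumerate(CHANNELS):
        v = t.copy() if value_fn is None else np.asarray(value_fn(k, t), dtype=float)
        data[ch] = (t, v)
    return MultiChannelSeries(data, sampling_interval=sampling_interval)
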