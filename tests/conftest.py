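import numpy as np
import pytest

from somnoseg import PsgPreprocessor, SimConfig, build_labels, make_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_cfg():
    """A 5-minute night: long enough for epochs, bouts and one window."""
    return SimConfig(duration_s=300.0, seed=3)


@pytest.fixture(scope="session")
def tiny_nights(short_cfg):
    """Six short synthetic nights, preprocessed, with modified labels."""
    nights = make_dataset(6, short_cfg, seed=11)
    pre = PsgPreprocessor()
    recs = [pre.transform_record(n.record) for n in nights]
    labels = [build_labels(n.epochs, n.arousals, "modified") for n in nights]
    return nights, recs, labels
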