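import numpy as np
import pytest

from pirnaspread import simulate
from pirnaspread.reference import Segment, TranscriptModel, build_transgene


@pytest.fixture(scope="session")
def sensor_construct():
    return simulate.make_sensor_construct()


@pytest.fixture(scope="session")
def sensor_refs(sensor_construct):
    return simulate.sensor_reference_set(sensor_construct)


@pytest.fixture
def small_transcript():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    return TranscriptModel.from_sequence("t1", seq)


@pytest.fixture
def tiny_construct():
    return build_transgene("mini", [
        Segment("cds", "coding", "ATGGCCATTGTAATGGGCCGCT"),
        Segment("norm", "normalizer", "CCGGAATTCCGGAATTCCGG"),
        Segment("utr", "utr", "TTTTAAAACCCCGGGG"),
    ])


@pytest.fixture(scope="session")
def shallow_cfg():
    # shallow libraries keep unit tests fast; statistical checks that need
    # depth use their own configs
    return simulate.SimConfig(seed=11, depth=20_000)
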