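import numpy as np
import pytest

from m5cboost.encoders import EncoderConfig, encode_all, train_embedding
from m5cboost.sequence_io import RnaSegment, SegmentSet
from m5cboost.synthetic import SyntheticSpec, generate

ALPHABET = "ACGU"


def random_segment(rng, length: int = 41, seg_id: str = "s") -> RnaSegment:
    """A uniformly random valid segment with the center fixed to C."""
    chars = [ALPHABET[i] for i in rng.integers(0, 4, size=length)]
    chars[length // 2] = "C"
    return RnaSegment(seg_id, "".join(chars), length // 2 + 1)


def random_segment_set(rng, n: int, length: int = 41) -> SegmentSet:
    return SegmentSet(
        random_segment(rng, length, f"s{i}") for i in range(n)
    )


@pytest.fixture(scope="session")
def small_labeled_set() -> SegmentSet:
    """20+20 planted-signal segments used across the unit suite."""
    return generate(SyntheticSpec(n_pos=20, n_neg=20, effect=0.5, seed=101))


@pytest.fixture(scope="session")
def small_embedding(small_labeled_set):
    return train_embedding(small_labeled_set, EncoderConfig(), seed=77)


@pytest.fixture(scope="session")
def small_matrix(small_labeled_set, small_embedding):
    return encode_all(small_labeled_set, EncoderConfig(), model=small_embedding)


@pytest.fixture(scope="session")
def separable_toy():
    """A linearly separable two-feature problem for classifier contracts."""
    rng = np.random.default_rng(9)
    n = 60
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 2.0, -2.0)
    return X, y
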