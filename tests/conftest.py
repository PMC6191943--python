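import numpy as np
import pytest

import histoquant as hq
from histoquant.features import compute_feature_planes
from histoquant.synthetic import annotations_from_samples
from histoquant.training import assemble


@pytest.fixture(scope="session")
def train_section() -> hq.SectionSample:
    return hq.generate_section(hq.SyntheticSpec(seed=100))


@pytest.fixture(scope="session")
def test_section() -> hq.SectionSample:
    return hq.generate_section(hq.SyntheticSpec(seed=200))


@pytest.fixture(scope="session")
def trained_cascade(train_section) -> hq.CascadeModel:
    """A cascade trained on one synthetic section's annotations."""
    ann = annotations_from_samples({"train.png": train_section}, seed=0)
    planes = {"train.png": compute_feature_planes(train_section.image)}
    ts = assemble(ann, planes)
    return hq.train_cascade(ts, seed=0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def dice_fn():
    return dice
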