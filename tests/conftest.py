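import numpy as np
import pytest
from hypothesis import settings

from froghop import ExpressionDataset, FixtureSpec, generate

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_dataset(values, labels, discrete_mask=None, names=None) -> ExpressionDataset:
    """Small hand-built dataset with auto-generated names."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionDataset(
        values=values,
        labels=np.asarray(labels),
        feature_names=names or [f"f{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
        positive_label="case",
        negative_label="control",
        discrete_mask=discrete_mask,
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Cheap ground-truth dataset: 40 samples, 60 features, 4 informative."""
    spec = FixtureSpec(
        n_samples=40,
        n_features=60,
        n_informative=4,
        n_redundant=4,
        class_balance=0.4,
        effect_size=2.0,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def standard_fixture():
    """The reference recovery fixture: 60 x 500, 5 informative, 10 redundant."""
    return generate(FixtureSpec(seed=1))
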