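import numpy as np
import pytest

from anodet import GeneratorConfig, HealthTensor, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_tensor(rng):
    """A fully observed 4 x 3 x 5 tensor with irregular values."""
    values = rng.normal(0.0, 2.0, size=(4, 3, 5))
    return HealthTensor(
        [f"s{i}" for i in range(1, 5)],
        [f"c{j}" for j in range(1, 4)],
        values,
    )


@pytest.fixture
def masked_tensor(rng):
    """A 5 x 3 x 6 tensor with ~15% of entries unobserved.

    The mask keeps every student, criterion and the final time index
    observed somewhere so a long-CSV round trip is exact.
    """
    values = rng.normal(0.0, 2.0, size=(5, 3, 6))
    while True:
        mask = rng.random((5, 3, 6)) > 0.15
        if (
            mask.any(axis=(1, 2)).all()
            and mask.any(axis=(0, 2)).all()
            and mask[:, :, -1].any()
        ):
            break
    return HealthTensor(
        [f"s{i}" for i in range(1, 6)],
        [f"c{j}" for j in range(1, 4)],
        values,
        mask,
    )


@pytest.fixture
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=7))
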