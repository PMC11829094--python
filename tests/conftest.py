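import numpy as np
import pytest

from fourierlogit import (
    CoefficientSet,
    OscillationCombo,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def cosine_spec():
    """Strong cosine signal on two predictors, true combo (2, 1)."""
    return SyntheticSpec(
        n=600,
        true_combo=OscillationCombo((2, 1)),
        true_beta=CoefficientSet(
            0.5,
            np.array([0.3, -0.2]),
            (np.array([2.0, -1.5]), np.array([1.8])),
        ),
        seed=103,
    )


@pytest.fixture
def cosine_dataset(cosine_spec):
    return generate_dataset(cosine_spec)


@pytest.fixture
def linear_dataset():
    spec = SyntheticSpec(
        n=500,
        true_combo=OscillationCombo((0, 0)),
        true_beta=CoefficientSet(1.0, np.array([0.8, -0.5]), (np.zeros(0), np.zeros(0))),
        seed=102,
    )
    return generate_dataset(spec)


def random_design(rng, n, combo):
    """Design on uniform [0, 2pi] predictors for a given combo."""
    from fourierlogit import build_design

    X = rng.uniform(0.0, 2.0 * np.pi, size=(n, len(combo)))
    return build_design(X, combo)


@pytest.fixture
def small_problem(rng):
    """n=20, m=5 cosine design with a balanced response: finite-difference scale."""
    from fourierlogit import build_design

    X = rng.uniform(0.0, 2.0 * np.pi, size=(20, 2))
    Z = build_design(X, (1, 1))
    y = np.array([0, 1] * 10)
    return Z, y
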