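import numpy as np
import pytest

import ctadose as cd


@pytest.fixture(scope="session")
def reference_model() -> cd.ModelArtifact:
    return cd.load_reference_model()


@pytest.fixture
def age_bounds() -> cd.FactorBounds:
    return cd.FactorBounds("age", 24, 90)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """450 synthetic patients whose responses are exactly the reference model."""
    spec = cd.derivation_cohort_spec(seed=20250920, residual_sd=0.0)
    return spec, cd.generate_cohort(spec)


def random_full_rank_problem(rng: np.random.Generator, n: int):
    """A random design with a known coefficient vector and noisy response."""
    V = rng.uniform(-1.0, 1.0, size=(n, 7))
    X = cd.design_matrix(V)
    a_true = rng.normal(scale=1.0, size=29)
    y = X @ a_true + rng.normal(scale=0.05, size=n)
    return X, y, a_true


def normal_equations_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent brute-force least squares via the explicit dense inverse."""
    return np.linalg.inv(X.T @ X) @ X.T @ y
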