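import numpy as np
import pytest

from fermrsm import QuadraticModel
from fermrsm.reference import FACTORS, REFERENCE_MODEL, reference_design


@pytest.fixture(scope="session")
def ref_model() -> QuadraticModel:
    """The built-in four-factor worked-example model."""
    return REFERENCE_MODEL


@pytest.fixture(scope="session")
def ref_factors():
    return FACTORS


@pytest.fixture(scope="session")
def ref_design():
    return reference_design()


def random_quadratic(rng: np.random.Generator, k: int) -> QuadraticModel:
    """A random full quadratic model with O(1) coefficients."""
    inter = np.triu(rng.normal(size=(k, k)), 1)
    return QuadraticModel(
        factors=[f"x{i + 1}" for i in range(k)],
        intercept=float(rng.normal()),
        linear=rng.normal(size=k),
        quadratic=rng.normal(size=k),
        interaction=inter + inter.T,
    )
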