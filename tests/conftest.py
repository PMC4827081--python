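import numpy as np
import pytest

from cohsh.models import (DiabaticModel, build_model1, build_model2,
                          build_model3, build_model4)


def _zero(x):
    return np.zeros_like(np.asarray(x, dtype=float))


@pytest.fixture(scope="session")
def model1():
    return build_model1()


@pytest.fixture(scope="session")
def model2():
    return build_model2()


@pytest.fixture(scope="session")
def model3():
    return build_model3()


@pytest.fixture(scope="session")
def model4():
    return build_model4()


@pytest.fixture(scope="session")
def all_models(model1, model2, model3, model4):
    return [model1, model2, model3, model4]


@pytest.fixture(scope="session")
def free_particle():
    """V identically zero: transmission must be exactly 1."""
    return DiabaticModel("free", _zero, _zero, _zero, _zero, _zero, _zero,
                         asym_left=(0.0, 0.0), asym_right=(0.0, 0.0))


@pytest.fixture(scope="session")
def gap_no_coupling():
    """Uncoupled two-level model with a position-dependent gap.

    V11 = 0, V22 = 0.03 + 0.01 tanh(x), V12 = 0: populations must freeze
    and the coherence phase must follow the quadrature of the gap.
    """

    def v22(x):
        return 0.03 + 0.01 * np.tanh(np.asarray(x, dtype=float))

    def dv22(x):
        return 0.01 / np.cosh(np.asarray(x, dtype=float)) ** 2

    return DiabaticModel("gap-only", _zero, v22, _zero, _zero, dv22, _zero,
                         asym_left=(0.0, 0.02), asym_right=(0.0, 0.04))
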