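import io

import numpy as np
import pytest

from loam import AgreementData, sums_of_squares, variance_components

TOY_VALUES = np.array([[1.0, 2.0], [3.0, 5.0]])  # 2 subjects x 2 observers, c=1

TOY_CSV = """subject,observer,value
s1,r1,1
s1,r2,2
s2,r1,3
s2,r2,5
"""


@pytest.fixture
def toy_data():
    return AgreementData(TOY_VALUES, ("s1", "s2"), ("r1", "r2"))


@pytest.fixture
def toy_ss(toy_data):
    return sums_of_squares(toy_data)


@pytest.fixture
def toy_vc(toy_ss):
    return variance_components(toy_ss)


@pytest.fixture
def toy_csv_stream():
    return io.StringIO(TOY_CSV)


def random_balanced_values(rng, a=None, b=None, c=None):
    """Random (a, b, c) array with genuine subject/observer/noise structure."""
    a = a or rng.integers(2, 8)
    b = b or rng.integers(2, 8)
    c = c or rng.integers(1, 4)
    return (
        rng.normal(0, 2, size=(a, 1, 1))
        + rng.normal(0, 1, size=(1, b, 1))
        + rng.normal(0, 0.5, size=(a, b, c))
    )
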