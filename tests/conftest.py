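import numpy as np
import pytest

from fermkin import datasets, doe


@pytest.fixture(scope="session")
def table1():
    return datasets.load_builtin("table1")


@pytest.fixture(scope="session")
def table3():
    return datasets.load_builtin("table3")


@pytest.fixture(scope="session")
def table7():
    return datasets.load_builtin("table7")


@pytest.fixture(scope="session")
def bbd_design():
    return doe.box_behnken(
        {"glucose": (10.0, 20.0, 30.0),
         "peptone": (20.0, 40.0, 60.0),
         "corn_juice": (4.0, 8.0, 12.0)},
        center_runs=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
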