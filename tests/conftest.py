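import numpy as np
import pytest

from addint.datasets import load_oral_cancer


@pytest.fixture(scope="session")
def oral_table():
    return load_oral_cancer()


@pytest.fixture(scope="session")
def oral_subjects(oral_table):
    return oral_table.to_subject_data()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
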