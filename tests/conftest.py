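import numpy as np
import pytest

from cysadc.assignment import build_library
from cysadc.conjugate_model import dissociate, enumerate_isoforms
from cysadc.synthetic_data import reference_igg1_assembly


@pytest.fixture(scope="session")
def assembly():
    return reference_igg1_assembly()


@pytest.fixture(scope="session")
def isoforms(assembly):
    return {c.label: c for c in enumerate_isoforms(assembly)}


@pytest.fixture(scope="session")
def signatures(assembly, isoforms):
    return {
        label: dissociate(iso, assembly, glycoform="G0F") for label, iso in isoforms.items()
    }


@pytest.fixture(scope="session")
def library(assembly):
    return build_library(assembly)


@pytest.fixture
def rng():
    return np.random.default_rng(20151083)
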