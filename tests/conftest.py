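import pytest

from lipidshift.annotation import build_ion_index, load_rt_windows
from lipidshift.lipid_model import DEFAULT_ADDUCTS, expand_class, load_class_definitions
from lipidshift.quantification import load_internal_standards


@pytest.fixture(scope="session")
def class_defs():
    return load_class_definitions()


@pytest.fixture(scope="session")
def is_table():
    return load_internal_standards()


@pytest.fixture(scope="session")
def rt_windows():
    return load_rt_windows()


@pytest.fixture(scope="session")
def full_database(class_defs):
    return [sp for cdef in class_defs.values() for sp in expand_class(cdef)]


@pytest.fixture(scope="session")
def ion_index(full_database):
    return build_ion_index(full_database, DEFAULT_ADDUCTS)
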