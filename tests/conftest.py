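import numpy as np
import pytest

from gammatail import Peptide, load_builtin, make_basis


@pytest.fixture(scope="session")
def helix_scale():
    return load_builtin("helix_chou_fasman")


@pytest.fixture(scope="session")
def sheet_scale():
    return load_builtin("sheet_chou_fasman")


@pytest.fixture(scope="session")
def disorder_scale():
    return load_builtin("disorder_top_idp")


@pytest.fixture(scope="session")
def hydropathy_scale():
    return load_builtin("hydropathy_kyte_doolittle")


@pytest.fixture(scope="session")
def default_basis():
    return make_basis(np.arange(190.0, 250.5, 0.5))


@pytest.fixture(scope="session")
def counting_scorer():
    """Toy helix scorer: percentage of alanines. Total and deterministic."""
    return lambda p: 100.0 * p.sequence.count("A") / len(p)


@pytest.fixture
def aeal16():
    return Peptide("aeal16", "AEAL" * 4)
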