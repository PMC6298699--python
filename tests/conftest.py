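import numpy as np
import pytest
from hypothesis import settings

from methyltarget import build_plasmid, get_condition, make_truth

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_plasmid():
    """600 bp plasmid with 8 non-target CpG dyads, target at gap 11."""
    return build_plasmid(length=600, n_nontarget_cpg=8, gap=11, seed=7)


@pytest.fixture(scope="session")
def linker15():
    return get_condition("linker15")


@pytest.fixture(scope="session")
def linker4():
    return get_condition("linker4")


@pytest.fixture(scope="session")
def small_truth(small_plasmid, linker15):
    return make_truth(small_plasmid, linker15, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
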