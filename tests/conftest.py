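import pytest

from karyocna import rat1
from karyocna.simdata import SimConfig


@pytest.fixture(scope="session")
def rat1_model():
    return rat1.karyotype_model()


@pytest.fixture(scope="session")
def rat1_map():
    return rat1.cytobands()


@pytest.fixture(scope="session")
def rat1_policy():
    return rat1.policy()


@pytest.fixture(scope="session")
def rat1_rule():
    return rat1.overrides()


@pytest.fixture(scope="session")
def rat1_regions():
    return rat1.cna_regions()


@pytest.fixture(scope="session")
def small_cfg():
    """A lighter genome than the default for quick property loops."""
    return SimConfig(n_autosomes=6, min_chrom_len=50_000,
                     max_chrom_len=200_000, n_translocations=1,
                     n_supernumerary=1)
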