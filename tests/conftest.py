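import pytest

from abdev.cli import default_plant
from abdev.design import FvContext
from abdev.synth import SynthConfig, make_case


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, n_germlines=6, domain_length=110, mutation_rate=0.05)


@pytest.fixture(scope="session")
def default_case(small_config):
    """A fully planted fixture: PTM motifs, hydrophobic CDR residues,
    framework charge surplus, germline deviation, epitope core."""
    return make_case(small_config, default_plant(11))


@pytest.fixture(scope="session")
def default_context(default_case):
    return FvContext(
        fv=default_case.fv,
        germline_sets=default_case.germlines,
        pssms=list(default_case.pssms),
    )
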