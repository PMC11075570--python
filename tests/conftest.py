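import pytest
from hypothesis import settings

from morfin import design_amplicon, fixtures

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_plasmid():
    """300-bp circular plasmid carrying a 150-bp + strand ORF."""
    return fixtures.synth_plasmid(11, backbone_len=150, orf_len=150, label="toy")


@pytest.fixture(scope="session")
def toy_fp_orf():
    return fixtures.synth_fp_orf(12, aa_len=20)


@pytest.fixture(scope="session")
def toy_amplicon(toy_fp_orf):
    return design_amplicon(toy_fp_orf, "none", fp_name="toyFP")


@pytest.fixture(scope="session")
def efg_plasmid():
    """Worked-example geometry: 2,109-bp target ORF on a 6,837-bp plasmid."""
    return fixtures.synth_plasmid(0, backbone_len=4728, orf_len=2109, label="EFG")


@pytest.fixture(scope="session")
def efg_fp_orf():
    return fixtures.synth_fp_orf(1, aa_len=238)


@pytest.fixture(scope="session")
def efg_amplicon(efg_fp_orf):
    return design_amplicon(efg_fp_orf, "none", fp_name="synthGFP")
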