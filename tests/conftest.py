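from pathlib import Path

import pytest

from bsascan.vcf_io import SampleRoles

DATA = Path(__file__).parent / "data"


@pytest.fixture
def toy_vcf() -> Path:
    return DATA / "toy.vcf"


@pytest.fixture
def toy_expected() -> Path:
    return DATA / "toy.expected.tsv"


@pytest.fixture
def two_bulk_roles() -> SampleRoles:
    return SampleRoles(parent="PARENT", bulk1="BULK1", bulk2="BULK2")


@pytest.fixture
def one_bulk_roles() -> SampleRoles:
    return SampleRoles(parent="PARENT", bulk1="BULK1")


@pytest.fixture(scope="session")
def small_synth_vcf(tmp_path_factory):
    """A small one-bulk synthetic VCF shared by pipeline/CLI tests."""
    from bsascan.synthetic_data import default_scenario, write_scenario

    d = tmp_path_factory.mktemp("synth")
    vcf, truth = d / "synth.vcf", d / "truth.tsv"
    write_scenario(default_scenario(seed=42, n_variants=400), str(vcf), str(truth))
    return vcf
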