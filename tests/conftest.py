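import pytest

from idrscape.simulate import FamilySpec, generate_family


@pytest.fixture(scope="session")
def default_family():
    """The packaged default synthetic family (4 subgroups x 6 members)."""
    return generate_family(FamilySpec(seed=1))


@pytest.fixture(scope="session")
def family_paths(default_family, tmp_path_factory):
    """Default family written to disk as pipeline input files."""
    outdir = tmp_path_factory.mktemp("family")
    return default_family.write(outdir), outdir
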