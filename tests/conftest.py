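import pytest

from plasmidkit import synth


@pytest.fixture(scope="session")
def small_spec() -> synth.CommunitySpec:
    """Scaled-down host+plasmid community used across module tests."""
    return synth.CommunitySpec(
        seed=11,
        host_length=60_000,
        plasmid_length=30_000,
        host_depth=30.0,
        copy_ratio=1.0,
        n_genes_plasmid=30,
        n_genes_host=60,
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    return synth.generate_community(small_spec)
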