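import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# The 27-nt inverted repeat bounding the invertible capsular-polysaccharide
# promoter region of B. uniformis DSM 6597, and its 174-nt spacer length.
CAPSULE_IR = "CGTCCATTAAACGAACGTTTAAAAAAC"
CAPSULE_SPACER_LEN = 174


@pytest.fixture
def capsule_ir():
    return CAPSULE_IR


@pytest.fixture
def reference_locus():
    """A synthetic reference locus built around the 27-nt repeat."""
    from invertiscan.simulate import make_reference_loci

    return make_reference_loci(
        seed=11, n_loci=1, ir_len=27, spacer_len=CAPSULE_SPACER_LEN,
        ir_seqs=[CAPSULE_IR],
    )[0]
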