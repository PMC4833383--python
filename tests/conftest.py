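import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "mirmotif",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mirmotif")


@pytest.fixture(scope="session")
def ccaat():
    from mirmotif import ccaat_matrix

    return ccaat_matrix()


@pytest.fixture(scope="session")
def policy():
    from mirmotif import default_policy

    return default_policy()


@pytest.fixture(scope="session")
def toy_genome():
    """Two 100-bp contigs with a recognisable landmark layout.

    chrA carries CCAAT at 1-based [61, 65] so a plus-strand locus there has
    the core as its 'pre-miRNA'; chrB is the reverse complement of chrA.
    """
    base = (
        "TGTAGCTAGCTTGCAGTCGGATCGTTCGAGTCGATGCTAGGATCGTTAGC"  # 1..50
        "AGTCGATGTACCAATGGTCGTAGCTGATCGTAGCTAGGTGCATGCTAGGA"  # 51..100
    )
    assert len(base) == 100 and base[60:65] == "CCAAT"
    from mirmotif.matrix import reverse_complement_str

    return {"chrA": base, "chrB": reverse_complement_str(base)}


@pytest.fixture()
def small_locus_set(tmp_path):
    """Deterministic synthetic locus set written to disk (scaled windows)."""
    from mirmotif.simulate import generate_locus_set

    out = tmp_path / "sim"
    genome, loci, truths = generate_locus_set(n_loci=8, seed=7, out_dir=out)
    return out, genome, loci, truths
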