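import pytest

from trioseg import GenomeRef, SimConfig, TranscriptModel, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """Default-scale synthetic universe (50 controls, 20 genes, 2000 variants)."""
    return simulate_bundle(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap bundle for exhaustive per-position checks."""
    return simulate_bundle(
        SimConfig(
            seed=5,
            n_genes=6,
            n_control_samples=12,
            n_same_breed_controls=3,
            n_background_variants=300,
            n_breed_private_variants=10,
            contig_length_bp=20_000,
        )
    )


def _toy_seq(cds_by_pos: dict, length: int = 200) -> str:
    """Background of 'C' with designed bases written at 1-based positions."""
    seq = ["C"] * length
    for pos, base in cds_by_pos.items():
        seq[pos - 1] = base
    return "".join(seq)


@pytest.fixture
def toy_plus_single():
    """+ strand, one CDS segment 101-109 coding ATG GAG TAA."""
    coding = "ATGGAGTAA"
    genome = GenomeRef({"c1": _toy_seq({101 + i: b for i, b in enumerate(coding)})})
    tx = TranscriptModel("txA", "GENEA", "c1", "+", [(101, 109)])
    return genome, tx


@pytest.fixture
def toy_plus_split():
    """+ strand, CDS split 101-103 + 107-112 coding ATG GAG TAA."""
    coding = "ATGGAGTAA"
    positions = [101, 102, 103, 107, 108, 109, 110, 111, 112]
    genome = GenomeRef({"c1": _toy_seq(dict(zip(positions, coding)))})
    tx = TranscriptModel("txB", "GENEB", "c1", "+", [(101, 103), (107, 112)])
    return genome, tx


@pytest.fixture
def toy_minus_single():
    """- strand, one CDS segment 101-109; genomic holds revcomp(ATG GAG TAA)."""
    genomic = "TTACTCCAT"  # reverse complement of ATGGAGTAA
    genome = GenomeRef({"c1": _toy_seq({101 + i: b for i, b in enumerate(genomic)})})
    tx = TranscriptModel("txC", "GENEC", "c1", "-", [(101, 109)])
    return genome, tx
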