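"""Consequence annotation: coordinate projection, codon arithmetic,
classification and the whole-ORF translation oracle."""

import pytest
from Bio.Seq import Seq

from trioseg import (
    DomainError,
    ReferenceMismatchError,
    VariantRecord,
    annotate_consequence,
    cds_to_genomic,
    codon_of,
    genomic_to_cds,
    is_protein_changing,
    truncation_fraction,
)
from trioseg.consequence import Consequence, PROTEIN_CHANGING_CLASSES

# ---------------------------------------------------------------------------
# genomic <-> CDS projection
# ---------------------------------------------------------------------------


def test_genomic_to_cds_plus_strand_first_base(toy_plus_single):
    _, tx = toy_plus_single
    assert genomic_to_cds(101, tx) == 1
    assert genomic_to_cds(109, tx) == 9
    assert genomic_to_cds(100, tx) is None
    assert genomic_to_cds(110, tx) is None


def test_genomic_to_cds_walks_exon_chain(toy_plus_split):
    # segments 101-103 and 107-112: genomic 107 is the 4th coding base
    _, tx = toy_plus_split
    assert genomic_to_cds(103, tx) == 3
    assert genomic_to_cds(107, tx) == 4
    assert genomic_to_cds(105, tx) is None  # intronic


def test_genomic_to_cds_minus_strand_reverse_walk(toy_minus_single):
    _, tx = toy_minus_single
    assert genomic_to_cds(109, tx) == 1
    assert genomic_to_cds(101, tx) == 9


def test_projection_is_a_bijection_on_synthetic_transcripts(small_bundle):
    for tx in small_bundle.transcripts:
        seen = set()
        for cds_pos in range(1, tx.cds_length + 1):
            g = cds_to_genomic(cds_pos, tx)
            assert genomic_to_cds(g, tx) == cds_pos
            seen.add(g)
        assert len(seen) == tx.cds_length


# ---------------------------------------------------------------------------
# codon arithmetic and truncation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cds_pos,expected",
    [(7195, (2399, 1)), (1, (1, 1)), (3, (1, 3)), (4, (2, 1))],
)
def test_codon_of(cds_pos, expected):
    assert codon_of(cds_pos) == expected


def test_codon_of_rejects_nonpositive():
    with pytest.raises(DomainError):
        codon_of(0)


def test_truncation_fraction_of_published_stop_gain():
    # premature stop at codon 2399 of a 4311-codon ORF removes >44% of it
    frac = truncation_fraction(2399, 4311)
    assert frac == pytest.approx(1913 / 4311)
    assert frac > 0.44


@pytest.mark.parametrize("total", [10, 500, 4311])
def test_truncation_fraction_boundaries(total):
    assert truncation_fraction(1, total) == 1.0
    assert truncation_fraction(total, total) == pytest.approx(1 / total)


def test_truncation_fraction_strictly_decreasing():
    values = [truncation_fraction(i, 50) for i in range(1, 51)]
    assert all(a > b for a, b in zip(values, values[1:]))
    with pytest.raises(DomainError):
        truncation_fraction(0, 50)
    with pytest.raises(DomainError):
        truncation_fraction(51, 50)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _snv(pos, ref, alt):
    return VariantRecord("c1", pos, ref, alt)


@pytest.mark.parametrize(
    "alt,effect,alt_aa",
    [("T", "stop_gain", "*"), ("A", "synonymous", "E"), ("T2", "missense", "V")],
    ids=["GAG>TAG", "GAG>GAA", "GAG>GTG"],
)
def test_snv_classification_on_glu_codon(toy_plus_single, alt, effect, alt_aa):
    genome, tx = toy_plus_single  # codon 2 is GAG (Glu) at genomic 104-106
    if alt == "T":
        variant = _snv(104, "G", "T")  # GAG -> TAG
    elif alt == "A":
        variant = _snv(106, "G", "A")  # GAG -> GAA
    else:
        variant = _snv(105, "A", "T")  # GAG -> GTG
    cons = annotate_consequence(variant, tx, genome)
    assert cons.effect_class == effect
    assert cons.codon_index == 2
    assert cons.ref_aa == "E" and cons.alt_aa == alt_aa
    if effect == "stop_gain":
        assert cons.truncation_fraction == pytest.approx(2 / 3)
    else:
        assert cons.truncation_fraction is None


def test_stop_gain_on_minus_strand_transcript(toy_minus_single):
    genome, tx = toy_minus_single  # coding GAG codon at c.4-6 = genomic 106-104
    # coding-strand change G>T at c.4 is genomic C>A at position 106
    variant = _snv(106, "C", "A")
    cons = annotate_consequence(variant, tx, genome)
    assert cons.effect_class == "stop_gain"
    assert cons.cds_pos == 4
    assert cons.ref_codon == "GAG" and cons.alt_codon == "TAG"


def test_start_loss_and_stop_loss(toy_plus_single):
    genome, tx = toy_plus_single
    start = annotate_consequence(_snv(102, "T", "C"), tx, genome)  # ATG -> ACG
    assert start.effect_class == "start_loss"
    stop = annotate_consequence(_snv(108, "A", "C"), tx, genome)  # TAA -> TCA
    assert stop.effect_class == "stop_loss"
    silent_stop = annotate_consequence(_snv(109, "A", "G"), tx, genome)  # TAA -> TAG
    assert silent_stop.effect_class == "synonymous"


def test_splice_site_window_around_internal_junction(toy_plus_split):
    genome, tx = toy_plus_split  # intron 104-106
    for pos in (104, 105, 106):
        cons = annotate_consequence(_snv(pos, "C", "A"), tx, genome)
        assert cons.effect_class == "splice_site", pos
    outside = annotate_consequence(_snv(120, "C", "A"), tx, genome)
    assert outside.effect_class == "non_coding"


def test_indel_classification(toy_plus_single):
    genome, tx = toy_plus_single
    fs = annotate_consequence(VariantRecord("c1", 104, "G", "GT"), tx, genome)
    assert fs.effect_class == "frameshift"
    inframe = annotate_consequence(VariantRecord("c1", 103, "GGAG", "G"), tx, genome)
    assert inframe.effect_class == "inframe_indel"


def test_reference_mismatch_raises(toy_plus_single):
    genome, tx = toy_plus_single
    with pytest.raises(ReferenceMismatchError):
        annotate_consequence(_snv(104, "A", "T"), tx, genome)


def test_protein_changing_membership():
    for effect in PROTEIN_CHANGING_CLASSES:
        kwargs = {"truncation_fraction": 0.5} if effect == "stop_gain" else {}
        assert is_protein_changing(Consequence("tx", effect, **kwargs))
    assert not is_protein_changing(Consequence("tx", "synonymous"))
    assert not is_protein_changing(Consequence("tx", "non_coding"))


# ---------------------------------------------------------------------------
# whole-ORF translation oracle
# ---------------------------------------------------------------------------


def _cds_string(tx, genome) -> str:
    """Independent CDS reconstruction by slicing + Bio.Seq revcomp."""
    parts = [genome.slice(tx.contig, s, e) for s, e in tx.cds_segments]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def test_annotation_matches_whole_orf_translation_oracle(small_bundle):
    """For every CDS position and all 3 alternative bases, the codon-wise
    annotation equals a brute-force full-ORF substitution + translation."""
    genome = small_bundle.genome
    comp = str.maketrans("ACGT", "TGCA")
    for tx in small_bundle.transcripts:
        cds = _cds_string(tx, genome)
        protein = str(Seq(cds).translate())
        for cds_pos in range(1, tx.cds_length + 1):
            g_pos = cds_to_genomic(cds_pos, tx)
            g_ref = genome.base(tx.contig, g_pos)
            for g_alt in "ACGT":
                if g_alt == g_ref:
                    continue
                coding_alt = g_alt if tx.strand == "+" else g_alt.translate(comp)
                mutated = cds[: cds_pos - 1] + coding_alt + cds[cds_pos:]
                mutated_protein = str(Seq(mutated).translate())
                aa_idx = (cds_pos - 1) // 3
                cons = annotate_consequence(
                    VariantRecord(tx.contig, g_pos, g_ref, g_alt), tx, genome
                )
                assert cons.cds_pos == cds_pos
                assert cons.ref_aa == protein[aa_idx]
                assert cons.alt_aa == mutated_protein[aa_idx]
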