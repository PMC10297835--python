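"""Synthetic-data generator: determinism, transcript integrity, planted
variant, Mendelian structure and transmission statistics."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from trioseg import (
    ConfigurationError,
    GenomeRef,
    SimConfig,
    TranscriptModel,
    annotate_consequence,
    generate_genome,
    generate_transcripts,
    mendelian_consistent,
    plant_stop_gain,
    simulate_bundle,
    write_bundle,
)
from trioseg.consequence import complement


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(n_same_breed_controls=5, n_control_samples=2)
    with pytest.raises(ConfigurationError):
        SimConfig(penetrance=1.5)
    with pytest.raises(ConfigurationError):
        SimConfig(background_alt_freq=0.0)


def test_generate_genome_shapes_and_determinism():
    config = SimConfig(seed=3, n_contigs=2, contig_length_bp=10_000)
    g1 = generate_genome(config)
    g2 = generate_genome(config)
    assert list(g1.contigs) == ["chr1", "chr2"]
    assert all(len(seq) == 10_000 for seq in g1.contigs.values())
    assert g1.contigs == g2.contigs
    g3 = generate_genome(SimConfig(seed=4, n_contigs=2, contig_length_bp=10_000))
    assert g1.contigs != g3.contigs


def test_generated_transcripts_translate_to_clean_orfs():
    """Independent slicing + Bio.Seq translation: every CDS is Met...stop
    with exactly one stop, at the end."""
    config = SimConfig(seed=9)
    genome = generate_genome(config)
    transcripts = generate_transcripts(genome, config)
    assert len(transcripts) == config.n_genes
    assert {t.strand for t in transcripts} == {"+", "-"}
    for tx in transcripts:
        cds = "".join(genome.slice(tx.contig, s, e) for s, e in tx.cds_segments)
        if tx.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        assert cds.startswith("ATG")
        protein = str(Seq(cds).translate())
        assert protein.count("*") == 1 and protein.endswith("*")


def test_generate_transcripts_empty_and_overflow():
    config = SimConfig(seed=1, n_genes=0)
    genome = generate_genome(config)
    assert generate_transcripts(genome, config) == []
    cramped = SimConfig(seed=1, n_genes=50, n_contigs=1, contig_length_bp=2_000)
    genome = generate_genome(cramped)
    with pytest.raises(ConfigurationError):
        generate_transcripts(genome, cramped)


def test_plant_stop_gain_round_trips_through_annotation():
    config = SimConfig(seed=21, n_genes=8)
    genome = generate_genome(config)
    transcripts = generate_transcripts(genome, config)
    rng = np.random.default_rng(21)
    for tx in transcripts:
        variant, expected = plant_stop_gain(tx, genome, rng)
        cons = annotate_consequence(variant, tx, genome)
        assert cons.effect_class == "stop_gain"
        assert cons.codon_index == expected["codon_index"]
        assert cons.cds_pos == expected["cds_pos"]
        assert cons.ref_codon == expected["ref_codon"]
        assert cons.alt_codon == expected["alt_codon"]
        assert 2 <= cons.codon_index <= tx.n_codons - 1  # interior only


def test_plant_stop_gain_minus_strand_emits_reverse_complement_alleles():
    # coding ORF: ATG, GAA, nine Pro codons, TAA; GAA is the only interior
    # codon within one substitution of a stop (GAA -> TAA)
    coding = "ATG" + "GAA" + "CCC" * 9 + "TAA"
    genomic = str(Seq(coding).reverse_complement())
    seq = "C" * 100 + genomic + "C" * 100
    genome = GenomeRef({"c1": seq})
    tx = TranscriptModel("t", "G", "c1", "-", [(101, 100 + len(coding))])
    rng = np.random.default_rng(0)
    variant, expected = plant_stop_gain(tx, genome, rng)
    assert expected == {"cds_pos": 4, "codon_index": 2, "ref_codon": "GAA", "alt_codon": "TAA"}
    # 4th coding base, walking downstream from the segment's genomic end
    assert variant.pos == 100 + len(coding) - 3
    assert variant.ref == complement("G") and variant.alt == complement("T")


def test_bundle_determinism_byte_identical_vcf(tmp_path):
    config = SimConfig(
        seed=13, n_genes=5, n_control_samples=8, n_same_breed_controls=2,
        n_background_variants=120, n_breed_private_variants=5, contig_length_bp=15_000,
    )
    paths1 = write_bundle(simulate_bundle(config), tmp_path / "a")
    paths2 = write_bundle(simulate_bundle(config), tmp_path / "b")
    for key in ("vcf", "fasta", "gff3", "ped", "samples", "truth"):
        with open(paths1[key], "rb") as f1, open(paths2[key], "rb") as f2:
            assert f1.read() == f2.read(), key


def test_planted_site_trio_and_control_genotypes(default_bundle):
    truth = default_bundle.truth
    planted = next(
        r for r in default_bundle.records
        if r.site_key() == truth.planted_variant.site_key()
    )
    assert planted.gt("index") == (0, 1)
    assert planted.gt("father") == (0, 0) and planted.gt("mother") == (0, 0)
    controls = [s for s, role in default_bundle.panel.roles.items() if role == "control"]
    assert all(planted.gt(c) == (0, 0) for c in controls)
    assert "index" in truth.carrier_ids
    carriers_in_vcf = {s for s, g in planted.genotypes.items() if 1 in g}
    assert carriers_in_vcf == truth.carrier_ids


def test_full_penetrance_makes_phenotype_equal_carrier_status(default_bundle):
    truth = default_bundle.truth
    for ind in default_bundle.pedigree.individuals:
        expected = "affected" if ind.id in truth.carrier_ids else "unaffected"
        assert ind.phenotype == expected, ind.id


def test_mendelian_consistency_of_non_planted_family_genotypes(small_bundle):
    """Every offspring genotype at every non-planted site is composable from
    one allele of each parent (exhaustive rule)."""
    truth = small_bundle.truth
    special = {truth.planted_variant.site_key()}
    if truth.decoy_shared_site:
        special.add(truth.decoy_shared_site)
    if truth.decoy_synonymous_site:
        special.add(truth.decoy_synonymous_site)
    ped = small_bundle.pedigree
    children = [ind for ind in ped.individuals if ind.sire and ind.dam]
    for rec in small_bundle.records:
        for child in children:
            if child.id == "index" and rec.site_key() in special:
                continue  # the de novo / decoy events are planted in the index
            assert mendelian_consistent(
                rec.gt(child.id), rec.gt(child.sire), rec.gt(child.dam)
            ), (rec.site_key(), child.id)


def test_planted_pattern_is_exclusive_to_planted_site(default_bundle):
    """No background site shows proband-het / parents-and-controls-hom-ref
    while being protein-changing."""
    from trioseg.consequence import annotate_all, is_protein_changing

    truth = default_bundle.truth
    allowed = {truth.planted_variant.site_key(), truth.decoy_shared_site,
               truth.decoy_synonymous_site}
    controls = [s for s, role in default_bundle.panel.roles.items() if role == "control"]
    hits = []
    for rec in default_bundle.records:
        if rec.gt("index") != (0, 1):
            continue
        if rec.gt("father") != (0, 0) or rec.gt("mother") != (0, 0):
            continue
        if any(rec.gt(c) != (0, 0) for c in controls):
            continue
        conseqs = annotate_all(rec, default_bundle.transcripts, default_bundle.genome)
        if any(is_protein_changing(c) for c in conseqs):
            hits.append(rec.site_key())
    assert hits == [truth.planted_variant.site_key()]
    assert truth.decoy_synonymous_site not in hits  # rejected for being silent
    assert truth.decoy_shared_site not in hits  # rejected for the control carrier


def test_breed_private_variants_confined_to_same_breed_controls(small_bundle):
    from trioseg.synthetic_data import PROBAND_BREED

    panel = small_bundle.panel
    same_breed_controls = {
        s for s, role in panel.roles.items()
        if role == "control" and panel.breed_labels[s] == PROBAND_BREED
    }
    truth_sites = {small_bundle.truth.planted_variant.site_key(),
                   small_bundle.truth.decoy_shared_site,
                   small_bundle.truth.decoy_synonymous_site}
    n_private = 0
    for rec in small_bundle.records:
        carriers = {s for s, g in rec.genotypes.items() if 1 in g}
        if not carriers or rec.site_key() in truth_sites:
            continue
        if carriers <= same_breed_controls:
            n_private += 1
    assert n_private >= small_bundle.config.n_breed_private_variants


def test_offspring_transmission_fraction_near_half():
    """Binomial oracle: over 2000 offspring the planted-allele carrier
    fraction lies within 3 standard errors of 1/2."""
    config = SimConfig(
        seed=17, n_offspring=2000, n_sires=3, n_genes=4, n_control_samples=4,
        n_same_breed_controls=1, n_background_variants=40,
        n_breed_private_variants=4, contig_length_bp=12_000,
    )
    bundle = simulate_bundle(config)
    carriers = bundle.truth.carrier_ids - {"index"}
    fraction = len(carriers) / config.n_offspring
    se = 0.5 / math.sqrt(config.n_offspring)
    assert abs(fraction - 0.5) < 3 * se
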