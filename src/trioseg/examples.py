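"""Bundled worked example: a canine autosomal-dominant PKD family.

A published Lagotto Romagnolo family segregating autosomal dominant
polycystic kidney disease caused by a de novo *PKD1* nonsense variant,
chr6:39295382G>T (NM_001006650.1:c.7195G>T, NP_001006651.1:p.(Glu2399*)).
The genotyped family comprises the affected index female, her two
unaffected parents (the sequenced trio), the three sires of her two
litters, twelve genotyped offspring (six affected, six unaffected) and four
unaffected littermates of the index female.  The surrounding cohorts — 103
genotyped plus 26 sequenced unrelated Lagotto Romagnolo dogs and 931
sequenced dogs of other breeds — are all clear of the mutant allele.

Genotypes here reproduce the published association table so the
segregation machinery can be exercised on real numbers without any
sequencing data.
"""

from __future__ import annotations

from .io_formats import Individual, Pedigree, VariantRecord

PKD1_MRNA_ACCESSION = "NM_001006650.1"
PKD1_PROTEIN_ACCESSION = "NP_001006651.1"
PKD1_TOTAL_CODONS = 4311  # ORF codons including the terminal stop
PKD1_VARIANT_CDS_POS = 7195


def lagotto_adpkd_family():
    """Build the genotyped family, cohorts and the c.7195G>T site.

    Returns a dict with keys ``record`` (the variant with all genotypes),
    ``pedigree``, ``proband``, ``cohort_groups`` (unrelated group -> ids)
    and ``phenotypes``.
    """
    affected_offspring = [f"aff_off{i}" for i in range(1, 7)]
    unaffected_offspring = [f"unaff_off{i}" for i in range(1, 7)]
    littermates = [f"littermate{i}" for i in range(1, 5)]
    sires = [f"sire{i}" for i in range(1, 4)]

    individuals = [
        Individual("father", None, None, "male", "unaffected"),
        Individual("mother", None, None, "female", "unaffected"),
        Individual("index", "father", "mother", "female", "affected"),
    ]
    individuals += [Individual(s, None, None, "male", "unaffected") for s in sires]
    individuals += [
        Individual(lm, "father", "mother", "unknown", "unaffected") for lm in littermates
    ]
    # first litter by sire1; the second litter was dual-sired (sire2/sire3)
    litter_sires = ["sire1"] * 6 + ["sire2"] * 3 + ["sire3"] * 3
    offspring = affected_offspring + unaffected_offspring
    individuals += [
        Individual(o, litter_sires[i], "index", "male" if i % 2 else "female",
                   "affected" if o in affected_offspring else "unaffected")
        for i, o in enumerate(offspring)
    ]
    pedigree = Pedigree(individuals)

    cohort_groups = {
        "other_lagotto_romagnolo": [f"lagotto_geno{i:03d}" for i in range(1, 104)],
        "sequenced_lagotto_genomes": [f"lagotto_wgs{i:02d}" for i in range(1, 27)],
        "other_breed_genomes": [f"other_breed{i:03d}" for i in range(1, 932)],
    }

    genotypes = {"index": (0, 1), "father": (0, 0), "mother": (0, 0)}
    genotypes.update({o: (0, 1) for o in affected_offspring})
    for iid in unaffected_offspring + littermates + sires:
        genotypes[iid] = (0, 0)
    for ids in cohort_groups.values():
        genotypes.update({sid: (0, 0) for sid in ids})

    record = VariantRecord(
        contig="chr6", pos=39295382, ref="G", alt="T", genotypes=genotypes
    )
    phenotypes = {ind.id: ind.phenotype for ind in pedigree.individuals}
    return {
        "record": record,
        "pedigree": pedigree,
        "proband": "index",
        "cohort_groups": cohort_groups,
        "phenotypes": phenotypes,
    }
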