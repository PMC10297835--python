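"""Genotype-by-phenotype tabulation across an extended pedigree.

Given one candidate site, counts genotype classes (hom-ref / het / hom-alt)
within pedigree categories — the proband, her parents, her affected
offspring, unaffected relatives — plus any number of unrelated cohort
groups, and decides whether the variant co-segregates perfectly with the
phenotype: every phenotyped affected individual carries the alt allele and
every phenotyped unaffected individual is homozygous reference.

No formal segregation statistic (LOD score, exact test) is computed; for a
fully penetrant dominant variant in a moderately sized family the count
table plus the perfect-co-segregation flag is the informative summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import PedigreeError
from .io_formats import Pedigree, VariantRecord

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt", "missing")

#: fixed ordering of the family categories in reports
FAMILY_CATEGORIES = (
    "proband",
    "parents",
    "affected_offspring",
    "unaffected_related",
    "affected_related",
    "unknown",
)


def genotype_class(gt) -> str:
    if None in gt:
        return "missing"
    n_alt = sum(gt)
    return ("hom_ref", "het", "hom_alt")[n_alt]


def allele_label(record: VariantRecord, klass: str) -> str:
    """Render a genotype class as allele letters, e.g. het at G>T -> 'GT'."""
    if klass == "missing":
        return "./."
    return {
        "hom_ref": record.ref + record.ref,
        "het": record.ref + record.alt,
        "hom_alt": record.alt + record.alt,
    }[klass]


@dataclass
class SegregationTable:
    """Counts per category x genotype class, with the co-segregation verdict."""

    site: tuple  # (contig, pos, ref, alt)
    counts: dict  # category -> {genotype_class: count}
    category_sizes: dict  # category -> number of individuals
    perfect_cosegregation: bool
    discordant_ids: list

    def __post_init__(self):
        for cat, row in self.counts.items():
            if sum(row.values()) != self.category_sizes.get(cat, 0):
                raise PedigreeError(f"category {cat!r}: row sum != category size")
        if self.perfect_cosegregation != (not self.discordant_ids):
            raise PedigreeError("perfect_cosegregation inconsistent with discordant_ids")

    def count(self, category: str, klass: str) -> int:
        return self.counts.get(category, {}).get(klass, 0)

    def to_dict(self) -> dict:
        return {
            "site": list(self.site),
            "counts": self.counts,
            "category_sizes": self.category_sizes,
            "perfect_cosegregation": self.perfect_cosegregation,
            "discordant_ids": list(self.discordant_ids),
        }


def categorize_individuals(
    pedigree: Pedigree, proband: str, cohort_groups: dict | None = None
) -> dict:
    """Map individual/sample ids to report categories.

    Family categories: the proband; her recorded parents; her affected
    offspring; other relatives split into unaffected / affected / unknown.
    ``cohort_groups`` (group name -> sample ids) are appended verbatim.
    """
    if proband not in pedigree:
        raise PedigreeError(f"proband {proband!r} not in pedigree")
    ind = pedigree[proband]
    parents = {p for p in (ind.sire, ind.dam) if p is not None}
    offspring = set(pedigree.offspring_of(proband))

    categories = {proband: "proband"}
    for p in parents:
        categories[p] = "parents"
    for iid in pedigree.ids():
        if iid in categories:
            continue
        phen = pedigree[iid].phenotype
        if iid in offspring and phen == "affected":
            categories[iid] = "affected_offspring"
        elif phen == "unaffected":
            categories[iid] = "unaffected_related"
        elif phen == "affected":
            categories[iid] = "affected_related"
        else:
            categories[iid] = "unknown"
    for group, ids in (cohort_groups or {}).items():
        for sid in ids:
            categories[sid] = group
    return categories


def tabulate(record: VariantRecord, categories: dict, phenotypes: dict | None = None) -> SegregationTable:
    """Count genotype classes per category and test perfect co-segregation.

    ``phenotypes`` maps id -> affected/unaffected/unknown; ids absent from
    it (e.g. anonymous cohort members) are treated as unphenotyped and
    cannot be discordant.
    """
    phenotypes = phenotypes or {}
    counts: dict = {}
    sizes: dict = {}
    discordant = []
    for iid, category in categories.items():
        gt = record.genotypes.get(iid, (None, None))
        klass = genotype_class(gt)
        counts.setdefault(category, {k: 0 for k in GENOTYPE_CLASSES})[klass] += 1
        sizes[category] = sizes.get(category, 0) + 1
        phen = phenotypes.get(iid, "unknown")
        if klass == "missing" or phen == "unknown":
            continue
        carrier = klass in ("het", "hom_alt")
        if (phen == "affected") != carrier:
            discordant.append(iid)
    return SegregationTable(
        site=record.site_key(),
        counts=counts,
        category_sizes=sizes,
        perfect_cosegregation=not discordant,
        discordant_ids=sorted(discordant),
    )


def cohort_absence_summary(record: VariantRecord, panel_groups: dict) -> dict:
    """Per-group genotype tallies for unrelated cohorts.

    ``panel_groups`` maps group name -> sample ids; the result maps group
    name -> {n_hom_ref, n_het, n_hom_alt, n_missing}.
    """
    summary = {}
    for group, ids in panel_groups.items():
        row = {"n_hom_ref": 0, "n_het": 0, "n_hom_alt": 0, "n_missing": 0}
        for sid in ids:
            klass = genotype_class(record.genotypes.get(sid, (None, None)))
            row["n_" + klass] += 1
        summary[group] = row
    return summary


def write_segregation_tsv(table: SegregationTable, record: VariantRecord, path) -> None:
    """Human-readable table with allele-letter column headers (GG/GT/TT)."""
    classes = ("hom_ref", "het", "hom_alt", "missing")
    with open(path, "w") as fh:
        header = "\t".join(["category"] + [allele_label(record, k) for k in classes])
        fh.write(header + "\n")
        ordered = [c for c in FAMILY_CATEGORIES if c in table.counts]
        ordered += [c for c in table.counts if c not in FAMILY_CATEGORIES]
        for cat in ordered:
            row = table.counts[cat]
            fh.write("\t".join([cat] + [str(row[k]) for k in classes]) + "\n")
        fh.write(f"# perfect_cosegregation: {table.perfect_cosegregation}\n")
        if table.discordant_ids:
            fh.write("# discordant: " + ",".join(table.discordant_ids) + "\n")
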