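"""Trio variant-filtering cascade for rare dominant / recessive traits.

The cascade mirrors the classic trio design for a fully penetrant monogenic
trait: tally the proband's variants by zygosity, keep those whose trio
genotype pattern fits an inheritance scenario, drop any variant seen in an
unrelated control cohort (with a breed-carrier allowance in the recessive
scenario), and finally keep only protein-changing variants.  Two scenarios
are considered for an affected proband with unaffected parents:

* ``dominant_de_novo`` — proband het, both parents homozygous reference;
* ``recessive``       — proband hom-alt, both parents het carriers.

A Mendelian-error scan over the trio doubles as a parentage check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consequence import annotate_all, is_protein_changing
from .errors import DomainError, InsufficientDataError, PedigreeError
from .io_formats import CohortPanel, Pedigree, VariantRecord
from .nomenclature import format_hgvs

SCENARIOS = ("dominant_de_novo", "recessive")


@dataclass(frozen=True)
class InheritanceScenario:
    kind: str

    def __post_init__(self):
        if self.kind not in SCENARIOS:
            raise DomainError(f"unknown scenario {self.kind!r}")


@dataclass
class Candidate:
    """One variant surviving the whole cascade, with its annotations."""

    record: VariantRecord
    consequence: object  # best (most severe) Consequence
    hgvs: object  # HgvsTriplet
    gene_symbol: str
    in_gene_panel: bool = False


@dataclass
class ScenarioCounts:
    """Surviving-variant counts along one scenario's cascade stages."""

    n_start: int
    n_pattern_pass: int
    n_private: int
    n_protein_changing: int

    def __post_init__(self):
        stages = (self.n_start, self.n_pattern_pass, self.n_private, self.n_protein_changing)
        if any(b > a for a, b in zip(stages, stages[1:])):
            raise DomainError("cascade counts must be non-increasing")


@dataclass
class FilterReport:
    """Per-stage counts for both scenarios plus the candidate lists."""

    n_total_by_zygosity: tuple  # (n_het, n_hom_alt) in the proband
    scenarios: dict  # kind -> ScenarioCounts
    candidates: dict  # kind -> [Candidate, ...]
    proband: str = ""
    sire: str = ""
    dam: str = ""

    def to_dict(self) -> dict:
        return {
            "proband": self.proband,
            "sire": self.sire,
            "dam": self.dam,
            "n_total_by_zygosity": {
                "het": self.n_total_by_zygosity[0],
                "hom_alt": self.n_total_by_zygosity[1],
            },
            "scenarios": {
                kind: {
                    "n_start": c.n_start,
                    "n_pattern_pass": c.n_pattern_pass,
                    "n_private": c.n_private,
                    "n_protein_changing": c.n_protein_changing,
                }
                for kind, c in self.scenarios.items()
            },
            "candidates": {
                kind: [
                    {
                        "contig": cand.record.contig,
                        "pos": cand.record.pos,
                        "ref": cand.record.ref,
                        "alt": cand.record.alt,
                        "gene": cand.gene_symbol,
                        "effect": cand.consequence.effect_class,
                        "g_name": cand.hgvs.g_name,
                        "c_name": cand.hgvs.c_name,
                        "p_name": cand.hgvs.p_name,
                        "truncation_fraction": cand.consequence.truncation_fraction,
                        "in_gene_panel": cand.in_gene_panel,
                    }
                    for cand in cands
                ]
                for kind, cands in self.candidates.items()
            },
        }


def tally_zygosity(records, proband: str) -> tuple:
    """Count the proband's het and hom-alt genotypes across all records."""
    n_het = n_hom = 0
    seen = False
    for rec in records:
        if proband not in rec.genotypes:
            continue
        seen = True
        gt = rec.gt(proband)
        if gt == (0, 1):
            n_het += 1
        elif gt == (1, 1):
            n_hom += 1
    if records and not seen:
        raise PedigreeError(f"proband {proband!r} absent from all records")
    return n_het, n_hom


def matches_scenario(
    record: VariantRecord, proband: str, sire: str, dam: str, scenario: InheritanceScenario
) -> bool:
    """Trio genotype-pattern test; any missing genotype fails the pattern."""
    gp, gs, gd = record.gt(proband), record.gt(sire), record.gt(dam)
    if any(None in g for g in (gp, gs, gd)):
        return False
    if scenario.kind == "dominant_de_novo":
        return gp == (0, 1) and gs == (0, 0) and gd == (0, 0)
    return gp == (1, 1) and gs == (0, 1) and gd == (0, 1)


def is_private(
    record: VariantRecord,
    panel: CohortPanel,
    scenario: InheritanceScenario,
    proband_breed: str,
) -> bool:
    """Control-cohort privacy filter.

    Dominant de novo: the alt allele must be absent from every control.
    Recessive: no control may be hom-alt, and het carriers are tolerated
    only among controls of the proband's own breed.
    """
    for sample in panel.sample_ids:
        gt = record.genotypes.get(sample, (None, None))
        n_alt = sum(1 for a in gt if a == 1)
        if n_alt == 0:
            continue
        if scenario.kind == "dominant_de_novo":
            return False
        if n_alt == 2:
            return False
        if panel.breed_of(sample) != proband_breed:
            return False
    return True


def select_proband(pedigree: Pedigree, genotyped, proband: str | None = None) -> tuple:
    """Resolve (proband, sire, dam): the unique affected individual whose
    recorded sire and dam are both genotyped and unaffected (both scenarios
    assume unaffected parents), unless overridden."""
    genotyped = set(genotyped)
    if proband is not None:
        if proband not in pedigree:
            raise PedigreeError(f"proband override {proband!r} not in pedigree")
        ind = pedigree[proband]
        if ind.sire is None or ind.dam is None:
            raise PedigreeError(f"proband {proband!r} lacks recorded parents")
        return proband, ind.sire, ind.dam
    eligible = [
        ind
        for ind in pedigree.individuals
        if ind.phenotype == "affected"
        and ind.sire in genotyped
        and ind.dam in genotyped
        and ind.id in genotyped
        and pedigree[ind.sire].phenotype == "unaffected"
        and pedigree[ind.dam].phenotype == "unaffected"
    ]
    if len(eligible) != 1:
        raise PedigreeError(
            f"expected exactly one affected individual with both parents genotyped "
            f"and unaffected, found {len(eligible)}"
        )
    ind = eligible[0]
    return ind.id, ind.sire, ind.dam


def run_cascade(
    records,
    pedigree: Pedigree,
    panel: CohortPanel,
    transcripts,
    genome,
    scenario_set=SCENARIOS,
    proband: str | None = None,
    proband_breed: str | None = None,
    accessions: dict | None = None,
    gene_panel=None,
    min_called_controls: float = 0.0,
) -> FilterReport:
    """Run the full cascade for each requested scenario.

    ``accessions`` maps transcript_id -> (mRNA, protein) accession; when
    absent, transcript ids stand in for both.  ``gene_panel`` is an optional
    collection of known candidate gene symbols used to flag candidates.
    ``min_called_controls`` drops sites where fewer than this fraction of
    control genotypes are called.
    """
    genotyped = set(records[0].genotypes) if records else set(pedigree.ids())
    proband, sire, dam = select_proband(pedigree, genotyped, proband)
    if proband_breed is None:
        proband_breed = panel.breed_labels.get(proband, "")
    if accessions is None:
        accessions = {tx.transcript_id: (tx.transcript_id, tx.transcript_id) for tx in transcripts}
    gene_panel = set(gene_panel or ())
    tx_by_id = {tx.transcript_id: tx for tx in transcripts}

    n_het, n_hom = tally_zygosity(records, proband)
    usable = []
    for rec in records:
        called = [
            s for s in panel.sample_ids if None not in rec.genotypes.get(s, (None, None))
        ]
        if panel.sample_ids and len(called) / len(panel.sample_ids) < min_called_controls:
            continue
        usable.append(rec)

    scenarios, candidates = {}, {}
    for kind in scenario_set:
        scenario = InheritanceScenario(kind)
        n_start = n_het if kind == "dominant_de_novo" else n_hom
        pattern = [r for r in usable if matches_scenario(r, proband, sire, dam, scenario)]
        private = [r for r in pattern if is_private(r, panel, scenario, proband_breed)]
        cands = []
        for rec in private:
            conseqs = [c for c in annotate_all(rec, transcripts, genome) if is_protein_changing(c)]
            if not conseqs:
                continue
            best = max(conseqs, key=_severity)
            tx = tx_by_id[best.transcript_id]
            hgvs = format_hgvs(rec, best, accessions, strand=tx.strand)
            cands.append(
                Candidate(
                    record=rec,
                    consequence=best,
                    hgvs=hgvs,
                    gene_symbol=tx.gene_symbol,
                    in_gene_panel=tx.gene_symbol in gene_panel,
                )
            )
        scenarios[kind] = ScenarioCounts(
            n_start=n_start,
            n_pattern_pass=len(pattern),
            n_private=len(private),
            n_protein_changing=len(cands),
        )
        candidates[kind] = cands
    return FilterReport(
        n_total_by_zygosity=(n_het, n_hom),
        scenarios=scenarios,
        candidates=candidates,
        proband=proband,
        sire=sire,
        dam=dam,
    )


_SEVERITY_ORDER = (
    "non_coding",
    "synonymous",
    "splice_site",
    "inframe_indel",
    "missense",
    "start_loss",
    "stop_loss",
    "frameshift",
    "stop_gain",
)


def _severity(consequence) -> int:
    return _SEVERITY_ORDER.index(consequence.effect_class)


def mendelian_consistent(child_gt, sire_gt, dam_gt) -> bool:
    """Whether a child genotype is composable from one allele of each parent."""
    child = tuple(sorted(child_gt))
    return any(tuple(sorted((x, y))) == child for x in sire_gt for y in dam_gt)


def verify_parentage(
    records, proband: str, sire: str, dam: str, threshold: float = 0.01, min_sites: int = 100
) -> tuple:
    """Mendelian-error scan over the trio.

    Counts, among sites where all three genotypes are complete, the fraction
    at which the proband's genotype cannot be formed from one allele of each
    recorded parent.  Returns ``(error_rate, consistent)``; raises when
    fewer than ``min_sites`` informative sites are available.
    """
    n_sites = n_errors = 0
    for rec in records:
        try:
            gp, gs, gd = rec.gt(proband), rec.gt(sire), rec.gt(dam)
        except KeyError:
            continue
        if any(None in g for g in (gp, gs, gd)):
            continue
        n_sites += 1
        if not mendelian_consistent(gp, gs, gd):
            n_errors += 1
    if n_sites < min_sites:
        raise InsufficientDataError(
            f"only {n_sites} complete-genotype sites (need >= {min_sites})"
        )
    rate = n_errors / n_sites
    return rate, rate < threshold
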