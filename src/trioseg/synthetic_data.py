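"""Self-contained synthetic test universe for the trio-filtering pipeline.

Generates a toy genome, clean transcript models (ATG ... stop, no internal
stop), a control cohort with background polymorphisms and breed-private
variants, and a three-generation family — an affected index female, her two
unaffected parents (the sequenced trio), the sires of her litters, and her
offspring — with exactly one planted de novo stop-gain variant in a
designated gene.

The planted variant is heterozygous in the index female, absent from her
parents and from every control; each offspring inherits it with probability
1/2; with full penetrance (the default) affection status equals carrier
status, emulating perfect co-segregation of a fully penetrant dominant
trait.  Two decoy variants are planted so that every stage of the filter
cascade rejects something: a protein-changing het shared with exactly one
control (caught by the privacy filter) and a private synonymous het in the
index female (caught by the protein-changing filter).

All randomness flows from one seeded generator, so a fixed seed reproduces
the bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .consequence import annotate_consequence, complement, is_protein_changing
from .errors import ConfigurationError, SimulationError
from .io_formats import (
    CohortPanel,
    GenomeRef,
    Individual,
    Pedigree,
    TranscriptModel,
    VariantRecord,
    write_fasta,
    write_gff3,
    write_ped,
    write_samples_tsv,
    write_vcf,
)

PROBAND_BREED = "LagottoRomagnolo"

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOP_CODONS
]


@dataclass
class SimConfig:
    """Knobs of the synthetic universe (defaults are the study conditions).

    The cohort and family sizes mirror, at desk scale, a panel of control
    genomes containing a handful of same-breed dogs and a family of one
    affected female, her parents, three sires and thirteen offspring.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length_bp: int = 60_000
    n_genes: int = 20
    n_control_samples: int = 50
    n_same_breed_controls: int = 5
    n_background_variants: int = 2000
    n_breed_private_variants: int = 40
    background_alt_freq: float = 0.2
    n_offspring: int = 13
    n_sires: int = 3
    penetrance: float = 1.0

    def __post_init__(self):
        counts = (
            self.n_contigs, self.contig_length_bp, self.n_genes,
            self.n_control_samples, self.n_same_breed_controls,
            self.n_background_variants, self.n_breed_private_variants,
            self.n_offspring, self.n_sires,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all simulation counts must be >= 0")
        if self.n_same_breed_controls > self.n_control_samples:
            raise ConfigurationError("n_same_breed_controls exceeds n_control_samples")
        if not 0 < self.background_alt_freq < 1:
            raise ConfigurationError("background_alt_freq must lie in (0, 1)")
        if not 0 <= self.penetrance <= 1:
            raise ConfigurationError("penetrance must lie in [0, 1]")
        if self.n_contigs < 1 or self.contig_length_bp < 1:
            raise ConfigurationError("need at least one non-empty contig")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth of one simulated bundle."""

    planted_variant: VariantRecord  # coordinates + alleles (no genotypes)
    target_transcript_id: str
    carrier_ids: set
    expected_codon_index: int
    expected_cds_pos: int
    decoy_shared_site: tuple | None = None  # (contig, pos, ref, alt)
    decoy_synonymous_site: tuple | None = None

    def to_json_dict(self) -> dict:
        pv = self.planted_variant
        return {
            "planted_variant": {"contig": pv.contig, "pos": pv.pos, "ref": pv.ref, "alt": pv.alt},
            "target_transcript_id": self.target_transcript_id,
            "carrier_ids": sorted(self.carrier_ids),
            "expected_codon_index": self.expected_codon_index,
            "expected_cds_pos": self.expected_cds_pos,
            "decoy_shared_site": list(self.decoy_shared_site) if self.decoy_shared_site else None,
            "decoy_synonymous_site": (
                list(self.decoy_synonymous_site) if self.decoy_synonymous_site else None
            ),
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "SimTruth":
        pv = data["planted_variant"]
        return cls(
            planted_variant=VariantRecord(pv["contig"], pv["pos"], pv["ref"], pv["alt"]),
            target_transcript_id=data["target_transcript_id"],
            carrier_ids=set(data["carrier_ids"]),
            expected_codon_index=data["expected_codon_index"],
            expected_cds_pos=data["expected_cds_pos"],
            decoy_shared_site=tuple(data["decoy_shared_site"]) if data["decoy_shared_site"] else None,
            decoy_synonymous_site=(
                tuple(data["decoy_synonymous_site"]) if data["decoy_synonymous_site"] else None
            ),
        )


@dataclass
class SimBundle:
    """Everything one simulation produces, in memory."""

    genome: GenomeRef
    transcripts: list
    records: list
    samples: list
    pedigree: Pedigree
    panel: CohortPanel  # all samples, with roles; controls have role 'control'
    truth: SimTruth
    config: SimConfig

    def control_panel(self) -> CohortPanel:
        ids = [s for s in self.panel.sample_ids if self.panel.roles.get(s) == "control"]
        return CohortPanel(
            sample_ids=ids,
            breed_labels={s: self.panel.breed_labels[s] for s in ids},
            roles={s: "control" for s in ids},
        )


# ---------------------------------------------------------------------------
# Genome and transcript generation
# ---------------------------------------------------------------------------


def generate_genome(config: SimConfig, rng=None) -> GenomeRef:
    """Uniform-random A/C/G/T contigs, deterministic given the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    contigs = {}
    for i in range(config.n_contigs):
        seq = "".join(rng.choice(_BASES, size=config.contig_length_bp))
        contigs[f"chr{i + 1}"] = seq
    return GenomeRef(contigs)


def generate_transcripts(genome: GenomeRef, config: SimConfig, rng=None) -> list:
    """Place non-overlapping genes and rewrite the genome under their CDS.

    Each gene gets 1-4 CDS segments on a random strand; the coding sequence
    is rebuilt as ATG + sense codons + stop, so translating any generated
    CDS yields Met...stop with no internal stop codon.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.n_genes == 0:
        return []

    editable = {name: bytearray(seq, "ascii") for name, seq in genome.contigs.items()}
    contig_names = list(genome.contigs)
    cursors = {name: 1 for name in contig_names}
    transcripts = []

    for gene_idx in range(config.n_genes):
        n_codons = int(rng.integers(30, 121))
        cds_len = 3 * n_codons
        n_segments = int(rng.integers(1, 5))
        n_segments = min(n_segments, cds_len // 3)
        # split the CDS into n_segments parts of length >= 3
        cuts = sorted(rng.choice(np.arange(1, cds_len // 3), size=n_segments - 1, replace=False)) if n_segments > 1 else []
        bounds = [0] + [3 * c for c in cuts] + [cds_len]
        seg_lengths = [bounds[i + 1] - bounds[i] for i in range(n_segments)]
        intron_lengths = [int(rng.integers(10, 51)) for _ in range(n_segments - 1)]
        span = sum(seg_lengths) + sum(intron_lengths)

        placed = False
        for contig in sorted(contig_names, key=lambda c: cursors[c]):
            gap = int(rng.integers(50, 201))
            start = cursors[contig] + gap
            if start + span - 1 <= len(editable[contig]):
                cursors[contig] = start + span - 1
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"contigs too small to place {config.n_genes} genes "
                f"(failed at gene {gene_idx + 1})"
            )

        segments = []
        seg_start = start
        for i, seg_len in enumerate(seg_lengths):
            segments.append((seg_start, seg_start + seg_len - 1))
            seg_start += seg_len + (intron_lengths[i] if i < len(intron_lengths) else 0)

        strand = "+" if rng.random() < 0.5 else "-"
        tx = TranscriptModel(
            transcript_id=f"tx{gene_idx + 1:03d}",
            gene_symbol=f"GENE{gene_idx + 1:03d}",
            contig=contig,
            strand=strand,
            cds_segments=segments,
        )

        interior = rng.choice(_SENSE_CODONS, size=n_codons - 2)
        coding_seq = "ATG" + "".join(interior) + _STOP_CODONS[int(rng.integers(0, 3))]
        buf = editable[contig]
        for base, pos in zip(coding_seq, tx.coding_positions()):
            written = base if strand == "+" else complement(base)
            buf[pos - 1] = ord(written)
        transcripts.append(tx)

    for name in contig_names:
        genome.contigs[name] = editable[name].decode("ascii")
    return transcripts


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


def _codon_str(tx: TranscriptModel, genome: GenomeRef, codon_index: int) -> str:
    positions = tx.coding_positions()[(codon_index - 1) * 3 : codon_index * 3]
    bases = [genome.base(tx.contig, p) for p in positions]
    if tx.strand == "-":
        bases = [complement(b) for b in bases]
    return "".join(bases)


def _site_from_coding_change(tx, genome, cds_pos, coding_ref, coding_alt) -> VariantRecord:
    pos = tx.coding_positions()[cds_pos - 1]
    if tx.strand == "+":
        ref, alt = coding_ref, coding_alt
    else:
        ref, alt = complement(coding_ref), complement(coding_alt)
    assert genome.base(tx.contig, pos) == ref
    return VariantRecord(contig=tx.contig, pos=pos, ref=ref, alt=alt)


def plant_stop_gain(transcript: TranscriptModel, genome: GenomeRef, rng=None):
    """Pick an interior codon where one substitution creates a stop codon.

    Returns ``(variant_template, expected)`` where the template carries the
    strand-corrected genomic REF/ALT and ``expected`` records the CDS
    position, codon index and codon change on the coding strand.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n = transcript.n_codons
    if n - 2 < 10:
        raise SimulationError(f"{transcript.transcript_id}: fewer than 10 interior codons")
    candidates = list(range(2, n))  # interior: not codon 1, not terminal stop
    rng.shuffle(candidates)
    for codon_index in candidates:
        codon = _codon_str(transcript, genome, codon_index)
        options = []
        for stop in _STOP_CODONS:
            diff = [i for i in range(3) if codon[i] != stop[i]]
            if len(diff) == 1:
                options.append((diff[0], stop))
        if not options:
            continue
        offset0, stop = options[int(rng.integers(0, len(options)))]
        cds_pos = (codon_index - 1) * 3 + offset0 + 1
        variant = _site_from_coding_change(
            transcript, genome, cds_pos, codon[offset0], stop[offset0]
        )
        expected = {
            "cds_pos": cds_pos,
            "codon_index": codon_index,
            "ref_codon": codon,
            "alt_codon": stop,
        }
        return variant, expected
    raise SimulationError(
        f"{transcript.transcript_id}: no stop-gain-capable interior codon found"
    )


def _plant_coding_site(transcript, genome, rng, want: str):
    """Find an SNV in the CDS whose effect class is ``want`` (missense/synonymous)."""
    n = transcript.n_codons
    candidates = list(range(2, n))
    rng.shuffle(candidates)
    for codon_index in candidates:
        codon = _codon_str(transcript, genome, codon_index)
        for offset0 in rng.permutation(3):
            for base in "ACGT":
                if base == codon[offset0]:
                    continue
                alt_codon = codon[:offset0] + base + codon[offset0 + 1 :]
                cds_pos = (codon_index - 1) * 3 + offset0 + 1
                variant = _site_from_coding_change(
                    transcript, genome, cds_pos, codon[offset0], base
                )
                effect = annotate_consequence(variant, transcript, genome).effect_class
                if effect == want:
                    return variant
    raise SimulationError(f"{transcript.transcript_id}: no {want} site found")


# ---------------------------------------------------------------------------
# Cohort and family simulation
# ---------------------------------------------------------------------------


def _family_sample_ids(config: SimConfig):
    sires = [f"sire{i + 1}" for i in range(config.n_sires)]
    offspring = [f"off{i + 1:02d}" for i in range(config.n_offspring)]
    return ["index", "father", "mother"] + sires + offspring


def simulate_cohort_and_family(genome, transcripts, config: SimConfig, rng=None):
    """Simulate genotypes for the family and the control cohort.

    Background variants follow Hardy-Weinberg sampling in founders and
    Mendelian transmission within the family; breed-private variants occur
    only in same-breed controls; the planted stop-gain is a de novo het in
    the index female transmitted to each offspring with probability 1/2.

    Returns ``(records, samples, pedigree, panel, truth)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if not transcripts:
        raise SimulationError("need at least one transcript to plant the causal variant")

    sires = [f"sire{i + 1}" for i in range(config.n_sires)]
    offspring = [f"off{i + 1:02d}" for i in range(config.n_offspring)]
    family = _family_sample_ids(config)
    controls = [f"ctrl{i + 1:03d}" for i in range(config.n_control_samples)]
    samples = family + controls
    same_breed_controls = controls[: config.n_same_breed_controls]

    # --- special sites -----------------------------------------------------
    eligible = [t for t in transcripts if t.n_codons - 2 >= 10]
    if not eligible:
        raise SimulationError("no transcript with >= 10 interior codons")
    order = rng.permutation(len(eligible))
    target = eligible[int(order[0])]
    planted, expected = plant_stop_gain(target, genome, rng)

    decoy_shared = decoy_syn = None
    if len(eligible) > 1:
        decoy_shared = _plant_coding_site(eligible[int(order[1])], genome, rng, "missense")
        decoy_syn = _plant_coding_site(
            eligible[int(order[2 % len(eligible)])], genome, rng, "synonymous"
        )
    special_keys = {planted.site_key()[:2]}
    for d in (decoy_shared, decoy_syn):
        if d is not None:
            special_keys.add(d.site_key()[:2])

    # --- background variant sites ------------------------------------------
    contig_names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contig_names])
    total = int(lengths.sum())
    n_special_draw = config.n_background_variants + config.n_breed_private_variants
    flat = rng.choice(total, size=min(n_special_draw + 16, total), replace=False)
    sites = []
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    for f in flat:
        ci = int(np.searchsorted(bounds, f, side="right") - 1)
        contig = contig_names[ci]
        pos = int(f - bounds[ci]) + 1
        if (contig, pos) in special_keys:
            continue
        sites.append((contig, pos))
        if len(sites) == n_special_draw:
            break
    if len(sites) < n_special_draw:
        raise SimulationError("genome too small for the requested variant counts")
    bg_sites = sites[: config.n_background_variants]
    private_sites = sites[config.n_background_variants :]

    def alt_base(contig, pos):
        ref = genome.base(contig, pos)
        choices = [b for b in "ACGT" if b != ref]
        return ref, choices[int(rng.integers(0, 3))]

    bg_alleles = [alt_base(c, p) for c, p in bg_sites]
    private_alleles = [alt_base(c, p) for c, p in private_sites]

    # --- background genotypes ----------------------------------------------
    B = config.n_background_variants
    founders = ["father", "mother"] + sires + controls
    p = config.background_alt_freq
    geno = {}  # sample -> (B, 2) int array
    for s in founders:
        geno[s] = (rng.random((B, 2)) < p).astype(np.int8)

    def transmit(parent_a, parent_b):
        pick_a = rng.integers(0, 2, size=B)
        pick_b = rng.integers(0, 2, size=B)
        child = np.empty((B, 2), dtype=np.int8)
        child[:, 0] = parent_a[np.arange(B), pick_a]
        child[:, 1] = parent_b[np.arange(B), pick_b]
        return child

    sire_of = {o: sires[int(rng.integers(0, config.n_sires))] for o in offspring}
    geno["index"] = transmit(geno["father"], geno["mother"])
    for o in offspring:
        geno[o] = transmit(geno["index"], geno[sire_of[o]])

    # --- exclusivity: no background site may mimic the planted pattern ------
    protein_changing_bg = np.zeros(B, dtype=bool)
    for i, ((contig, pos), (ref, alt)) in enumerate(zip(bg_sites, bg_alleles)):
        rec = VariantRecord(contig, pos, ref, alt)
        for tx in transcripts:
            if tx.contig != contig:
                continue
            span = tx.span
            if not span[0] - 2 <= pos <= span[1] + 2:
                continue
            if is_protein_changing(annotate_consequence(rec, tx, genome)):
                protein_changing_bg[i] = True
                break

    def colliding_sites():
        index_het = geno["index"].sum(axis=1) == 1
        parents_ref = (geno["father"].sum(axis=1) == 0) & (geno["mother"].sum(axis=1) == 0)
        if controls:
            control_mat = np.stack([geno[c] for c in controls])  # (C, B, 2)
            controls_ref = (control_mat.sum(axis=2) == 0).all(axis=0)
        else:
            controls_ref = np.ones(B, dtype=bool)
        return np.where(protein_changing_bg & index_het & parents_ref & controls_ref)[0]

    for _ in range(25):
        colliding = colliding_sites()
        if colliding.size == 0:
            break
        for i in colliding:
            for s in founders:
                geno[s][i] = (rng.random(2) < p).astype(np.int8)
            geno["index"][i] = geno["father"][i, rng.integers(0, 2)], geno["mother"][i, rng.integers(0, 2)]
            for o in offspring:
                geno[o][i] = geno["index"][i, rng.integers(0, 2)], geno[sire_of[o]][i, rng.integers(0, 2)]
    else:
        if controls:
            for i in colliding_sites():
                geno[controls[int(rng.integers(0, len(controls)))]][i] = (0, 1)

    # --- assemble records ---------------------------------------------------
    records = []
    for i, ((contig, pos), (ref, alt)) in enumerate(zip(bg_sites, bg_alleles)):
        gts = {s: tuple(int(a) for a in geno[s][i]) for s in samples}
        records.append(VariantRecord(contig, pos, ref, alt, gts))

    # breed-private variants: only same-breed controls carry them
    for (contig, pos), (ref, alt) in zip(private_sites, private_alleles):
        gts = {s: (0, 0) for s in samples}
        if same_breed_controls:
            carriers = np.int8(rng.random((len(same_breed_controls), 2)) < 0.3)
            if carriers.sum() == 0:
                carriers[int(rng.integers(0, len(same_breed_controls))), 0] = 1
            for s, g in zip(same_breed_controls, carriers):
                gts[s] = tuple(int(a) for a in g)
        records.append(VariantRecord(contig, pos, ref, alt, gts))

    # planted de novo stop-gain
    planted_gts = {s: (0, 0) for s in samples}
    planted_gts["index"] = (0, 1)
    carrier_offspring = [o for o in offspring if rng.random() < 0.5]
    for o in carrier_offspring:
        planted_gts[o] = (0, 1)
    records.append(
        VariantRecord(planted.contig, planted.pos, planted.ref, planted.alt, planted_gts)
    )
    carriers = {"index"} | set(carrier_offspring)

    # decoy 1: protein-changing het shared with exactly one control
    if decoy_shared is not None:
        gts = {s: (0, 0) for s in samples}
        gts["index"] = (0, 1)
        gts[controls[int(rng.integers(0, len(controls)))]] = (0, 1)
        for o in offspring:
            if rng.random() < 0.5:
                gts[o] = (0, 1)
        records.append(
            VariantRecord(decoy_shared.contig, decoy_shared.pos, decoy_shared.ref,
                          decoy_shared.alt, gts)
        )
    # decoy 2: private synonymous het in the index female
    if decoy_syn is not None:
        gts = {s: (0, 0) for s in samples}
        gts["index"] = (0, 1)
        for o in offspring:
            if rng.random() < 0.5:
                gts[o] = (0, 1)
        records.append(
            VariantRecord(decoy_syn.contig, decoy_syn.pos, decoy_syn.ref, decoy_syn.alt, gts)
        )

    records.sort(key=lambda r: (r.contig, r.pos))

    # --- pedigree and phenotypes --------------------------------------------
    def phenotype_of(sample_id):
        if sample_id in carriers:
            return "affected" if rng.random() < config.penetrance else "unaffected"
        return "unaffected"

    individuals = [
        Individual("father", None, None, "male", "unaffected"),
        Individual("mother", None, None, "female", "unaffected"),
        Individual("index", "father", "mother", "female", phenotype_of("index")),
    ]
    for s in sires:
        individuals.append(Individual(s, None, None, "male", "unaffected"))
    for o in offspring:
        sex = "male" if rng.random() < 0.5 else "female"
        individuals.append(Individual(o, sire_of[o], "index", sex, phenotype_of(o)))
    pedigree = Pedigree(individuals)

    breed_labels = {s: PROBAND_BREED for s in family}
    roles = {"index": "proband", "father": "parent", "mother": "parent"}
    roles.update({s: "sire" for s in sires})
    roles.update({o: "offspring" for o in offspring})
    for i, c in enumerate(controls):
        breed_labels[c] = PROBAND_BREED if c in same_breed_controls else f"Breed{i + 1:03d}"
        roles[c] = "control"
    panel = CohortPanel(sample_ids=samples, breed_labels=breed_labels, roles=roles)

    truth = SimTruth(
        planted_variant=VariantRecord(planted.contig, planted.pos, planted.ref, planted.alt),
        target_transcript_id=target.transcript_id,
        carrier_ids=carriers,
        expected_codon_index=expected["codon_index"],
        expected_cds_pos=expected["cds_pos"],
        decoy_shared_site=decoy_shared.site_key() if decoy_shared is not None else None,
        decoy_synonymous_site=decoy_syn.site_key() if decoy_syn is not None else None,
    )
    return records, samples, pedigree, panel, truth


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run the whole generator with one seeded random stream."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    transcripts = generate_transcripts(genome, config, rng)
    records, samples, pedigree, panel, truth = simulate_cohort_and_family(
        genome, transcripts, config, rng
    )
    return SimBundle(genome, transcripts, records, samples, pedigree, panel, truth, config)


def write_bundle(bundle: SimBundle, out_dir) -> dict:
    """Write the bundle directory: genome.fa, genes.gff3, cohort.vcf,
    family.ped, samples.tsv, truth.json.  Returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "ped": os.path.join(out_dir, "family.ped"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_fasta(bundle.genome, paths["fasta"])
    write_gff3(bundle.transcripts, paths["gff3"])
    contig_lengths = {name: len(seq) for name, seq in bundle.genome.contigs.items()}
    write_vcf(bundle.records, bundle.samples, paths["vcf"], contig_lengths=contig_lengths)
    write_ped(bundle.pedigree, paths["ped"])
    write_samples_tsv(bundle.panel, paths["samples"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
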