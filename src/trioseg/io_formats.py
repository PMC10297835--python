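"""Readers and writers for the formats the pipeline touches.

FASTA (reference genome), GFF3 (transcript CDS models), multi-sample VCF
(genotypes), PED (pedigree with affection status) and a sample-metadata TSV
(breed / cohort-role sidecar, since VCF has no breed field).

Coordinates are 1-based inclusive throughout the public surface, matching
the VCF and GFF3 conventions.  Genotypes are unordered diploid allele pairs
over {0, 1, None}; phased separators are read as unphased and multi-allelic
sites are decomposed into biallelic records on input.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO

from .errors import FormatError, ModelError, PedigreeError

#: allele value for an uncalled genotype slot
MISSING = None

_VALID_BASES = frozenset("ACGTN")


def canonical_gt(gt) -> tuple:
    """Canonicalize a diploid genotype to a sorted (called-first) pair.

    Accepts any 2-iterable over {0, 1, None}; returns a tuple usable as an
    unordered-pair value, e.g. ``canonical_gt((1, 0)) == (0, 1)`` and
    ``canonical_gt((None, 1)) == (1, None)``.
    """
    alleles = tuple(gt)
    if len(alleles) != 2:
        raise FormatError(f"genotype must have exactly two allele slots, got {alleles!r}")
    for a in alleles:
        if a not in (0, 1, None):
            raise FormatError(f"allele out of range in genotype {alleles!r}")
    return tuple(sorted(alleles, key=lambda a: (a is None, a)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRef:
    """A reference genome held in memory as uppercase contig sequences."""

    contigs: dict  # name -> sequence (A/C/G/T/N)

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(f"contig {name!r} contains non-nucleotide characters {sorted(bad)}")

    def base(self, contig: str, pos: int) -> str:
        """Return the base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Return the sequence on [start, end], 1-based inclusive."""
        return self.contigs[contig][start - 1 : end]


@dataclass(eq=False)
class TranscriptModel:
    """Strand-aware CDS structure of one transcript.

    ``cds_segments`` are (start, end) pairs in 1-based inclusive genomic
    coordinates, stored sorted by genomic start regardless of strand; coding
    order on the minus strand walks the segments in reverse, complementing.
    """

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str  # '+' or '-'
    cds_segments: list  # [(start, end), ...] sorted by start

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.transcript_id}: strand must be '+' or '-'")
        segs = sorted(tuple(s) for s in self.cds_segments)
        if not segs:
            raise ModelError(f"{self.transcript_id}: no CDS segments")
        prev_end = 0
        for start, end in segs:
            if start < 1 or end < start:
                raise ModelError(f"{self.transcript_id}: malformed CDS segment ({start}, {end})")
            if start <= prev_end:
                raise ModelError(f"{self.transcript_id}: overlapping CDS segments")
            prev_end = end
        self.cds_segments = segs
        length = self.cds_length
        if length % 3 != 0:
            raise ModelError(
                f"{self.transcript_id}: CDS length {length} is not divisible by 3"
            )
        if length < 6:
            raise ModelError(f"{self.transcript_id}: CDS shorter than start + stop codon")
        self._coding_positions = None

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def n_codons(self) -> int:
        """ORF length in codons, terminal stop included."""
        return self.cds_length // 3

    @property
    def span(self) -> tuple:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def coding_positions(self) -> list:
        """Genomic positions of CDS bases in coding (5'->3' mRNA) order."""
        if self._coding_positions is None:
            pos = []
            for start, end in self.cds_segments:
                pos.extend(range(start, end + 1))
            if self.strand == "-":
                pos.reverse()
            self._coding_positions = pos
        return self._coding_positions

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds_segments)


@dataclass
class VariantRecord:
    """One biallelic site with per-sample unordered diploid genotypes."""

    contig: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    genotypes: dict = field(default_factory=dict)  # sample_id -> (a, b)

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise FormatError(f"REF equals ALT ({self.ref}) at {self.contig}:{self.pos}")
        self.genotypes = {s: canonical_gt(g) for s, g in self.genotypes.items()}

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def gt(self, sample: str) -> tuple:
        return self.genotypes[sample]

    def site_key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: str  # 'male' / 'female' / 'unknown'
    phenotype: str  # 'affected' / 'unaffected' / 'unknown'


@dataclass
class Pedigree:
    """Individuals with parent links, sex and affection status."""

    individuals: list  # [Individual, ...]

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            raise PedigreeError("duplicate individual ids in pedigree")
        self._by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in self._by_id:
                    raise PedigreeError(f"{ind.id}: parent {parent!r} not in pedigree")
        self._check_acyclic()

    def _check_acyclic(self):
        state = {}  # 0 visiting, 1 done

        def visit(iid, stack):
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"{iid} is its own ancestor")
            state[iid] = 0
            ind = self._by_id[iid]
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    visit(parent, stack)
            state[iid] = 1

        for iid in self._by_id:
            visit(iid, [])

    def __contains__(self, iid):
        return iid in self._by_id

    def __getitem__(self, iid) -> Individual:
        return self._by_id[iid]

    def ids(self) -> list:
        return [ind.id for ind in self.individuals]

    def affected(self) -> list:
        return [ind.id for ind in self.individuals if ind.phenotype == "affected"]

    def offspring_of(self, iid: str) -> list:
        return [ind.id for ind in self.individuals if iid in (ind.sire, ind.dam)]


@dataclass
class CohortPanel:
    """Control-cohort samples with breed labels (and optional roles)."""

    sample_ids: list
    breed_labels: dict  # sample_id -> breed
    roles: dict = field(default_factory=dict)  # sample_id -> cohort role

    def __post_init__(self):
        known = set(self.sample_ids)
        for sid in self.breed_labels:
            if sid not in known:
                raise FormatError(f"breed label for unknown sample {sid!r}")

    def breed_of(self, sample: str) -> str | None:
        return self.breed_labels.get(sample)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeRef:
    """Read a FASTA file into a :class:`GenomeRef` (sequences uppercased)."""
    contigs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig name {record.id!r} in {path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeRef(contigs)


def write_fasta(genome: GenomeRef, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 transcript models
# ---------------------------------------------------------------------------


def read_gff3_transcripts(path) -> list:
    """Read CDS features grouped by Parent into :class:`TranscriptModel` s.

    The phase column is ignored; models are expected to be phase-0
    consistent, which the divisible-by-3 invariant enforces.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # sqlite/parse failures
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    grouped = {}  # transcript_id -> dict(gene, contig, strand, segments)
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent", [])
        if not parents:
            raise FormatError(f"CDS at {feat.seqid}:{feat.start} lacks a Parent attribute")
        gene = feat.attributes.get("gene", [""])[0]
        for parent in parents:
            entry = grouped.setdefault(
                parent, {"gene": gene, "contig": feat.seqid, "strand": feat.strand, "segments": []}
            )
            if entry["contig"] != feat.seqid or entry["strand"] != feat.strand:
                raise ModelError(f"{parent}: CDS segments disagree on contig/strand")
            entry["segments"].append((feat.start, feat.end))

    models = []
    for tid, entry in grouped.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=entry["gene"],
                contig=entry["contig"],
                strand=entry["strand"],
                cds_segments=sorted(entry["segments"]),
            )
        )
    return models


def write_gff3(transcripts, path) -> None:
    """Write transcript CDS models as minimal GFF3 (gene/mRNA/CDS lines)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            start, end = tx.span
            fh.write(
                f"{tx.contig}\ttrioseg\tgene\t{start}\t{end}\t.\t{tx.strand}\t.\t"
                f"ID=gene:{tx.gene_symbol};Name={tx.gene_symbol}\n"
            )
            fh.write(
                f"{tx.contig}\ttrioseg\tmRNA\t{start}\t{end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent=gene:{tx.gene_symbol};gene={tx.gene_symbol}\n"
            )
            for seg_start, seg_end in tx.cds_segments:
                fh.write(
                    f"{tx.contig}\ttrioseg\tCDS\t{seg_start}\t{seg_end}\t.\t{tx.strand}\t0\t"
                    f"Parent={tx.transcript_id};gene={tx.gene_symbol}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _decompose_gt(raw_gt, alt_index: int) -> tuple:
    """Recode one sample genotype for the biallelic record of alt ``alt_index``.

    Reference alleles stay 0, the matching alt becomes 1, any other alt
    allele becomes missing.
    """
    out = []
    for a in raw_gt:
        if a is None or a == 0:
            out.append(0 if a == 0 else None)
        elif a == alt_index:
            out.append(1)
        else:
            out.append(None)
    return canonical_gt(out)


def read_vcf(path):
    """Read a VCF into ``(records, samples)``.

    Multi-allelic sites are decomposed into biallelic :class:`VariantRecord`
    s; only the GT field is parsed, phase separators are dropped.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: FORMAT/GT not declared in header")
        samples = list(vf.header.samples)
        records = []
        try:
            for rec in vf:
                if rec.alts is None:
                    continue
                raw = {}
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or len(gt) != 2:
                        gt = (None, None)
                    raw[sample] = gt
                for alt_index, alt in enumerate(rec.alts, start=1):
                    genotypes = {s: _decompose_gt(g, alt_index) for s, g in raw.items()}
                    records.append(
                        VariantRecord(
                            contig=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            genotypes=genotypes,
                        )
                    )
        except (ValueError, OSError) as exc:
            raise FormatError(f"malformed VCF line in {path}: {exc}") from exc
    return records, samples


def write_vcf(records, samples, path, contig_lengths=None) -> None:
    """Write biallelic records (sorted by contig, pos) as a plain-text VCF."""
    order = [(r.contig, r.pos) for r in records]
    if order != sorted(order):
        raise FormatError("records must be sorted by (contig, pos) before writing")

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    lengths = dict(contig_lengths or {})
    for rec in records:
        end = rec.pos + len(rec.ref) - 1
        lengths[rec.contig] = max(lengths.get(rec.contig, 0), end)
    for contig, length in lengths.items():
        header.contigs.add(contig, length=length)
    for sample in samples:
        header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vr = out.new_record(
                contig=rec.contig,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            for sample in samples:
                vr.samples[sample]["GT"] = rec.genotypes.get(sample, (None, None))
                vr.samples[sample].phased = False
            out.write(vr)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PHENOTYPE_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}


def read_ped(path) -> Pedigree:
    """Read a 6-column PED file (family, id, sire, dam, sex, phenotype)."""
    individuals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}:{line_no}: expected 6 columns, got {len(fields)}")
            _fam, iid, sire, dam, sex, phen = fields
            if phen not in _PHENOTYPE_CODES:
                raise FormatError(f"{path}:{line_no}: unknown phenotype code {phen!r}")
            individuals.append(
                Individual(
                    id=iid,
                    sire=None if sire == "0" else sire,
                    dam=None if dam == "0" else dam,
                    sex=_SEX_CODES.get(sex, "unknown"),
                    phenotype=_PHENOTYPE_CODES[phen],
                )
            )
    try:
        return Pedigree(individuals)
    except PedigreeError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ped(pedigree: Pedigree, path, family_id: str = "FAM1") -> None:
    rev_phen = {"affected": "2", "unaffected": "1", "unknown": "0"}
    rev_sex = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.id,
                        ind.sire or "0",
                        ind.dam or "0",
                        rev_sex[ind.sex],
                        rev_phen[ind.phenotype],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample metadata sidecar (breed / cohort role)
# ---------------------------------------------------------------------------


def read_samples_tsv(path) -> CohortPanel:
    """Read the sample-metadata TSV: sample_id <tab> breed <tab> role."""
    sample_ids, breeds, roles = [], {}, {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{line_no}: expected 3 tab-separated columns")
            sid, breed, role = fields
            if sid in breeds:
                raise FormatError(f"{path}:{line_no}: duplicate sample {sid!r}")
            sample_ids.append(sid)
            breeds[sid] = breed
            roles[sid] = role
    return CohortPanel(sample_ids=sample_ids, breed_labels=breeds, roles=roles)


def write_samples_tsv(panel: CohortPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tbreed\trole\n")
        for sid in panel.sample_ids:
            fh.write(f"{sid}\t{panel.breed_labels.get(sid, '')}\t{panel.roles.get(sid, '')}\n")
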