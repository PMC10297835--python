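"""Coding-consequence annotation from first principles.

Projects a genomic variant onto a transcript model, derives the codon and
amino-acid change by translating the affected codon with the standard
genetic code, classifies the effect, and — for premature stop codons —
computes the fraction of the open reading frame that the truncation
removes.

The "protein-changing" set used by the downstream filter cascade is
{stop_gain, stop_loss, start_loss, missense, frameshift, inframe_indel,
splice_site}: roughly the HIGH + MODERATE impact classes of conventional
annotators, with synonymous and non-coding changes excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import DomainError, ReferenceMismatchError
from .io_formats import GenomeRef, TranscriptModel, VariantRecord

#: effect classes counted as protein-changing by the filter cascade
PROTEIN_CHANGING_CLASSES = frozenset(
    {
        "stop_gain",
        "stop_loss",
        "start_loss",
        "missense",
        "frameshift",
        "inframe_indel",
        "splice_site",
    }
)

#: intronic bases on each side of a CDS-segment junction treated as splice
#: region (the canonical GT/AG donor/acceptor dinucleotides)
SPLICE_WINDOW = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class Consequence:
    """Classified coding effect of one variant on one transcript."""

    transcript_id: str
    effect_class: str
    cds_pos: int | None = None  # 1-based c. coordinate
    codon_index: int | None = None  # 1-based codon number
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None  # one-letter, '*' for stop
    alt_aa: str | None = None
    total_codons: int | None = None  # ORF codons including the terminal stop
    truncation_fraction: float | None = None  # stop_gain only

    def __post_init__(self):
        if self.cds_pos is not None and self.codon_index is not None:
            if self.codon_index != (self.cds_pos - 1) // 3 + 1:
                raise DomainError("codon_index inconsistent with cds_pos")
        if (self.truncation_fraction is not None) != (self.effect_class == "stop_gain"):
            raise DomainError("truncation_fraction is set iff effect_class is stop_gain")
        if self.codon_index is not None and self.total_codons is not None:
            if not 1 <= self.codon_index <= self.total_codons:
                raise DomainError("codon_index out of ORF range")


def genomic_to_cds(variant_pos: int, transcript: TranscriptModel) -> int | None:
    """Map a genomic position to its 1-based CDS (c.) coordinate.

    Walks the CDS segments in coding order (reversed for the minus strand);
    c.1 is the A of the start ATG.  Returns None when the position lies
    outside every CDS segment.
    """
    offset = 0
    segments = transcript.cds_segments
    if transcript.strand == "+":
        for start, end in segments:
            if start <= variant_pos <= end:
                return offset + (variant_pos - start) + 1
            offset += end - start + 1
    else:
        for start, end in reversed(segments):
            if start <= variant_pos <= end:
                return offset + (end - variant_pos) + 1
            offset += end - start + 1
    return None


def cds_to_genomic(cds_pos: int, transcript: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_cds` (1-based both sides)."""
    if not 1 <= cds_pos <= transcript.cds_length:
        raise DomainError(f"cds_pos {cds_pos} outside 1..{transcript.cds_length}")
    return transcript.coding_positions()[cds_pos - 1]


def codon_of(cds_pos: int) -> tuple:
    """Return (codon_index, offset_in_codon) for a 1-based CDS position."""
    if cds_pos < 1:
        raise DomainError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def truncation_fraction(codon_index: int, total_codons: int) -> float:
    """Fraction of ORF codons at and beyond a premature stop.

    The denominator is the full ORF codon count including the terminal
    stop; a stop gained at the start codon truncates everything (1.0) and
    one at the terminal-stop position truncates only that codon (1/L).
    """
    if not 1 <= codon_index <= total_codons:
        raise DomainError(
            f"codon_index {codon_index} outside 1..{total_codons}"
        )
    return (total_codons - codon_index + 1) / total_codons


def _splice_distance(pos: int, transcript: TranscriptModel) -> int | None:
    """Distance (bp) from ``pos`` to the nearest intron-side junction, if <= window."""
    segments = transcript.cds_segments
    best = None
    for i in range(len(segments) - 1):
        intron_start = segments[i][1] + 1
        intron_end = segments[i + 1][0] - 1
        if not intron_start <= pos <= intron_end:
            continue
        dist = min(pos - intron_start, intron_end - pos) + 1
        if dist <= SPLICE_WINDOW:
            best = dist if best is None else min(best, dist)
    return best


def _codon_seq(transcript: TranscriptModel, genome: GenomeRef, codon_index: int) -> str:
    """The codon's three bases read along the coding strand."""
    positions = transcript.coding_positions()[(codon_index - 1) * 3 : codon_index * 3]
    bases = [genome.base(transcript.contig, p) for p in positions]
    if transcript.strand == "-":
        bases = [complement(b) for b in bases]
    return "".join(bases)


def _verify_ref(variant: VariantRecord, genome: GenomeRef) -> None:
    expected = genome.slice(variant.contig, variant.pos, variant.pos + len(variant.ref) - 1)
    if expected != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.contig}:{variant.pos} REF {variant.ref!r} disagrees with "
            f"reference sequence {expected!r}"
        )


def annotate_consequence(
    variant: VariantRecord, transcript: TranscriptModel, genome: GenomeRef
) -> Consequence:
    """Classify one variant against one transcript.

    SNVs inside the CDS are translated codon-wise; indels are classified by
    length delta (no 3' normalisation); SNVs within the splice window of an
    internal CDS junction are splice_site; everything else is non_coding.
    Raises :class:`ReferenceMismatchError` when REF disagrees with the
    genome.
    """
    total = transcript.n_codons
    if variant.contig != transcript.contig:
        return Consequence(transcript.transcript_id, "non_coding", total_codons=total)
    _verify_ref(variant, genome)

    if not variant.is_snv:
        span = range(variant.pos, variant.pos + max(len(variant.ref), 1))
        if any(transcript.contains(p) for p in span):
            delta = len(variant.alt) - len(variant.ref)
            effect = "inframe_indel" if delta % 3 == 0 else "frameshift"
            cds_pos = next(
                (genomic_to_cds(p, transcript) for p in span if transcript.contains(p)),
                None,
            )
            codon_index = codon_of(cds_pos)[0] if cds_pos else None
            return Consequence(
                transcript.transcript_id,
                effect,
                cds_pos=cds_pos,
                codon_index=codon_index,
                total_codons=total,
            )
        return Consequence(transcript.transcript_id, "non_coding", total_codons=total)

    cds_pos = genomic_to_cds(variant.pos, transcript)
    if cds_pos is None:
        if _splice_distance(variant.pos, transcript) is not None:
            return Consequence(transcript.transcript_id, "splice_site", total_codons=total)
        return Consequence(transcript.transcript_id, "non_coding", total_codons=total)

    codon_index, offset = codon_of(cds_pos)
    ref_codon = _codon_seq(transcript, genome, codon_index)
    alt_base = variant.alt if transcript.strand == "+" else complement(variant.alt)
    alt_codon = ref_codon[: offset - 1] + alt_base + ref_codon[offset:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if codon_index == 1 and ref_aa == "M" and alt_aa != "M":
        effect = "start_loss"
    elif alt_aa == "*" and ref_aa != "*":
        effect = "stop_gain"
    elif ref_aa == "*" and alt_aa != "*":
        effect = "stop_loss"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "missense"

    return Consequence(
        transcript_id=transcript.transcript_id,
        effect_class=effect,
        cds_pos=cds_pos,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        total_codons=total,
        truncation_fraction=(
            truncation_fraction(codon_index, total) if effect == "stop_gain" else None
        ),
    )


def is_protein_changing(consequence: Consequence) -> bool:
    """Whether an effect class survives the protein-changing filter stage."""
    return consequence.effect_class in PROTEIN_CHANGING_CLASSES


def annotate_all(variant: VariantRecord, transcripts, genome: GenomeRef) -> list:
    """Annotate a variant against every transcript whose span it touches."""
    out = []
    for tx in transcripts:
        if tx.contig != variant.contig:
            continue
        start, end = tx.span
        if variant.pos < start - SPLICE_WINDOW or variant.pos > end + SPLICE_WINDOW:
            continue
        out.append(annotate_consequence(variant, tx, genome))
    return out
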