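"""HGVS-style g. / c. / p. designations for annotated variants.

Covers the SNV grammar needed by the candidate report: genomic names like
``chr6:39295382G>T``, coding names like ``NM_001006650.1:c.7195G>T`` (alleles
on the coding strand), and predicted protein names like
``NP_001006651.1:p.(Glu2399*)`` with three-letter amino-acid codes and the
predicted change parenthesized.  Indels get a best-effort, non-normalized
del/ins name.  Thousands separators are left to the display formatter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .consequence import Consequence, complement
from .errors import ConfigurationError
from .io_formats import VariantRecord

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "*",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


@dataclass
class HgvsTriplet:
    """Genomic, coding and protein names for one variant on one transcript."""

    g_name: str
    c_name: str | None  # present iff the variant lies in the CDS
    p_name: str | None  # present iff the variant is a coding SNV


def aa3(one_letter: str) -> str:
    return THREE_LETTER[one_letter]


def _coding_strand_alleles(variant: VariantRecord, strand: str) -> tuple:
    if strand == "+":
        return variant.ref, variant.alt
    return complement(variant.ref), complement(variant.alt)


def format_hgvs(
    variant: VariantRecord,
    consequence: Consequence,
    accessions: dict,
    strand: str = "+",
) -> HgvsTriplet:
    """Build the g./c./p. triplet for an annotated variant.

    ``accessions`` maps transcript_id -> (mRNA accession, protein accession);
    a transcript absent from the map is a configuration error.  ``strand``
    is the transcript's strand, used to emit coding-strand alleles in the
    c. name.
    """
    if consequence.transcript_id not in accessions:
        raise ConfigurationError(
            f"no accession mapping for transcript {consequence.transcript_id!r}"
        )
    mrna_acc, prot_acc = accessions[consequence.transcript_id]

    g_name = f"{variant.contig}:{variant.pos}{variant.ref}>{variant.alt}"

    c_name = None
    p_name = None
    if consequence.cds_pos is not None:
        c_ref, c_alt = _coding_strand_alleles(variant, strand)
        if variant.is_snv:
            c_name = f"{mrna_acc}:c.{consequence.cds_pos}{c_ref}>{c_alt}"
            effect = consequence.effect_class
            if effect == "synonymous":
                p_name = f"{prot_acc}:p.(=)"
            elif effect == "start_loss":
                p_name = f"{prot_acc}:p.(Met1?)"
            elif effect == "stop_loss":
                p_name = (
                    f"{prot_acc}:p.(*{consequence.codon_index}"
                    f"{aa3(consequence.alt_aa)}ext*?)"
                )
            elif effect in ("stop_gain", "missense"):
                p_name = (
                    f"{prot_acc}:p.({aa3(consequence.ref_aa)}"
                    f"{consequence.codon_index}{aa3(consequence.alt_aa)})"
                )
        else:
            # non-normalized best-effort indel name
            delta = len(variant.alt) - len(variant.ref)
            if delta < 0:
                c_name = f"{mrna_acc}:c.{consequence.cds_pos}del"
            else:
                c_name = f"{mrna_acc}:c.{consequence.cds_pos}ins{c_alt[len(c_ref):]}"
    return HgvsTriplet(g_name=g_name, c_name=c_name, p_name=p_name)


def read_accession_map(path) -> dict:
    """Read a TSV mapping transcript_id -> (mRNA accession, protein accession)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ConfigurationError(f"accession map rows need 3 columns: {line!r}")
            out[fields[0]] = (fields[1], fields[2])
    return out


def format_g_display(variant: VariantRecord) -> str:
    """Genomic name with thousands separators for human-readable reports."""
    return f"{variant.contig}:{variant.pos:,}{variant.ref}>{variant.alt}"


_C_RE = re.compile(r"^(?P<acc>[^:]+):c\.(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_P_RE = re.compile(
    r"^(?P<acc>[^:]+):p\.\((?:(?P<ref>[A-Z][a-z]{2})(?P<codon>\d+)(?P<alt>[A-Z][a-z]{2}|\*)|=)\)$"
)


def parse_c_name(c_name: str) -> dict:
    """Parse a c. SNV name back into accession, cds_pos and alleles."""
    m = _C_RE.match(c_name)
    if m is None:
        raise ValueError(f"unparseable c. name {c_name!r}")
    return {
        "accession": m["acc"],
        "cds_pos": int(m["pos"]),
        "ref": m["ref"],
        "alt": m["alt"],
    }


def parse_p_name(p_name: str) -> dict:
    """Parse a p. substitution name; silent changes return aa fields as None."""
    m = _P_RE.match(p_name)
    if m is None:
        raise ValueError(f"unparseable p. name {p_name!r}")
    if m["codon"] is None:
        return {"accession": m["acc"], "codon_index": None, "ref_aa": None, "alt_aa": None}
    return {
        "accession": m["acc"],
        "codon_index": int(m["codon"]),
        "ref_aa": ONE_LETTER[m["ref"]],
        "alt_aa": ONE_LETTER[m["alt"]],
    }
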