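"""Dual-frame re-annotation of variants that look silent in the main ORF.

A variant that is synonymous with respect to a gene's main ORF, or that
sits in its 5' UTR, can still change the protein of an overlapping ORF
translated in another frame.  This module classifies each variant's
effect in the main frame, then re-annotates it against every overlapping
ORF, producing consequence strings of the form ``<refAA><index><altAA>``
(multi-allelic alternatives '/'-joined, e.g. ``A146T/A146S/A146P``).

Residue numbering: by default the start codon is residue 1
(``numbering_base=1`` on the ORF).  The published POLG ORF-Y table is
internally consistent with a numbering in which the codon containing
the start anchor is residue 0, i.e. ``index = floor((anchor_high -
pos) / 3)`` on the minus strand; setting ``numbering_base=0``
reproduces it.  The convention in force is surfaced in output headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .code import aa
from .seq_io import (
    OrfDefinition,
    Transcript,
    VariantRecord,
    complement,
    genomic_to_tx,
)

__all__ = [
    "DualConsequence",
    "residue_index",
    "classify_main_effect",
    "annotate_dual",
    "annotate_table",
    "filter_table",
    "consequence_kind",
    "write_annotated_table",
]


@dataclass
class DualConsequence:
    rsid: str
    main_effect: str  # synonymous | missense | nonsense | utr5 | utr3 | non_coding
    per_orf: dict[str, str] = field(default_factory=dict)


def residue_index(orf: OrfDefinition, genomic_pos: int) -> int:
    """Residue index of the codon containing ``genomic_pos``, by
    coordinate arithmetic from the ORF's genomic start-codon anchor.

    For a minus-strand single-exon ORF the anchor is the *highest*
    genomic coordinate of the start codon and
    ``index = floor((anchor - pos) / 3) + numbering_base``;
    for plus strand, ``index = floor((pos - anchor) / 3) +
    numbering_base`` with the anchor at the lowest coordinate.  Raises
    LookupError for positions outside the ORF's genomic extent (spliced
    ORFs need transcript-space annotation via :func:`annotate_dual`).
    """
    if orf.genomic_anchor is None:
        raise ValueError(f"ORF {orf.name} has no genomic anchor")
    if orf.strand == "-":
        delta = orf.genomic_anchor - genomic_pos
    else:
        delta = genomic_pos - orf.genomic_anchor
    if delta < 0 or delta >= len(orf):
        raise LookupError(f"position {genomic_pos} not in ORF {orf.name}")
    return delta // 3 + orf.numbering_base


def classify_main_effect(
    transcript: Transcript, main_orf: OrfDefinition, variant: VariantRecord, alt: str
) -> str:
    """Effect of a single alt on the main ORF: synonymous, missense,
    nonsense, utr5, utr3 or non_coding.

    Variant ref/alt are plus-strand (ClinVar dialect) and complemented
    on the fly for a minus-strand transcript.  A ref allele that does
    not match the transcript raises a data-integrity error naming the
    rsid.  SNVs only.
    """
    if len(variant.ref) != 1 or len(alt) != 1:
        raise ValueError(
            f"variant {variant.rsid}: only single-nucleotide variants are supported; "
            "no indel consequence model is defined for dual-coding regions"
        )
    if transcript.exons:
        tx_pos = genomic_to_tx(transcript, variant.position)
    else:
        # transcript-space variant: position interpreted as 0-based offset
        tx_pos = variant.position
    ref_tx = variant.ref if transcript.strand == "+" else complement(variant.ref)
    alt_tx = alt if transcript.strand == "+" else complement(alt)
    if transcript.sequence[tx_pos] != ref_tx:
        raise ValueError(
            f"variant {variant.rsid}: ref allele {variant.ref} (transcript "
            f"{ref_tx}) does not match transcript base "
            f"{transcript.sequence[tx_pos]} at offset {tx_pos}"
        )
    if tx_pos < main_orf.start_tx:
        return "utr5"
    if tx_pos >= main_orf.end_tx:
        return "utr3"
    offset = tx_pos - main_orf.start_tx
    codon_start = main_orf.start_tx + 3 * (offset // 3)
    codon = transcript.sequence[codon_start : codon_start + 3]
    within = tx_pos - codon_start
    alt_codon = codon[:within] + alt_tx + codon[within + 1 :]
    ref_aa, alt_aa = aa(codon), aa(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def _orf_consequence(
    transcript: Transcript, orf: OrfDefinition, tx_pos: int, alt_tx: str
) -> str:
    if not orf.contains_tx(tx_pos):
        return "not in ORF"
    offset = tx_pos - orf.start_tx
    codon_index = offset // 3
    codon_start = orf.start_tx + 3 * codon_index
    codon = transcript.sequence[codon_start : codon_start + 3]
    within = tx_pos - codon_start
    alt_codon = codon[:within] + alt_tx + codon[within + 1 :]
    if codon_index == 0:
        # the initiation codon decodes as Met whether or not it is AUG;
        # a changed start codon is reported against M with the altered
        # codon's own reading (it may abolish initiation instead)
        ref_aa = "M"
        alt_aa = "M" if alt_codon == codon else aa(alt_codon)
    else:
        ref_aa, alt_aa = aa(codon), aa(alt_codon)
    if codon == alt_codon or ref_aa == alt_aa:
        return "no change"
    index = codon_index + orf.numbering_base
    return f"{ref_aa}{index}{alt_aa}"


def annotate_dual(
    transcript: Transcript,
    orfs: list[OrfDefinition],
    variant: VariantRecord,
    main_orf: OrfDefinition | None = None,
) -> DualConsequence:
    """Annotate one variant against the main ORF and every overlap ORF.

    Per ORF, each alt yields "not in ORF", "no change" (synonymous in
    that frame) or ``<refAA><index><altAA>``; multi-allelic consequences
    are '/'-joined in alt order.  The main effect is taken from
    ``main_orf`` (default: the ORF named "main").
    """
    if main_orf is None:
        main_orf = next((o for o in orfs if o.name == "main"), None)
    if transcript.exons:
        tx_pos = genomic_to_tx(transcript, variant.position)
    else:
        tx_pos = variant.position

    main_effects = []
    if main_orf is not None:
        for alt in variant.alts:
            main_effects.append(classify_main_effect(transcript, main_orf, variant, alt))
    main_effect = "/".join(dict.fromkeys(main_effects)) if main_effects else "non_coding"

    per_orf: dict[str, str] = {}
    for orf in orfs:
        if main_orf is not None and orf.name == main_orf.name:
            continue
        parts = []
        for alt in variant.alts:
            alt_tx = alt if transcript.strand == "+" else complement(alt)
            parts.append(_orf_consequence(transcript, orf, tx_pos, alt_tx))
        if all(p == "not in ORF" for p in parts):
            per_orf[orf.name] = "not in ORF"
        elif all(p in ("no change", "not in ORF") for p in parts):
            per_orf[orf.name] = "no change"
        else:
            # substitutions listed per alt; silent alts render as "no change"
            per_orf[orf.name] = "/".join(parts) if len(parts) > 1 else parts[0]
    return DualConsequence(rsid=variant.rsid, main_effect=main_effect, per_orf=per_orf)


def annotate_table(
    transcript: Transcript,
    orfs: list[OrfDefinition],
    variants: list[VariantRecord],
    main_orf: OrfDefinition | None = None,
) -> list[DualConsequence]:
    return [annotate_dual(transcript, orfs, v, main_orf) for v in variants]


def consequence_kind(consequence: str) -> str:
    """Classify a per-ORF consequence string: 'substitution' (at least
    one alt changes an amino acid), 'no change', or 'not in ORF'."""
    parts = consequence.split("/")
    subs = [
        p
        for p in parts
        if p not in ("no change", "not in ORF")
        and len(p) >= 3
        and p[1:-1].isdigit()
        and p[0] != p[-1]
    ]
    if subs:
        return "substitution"
    if all(p == "not in ORF" for p in parts):
        return "not in ORF"
    return "no change"


def filter_table(
    annotations: list[dict[str, str] | DualConsequence],
    orf_y: str = "ORF-Y",
    orf_z: str = "ORF-Z",
) -> dict[str, int]:
    """Summary counts over annotated variants.

    Accepts either :class:`DualConsequence` objects or plain mappings of
    ORF name to consequence string (e.g. a published table's columns).
    Returns counts of variants changing the ORF-Y peptide, silent in
    ORF-Y, outside ORF-Y, and changing the ORF-Z peptide.
    """
    counts = {
        "orf_y_changed": 0,
        "orf_y_no_change": 0,
        "not_in_orf_y": 0,
        "orf_z_changed": 0,
        "total": 0,
    }
    for ann in annotations:
        per_orf = ann.per_orf if isinstance(ann, DualConsequence) else ann
        counts["total"] += 1
        kind_y = consequence_kind(per_orf.get(orf_y, "not in ORF"))
        if kind_y == "substitution":
            counts["orf_y_changed"] += 1
        elif kind_y == "no change":
            counts["orf_y_no_change"] += 1
        else:
            counts["not_in_orf_y"] += 1
        if consequence_kind(per_orf.get(orf_z, "not in ORF")) == "substitution":
            counts["orf_z_changed"] += 1
    return counts


def write_annotated_table(path, variants, annotations, orf_names) -> None:
    """TSV mirroring the published layout: rsid, change, position, one
    column per overlap ORF, plus the main-frame effect."""
    with open(path, "w") as fh:
        fh.write("rsid\tchange\tposition\tmain_effect\t" + "\t".join(orf_names) + "\n")
        for var, ann in zip(variants, annotations):
            change = f"{var.ref}>{'/'.join(var.alts)}"
            cols = [ann.per_orf.get(name, "not in ORF") for name in orf_names]
            fh.write(
                f"{var.rsid}\t{change}\t{var.chrom}:{var.position}\t"
                f"{ann.main_effect}\t" + "\t".join(cols) + "\n"
            )
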