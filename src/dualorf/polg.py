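"""Published POLG dual-coding annotations packaged with the library.

POLG (minus strand of chromosome 15) carries, besides its main ORF, a
CUG-initiated overlapping ORF in the -1 (+2) frame ("ORF-Y", start
codon at chr15:89,333,807-89,333,809 on GRCh38) and a short AUG uORF
("ORF-Z").  The packaged variant table lists the ClinVar variants that
are synonymous or UTR with respect to the main ORF together with their
published predicted effects on the ORF-Y/ORF-Z peptides.

Residue numbering for ORF-Y follows the published table, which is
internally consistent with ``index = floor((89333809 - pos) / 3)``:
the codon containing the anchor is residue 0 (``numbering_base=0``).
Naive start-codon-equals-residue-1 arithmetic gives indices one higher
than the table throughout; the discrepancy between the quoted start-
codon coordinates and the table numbering is a property of the source
data, recorded here rather than resolved.
"""

from __future__ import annotations

from importlib import resources

from .dual_variant import filter_table
from .seq_io import OrfDefinition, Transcript, VariantRecord, read_variant_table

__all__ = [
    "ORF_Y_ANCHOR_HIGH",
    "orf_y_published",
    "load_table1",
    "table1_consequence_counts",
    "orf_architecture",
]

#: highest genomic coordinate of the ORF-Y CUG start codon (GRCh38, minus strand)
ORF_Y_ANCHOR_HIGH = 89_333_809

#: residues in the published ORF-Y translation (stop excluded)
ORF_Y_AA_LENGTH = 260


def orf_y_published() -> OrfDefinition:
    """The published ORF-Y as a coordinate-arithmetic ORF definition.

    Transcript offsets are a local frame over the ORF itself (0..783);
    the genomic anchor plus minus-strand arithmetic is what Table-style
    residue indices are computed from.  Only the exon-2 portion is
    reachable by coordinate arithmetic alone; positions beyond the
    exon-2 donor need an exon structure.
    """
    return OrfDefinition(
        name="ORF-Y",
        start_tx=0,
        end_tx=3 * (ORF_Y_AA_LENGTH + 1),
        start_codon="CTG",
        frame_offset_vs_main=2,
        genomic_anchor=ORF_Y_ANCHOR_HIGH,
        strand="-",
        numbering_base=0,
    )


def load_table1() -> list[VariantRecord]:
    """The packaged POLG dual-coding variant table (44 rows as published),
    with the published ORF-Y/ORF-Z consequence strings as annotations."""
    ref = resources.files("dualorf.data") / "table1_variants.tsv"
    with resources.as_file(ref) as path:
        return read_variant_table(path)


def table1_consequence_counts() -> dict[str, int]:
    """Summary counts over the packaged variant table's consequences."""
    records = load_table1()
    return filter_table(
        [
            {"ORF-Y": r.annotations.get("orf_y", ""), "ORF-Z": r.annotations.get("orf_z", "")}
            for r in records
        ]
    )


def orf_architecture(transcript: Transcript, orfs: list[OrfDefinition], main_name: str = "main"):
    """Translation lengths and pairwise overlap spans of a set of ORFs.

    Returns ``{orf_name: {"aa_length": ..., "overlap_with_main_nt": ...}}``
    where ``aa_length`` excludes the stop codon and the overlap span is
    the transcript-space intersection with the main ORF.
    """
    main = next((o for o in orfs if o.name == main_name), None)
    out = {}
    for orf in orfs:
        entry = {"aa_length": orf.n_codons - 1, "length_nt": len(orf)}
        if main is not None and orf.name != main_name:
            entry["overlap_with_main_nt"] = max(
                0, min(orf.end_tx, main.end_tx) - max(orf.start_tx, main.start_tx)
            )
        out[orf.name] = entry
    return out
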