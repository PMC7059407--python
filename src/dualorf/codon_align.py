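"""Reference-mapped codon alignments from orthologous CDS sets.

The pipeline mirrors the classical protein-guided route: orthologs pass
quality-control filters, proteins are aligned, the protein alignment is
back-translated codon-by-codon onto the nucleotide sequences (the
``tranalign`` operation), and finally every alignment column containing a
gap in the reference row is removed so that columns index reference
transcript offsets directly.

The built-in protein aligner is a deterministic center-star progressive
aligner (affine gaps, BLOSUM62) intended for synthetic test sets;
production alignments from external tools can be supplied pre-computed as
aligned FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .code import CODON_TO_AA, STOP_CODONS
from .seq_io import normalize, translate

__all__ = [
    "CodonAlignment",
    "OrthologQc",
    "filter_orthologs",
    "align_proteins",
    "back_translate_alignment",
    "map_to_reference",
    "row_quality_report",
]

GAP = "-"


@dataclass
class CodonAlignment:
    """A gap-aware nucleotide alignment indexed in codons.

    ``frame`` declares the reading frame of column 0; ``column_map``
    (present after reference mapping) gives, for each alignment column,
    the corresponding 0-based offset in the ungapped reference sequence.
    """

    reference_id: str
    rows: dict[str, str]
    frame: int = 0
    column_map: list[int] | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def reference_row(self) -> str:
        try:
            return self.rows[self.reference_id]
        except KeyError:
            raise LookupError(f"reference {self.reference_id!r} not in alignment")

    def codon(self, species: str, index: int, frame: int = 0) -> str:
        """The 3 characters of ``species`` at codon ``index`` in ``frame``."""
        start = 3 * index + frame
        return self.rows[species][start : start + 3]


@dataclass
class OrthologQc:
    """BLAST-hit retention rules for ortholog collection."""

    min_query_cover: float = 0.80
    drop_partial: bool = True
    isoform_rule: str = "highest_bit_score"

    def __post_init__(self) -> None:
        if not 0 < self.min_query_cover <= 1:
            raise ValueError("min_query_cover must be in (0, 1]")


def filter_orthologs(hits, qc: OrthologQc | None = None) -> list[str]:
    """Apply ortholog QC to BLAST-style hits.

    ``hits`` are ``(id, name, query_cover, bit_score, species)`` tuples.
    Hits below the query-cover threshold or whose name mentions
    'partial mRNA' are dropped; among same-species survivors only the
    highest-bit-score hit is kept (ties broken by input order).
    """
    qc = qc or OrthologQc()
    best: dict[str, tuple[float, int, str]] = {}
    for order, (hit_id, name, cover, bit_score, species) in enumerate(hits):
        if cover < qc.min_query_cover:
            continue
        if qc.drop_partial and "partial mrna" in name.lower():
            continue
        prev = best.get(species)
        if prev is None or bit_score > prev[0]:
            best[species] = (bit_score, order, hit_id)
    return [hit_id for _, _, hit_id in sorted(best.values(), key=lambda t: t[1])]


# ---------------------------------------------------------------------------
# Protein alignment (center-star progressive, for synthetic tests)


def _pairwise(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    aln = next(iter(aligner.align(a, b)))
    return str(aln[0]), str(aln[1])


def align_proteins(
    seqs: dict[str, str], gap_open: float = -11.0, gap_extend: float = -1.0
) -> dict[str, str]:
    """Global multiple protein alignment around the first sequence.

    Each sequence is aligned pairwise (Needleman-Wunsch, BLOSUM62,
    affine gaps) to the first input sequence, and the pairwise gap
    patterns are merged on the center's coordinates.  Deterministic for
    fixed inputs; input order is the guide order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {name!r}")

    names = list(seqs)
    center = names[0]
    center_seq = seqs[center]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    # Per pairwise alignment, record insertions relative to the center:
    # ins[k] = number of inserted columns before center residue k.
    pairwise: dict[str, tuple[list[int], list[str]]] = {}
    max_ins = [0] * (len(center_seq) + 1)
    for name in names[1:]:
        a_row, b_row = _pairwise(aligner, center_seq, seqs[name])
        ins = [0] * (len(center_seq) + 1)
        cols: list[str] = []  # b characters, grouped per center slot
        k = 0
        for ca, cb in zip(a_row, b_row):
            if ca == GAP:
                ins[k] += 1
            else:
                k += 1
            cols.append(cb)
        pairwise[name] = (ins, cols)
        max_ins = [max(m, i) for m, i in zip(max_ins, ins)]

    out: dict[str, str] = {}
    out[center] = "".join(
        GAP * max_ins[k] + c for k, c in enumerate(center_seq)
    ) + GAP * max_ins[len(center_seq)]
    for name in names[1:]:
        ins, cols = pairwise[name]
        merged: list[str] = []
        k = 0
        i = 0
        while k <= len(center_seq):
            merged.append(GAP * (max_ins[k] - ins[k]))
            merged.append("".join(cols[i : i + ins[k]]))
            i += ins[k]
            if k < len(center_seq):
                merged.append(cols[i])
                i += 1
            k += 1
        out[name] = "".join(merged)

    lengths = {len(s) for s in out.values()}
    assert len(lengths) == 1, "merge produced ragged rows"
    return out


# ---------------------------------------------------------------------------
# Back-translation (tranalign-equivalent)


def back_translate_alignment(
    protein_alignment: dict[str, str],
    cds: dict[str, str],
    reference_id: str | None = None,
) -> CodonAlignment:
    """Thread CDS nucleotides onto a protein alignment, codon per residue.

    Terminal stop codons in the CDS are tolerated (stripped before the
    residue/codon pairing and re-appended as a final codon column when
    every sequence has one).  A residue that does not match the
    translation of its codon raises a per-species error.
    """
    rows: dict[str, str] = {}
    stops: dict[str, str] = {}
    for species, aa_row in protein_alignment.items():
        if species not in cds:
            raise LookupError(f"no CDS for {species!r}")
        nt = normalize(cds[species])
        if len(nt) % 3:
            raise ValueError(f"{species}: CDS length {len(nt)} not a multiple of 3")
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons and codons[-1] in STOP_CODONS:
            stops[species] = codons.pop()
        residues = aa_row.replace(GAP, "")
        if len(residues) != len(codons):
            raise ValueError(
                f"{species}: {len(residues)} aligned residues vs {len(codons)} codons"
            )
        out: list[str] = []
        k = 0
        for pos, ch in enumerate(aa_row):
            if ch == GAP:
                out.append(GAP * 3)
                continue
            codon = codons[k]
            expected = CODON_TO_AA.get(codon, "X")
            if ch != expected and ch != "X" and expected != "X":
                raise ValueError(
                    f"{species}: residue {ch!r} at alignment column {pos} "
                    f"does not match codon {codon} ({expected})"
                )
            out.append(codon)
            k += 1
        rows[species] = "".join(out)

    if stops and len(stops) == len(rows):
        rows = {sp: row + stops[sp] for sp, row in rows.items()}

    ref = reference_id or next(iter(rows))
    return CodonAlignment(reference_id=ref, rows=rows, frame=0)


def map_to_reference(aln: CodonAlignment, reference_id: str | None = None) -> CodonAlignment:
    """Drop every column that is a gap in the reference row.

    The returned reference row is gapless, and ``column_map`` records the
    reference offset of each surviving column.  Idempotent.
    """
    ref_id = reference_id or aln.reference_id
    if ref_id not in aln.rows:
        raise LookupError(f"reference {ref_id!r} not in alignment")
    ref_row = aln.rows[ref_id]
    keep = [i for i, c in enumerate(ref_row) if c != GAP]
    rows = {sp: "".join(row[i] for i in keep) for sp, row in aln.rows.items()}
    return CodonAlignment(
        reference_id=ref_id,
        rows=rows,
        frame=aln.frame,
        column_map=list(range(len(keep))),
    )


def row_quality_report(aln: CodonAlignment) -> dict[str, dict[str, float]]:
    """Per-row gap fraction and identity to the reference.

    Diagnostic only: sequences are reported, never auto-dropped, so that
    a poorly aligning ortholog can be removed by explicit choice.
    """
    ref = aln.reference_row()
    report = {}
    for sp, row in aln.rows.items():
        ungapped = sum(1 for c in row if c != GAP)
        both = [(a, b) for a, b in zip(ref, row) if a != GAP and b != GAP]
        ident = sum(1 for a, b in both if a == b) / len(both) if both else 0.0
        report[sp] = {
            "gap_fraction": 1 - ungapped / len(row) if row else 0.0,
            "identity_to_reference": ident,
        }
    return report
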