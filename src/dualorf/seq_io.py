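"""Sequence, track and variant I/O plus the shared coordinate model.

Conventions used throughout the package:

* transcript offsets are 0-based, half-open;
* genomic positions are 1-based, inclusive (the ClinVar dialect), except
  for bedGraph input which is 0-based half-open as usual;
* the internal alphabet is DNA (``T``); ``U`` in input is normalized to
  ``T`` and the original alphabet is remembered per record so writers can
  round-trip RNA;
* variant ref/alt alleles are always given on the plus strand and are
  complemented on the fly for minus-strand transcripts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Transcript",
    "OrfDefinition",
    "FootprintTrack",
    "VariantRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_track",
    "write_track",
    "read_variant_table",
    "write_variant_table",
    "read_orf_table",
    "write_orf_table",
    "tx_to_genomic",
    "genomic_to_tx",
    "complement",
]

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def complement(base: str) -> str:
    """Complement of a plus-strand base (DNA alphabet)."""
    return base.translate(_COMPLEMENT)


def normalize(seq: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


@dataclass
class Transcript:
    """An mRNA: sense-strand sequence plus optional genomic exon blocks.

    Exon blocks are ``(chrom, genomic_start, genomic_end, strand)`` with
    1-based inclusive genomic coordinates, ordered 5'->3' in transcript
    space (for a minus-strand transcript that means descending genomic
    coordinates).
    """

    id: str
    sequence: str
    exons: list[tuple[str, int, int, str]] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if self.exons:
            exon_len = sum(e[2] - e[1] + 1 for e in self.exons)
            if self.sequence and exon_len != len(self.sequence):
                raise ValueError(
                    f"transcript {self.id}: exon length {exon_len} != "
                    f"sequence length {len(self.sequence)}"
                )
            strands = {e[3] for e in self.exons}
            if len(strands) > 1:
                raise ValueError(f"transcript {self.id}: mixed exon strands")
            self.strand = self.exons[0][3]
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"transcript {self.id}: bad characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfDefinition:
    """An open reading frame on a transcript.

    ``frame_offset_vs_main`` is the frame of this ORF relative to a main
    ORF, in {0, +1, +2}; a "-1 frame" ORF is +2 here.  ``numbering_base``
    is the residue index assigned to the start codon in reported
    consequence strings (1 is the conventional choice; 0 reproduces the
    published POLG ORF-Y table numbering).
    """

    name: str
    start_tx: int
    end_tx: int
    start_codon: str = "ATG"
    frame_offset_vs_main: int = 0
    genomic_anchor: int | None = None
    strand: str = "+"
    numbering_base: int = 1

    def __post_init__(self) -> None:
        self.start_codon = normalize(self.start_codon)
        length = self.end_tx - self.start_tx
        if length <= 0 or length % 3:
            raise ValueError(
                f"ORF {self.name}: length {length} is not a positive multiple of 3"
            )

    def __len__(self) -> int:
        return self.end_tx - self.start_tx

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def contains_tx(self, tx_pos: int) -> bool:
        return self.start_tx <= tx_pos < self.end_tx

    def validate_against(self, transcript: Transcript) -> None:
        """Check start/stop codon identity on the transcript sequence."""
        seq = transcript.sequence
        if seq[self.start_tx : self.start_tx + 3] != self.start_codon:
            raise ValueError(
                f"ORF {self.name}: sequence at {self.start_tx} is "
                f"{seq[self.start_tx:self.start_tx + 3]}, not {self.start_codon}"
            )
        last = seq[self.end_tx - 3 : self.end_tx]
        if last not in STOP_CODONS:
            raise ValueError(f"ORF {self.name}: terminal codon {last} is not a stop")


@dataclass
class FootprintTrack:
    """Per-nucleotide ribosome footprint counts for one sample class."""

    sample_class: str  # "initiating" | "elongating"
    counts: dict[int, int] = field(default_factory=dict)
    coordinate_space: str = "transcript"

    def __post_init__(self) -> None:
        if self.sample_class not in ("initiating", "elongating"):
            raise ValueError(f"unknown sample class {self.sample_class!r}")
        for pos, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count {c} at position {pos}")

    def get(self, pos: int) -> int:
        return self.counts.get(pos, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def span(self) -> tuple[int, int]:
        """(min, max+1) over positions with any recorded count."""
        if not self.counts:
            return (0, 0)
        return (min(self.counts), max(self.counts) + 1)

    def scaled(self, factor: int) -> "FootprintTrack":
        return FootprintTrack(
            self.sample_class,
            {p: c * factor for p, c in self.counts.items()},
            self.coordinate_space,
        )


@dataclass
class VariantRecord:
    """A single-nucleotide substitution (possibly multi-allelic)."""

    rsid: str
    chrom: str
    position: int  # genomic, 1-based
    ref: str
    alts: list[str]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref = normalize(self.ref)
        self.alts = [normalize(a) for a in self.alts]
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise ValueError(f"variant {self.rsid}: empty allele")
        if any(a == self.ref for a in self.alts):
            raise ValueError(f"variant {self.rsid}: alt equals ref")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` preserving file order.

    ``U`` is normalized to ``T``.  An empty record raises
    :class:`FastaFormatError` naming the header line.
    """
    records: list[tuple[str, str]] = []
    header_lines: dict[int, int] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    current: str | None = None
    chunks: list[str] = []
    current_line = 0

    def flush() -> None:
        if current is None:
            return
        seq = normalize("".join(chunks))
        if not seq:
            raise FastaFormatError(
                f"{path}: record {current!r} at line {current_line} has no sequence"
            )
        records.append((current, seq))

    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            current = line[1:].split()[0] if len(line) > 1 else ""
            if not current:
                raise FastaFormatError(f"{path}: empty header at line {i}")
            current_line = i
            chunks = []
            header_lines[len(records)] = i
        else:
            if current is None:
                raise FastaFormatError(f"{path}: sequence before any header at line {i}")
            chunks.append(line)
    flush()
    if current is None:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs (or SeqRecord-compatible tuples)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_biopython(path):
    """Bio.SeqIO view of a FASTA file (records as SeqRecord objects)."""
    return list(SeqIO.parse(path, "fasta"))


# ---------------------------------------------------------------------------
# Footprint tracks (bedGraph-like)


def read_track(path, sample_class: str, coordinate_space: str = "transcript") -> FootprintTrack:
    """Read a bedGraph-like count track into per-nucleotide counts.

    Accepted rows: ``chrom start end count`` (bedGraph proper),
    ``start end count``, or ``position count``.  Interval rows are
    0-based half-open and expanded per nucleotide; overlapping rows sum.
    """
    counts: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if len(fields) == 4:
                    start, end, value = int(fields[1]), int(fields[2]), int(float(fields[3]))
                elif len(fields) == 3:
                    start, end, value = int(fields[0]), int(fields[1]), int(float(fields[2]))
                elif len(fields) == 2:
                    start, value = int(fields[0]), int(float(fields[1]))
                    end = start + 1
                else:
                    raise ValueError("expected 2-4 columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable track row: {exc}") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            for pos in range(start, end):
                counts[pos] = counts.get(pos, 0) + value
    return FootprintTrack(sample_class, counts, coordinate_space)


def write_track(path, track: FootprintTrack, chrom: str = "tx") -> None:
    """Write a track as 4-column bedGraph, merging equal-count runs."""
    with open(path, "w") as fh:
        run_start = run_val = None
        prev = None
        for pos in sorted(track.counts):
            val = track.counts[pos]
            if run_start is not None and pos == prev + 1 and val == run_val:
                prev = pos
                continue
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")
            run_start, run_val, prev = pos, val, pos
        if run_start is not None:
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")


# ---------------------------------------------------------------------------
# Variant tables

_CHANGE_RE = re.compile(r"^([ACGTUacgtu]+)\s*>\s*([ACGTUacgtu]+(?:/[ACGTUacgtu]+)*)$")
_POS_RE = re.compile(r"^(\S+?):(\d+)")


def read_variant_table(path) -> list[VariantRecord]:
    """Read a TSV of variants: columns rsid, change (``G>A/C``), position
    (``chr15:89333491``); extra columns are kept as annotations keyed by
    the header name.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                for req in ("rsid", "change", "position"):
                    if req not in header:
                        raise ValueError(f"{path}: missing required column {req!r}")
                continue
            row = dict(zip(header, (f.strip() for f in fields)))
            rsid = row.get("rsid", "")
            m = _CHANGE_RE.match(row.get("change", ""))
            if not m:
                raise ValueError(
                    f"{path}:{lineno}: variant {rsid!r}: unparseable change "
                    f"{row.get('change')!r}"
                )
            ref, alts = m.group(1), m.group(2).split("/")
            pm = _POS_RE.match(row.get("position", ""))
            if not pm:
                raise ValueError(
                    f"{path}:{lineno}: variant {rsid!r}: unparseable position "
                    f"{row.get('position')!r}"
                )
            extra = {
                k: v
                for k, v in row.items()
                if k not in ("rsid", "change", "position") and v
            }
            records.append(
                VariantRecord(
                    rsid=rsid,
                    chrom=pm.group(1),
                    position=int(pm.group(2)),
                    ref=ref,
                    alts=alts,
                    annotations=extra,
                )
            )
    return records


def write_variant_table(path, records: list[VariantRecord], annotation_columns=()) -> None:
    cols = ["rsid", "change", "position", *annotation_columns]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            change = f"{rec.ref}>{'/'.join(rec.alts)}"
            row = [rec.rsid, change, f"{rec.chrom}:{rec.position}"]
            row += [rec.annotations.get(c, "") for c in annotation_columns]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# ORF definition tables (BED-like)


def read_orf_table(path) -> list[OrfDefinition]:
    """Read a BED-like ORF table: name, tx_start, tx_end, start_codon,
    frame_offset[, genomic_anchor, strand, numbering_base]."""
    orfs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            orfs.append(
                OrfDefinition(
                    name=f[0],
                    start_tx=int(f[1]),
                    end_tx=int(f[2]),
                    start_codon=f[3] if len(f) > 3 else "ATG",
                    frame_offset_vs_main=int(f[4]) if len(f) > 4 else 0,
                    genomic_anchor=int(f[5]) if len(f) > 5 and f[5] != "." else None,
                    strand=f[6] if len(f) > 6 else "+",
                    numbering_base=int(f[7]) if len(f) > 7 else 1,
                )
            )
    return orfs


def write_orf_table(path, orfs: list[OrfDefinition]) -> None:
    with open(path, "w") as fh:
        fh.write("#name\ttx_start\ttx_end\tstart_codon\tframe_offset\tanchor\tstrand\tbase\n")
        for o in orfs:
            anchor = o.genomic_anchor if o.genomic_anchor is not None else "."
            fh.write(
                f"{o.name}\t{o.start_tx}\t{o.end_tx}\t{o.start_codon}\t"
                f"{o.frame_offset_vs_main}\t{anchor}\t{o.strand}\t{o.numbering_base}\n"
            )


# ---------------------------------------------------------------------------
# Coordinate mapping


def tx_to_genomic(transcript: Transcript, tx_pos: int) -> int:
    """Map a 0-based transcript offset to a 1-based genomic position.

    On the minus strand, increasing transcript position maps to
    decreasing genomic coordinate.
    """
    if not transcript.exons:
        raise LookupError(f"transcript {transcript.id} has no exon blocks")
    if tx_pos < 0:
        raise LookupError(f"transcript position {tx_pos} is negative")
    offset = tx_pos
    for _, gstart, gend, strand in transcript.exons:
        exon_len = gend - gstart + 1
        if offset < exon_len:
            if strand == "+":
                return gstart + offset
            return gend - offset
        offset -= exon_len
    raise LookupError(
        f"transcript position {tx_pos} beyond transcript {transcript.id} "
        f"({len(transcript)} nt)"
    )


def genomic_to_tx(transcript: Transcript, genomic_pos: int) -> int:
    """Inverse of :func:`tx_to_genomic`; raises LookupError off-exon."""
    if not transcript.exons:
        raise LookupError(f"transcript {transcript.id} has no exon blocks")
    offset = 0
    for _, gstart, gend, strand in transcript.exons:
        if gstart <= genomic_pos <= gend:
            if strand == "+":
                return offset + (genomic_pos - gstart)
            return offset + (gend - genomic_pos)
        offset += gend - gstart + 1
    raise LookupError(
        f"genomic position {genomic_pos} is not exonic in transcript {transcript.id}"
    )


def translate(seq: str) -> str:
    """Translate a DNA string in frame 0 (standard code, '*' for stop)."""
    return str(Seq(normalize(seq)).translate())
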