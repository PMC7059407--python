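"""Per-frame stop/start codon maps and ORF conservation classification.

Given a reference-mapped codon alignment, these functions locate stop
codons and (near-)cognate start codons in any of the three reading
frames, find long stop-free regions shared across species, and classify
whether an ORF is intact, disrupted or absent in each species — the
comparative-genomics side of the dual-coding argument: an overlapping
ORF that is real should show a long, conserved stop-free region in its
frame in the species that possess it, and lesions (frameshifts, early
stops) in the species that do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .code import NEAR_COGNATE_STARTS, STOP_CODONS
from .codon_align import GAP, CodonAlignment
from .seq_io import OrfDefinition

__all__ = [
    "FrameMap",
    "OrfConservation",
    "stop_map",
    "stop_free_region",
    "classify_orf_conservation",
    "write_frame_map",
    "write_conservation_report",
]

_VALID = set("ACGT")


@dataclass
class FrameMap:
    """Per-species codon-index lists of stops and candidate starts in one frame."""

    frame: int
    n_codons: int
    stops: dict[str, list[int]] = field(default_factory=dict)
    starts_atg: dict[str, list[int]] = field(default_factory=dict)
    starts_near_cognate: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class OrfConservation:
    species: str
    status: str  # intact | early_stop | frameshifted | start_lost | missing
    first_stop_codon: int | None = None  # codon index of the first premature stop


def stop_map(aln: CodonAlignment, frame: int) -> FrameMap:
    """Locate stops, ATGs and near-cognate starts in a shifted frame.

    Codon index ``k`` covers alignment columns ``[3k+frame, 3k+frame+3)``.
    Triplets containing gaps or ambiguity codes are no-calls (skipped),
    matching the convention of treating gapped alignment regions as
    uninformative rather than stop-free.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    n_codons = (aln.length - frame) // 3
    fmap = FrameMap(frame=frame, n_codons=n_codons)
    for species, row in aln.rows.items():
        stops, atgs, near = [], [], []
        for k in range(n_codons):
            triplet = row[3 * k + frame : 3 * k + frame + 3]
            if set(triplet) - _VALID:
                continue
            if triplet in STOP_CODONS:
                stops.append(k)
            if triplet == "ATG":
                atgs.append(k)
            elif triplet in NEAR_COGNATE_STARTS:
                near.append(k)
        fmap.stops[species] = stops
        fmap.starts_atg[species] = atgs
        fmap.starts_near_cognate[species] = near
    return fmap


def stop_free_region(fmap: FrameMap, min_species_fraction: float = 1.0) -> list[tuple[int, int]]:
    """Maximal codon intervals where >= ``min_species_fraction`` of
    species lack a stop codon; returned sorted and non-overlapping,
    half-open in codon indices."""
    n_species = len(fmap.stops)
    if n_species == 0 or fmap.n_codons == 0:
        return []
    stop_counts = [0] * fmap.n_codons
    for stops in fmap.stops.values():
        for k in stops:
            stop_counts[k] += 1
    ok = [
        (n_species - c) / n_species >= min_species_fraction for c in stop_counts
    ]
    intervals = []
    start = None
    for k, good in enumerate(ok):
        if good and start is None:
            start = k
        elif not good and start is not None:
            intervals.append((start, k))
            start = None
    if start is not None:
        intervals.append((start, fmap.n_codons))
    return intervals


def classify_orf_conservation(
    aln: CodonAlignment,
    orf: OrfDefinition,
    allow_near_cognate: bool = True,
    missing_gap_fraction: float = 0.5,
) -> list[OrfConservation]:
    """Classify each species' state of an ORF defined on the reference.

    Checked in precedence order: ``missing`` (more than
    ``missing_gap_fraction`` of the ORF's columns are gaps),
    ``frameshifted`` (the species' ungapped length over the ORF differs
    from the reference's by a non-multiple of 3), ``start_lost`` (no
    exact — or, if ``allow_near_cognate``, no one-mismatch-from-ATG —
    start codon at the homologous start position), ``early_stop`` (an
    in-frame stop before the reference stop codon), else ``intact``.

    Frameshift takes precedence over codon-level calls because an
    out-of-frame row makes positional stop/start calls meaningless.
    """
    ref_row = aln.reference_row()
    lo, hi = orf.start_tx, orf.end_tx
    if hi > aln.length:
        raise ValueError(f"ORF {orf.name} extends past the alignment ({aln.length})")
    ref_ungapped = sum(1 for c in ref_row[lo:hi] if c != GAP)

    results = []
    for species, row in aln.rows.items():
        segment = row[lo:hi]
        gap_frac = segment.count(GAP) / len(segment)
        ungapped = len(segment) - segment.count(GAP)
        start_codon = row[lo : lo + 3]
        n_codons = (hi - lo) // 3

        first_stop = None
        for k in range(n_codons - 1):  # exclude the reference stop codon itself
            triplet = row[lo + 3 * k : lo + 3 * k + 3]
            if set(triplet) - _VALID:
                continue
            if triplet in STOP_CODONS:
                first_stop = k
                break

        if gap_frac > missing_gap_fraction:
            status = "missing"
        elif (ungapped - ref_ungapped) % 3:
            status = "frameshifted"
        elif not _start_ok(start_codon, orf.start_codon, allow_near_cognate):
            status = "start_lost"
        elif first_stop is not None:
            status = "early_stop"
        else:
            status = "intact"
        results.append(OrfConservation(species, status, first_stop))
    return results


def _start_ok(observed: str, expected: str, allow_near_cognate: bool) -> bool:
    if set(observed) - _VALID:
        return False
    if observed == expected:
        return True
    if allow_near_cognate:
        return observed in NEAR_COGNATE_STARTS
    return False


def write_frame_map(path, fmap: FrameMap) -> None:
    """TSV of per-species stop positions for one frame (plot-ready)."""
    with open(path, "w") as fh:
        fh.write("species\tframe\tkind\tcodon_index\n")
        for kind, table in (
            ("stop", fmap.stops),
            ("atg", fmap.starts_atg),
            ("near_cognate", fmap.starts_near_cognate),
        ):
            for species, indices in table.items():
                for k in indices:
                    fh.write(f"{species}\t{fmap.frame}\t{kind}\t{k}\n")


def write_conservation_report(path, results: list[OrfConservation]) -> None:
    with open(path, "w") as fh:
        fh.write("species\tstatus\tfirst_premature_stop_codon\n")
        for r in results:
            stop = r.first_stop_codon if r.first_stop_codon is not None else "."
            fh.write(f"{r.species}\t{r.status}\t{stop}\n")
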