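"""Synthetic-data generators with labelled ground truth.

Every analysis stage in this package gets a test bed here:

* :func:`simulate_alignment` — star-phylogeny codon alignments evolved
  with only-synonymous substitutions, optionally with a dual-coded
  segment in which proposed changes must also be synonymous in the
  overlapping frame (the evolutionary signature of an overlapping ORF);
* :func:`simulate_footprints` — phased ribosome-footprint tracks from a
  leaky-scanning/reinitiation flux model, with initiation peaks at start
  codons and a density step at internal stop codons;
* :func:`simulate_variants` — variant sets synonymous (or UTR) with
  respect to a main ORF, with oracle dual-frame consequences;
* :func:`make_fixture_transcript` — a deterministic ~1 kb miniature
  transcript with the three-ORF architecture studied here: a short
  AUG uORF, a CUG-initiated ORF in the +2 frame with a strong
  GCCAAGCTGG initiation context and a stem-loop whose first paired base
  sits 14 nt downstream of the G of the CUG, overlapping a main AUG ORF.

Generators are deterministic under their seed and always return truth
labels alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .code import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, aa
from .codon_align import CodonAlignment
from .dual_variant import annotate_dual
from .seq_io import FootprintTrack, OrfDefinition, Transcript, complement, tx_to_genomic

__all__ = [
    "AlignmentSimParams",
    "FootprintSimParams",
    "simulate_alignment",
    "inject_lesion",
    "simulate_footprints",
    "simulate_variants",
    "make_fixture_transcript",
]

BASES = "ACGT"
REINIT_MAX_CODONS = 30  # uORFs at most this long can resume scanning after their stop


@dataclass
class AlignmentSimParams:
    """Conditions for the star-phylogeny alignment simulator.

    ``branch_length`` is the expected number of proposed substitutions
    per nucleotide site on each terminal branch; only proposals that are
    synonymous in frame 0 (and, in the dual-coded segment of
    ``dual_constrained`` mode, also in the overlapping frame) are
    accepted, so the realized synonymous divergence is lower.
    ``overlap`` is a half-open codon interval of frame-0 codons.
    """

    n_species: int = 12
    branch_length: float = 0.4
    orf_len: int = 400
    overlap: tuple[int, int] | None = None
    mode: str = "neutral_synonymous"  # or "dual_constrained"
    overlap_frame: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_length < 0:
            raise ValueError("branch_length must be >= 0")
        if self.mode not in ("neutral_synonymous", "dual_constrained"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.overlap is not None:
            a, b = self.overlap
            if not (0 <= a < b <= self.orf_len):
                raise ValueError(f"overlap {self.overlap} outside [0, {self.orf_len})")
        if self.overlap_frame not in (1, 2):
            raise ValueError("overlap_frame must be +1 or +2")


def _sample_ancestor(params: AlignmentSimParams, rng: np.random.Generator) -> str:
    """Ancestral CDS: sense codons in frame 0, with no stop codons in the
    overlapping frame inside the dual-coded segment."""
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), params.orf_len)]
    if params.overlap is None:
        return "".join(codons)
    a, b = params.overlap
    f = params.overlap_frame
    for _ in range(500):
        seq = "".join(codons)
        bad = _alt_frame_stops(seq, 3 * a, 3 * b, f)
        if not bad:
            return seq
        for pos in bad:  # resample the frame-0 codons touching this triplet
            for c0 in {pos // 3, (pos + 2) // 3}:
                if a <= c0 < b:
                    codons[c0] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
    raise RuntimeError("could not build a stop-free dual-coded ancestor")


def _alt_frame_stops(seq: str, nt_lo: int, nt_hi: int, frame: int) -> list[int]:
    """Start positions of stop triplets in the shifted frame within [nt_lo, nt_hi)."""
    bad = []
    start = nt_lo + frame
    for p in range(start, nt_hi - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            bad.append(p)
    return bad


def simulate_alignment(params: AlignmentSimParams) -> tuple[CodonAlignment, dict]:
    """Evolve a star-tree codon alignment under synonymous-only change.

    Per species, Poisson(branch_length x 3 x orf_len) single-nucleotide
    proposals are applied sequentially; a proposal is accepted iff it is
    synonymous in frame 0 and (outside the overlap, or the mode is
    neutral, or also synonymous in the overlapping frame).  The ancestor
    is included as the reference row ``ref``.
    """
    rng = np.random.default_rng(params.seed)
    ancestor = _sample_ancestor(params, rng)
    n_nt = 3 * params.orf_len
    a, b = params.overlap if params.overlap is not None else (0, 0)
    nt_lo, nt_hi = 3 * a, 3 * b
    f = params.overlap_frame
    constrain = params.mode == "dual_constrained" and params.overlap is not None

    rows = {"ref": ancestor}
    accepted_in = accepted_out = 0
    for s in range(params.n_species):
        seq = list(ancestor)
        n_prop = rng.poisson(params.branch_length * n_nt)
        positions = rng.integers(0, n_nt, n_prop)
        draws = rng.integers(0, 3, n_prop)
        for pos, draw in zip(positions, draws):
            old = seq[pos]
            new = [b_ for b_ in BASES if b_ != old][draw]
            c0 = pos // 3
            codon_lo = 3 * c0
            old_codon = "".join(seq[codon_lo : codon_lo + 3])
            new_codon = (
                old_codon[: pos - codon_lo] + new + old_codon[pos - codon_lo + 1 :]
            )
            if CODON_TO_AA[old_codon] != CODON_TO_AA.get(new_codon):
                continue
            inside = nt_lo <= pos < nt_hi
            if constrain and inside:
                j = (pos - f) // 3
                alt_lo = 3 * j + f
                if alt_lo >= nt_lo and alt_lo + 3 <= nt_hi:
                    old_alt = "".join(seq[alt_lo : alt_lo + 3])
                    new_alt = (
                        old_alt[: pos - alt_lo] + new + old_alt[pos - alt_lo + 1 :]
                    )
                    if CODON_TO_AA.get(old_alt) != CODON_TO_AA.get(new_alt):
                        continue
            seq[pos] = new
            if inside:
                accepted_in += 1
            else:
                accepted_out += 1
        rows[f"sp{s + 1:02d}"] = "".join(seq)

    aln = CodonAlignment(reference_id="ref", rows=rows, frame=0)
    truth = {
        "mode": params.mode,
        "overlap_codons": params.overlap,
        "overlap_frame": params.overlap_frame,
        "accepted_inside_overlap": accepted_in,
        "accepted_outside_overlap": accepted_out,
    }
    return aln, truth


def inject_lesion(
    row: str,
    kind: str,
    orf_span: tuple[int, int],
    rng: np.random.Generator,
) -> str:
    """Introduce one ORF-disrupting lesion into an alignment row.

    ``frameshift`` deletes one base (as an alignment gap) inside the
    ORF; ``early_stop`` converts an internal codon to TAA;
    ``start_lost`` replaces the start codon with AAA (not near-cognate);
    ``missing`` gaps out the first 60% of the ORF.
    """
    lo, hi = orf_span
    chars = list(row)
    if kind == "frameshift":
        pos = int(rng.integers(lo + 3, hi - 3))
        chars[pos] = "-"
    elif kind == "early_stop":
        n_codons = (hi - lo) // 3
        k = int(rng.integers(1, max(2, n_codons - 1)))
        chars[lo + 3 * k : lo + 3 * k + 3] = "TAA"
    elif kind == "start_lost":
        chars[lo : lo + 3] = "AAA"
    elif kind == "missing":
        span = int(0.6 * (hi - lo))
        chars[lo : lo + span] = "-" * span
    else:
        raise ValueError(f"unknown lesion kind {kind!r}")
    return "".join(chars)


# ---------------------------------------------------------------------------
# Ribosome-footprint simulation


@dataclass
class FootprintSimParams:
    """Leaky-scanning/reinitiation flux model for footprint tracks.

    ``init_fraction[name]`` is the fraction of scanning ribosomes
    arriving at that ORF's start that initiate there; the rest scan on.
    Ribosomes terminating a uORF of at most REINIT_MAX_CODONS codons
    re-enter the scanning pool with probability ``reinit_fraction`` for
    ORFs starting downstream of that uORF's stop.  Elongating reads are
    Poisson-placed per nucleotide with ``frame_fidelity`` probability of
    landing on the first sub-codon position of their ORF's frame;
    initiating reads concentrate at start codons (``peak_boost``).
    """

    orf_layout: list[OrfDefinition] = field(default_factory=list)
    init_fraction: dict[str, float] = field(default_factory=dict)
    frame_fidelity: float = 0.9
    n_reads: int = 50_000
    peak_boost: float = 50.0
    reinit_fraction: float = 0.5
    stop_boost: float = 1.0
    background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in self.init_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"init fraction for {name} must be in [0, 1]")
        if not 1 / 3 < self.frame_fidelity <= 1:
            raise ValueError("frame_fidelity must be in (1/3, 1]")


def _compute_fluxes(params: FootprintSimParams) -> dict[str, float]:
    """Initiated ribosome flux per ORF under leaky scanning/reinitiation."""
    orfs = sorted(params.orf_layout, key=lambda o: o.start_tx)
    initiated: dict[str, float] = {}
    for orf in orfs:
        scanning = 1.0
        for prev in orfs:
            if prev.start_tx >= orf.start_tx:
                break
            taken = initiated[prev.name]
            reinit_ok = (
                prev.n_codons <= REINIT_MAX_CODONS and prev.end_tx <= orf.start_tx
            )
            returned = taken * params.reinit_fraction if reinit_ok else 0.0
            scanning -= taken - returned
        initiated[orf.name] = scanning * params.init_fraction.get(orf.name, 0.0)
    return initiated


def simulate_footprints(
    params: FootprintSimParams,
) -> tuple[FootprintTrack, FootprintTrack, dict]:
    """Generate (initiating, elongating) tracks plus truth labels.

    Truth records the per-ORF initiated flux and, for every ORF whose
    stop codon lies inside another ORF, the expected upstream/downstream
    density ratio across that stop (1/(1 - terminating fraction)).
    """
    if not params.orf_layout:
        raise ValueError("orf_layout is empty")
    rng = np.random.default_rng(params.seed)
    orfs = sorted(params.orf_layout, key=lambda o: o.start_tx)
    length = max(o.end_tx for o in orfs) + 60
    flux = _compute_fluxes(params)

    # elongating track
    lam = np.zeros(length)
    unit_total = sum(flux[o.name] * len(o) for o in orfs)
    if unit_total <= 0:
        depth = 0.0
    else:
        depth = params.n_reads / unit_total
    for o in orfs:
        fl = flux[o.name] * depth
        if fl == 0:
            continue
        for p in range(o.start_tx, o.end_tx):
            in_frame = (p - o.start_tx) % 3 == 0
            factor = (
                3 * params.frame_fidelity
                if in_frame
                else 3 * (1 - params.frame_fidelity) / 2
            )
            boost = params.stop_boost if p >= o.end_tx - 3 else 1.0
            lam[p] += fl * factor * boost
    elong_counts = rng.poisson(lam)
    elongating = FootprintTrack(
        "elongating", {p: int(c) for p, c in enumerate(elong_counts) if c > 0}
    )

    # initiating track: peaks on start codons over a faint scanning background
    n_init = max(1000, params.n_reads // 10)
    weight = np.full(length, params.background)
    for o in orfs:
        for p in range(o.start_tx, o.start_tx + 3):
            weight[p] += flux[o.name] * params.peak_boost
    lam_init = n_init * weight / weight.sum()
    init_counts = rng.poisson(lam_init)
    initiating = FootprintTrack(
        "initiating", {p: int(c) for p, c in enumerate(init_counts) if c > 0}
    )

    drop_ratios = {}
    for o in orfs:
        others = [
            x for x in orfs if x is not o and x.start_tx < o.end_tx <= x.end_tx
        ]
        if not others:
            continue
        down = sum(flux[x.name] for x in others)
        up = down + flux[o.name]
        if down > 0:
            drop_ratios[o.name] = up / down
    truth = {
        "flux": flux,
        "depth": depth,
        "drop_ratio_at_stop": drop_ratios,
        "terminating_fraction": {
            name: 1 - 1 / ratio for name, ratio in drop_ratios.items()
        },
    }
    return initiating, elongating, truth


# ---------------------------------------------------------------------------
# Variant sets


def simulate_variants(
    transcript: Transcript,
    orfs: list[OrfDefinition],
    n: int = 20,
    seed: int = 0,
    main_name: str = "main",
) -> tuple[list, dict]:
    """Sample SNVs that are synonymous in the main frame (or UTR).

    Positions are drawn until ``n`` qualifying variants are found; the
    truth labels carry each variant's oracle dual-frame consequence
    computed with :func:`dualorf.dual_variant.annotate_dual`.
    Returned refs/alts are plus-strand (ClinVar dialect).
    """
    from .seq_io import VariantRecord

    rng = np.random.default_rng(seed)
    main = next(o for o in orfs if o.name == main_name)
    seq = transcript.sequence
    variants = []
    truth = {}
    attempts = 0
    while len(variants) < n and attempts < 200 * n:
        attempts += 1
        tx_pos = int(rng.integers(0, len(seq)))
        ref_tx = seq[tx_pos]
        alt_tx = BASES[rng.integers(0, 4)]
        if alt_tx == ref_tx:
            continue
        if main.contains_tx(tx_pos):
            off = tx_pos - main.start_tx
            cstart = main.start_tx + 3 * (off // 3)
            codon = seq[cstart : cstart + 3]
            alt_codon = (
                codon[: tx_pos - cstart] + alt_tx + codon[tx_pos - cstart + 1 :]
            )
            if aa(codon) != aa(alt_codon):
                continue
        if transcript.exons:
            pos = tx_to_genomic(transcript, tx_pos)
            ref = ref_tx if transcript.strand == "+" else complement(ref_tx)
            alt = alt_tx if transcript.strand == "+" else complement(alt_tx)
            chrom = transcript.exons[0][0]
        else:
            pos, ref, alt, chrom = tx_pos, ref_tx, alt_tx, "tx"
        rsid = f"sim{len(variants) + 1}"
        rec = VariantRecord(rsid=rsid, chrom=chrom, position=pos, ref=ref, alts=[alt])
        variants.append(rec)
        truth[rsid] = annotate_dual(transcript, orfs, rec, main_orf=main)
    if len(variants) < n:
        raise RuntimeError("could not sample enough qualifying variants")
    return variants, truth


# ---------------------------------------------------------------------------
# The canonical miniature fixture


def _repair_stops(
    seq: list[str],
    frames: list[tuple[int, int, int]],
    frozen: set[int],
    rng: np.random.Generator,
) -> None:
    """Resample bases until no frame in ``frames`` contains a stop codon.

    Each frame is (nt_lo, nt_hi, phase_anchor): triplets start at
    phase_anchor + 3k within [nt_lo, nt_hi).  Bases at ``frozen``
    offsets are never touched.
    """
    for _ in range(1000):
        dirty = False
        for nt_lo, nt_hi, anchor in frames:
            start = nt_lo + (anchor - nt_lo) % 3
            for p in range(start, nt_hi - 2, 3):
                if "".join(seq[p : p + 3]) in STOP_CODONS:
                    free = [q for q in range(p, p + 3) if q not in frozen]
                    if not free:
                        raise RuntimeError("stop codon locked by frozen bases")
                    for q in free:
                        seq[q] = BASES[rng.integers(0, 4)]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("could not repair stop codons")


def make_fixture_transcript(seed: int = 7):
    """Deterministic POLG-like miniature transcript and its three ORFs.

    Architecture (transcript offsets):

    * ORF-Z: AUG uORF at 30, 23 codons + stop (ends 102), G at -3 and +4;
    * ORF-Y: CUG at 150 in context GCCAAGCTGG, +2 frame relative to the
      main ORF, 120 codons + stop (ends 513); a 6-bp stem-loop whose
      first paired base is 14 nt downstream of the G of the CUG;
    * main ORF: AUG at 202, 250 codons incl. stop (ends 952).

    The transcript is anchored to a synthetic minus-strand single-exon
    gene so that genomic arithmetic (ClinVar-style positions) can be
    exercised.  Returns ``(transcript, orfs, extras)`` where ``extras``
    carries the stem dot-bracket over the post-start window (G = offset
    0) and the stem pairs in window coordinates.
    """
    rng = np.random.default_rng(seed)
    L = 1000
    seq = [BASES[i] for i in rng.integers(0, 4, L)]

    # ORF-Z: favorable context (G at -3/+4 via first codon GCT)
    seq[27] = "G"
    seq[30:33] = "ATG"
    seq[33:36] = "GCT"
    for k in range(2, 23):
        seq[30 + 3 * k : 33 + 3 * k] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
    seq[99:102] = "TGA"

    # ORF-Y start context and codon
    seq[144:153] = "GCCAAGCTG"
    seq[153] = "G"

    # stem-loop: first paired base at tx 166 = offset +14 from the G at 152
    stem5, loop, stem3 = "GGCGGC", "TCAAC", "GCCGCC"
    seq[166:172] = stem5
    seq[172:177] = loop
    seq[177:183] = stem3
    seq[165] = "A"  # completes codon 165..168 as AGG

    # main ORF start and the two stop codons
    seq[202:205] = "ATG"
    seq[510:513] = "TGA"  # ORF-Y stop
    seq[949:952] = "TAA"  # main stop

    frozen = (
        set(range(27, 28))
        | set(range(30, 36))
        | set(range(99, 102))
        | set(range(144, 154))
        | set(range(165, 183))
        | set(range(202, 205))
        | set(range(510, 513))
        | set(range(949, 952))
    )
    # keep ORF-Z internal codons as sampled (already sense codons)
    frames = [
        (150, 510, 150),  # ORF-Y frame, internally stop-free up to its stop
        (202, 949, 202),  # main frame, stop-free up to its stop
    ]
    _repair_stops(seq, frames, frozen, rng)

    sequence = "".join(seq)
    g_hi = 500_000 + L - 1
    transcript = Transcript(
        id="POLG-like-fixture",
        sequence=sequence,
        exons=[("chrS", 500_000, g_hi, "-")],
    )
    orfs = [
        OrfDefinition(
            name="main",
            start_tx=202,
            end_tx=952,
            start_codon="ATG",
            frame_offset_vs_main=0,
            genomic_anchor=tx_to_genomic(transcript, 202),
            strand="-",
        ),
        OrfDefinition(
            name="ORF-Y",
            start_tx=150,
            end_tx=513,
            start_codon="CTG",
            frame_offset_vs_main=2,
            genomic_anchor=tx_to_genomic(transcript, 150),
            strand="-",
        ),
        OrfDefinition(
            name="ORF-Z",
            start_tx=30,
            end_tx=102,
            start_codon="ATG",
            frame_offset_vs_main=2,
            genomic_anchor=tx_to_genomic(transcript, 30),
            strand="-",
        ),
    ]
    for orf in orfs:
        orf.validate_against(transcript)

    # dot-bracket over the window starting at the G of the CUG (tx 152)
    window_start = 152
    stem_pairs = [(166 - window_start + k, 182 - window_start - k) for k in range(6)]
    window_len = 183 - window_start
    structure = ["."] * window_len
    for i, j in stem_pairs:
        structure[i], structure[j] = "(", ")"
    extras = {
        "stem_structure": "".join(structure),
        "stem_pairs": stem_pairs,
        "stem_window_start_tx": window_start,
        "stem_seq": sequence[166:183],
        "context_10mer": sequence[144:154],
        "regions": [
            ("orfY_only", 150, 202),
            ("overlap", 202, 513),
            ("main_only", 513, 952),
        ],
    }
    return transcript, orfs, extras
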