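"""Evaluation of candidate (non-AUG) translation initiation sites.

Initiation efficiency at a near-cognate codon such as CUG depends on
two sequence features: the Kozak context (an A or G at position -3 and
a G at +4, with -3 dominating and A preferred over G) and a stable RNA
stem-loop beginning roughly 15 nt downstream of the initiation site,
which pauses the scanning pre-initiation complex over the codon.  This
module scores contexts, tallies context matrices for logo rendering,
measures start-to-stem distance in the "G of the start codon is
nucleotide 0" convention, and quantifies compensatory (pairing-
preserving) substitution support for a stem across an alignment.

The built-in folder maximizes Watson-Crick + GU pair count by dynamic
programming; thermodynamic consensus structures from external tools can
be supplied as dot-bracket strings instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .code import BASES, NEAR_COGNATE_STARTS
from .seq_io import normalize

__all__ = [
    "StartContext",
    "StemLoopCall",
    "find_near_cognate_starts",
    "score_context",
    "context_matrix",
    "write_context_matrix",
    "parse_dot_bracket",
    "stem_distance",
    "fold_window",
    "compensatory_pairs",
]

PURINES = {"A", "G"}
CANONICAL_PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG"}  # WC + GU wobble (DNA alphabet)
MIN_LOOP = 3  # unpaired bases inside the tightest hairpin
OPTIMAL_STEM_BAND = (12, 17)  # nt downstream of the start codon's last base


@dataclass
class StartContext:
    """Scored initiation context for one candidate start codon.

    ``context`` is the 10-mer spanning -6..+4 (six upstream bases, the
    codon, and the +4 base); position -3 and +4 determine ``strength``:
    strong needs a purine at -3 and G at +4, adequate exactly one of the
    two, weak neither.
    """

    position: int
    codon: str
    context: str
    minus3: str
    plus4: str
    strength: str
    score: float
    truncated: bool = False


@dataclass
class StemLoopCall:
    structure: str
    first_paired_offset: int | None
    pairs: list[tuple[int, int]]
    optimal_distance: bool
    compensatory_support: dict[tuple[int, int], dict[str, int]] = field(default_factory=dict)


def find_near_cognate_starts(seq: str, region: tuple[int, int] | None = None) -> list[tuple[int, str]]:
    """All positions in ``region`` whose 3-mer is ATG or one mismatch away.

    ``region`` is half-open over codon start offsets; default is the
    whole sequence.  Returns sorted (position, codon) pairs.
    """
    seq = normalize(seq)
    lo, hi = region if region is not None else (0, len(seq) - 2)
    if lo < 0 or hi > len(seq) - 2 + 1 or lo > hi:
        raise ValueError(f"region {region} outside sequence of length {len(seq)}")
    out = []
    for pos in range(lo, min(hi, len(seq) - 2)):
        codon = seq[pos : pos + 3]
        if codon in NEAR_COGNATE_STARTS:
            out.append((pos, codon))
    return out


def score_context(seq: str, start_pos: int) -> StartContext:
    """Score the initiation context around the codon at ``start_pos``.

    Score: 3 for A at -3, 2 for G at -3, 1 for G at +4, plus 0.5 for
    each of positions -6,-5,-4,-2,-1 matching the G,C,C,C,C consensus.
    Contexts truncated by the sequence end are scored on the available
    positions and flagged.
    """
    seq = normalize(seq)
    if not 0 <= start_pos <= len(seq) - 3:
        raise ValueError(f"start position {start_pos} out of range")
    codon = seq[start_pos : start_pos + 3]

    upstream = seq[max(0, start_pos - 6) : start_pos].rjust(6, ".")
    plus4 = seq[start_pos + 3] if start_pos + 3 < len(seq) else "."
    context = upstream + codon + plus4
    truncated = "." in context
    minus3 = upstream[3]

    score = 0.0
    if minus3 == "A":
        score += 3
    elif minus3 == "G":
        score += 2
    if plus4 == "G":
        score += 1
    consensus = {0: "G", 1: "C", 2: "C", 4: "C", 5: "C"}  # -6,-5,-4,-2,-1
    score += 0.5 * sum(1 for i, b in consensus.items() if upstream[i] == b)

    good_minus3 = minus3 in PURINES
    good_plus4 = plus4 == "G"
    if good_minus3 and good_plus4:
        strength = "strong"
    elif good_minus3 or good_plus4:
        strength = "adequate"
    else:
        strength = "weak"
    return StartContext(
        position=start_pos,
        codon=codon,
        context=context,
        minus3=minus3,
        plus4=plus4,
        strength=strength,
        score=score,
        truncated=truncated,
    )


def context_matrix(contexts: list[str]) -> tuple[np.ndarray, int]:
    """Position x base (A,C,G,T) count matrix over equal-length contexts.

    Contexts containing gaps or non-ACGT(U) characters are dropped; the
    number retained is returned alongside the matrix so logo tools can
    report coverage.  Column sums equal the retained count.
    """
    cleaned = []
    length = None
    for ctx in contexts:
        ctx = normalize(ctx)
        if length is None:
            length = len(ctx)
        elif len(ctx) != length:
            raise ValueError(f"mixed context lengths: {len(ctx)} vs {length}")
        if set(ctx) <= set(BASES):
            cleaned.append(ctx)
    if length is None:
        raise ValueError("no contexts given")
    matrix = np.zeros((length, 4), dtype=int)
    base_index = {b: i for i, b in enumerate(BASES)}
    for ctx in cleaned:
        for pos, b in enumerate(ctx):
            matrix[pos, base_index[b]] += 1
    return matrix, len(cleaned)


def write_context_matrix(path, matrix: np.ndarray, offsets=None) -> None:
    """TSV with one row per position (A,C,G,T columns), logo-tool ready."""
    n = matrix.shape[0]
    if offsets is None:
        offsets = list(range(-6, -6 + n))
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\n")
        for off, row in zip(offsets, matrix):
            fh.write(f"{off}\t" + "\t".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Secondary structure


def parse_dot_bracket(structure: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, from a dot-bracket string.

    Unbalanced structures raise a format error; hairpin loops shorter
    than MIN_LOOP are rejected as geometrically impossible.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs.append((j, i))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    for i, j in pairs:
        if j - i - 1 < MIN_LOOP and all(not (i < a and b < j) for a, b in pairs if (a, b) != (i, j)):
            raise ValueError(f"hairpin loop shorter than {MIN_LOOP} at pair ({i},{j})")
    return sorted(pairs)


def stem_distance(structure: str, start_pos_of_g: int = 0) -> StemLoopCall:
    """Distance from a start codon to the first paired base of a stem.

    Offsets follow the convention that the G (last base) of the start
    codon is nucleotide 0, so ``start_pos_of_g`` is the string index of
    that G.  The call is flagged optimal when the first paired base lies
    in the [12, 17] nt band around the ~15 nt distance that favors
    initiation at near-cognate codons (the observed value in POLG is 14).
    """
    pairs = parse_dot_bracket(structure)
    if not pairs:
        return StemLoopCall(structure, None, [], False)
    first_paired = min(i for i, _ in pairs)
    offset = first_paired - start_pos_of_g
    lo, hi = OPTIMAL_STEM_BAND
    return StemLoopCall(structure, offset, pairs, lo <= offset <= hi)


def fold_window(seq: str) -> str:
    """Maximum base-pairing (Nussinov) fold of a window, as dot-bracket.

    Watson-Crick and GU pairs, minimum hairpin loop of MIN_LOOP unpaired
    bases, deterministic traceback (prefers leaving the right end
    unpaired, then the smallest pairing partner).  A pair-count
    maximizer, not a thermodynamic model: use it for synthetic fixtures
    and tests, and supply external consensus structures for real data.
    """
    seq = normalize(seq)
    n = len(seq)
    if n == 0:
        return ""

    def can_pair(i: int, j: int) -> bool:
        return seq[i] + seq[j] in CANONICAL_PAIRS

    best = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            value = best[i][j - 1]
            for k in range(i, j - MIN_LOOP):
                if can_pair(k, j):
                    left = best[i][k - 1] if k > i else 0
                    cand = left + 1 + best[k + 1][j - 1]
                    if cand > value:
                        value = cand
            best[i][j] = value

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j > i:
            if best[i][j] == (best[i][j - 1] if j - 1 >= i else 0):
                j -= 1
                continue
            for k in range(i, j - MIN_LOOP):
                if can_pair(k, j):
                    left = best[i][k - 1] if k > i else 0
                    if left + 1 + best[k + 1][j - 1] == best[i][j]:
                        structure[k] = "("
                        structure[j] = ")"
                        traceback(k + 1, j - 1)
                        j = k - 1
                        break
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    return "".join(structure)


def compensatory_pairs(
    rows: dict[str, str],
    pairs: list[tuple[int, int]],
    reference_id: str | None = None,
) -> dict[tuple[int, int], dict[str, int]]:
    """Count pairing-preserving substitutions supporting each stem pair.

    For each pair (i, j) and each non-reference row: ``compensatory`` if
    both sides differ from the reference yet still form a WC/GU pair
    (the strongest comparative evidence for a real stem), ``consistent``
    if exactly one side changed and pairing is preserved, ``disruptive``
    if the row's bases cannot pair, ``conserved`` if identical to the
    reference.  Gapped or ambiguous rows are skipped for that pair.
    """
    if reference_id is None:
        reference_id = next(iter(rows))
    ref = normalize(rows[reference_id])
    valid = set(BASES)
    support: dict[tuple[int, int], dict[str, int]] = {}
    for i, j in pairs:
        tally = {"compensatory": 0, "consistent": 0, "disruptive": 0, "conserved": 0}
        for name, row in rows.items():
            if name == reference_id:
                continue
            row = normalize(row)
            if i >= len(row) or j >= len(row):
                continue
            bi, bj = row[i], row[j]
            if bi not in valid or bj not in valid:
                continue
            paired = bi + bj in CANONICAL_PAIRS
            changed_i = bi != ref[i]
            changed_j = bj != ref[j]
            if not paired:
                tally["disruptive"] += 1
            elif changed_i and changed_j:
                tally["compensatory"] += 1
            elif changed_i or changed_j:
                tally["consistent"] += 1
            else:
                tally["conserved"] += 1
        support[(i, j)] = tally
    return support
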