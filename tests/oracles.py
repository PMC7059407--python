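"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (enumeration, naive
scans, textbook DP) and deliberately shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

from functools import lru_cache

# --- standard genetic code, spelled out independently of Bio/dualorf ----
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def translate(seq: str) -> str:
    return "".join(_CODE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def codon_aa(codon: str) -> str | None:
    return _CODE.get(codon)


def degenerate_positions(codon: str) -> list[int]:
    """Positions with at least one synonymous single-nucleotide neighbor."""
    if codon not in _CODE or _CODE[codon] == "*":
        return []
    out = []
    for i in range(3):
        if any(
            _CODE[codon[:i] + b + codon[i + 1 :]] == _CODE[codon]
            for b in BASES
            if b != codon[i]
        ):
            out.append(i)
    return out


def synonymous_site_fraction(codon: str) -> float:
    """Sum over positions of (synonymous alternatives at that position)/3."""
    if codon not in _CODE or _CODE[codon] == "*":
        return 0.0
    total = sum(
        1
        for i in range(3)
        for b in BASES
        if b != codon[i] and _CODE[codon[:i] + b + codon[i + 1 :]] == _CODE[codon]
    )
    return total / 3.0


def stop_scan(row: str, frame: int) -> list[int]:
    """Naive rescan of every triplet in a shifted frame."""
    stops = []
    k = 0
    for p in range(frame, len(row) - 2, 3):
        triplet = row[p : p + 3]
        if all(c in BASES for c in triplet) and triplet in STOPS:
            stops.append(k)
        k += 1
    return stops


def near_cognate_scan(seq: str, lo: int, hi: int) -> list[tuple[int, str]]:
    """Brute-force Hamming-distance-from-ATG test over all offsets."""
    out = []
    for p in range(lo, min(hi, len(seq) - 2)):
        codon = seq[p : p + 3]
        if sum(a != b for a, b in zip(codon, "ATG")) <= 1:
            out.append((p, codon))
    return out


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Maximum WC+GU pair count by exhaustive recursion (n <= ~14)."""
    ok = {"AT", "TA", "GC", "CG", "GT", "TG"}
    seq = seq.upper().replace("U", "T")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        top = best(i, j - 1)
        for k in range(i, j - min_loop):
            if seq[k] + seq[j] in ok:
                left = best(i, k - 1) if k > i else 0
                top = max(top, left + 1 + best(k + 1, j - 1))
        return top

    return best(0, len(seq) - 1) if seq else 0


def affine_global_score(a: str, b: str, matrix, open_gap: float, extend_gap: float) -> float:
    """Optimal global affine-gap alignment score (Gotoh), end gaps penalized.

    ``open_gap``/``extend_gap`` are the scores of the first/each further
    gapped position (both negative), i.e. a gap of length L scores
    open_gap + (L-1)*extend_gap.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to '-')
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_gap + (i - 1) * extend_gap
    for j in range(1, m + 1):
        Y[0][j] = open_gap + (j - 1) * extend_gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_gap, X[i - 1][j] + extend_gap, Y[i - 1][j] + open_gap)
            Y[i][j] = max(M[i][j - 1] + open_gap, Y[i][j - 1] + extend_gap, X[i][j - 1] + open_gap)
    return max(M[n][m], X[n][m], Y[n][m])


def score_alignment_rows(row_a: str, row_b: str, matrix, open_gap: float, extend_gap: float) -> float:
    """Score a given 2-row alignment under the same affine model."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            score += extend_gap if in_gap_a else open_gap
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += extend_gap if in_gap_b else open_gap
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score


def orf_consequence_oracle(
    sequence: str, orf_start: int, orf_end: int, tx_pos: int, alt_base: str, numbering_base: int = 1
) -> str:
    """Translate-and-diff consequence of one SNV in one ORF.

    The initiation codon decodes as M in the reference peptide whatever
    its identity (near-cognate starts included); a mutated start codon
    is reported against M with the altered codon's own reading.
    """
    if not orf_start <= tx_pos < orf_end:
        return "not in ORF"
    ref_cds = sequence[orf_start:orf_end]
    off = tx_pos - orf_start
    alt_cds = ref_cds[:off] + alt_base + ref_cds[off + 1 :]
    ref_pep = "M" + translate(ref_cds)[1:]
    alt_pep = ("M" if alt_cds[:3] == ref_cds[:3] else translate(alt_cds[:3])) + translate(alt_cds)[1:]
    k = off // 3
    if ref_pep[k] == alt_pep[k]:
        return "no change"
    return f"{ref_pep[k]}{k + numbering_base}{alt_pep[k]}"
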