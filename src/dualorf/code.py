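"""Standard genetic code tables shared across modules."""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stops.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))

BASES = "ACGT"

#: the nine codons one substitution away from ATG, plus ATG itself.
NEAR_COGNATE_STARTS = frozenset(
    ["ATG"]
    + [
        "ATG"[:i] + b + "ATG"[i + 1 :]
        for i in range(3)
        for b in BASES
        if b != "ATG"[i]
    ]
)


def aa(codon: str) -> str | None:
    """Amino acid for a codon ('*' for stop); None if ambiguous/gapped."""
    return CODON_TO_AA.get(codon)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


@lru_cache(maxsize=None)
def synonymous_degenerate_positions(codon: str) -> tuple[int, ...]:
    """Positions of ``codon`` at which at least one single-nucleotide
    change is synonymous (stop codons and ambiguous codons yield ())."""
    ref_aa = CODON_TO_AA.get(codon)
    if ref_aa is None or ref_aa == "*":
        return ()
    out = []
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA.get(mut) == ref_aa:
                out.append(i)
                break
    return tuple(out)


def degeneracy_count(codon: str) -> int:
    """Number of synonymous-degenerate positions in ``codon`` (0-3)."""
    return len(synonymous_degenerate_positions(codon))


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> float:
    """Fractional synonymous sites in ``codon`` (Nei-Gojobori style).

    Each position contributes (number of synonymous single-nucleotide
    alternatives)/3, so a 4-fold degenerate third position counts 1.0
    and a 2-fold position 1/3.  This is the right exposure measure when
    substitutions arise as uniform random single-nucleotide proposals
    filtered for synonymy: expected synonymous changes are proportional
    to it for every codon class, which an integer count of degenerate
    positions is not.
    """
    ref_aa = CODON_TO_AA.get(codon)
    if ref_aa is None or ref_aa == "*":
        return 0.0
    total = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            if CODON_TO_AA.get(codon[:i] + b + codon[i + 1 :]) == ref_aa:
                total += 1
    return total / 3.0
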