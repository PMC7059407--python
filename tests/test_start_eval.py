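"""Initiation-context scoring, near-cognate scans and stem machinery."""

import numpy as np
import pytest

import oracles
from dualorf.start_eval import (
    compensatory_pairs,
    context_matrix,
    find_near_cognate_starts,
    fold_window,
    parse_dot_bracket,
    score_context,
    stem_distance,
)


# ---------------------------------------------------------------------------
# near-cognate starts


def test_find_near_cognate_simple_cases():
    assert find_near_cognate_starts("ATG") == [(0, "ATG")]
    assert find_near_cognate_starts("CTGGTG") == [(0, "CTG"), (3, "GTG")]


def test_find_near_cognate_matches_hamming_oracle():
    rng = np.random.default_rng(23)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    assert find_near_cognate_starts(seq) == oracles.near_cognate_scan(seq, 0, len(seq) - 2)


def test_find_near_cognate_region_bounds():
    seq = "AAATGAAA"
    assert find_near_cognate_starts(seq, (2, 3)) == [(2, "ATG")]
    with pytest.raises(ValueError):
        find_near_cognate_starts(seq, (0, 100))


# ---------------------------------------------------------------------------
# context scoring


def test_published_strong_context():
    """GCCAAG CTG G: A at -3 and G at +4 -> strong."""
    ctx = score_context("GCCAAGCTGG", 6)
    assert (ctx.minus3, ctx.plus4, ctx.strength) == ("A", "G", "strong")
    assert ctx.context == "GCCAAGCTGG"


def test_unfavorable_context_is_weak():
    ctx = score_context("TTTTTTATGT", 6)
    assert ctx.strength == "weak"
    assert ctx.score == 0.0


def _strength_oracle(minus3: str, plus4: str) -> str:
    purine = minus3 in "AG"
    g4 = plus4 == "G"
    if purine and g4:
        return "strong"
    if purine or g4:
        return "adequate"
    return "weak"


@pytest.mark.parametrize("minus3", "ACGT")
@pytest.mark.parametrize("plus4", "ACGT")
def test_strength_rule_table_by_enumeration(minus3, plus4):
    seq = "TTT" + minus3 + "TT" + "ATG" + plus4
    ctx = score_context(seq, 6)
    assert ctx.strength == _strength_oracle(minus3, plus4)


def test_score_monotonicity_in_minus3():
    """A at -3 scores strictly above G, and purines above pyrimidines."""
    def score_with(minus3):
        return score_context("TTT" + minus3 + "TTATGC", 6).score

    assert score_with("A") > score_with("G") > score_with("C") == score_with("T")


def test_truncated_context_flagged():
    ctx = score_context("ATGG", 0)
    assert ctx.truncated
    assert ctx.strength == "adequate"  # G at +4, no -3 purine


def test_score_context_out_of_range():
    with pytest.raises(ValueError):
        score_context("ATG", 5)


# ---------------------------------------------------------------------------
# context matrices


def test_context_matrix_consensus_counts():
    matrix, n = context_matrix(["GCCAAGCTGG"] * 3)
    assert n == 3
    assert matrix.sum(axis=1).tolist() == [3] * 10
    # every consensus base has count 3 at its position
    base_index = {b: i for i, b in enumerate("ACGT")}
    for pos, base in enumerate("GCCAAGCTGG"):
        assert matrix[pos, base_index[base]] == 3


def test_context_matrix_split_column_and_gap_dropping():
    matrix, n = context_matrix(["GCCA", "GCCT", "GC-A"])
    assert n == 2  # gapped row dropped
    assert matrix[3].tolist() == [1, 0, 0, 1]


def test_context_matrix_mixed_lengths_rejected():
    with pytest.raises(ValueError):
        context_matrix(["ACGT", "ACG"])


def test_context_matrix_matches_tally_oracle():
    rng = np.random.default_rng(29)
    contexts = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(50)]
    matrix, n = context_matrix(contexts)
    assert n == 50
    for pos in range(10):
        for bi, base in enumerate("ACGT"):
            assert matrix[pos, bi] == sum(1 for c in contexts if c[pos] == base)


# ---------------------------------------------------------------------------
# stem distance


def test_stem_distance_published_convention():
    """First paired base 14 nt from the G (G = nucleotide 0) is optimal."""
    call = stem_distance("..............((((...))))", 0)
    assert call.first_paired_offset == 14
    assert call.optimal_distance


def test_stem_distance_immediate_stem_not_optimal():
    call = stem_distance("((...))", 0)
    assert call.first_paired_offset == 0
    assert not call.optimal_distance


def test_stem_distance_offset_is_first_non_dot():
    rng = np.random.default_rng(31)
    for _ in range(20):
        lead = int(rng.integers(0, 30))
        stem = int(rng.integers(1, 6))
        loop = int(rng.integers(3, 8))
        structure = "." * lead + "(" * stem + "." * loop + ")" * stem + "." * int(rng.integers(0, 5))
        call = stem_distance(structure, 0)
        assert call.first_paired_offset == structure.index("(")
        assert call.optimal_distance == (12 <= lead <= 17)


def test_stem_distance_rejects_unbalanced():
    with pytest.raises(ValueError):
        stem_distance("((...)", 0)
    with pytest.raises(ValueError):
        stem_distance(".)..(", 0)


def test_parse_dot_bracket_pairs():
    assert parse_dot_bracket("((...))") == [(0, 6), (1, 5)]


# ---------------------------------------------------------------------------
# folding


def test_fold_perfect_hairpin():
    assert fold_window("GGGAAACCC") == "(((...)))"


def test_fold_unpairable_sequence():
    assert fold_window("AAAAAAA") == "......."


def test_fold_never_pairs_closer_than_four():
    rng = np.random.default_rng(37)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 30))))
        pairs = parse_dot_bracket(fold_window(seq))
        for i, j in pairs:
            assert j - i >= 4


def test_fold_pair_count_matches_exhaustive_enumeration():
    """For sequences up to 12 nt the DP pair count equals brute force."""
    rng = np.random.default_rng(41)
    for _ in range(40):
        n = int(rng.integers(1, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        structure = fold_window(seq)
        pairs = parse_dot_bracket(structure)
        # all pairs must be chemically legal
        s = seq.replace("U", "T")
        for i, j in pairs:
            assert s[i] + s[j] in {"AT", "TA", "GC", "CG", "GT", "TG"}
        assert len(pairs) == oracles.max_pairs_exhaustive(seq)


def test_fold_deterministic():
    assert fold_window("GGCGGCUCAACGCCGCC") == fold_window("GGCGGCUCAACGCCGCC")


# ---------------------------------------------------------------------------
# compensatory pairs


def test_compensatory_and_disruptive_rows():
    rows = {"ref": "G....C", "comp": "A....T", "bad": "A....C", "same": "G....C"}
    support = compensatory_pairs(rows, [(0, 5)], reference_id="ref")
    tally = support[(0, 5)]
    assert tally == {"compensatory": 1, "consistent": 0, "disruptive": 1, "conserved": 1}


def test_consistent_one_sided_change():
    rows = {"ref": "GC", "x": "GU"}  # G:C -> G:U still pairs (wobble)
    support = compensatory_pairs(rows, [(0, 1)], reference_id="ref")
    assert support[(0, 1)]["consistent"] == 1


def test_stem_preserving_evolution_shows_compensatory_excess(fixture_extras):
    """Rows evolved to preserve a known stem accumulate compensatory,
    not disruptive, changes at the true pairs."""
    rng = np.random.default_rng(43)
    ref = fixture_extras["stem_seq"]  # hairpin: 6 bp stem + 5 nt loop
    pairs = [(k, 16 - k) for k in range(6)]
    flips = {"A": "T", "T": "A", "G": "C", "C": "G"}
    rows = {"ref": ref}
    for r in range(12):
        chars = list(ref)
        for i, j in pairs:
            if rng.random() < 0.4:  # swap to the complementary pair
                chars[i], chars[j] = flips[chars[i]], flips[chars[j]]
        rows[f"s{r}"] = "".join(chars)
    support = compensatory_pairs(rows, pairs, reference_id="ref")
    total_comp = sum(t["compensatory"] for t in support.values())
    total_disr = sum(t["disruptive"] for t in support.values())
    assert total_comp > total_disr
    assert total_disr == 0
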