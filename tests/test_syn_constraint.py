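"""Synonymous-substitution counting, neutral rate fit and window scan."""

import numpy as np
import pytest
from scipy.stats import poisson

import oracles
from dualorf.code import SENSE_CODONS, degeneracy_count, synonymous_site_count
from dualorf.codon_align import CodonAlignment
from dualorf.syn_constraint import (
    SynSubCounts,
    count_synonymous_substitutions,
    fit_neutral_rate,
    scan_windows,
)
from dualorf.synth import AlignmentSimParams, simulate_alignment


def _pair_aln(codons_a, codons_b):
    return CodonAlignment(
        reference_id="a", rows={"a": "".join(codons_a), "b": "".join(codons_b)}
    )


# ---------------------------------------------------------------------------
# counting


def test_wobble_substitution_counts_one():
    counts = count_synonymous_substitutions(_pair_aln(["GCT"], ["GCA"]))
    assert counts.observed.tolist() == [1.0]


def test_identical_codons_count_zero():
    counts = count_synonymous_substitutions(_pair_aln(["GCT"], ["GCT"]))
    assert counts.observed.tolist() == [0.0]
    assert counts.comparable[0] == synonymous_site_count("GCT") == 1.0


def test_different_aa_pairs_contribute_nothing():
    counts = count_synonymous_substitutions(_pair_aln(["GCT"], ["ACT"]))  # Ala vs Thr
    assert counts.observed.tolist() == [0.0]
    assert counts.comparable.tolist() == [0.0]


def test_gapped_and_ambiguous_codons_skipped():
    counts = count_synonymous_substitutions(_pair_aln(["GCT", "GCN"], ["GC-", "GCA"]))
    assert counts.observed.sum() == 0
    assert counts.comparable.sum() == 0


def test_empty_comparison_list_rejected():
    with pytest.raises(ValueError):
        count_synonymous_substitutions(_pair_aln(["GCT"], ["GCA"]), comparisons=[])


def test_degeneracy_matches_enumeration_over_sense_codons():
    """Degenerate-position and fractional-site counts equal brute-force
    enumeration over the 61 sense codons and their 9 neighbors."""
    assert len(SENSE_CODONS) == 61
    for codon in SENSE_CODONS:
        assert degeneracy_count(codon) == len(oracles.degenerate_positions(codon))
        assert synonymous_site_count(codon) == pytest.approx(
            oracles.synonymous_site_fraction(codon)
        )


def test_observed_counts_match_bruteforce_on_random_pairs():
    rng = np.random.default_rng(13)
    for _ in range(10):
        n = int(rng.integers(5, 40))
        a = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
        # b: same-aa codon at each site with prob 0.7, else random codon
        b = []
        for codon in a:
            if rng.random() < 0.7:
                synonyms = [c for c in SENSE_CODONS if oracles.codon_aa(c) == oracles.codon_aa(codon)]
                b.append(synonyms[int(rng.integers(0, len(synonyms)))])
            else:
                b.append(SENSE_CODONS[int(rng.integers(0, 61))])
        counts = count_synonymous_substitutions(_pair_aln(a, b))
        for k, (ca, cb) in enumerate(zip(a, b)):
            if oracles.codon_aa(ca) == oracles.codon_aa(cb):
                expected_obs = sum(1 for x, y in zip(ca, cb) if x != y)
                expected_sites = oracles.synonymous_site_fraction(ca)
            else:
                expected_obs = expected_sites = 0
            assert counts.observed[k] == expected_obs
            assert counts.comparable[k] == pytest.approx(expected_sites)


# ---------------------------------------------------------------------------
# neutral rate


def test_rate_is_total_ratio():
    counts = SynSubCounts(observed=np.full(50, 0.2), comparable=np.full(50, 2.0))
    assert fit_neutral_rate(counts) == pytest.approx(10 / 100)
    assert counts.expected.tolist() == pytest.approx([0.2] * 50)


def test_zero_observed_gives_zero_rate_and_unit_pvalues():
    counts = SynSubCounts(observed=np.zeros(30), comparable=np.full(30, 2.0))
    assert fit_neutral_rate(counts) == 0.0
    stats = scan_windows(counts, w=5)
    assert all(s.p_value == 1.0 for s in stats)
    assert not any(s.significant for s in stats)


def test_zero_comparable_sites_is_an_error():
    counts = SynSubCounts(observed=np.zeros(10), comparable=np.zeros(10))
    with pytest.raises(ValueError):
        fit_neutral_rate(counts)


def test_rate_recovery_from_known_per_site_probability():
    """With each degenerate site mutated synonymously with prob 0.15, the
    fitted rate recovers 0.15 within 3 standard errors."""
    rng = np.random.default_rng(17)
    p = 0.15
    n = 2000
    # 4-fold families whose only degenerate position is the third
    # (excludes CTx/CGx, where A/G third bases add first-position degeneracy)
    fourfold = ["GC", "GG", "CC", "AC", "GT", "TC"]
    a, b = [], []
    for i in rng.integers(0, len(fourfold), n):
        stem = fourfold[i]
        third = "ACGT"[int(rng.integers(0, 4))]
        codon = stem + third
        if rng.random() < p:  # exactly one degenerate site per codon
            third = rng.choice([x for x in "ACGT" if x != third])
        a.append(codon)
        b.append(stem + third)
    counts = count_synonymous_substitutions(_pair_aln(a, b))
    assert counts.comparable.sum() == n  # third position only
    rate = fit_neutral_rate(counts)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(rate - p) < 3 * se


# ---------------------------------------------------------------------------
# window scan


def test_window_at_null_center_is_unsurprising():
    counts = SynSubCounts(observed=np.full(50, 0.8), comparable=np.full(50, 2.0))
    fit_neutral_rate(counts)
    stats = scan_windows(counts, w=25)
    mid = stats[25]
    assert mid.ratio == pytest.approx(1.0)
    assert mid.p_value > 0.4


def test_empty_window_closed_form_poisson():
    observed = np.full(100, 1.0)
    observed[40:65] = 0.0  # a 25-codon hole
    counts = SynSubCounts(observed=observed, comparable=np.full(100, 2.0))
    fit_neutral_rate(counts)
    stats = scan_windows(counts, w=25)
    center = stats[52]  # window [40, 65) exactly covers the hole
    assert center.obs == 0
    assert center.p_value == pytest.approx(np.exp(-center.exp))
    assert center.significant


def test_scaled_threshold_matches_published_correction():
    """w=25, threshold 0.05, ORF length 1239 codons -> per-window cutoff
    0.05 * 25/1239, applied to the Poisson deficit p-value."""
    observed = np.full(100, 2.0)
    counts = SynSubCounts(observed=observed, comparable=np.full(100, 4.0))
    fit_neutral_rate(counts)
    stats = scan_windows(counts, w=25, threshold=0.05, orf_len=1239)
    cutoff = 0.05 * 25 / 1239
    for s in stats:
        assert s.significant == (s.p_value <= cutoff)


def test_window_truncation_at_edges():
    counts = SynSubCounts(observed=np.arange(30, dtype=float), comparable=np.full(30, 2.0))
    fit_neutral_rate(counts)
    stats = scan_windows(counts, w=25)
    assert stats[0].obs == sum(range(0, 13))  # [0, 13)
    assert stats[29].obs == sum(range(17, 30))  # [17, 30)


def test_window_size_validation():
    counts = SynSubCounts(observed=np.zeros(10), comparable=np.full(10, 1.0))
    with pytest.raises(ValueError):
        scan_windows(counts, w=11)


# ---------------------------------------------------------------------------
# calibration and power (reduced-size versions; full sizes in acceptance)


def _scan_sim(params):
    aln, _ = simulate_alignment(params)
    counts = count_synonymous_substitutions(aln)
    fit_neutral_rate(counts)
    return scan_windows(counts, w=25, threshold=0.05)


def test_neutral_simulations_control_family_wise_error():
    n_sims = 40
    hits = 0
    for seed in range(n_sims):
        params = AlignmentSimParams(
            n_species=12, branch_length=0.4, orf_len=400, seed=seed
        )
        if any(s.significant for s in _scan_sim(params)):
            hits += 1
    bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sims)
    assert hits / n_sims <= bound


def test_dual_constrained_overlap_is_detected_and_localized():
    w = 25
    overlap = (150, 250)
    coverages = []
    for seed in range(10):
        params = AlignmentSimParams(
            n_species=12,
            branch_length=0.4,
            orf_len=400,
            overlap=overlap,
            mode="dual_constrained",
            seed=100 + seed,
        )
        stats = _scan_sim(params)
        covered = set()
        for s in stats:
            if s.significant:
                covered.update(
                    range(s.center_codon - w // 2, s.center_codon + w // 2 + 1)
                )
        coverages.append(
            len(covered & set(range(*overlap))) / (overlap[1] - overlap[0])
        )
        # significance dies out within one window length of the overlap end
        far = [
            s.center_codon
            for s in stats
            if s.significant and s.center_codon >= overlap[1] + w
        ]
        assert not far, f"seed {seed}: stray significant windows at {far}"
    assert np.mean(coverages) >= 0.8
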