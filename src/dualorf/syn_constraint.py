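"""Sliding-window synonymous-site conservation scan.

Translation in two overlapping reading frames suppresses synonymous
substitutions in the main frame, so a deficit of synonymous changes
relative to a neutral expectation is evidence for an overlapping
functional element.  The scan here uses a star-phylogeny pairwise
scheme: synonymous substitutions are counted per codon between the
reference and every other row, a single global per-site synonymous rate
is fitted over the whole ORF, and each sliding window is tested for a
deficit of observed vs expected synonymous counts with a one-sided
Poisson test.  Multiple testing across overlapping windows is handled
by scaling the p-value threshold by (window size)/(ORF length).

This is a deliberately simple, fully specified counting model — the
acceptance surface is calibration (type-I error control) and power on
simulated alignments, not numerical agreement with branch-model
likelihood methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .code import aa, synonymous_site_count
from .codon_align import CodonAlignment

__all__ = [
    "SynSubCounts",
    "WindowStat",
    "count_synonymous_substitutions",
    "star_comparisons",
    "independent_pair_comparisons",
    "fit_neutral_rate",
    "scan_windows",
    "write_window_stats",
]

_VALID = set("ACGT")


@dataclass
class SynSubCounts:
    """Per-codon observed synonymous substitutions and comparable sites."""

    observed: np.ndarray  # weighted substitution count per reference codon
    comparable: np.ndarray  # synonymous-degenerate site count per codon
    expected: np.ndarray | None = None  # filled by fit_neutral_rate
    rate: float | None = None

    @property
    def n_codons(self) -> int:
        return len(self.observed)


@dataclass
class WindowStat:
    center_codon: int
    window_codons: int
    obs: float
    exp: float
    ratio: float
    p_value: float
    significant: bool


def star_comparisons(aln: CodonAlignment) -> list[tuple[str, str]]:
    """Reference vs every other row — the default comparison scheme."""
    return [(aln.reference_id, sp) for sp in aln.rows if sp != aln.reference_id]


def independent_pair_comparisons(species: list[str]) -> list[tuple[str, str]]:
    """Disjoint species pairs (each species used at most once).

    A crude phylogenetically independent scheme: with a star guide every
    disjoint pairing is equivalent, so consecutive input pairs are used.
    """
    it = iter(species)
    return list(zip(it, it))


def count_synonymous_substitutions(
    aln: CodonAlignment,
    comparisons: list[tuple[str, str]] | None = None,
    weights: list[float] | None = None,
) -> SynSubCounts:
    """Count synonymous substitutions per reference codon over sequence pairs.

    For each pair and codon column where both codons are gapless,
    unambiguous and encode the same amino acid, the number of differing
    nucleotide positions is added to that codon's observed count, and
    the first sequence's fractional synonymous-site count (each position
    weighted by its share of synonymous single-nucleotide alternatives;
    see :func:`dualorf.code.synonymous_site_count`) is added to the
    codon's comparable-site count.  The fractional measure keeps the
    neutral per-site rate homogeneous across codon degeneracy classes,
    which an integer count of degenerate positions does not — windows
    enriched in 2-fold-degenerate codons would otherwise look spuriously
    conserved.  Codon pairs encoding different amino acids contribute to
    neither tally, which keeps the statistic free of any nonsynonymous
    rate model and is conservative for a deficit test.
    """
    if comparisons is None:
        comparisons = star_comparisons(aln)
    if not comparisons:
        raise ValueError("empty comparison list")
    if weights is None:
        weights = [1.0] * len(comparisons)
    if len(weights) != len(comparisons):
        raise ValueError("weights length must match comparisons")

    n_codons = aln.n_codons
    observed = np.zeros(n_codons)
    comparable = np.zeros(n_codons)
    for (sp_a, sp_b), w in zip(comparisons, weights):
        row_a, row_b = aln.rows[sp_a], aln.rows[sp_b]
        for k in range(n_codons):
            ca = row_a[3 * k : 3 * k + 3]
            cb = row_b[3 * k : 3 * k + 3]
            if set(ca) - _VALID or set(cb) - _VALID:
                continue
            aa_a, aa_b = aa(ca), aa(cb)
            if aa_a is None or aa_a == "*" or aa_a != aa_b:
                continue
            diffs = sum(1 for x, y in zip(ca, cb) if x != y)
            observed[k] += w * diffs
            comparable[k] += w * synonymous_site_count(ca)
    return SynSubCounts(observed=observed, comparable=comparable)


def fit_neutral_rate(counts: SynSubCounts) -> float:
    """Fit the single global per-site synonymous rate and fill expectations.

    ``r`` is total observed substitutions over total comparable
    synonymous sites across the whole ORF; each codon's expectation is
    ``r`` times its comparable-site count.  A rate of exactly zero is
    legal (it propagates to p-values of 1: no substitutions anywhere is
    evidence of nothing).
    """
    total_sites = float(counts.comparable.sum())
    if total_sites <= 0:
        raise ValueError("no comparable synonymous sites; cannot fit a rate")
    rate = float(counts.observed.sum()) / total_sites
    counts.rate = rate
    counts.expected = rate * counts.comparable
    return rate


def scan_windows(
    counts: SynSubCounts,
    w: int = 25,
    threshold: float = 0.05,
    orf_len: int | None = None,
) -> list[WindowStat]:
    """Slide a ``w``-codon window (step 1) and test for a synonymous deficit.

    Per window: obs and exp are summed (windows truncated at the ORF
    edges, obs and exp truncated together so the ratio stays unbiased);
    the p-value is P(X <= obs) for X ~ Poisson(exp); a window is
    significant iff p <= threshold * w / orf_len — the approximate
    multiple-testing correction for overlapping windows.
    """
    if counts.expected is None:
        fit_neutral_rate(counts)
    n = counts.n_codons
    if not 1 <= w <= n:
        raise ValueError(f"window size {w} out of range for {n} codons")
    orf_len = orf_len or n
    cutoff = threshold * w / orf_len
    half = w // 2

    obs_cum = np.concatenate([[0.0], np.cumsum(counts.observed)])
    exp_cum = np.concatenate([[0.0], np.cumsum(counts.expected)])

    stats = []
    for center in range(n):
        lo = max(0, center - half)
        hi = min(n, center + half + 1)
        obs = float(obs_cum[hi] - obs_cum[lo])
        exp = float(exp_cum[hi] - exp_cum[lo])
        if exp > 0:
            p = float(poisson.cdf(obs, exp))
            ratio = obs / exp
        else:
            p = 1.0
            ratio = float("nan")
        stats.append(
            WindowStat(
                center_codon=center,
                window_codons=w,
                obs=obs,
                exp=exp,
                ratio=ratio,
                p_value=p,
                significant=p <= cutoff,
            )
        )
    return stats


def write_window_stats(path, stats: list[WindowStat]) -> None:
    with open(path, "w") as fh:
        fh.write("center_codon\tobs\texp\tratio\tp_value\tsignificant\n")
        for s in stats:
            fh.write(
                f"{s.center_codon}\t{s.obs:.4f}\t{s.exp:.4f}\t{s.ratio:.4f}\t"
                f"{s.p_value:.6g}\t{int(s.significant)}\n"
            )
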