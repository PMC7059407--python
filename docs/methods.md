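# Methods

`dualorf` analyzes *dual coding*: a stretch of mRNA translated in two
reading frames at once, as in human *POLG*, where a CUG-initiated ORF
("ORF-Y", +2 frame) overlaps the main ORF and a short AUG uORF
("ORF-Z") sits further upstream. This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Coordinate and sequence conventions

Transcript offsets are 0-based half-open; genomic positions are 1-based
inclusive (the ClinVar dialect), so published variant positions are
consumed verbatim. Variant ref/alt alleles are always plus-strand and
complemented on the fly for minus-strand transcripts. The internal
alphabet is DNA (`U` → `T` on input); display layers may render U.
Frame offsets of overlapping ORFs are {0, +1, +2} relative to the main
ORF (a "−1 frame" ORF is +2 here).

## Ortholog collection and codon alignments

`codon_align` reproduces the protein-guided alignment route: BLAST-style
hits are filtered by a minimum query cover of 0.80, names containing
"partial mRNA" are dropped, and one isoform per species is kept by
highest bit score. Proteins are aligned and the alignment is
back-translated codon-per-residue (aa gaps → `---`; terminal stop
codons are stripped and re-appended). Reference mapping removes every
column that is a gap in the reference row, so that alignment columns
index reference transcript offsets directly; the operation is
idempotent.

The built-in protein aligner is a deterministic center-star scheme
(pairwise Needleman–Wunsch against the first input sequence, BLOSUM62,
affine gaps −11/−1, insertions merged on the center's coordinates). It
exists so that synthetic tests need no external aligner; real analyses
should supply pre-computed alignments from a dedicated MSA tool.
Per-row gap-fraction/identity diagnostics are reported but never
auto-drop a sequence — removing a poorly aligning ortholog is an
explicit, recorded choice.

## Frame survey

`stop_map` records stop codons, ATGs and near-cognate starts per
species per frame; triplets containing gaps or ambiguity codes are
*no-calls*, not "no stop" (a gapped region carries no evidence).
`stop_free_region` reports maximal codon intervals where at least a
configurable fraction of species (default all) lack a stop — the long
conserved stop-free region in an alternative frame that first suggests
an overlapping ORF.

`classify_orf_conservation` assigns each species one status with
precedence `missing > frameshifted > start_lost > early_stop > intact`.
Frameshift (ungapped length over the ORF differing from the reference's
by a non-multiple of 3) outranks codon-level calls because positional
stop/start calls are meaningless out of frame; `missing` (>50% gap
columns) outranks everything because there is nothing to call. The
early-stop classifier reports the first premature stop's codon index
rather than applying an arbitrary "shortly after the start" cutoff.
Near-cognate start codons count as conserved starts by default (the
biology under study is non-AUG initiation); an exact-match policy is a
flag away.

## Synonymous-site constraint scan

Translation in two frames suppresses synonymous substitutions in the
main frame. The scan quantifies this as a deficit of observed vs
expected synonymous changes in sliding windows:

* **Counting.** For each comparison pair (default: reference vs every
  other row — a star scheme matched to the star-phylogeny simulator)
  and each codon column where both codons are gapless, unambiguous and
  encode the same amino acid, the observed count gains the number of
  differing nucleotide positions and the comparable-site count gains
  the reference codon's *fractional synonymous sites* (each position
  weighted by its share of synonymous single-nucleotide alternatives —
  1.0 for a 4-fold third position, 1/3 for a 2-fold one). The
  fractional measure keeps the neutral per-site rate homogeneous across
  codon classes; an integer count of degenerate positions makes windows
  enriched in 2-fold codons look spuriously conserved and breaks
  type-I calibration. Different-amino-acid codon pairs contribute to
  neither tally, which avoids modeling nonsynonymous rates and is
  conservative for a deficit test.
* **Null model.** A single global rate r = Σ observed / Σ comparable
  over the whole ORF; per-codon expectation is r × comparable. If
  r = 0, all p-values are defined as 1 (no substitutions anywhere is
  evidence of nothing).
* **Test.** Windows of w codons (default 25) slide in 1-codon steps,
  truncated at the ORF edges with obs and exp truncated together; the
  one-sided deficit p-value is P(X ≤ obs) for X ~ Poisson(exp). A
  window is significant iff p ≤ threshold × w / L (threshold 0.05, L
  the ORF length in codons) — the approximate multiple-testing
  correction for heavily overlapping windows. Observed window counts
  are sums of per-site Bernoulli outcomes, so they are if anything
  underdispersed relative to Poisson, keeping the test conservative.

This is a deliberately simple, fully specified counting scheme, not a
reimplementation of branch-model likelihood methods; its acceptance
surface is calibration and power on simulations with known truth.
Measured on the packaged simulator at the default study conditions
(12 species, branch 0.4, 400 codons): family-wise false-positive rate
within binomial error of 0.05 over 200 neutral simulations, and
significant windows covering >80% of a 100-codon dual-coded segment
with significance dying out within one window length of its end.

## Non-AUG start evaluation

The initiation context is the 10-mer spanning −6..+4 (codon at 0..+2).
Strength follows the two key positions: **strong** = purine at −3 and
G at +4, **adequate** = exactly one of the two, **weak** = neither; the
numeric score adds 3 for A at −3 (2 for G — A is strictly preferred),
1 for G at +4, and 0.5 per match of the minor consensus positions
(−6..−4, −2, −1 to G,C,C,C,C). Context matrices for logo rendering drop
gapped rows and report the retained count.

Stem-loop distance uses the convention that the G (last base) of the
start codon is nucleotide 0 — one off from a first-base convention, and
recorded prominently for that reason. The "optimal" band is [12, 17] nt
around the ~15 nt pause distance that favors initiation at near-cognate
codons; a point rule at the observed 14 would be brittle. Flagged, not
filtered. Consensus structures are ingested as dot-bracket strings;
the built-in folder is a maximum-base-pairing (Nussinov) DP over
Watson–Crick + GU pairs with a minimum hairpin loop of 3 — a pair-count
maximizer for fixtures and tests, not a thermodynamic model.
Compensatory support counts, per stem pair, the rows where both sides
changed yet still pair (compensatory), one side changed and pairing
holds (consistent), pairing is lost (disruptive), or nothing changed.

## Ribosome-profiling analysis

Tracks are per-nucleotide, already P/A-site-assigned counts; footprint
length calibration is out of scope. Three signals are computed:

* **Initiation peaks**: reads in a ±1-codon window around a candidate
  start vs the mean per-nucleotide count in 60-nt flanks (excluding the
  peak window); enrichment is peak density over background density.
* **Frame counts**: per-region read counts by sub-codon frame relative
  to an anchor (typically the main start); inside an overlap the
  plurality frame shifts by the overlapping ORF's frame offset.
* **Density drop**: mean read density in flanking windows (default
  60 nt, minimum 30) upstream vs downstream of a stop codon, excluding
  the stop's 3 nt plus a one-codon buffer each side, because elongating
  footprints pile up on terminating ribosomes and would bias the
  upstream window. The ratio estimates 1/(1−f) for a terminating
  fraction f — a two-fold drop means half the ribosomes terminated at
  the internal stop.

## Variant re-annotation

A variant synonymous in the main frame (or UTR) is re-annotated against
every overlapping ORF: "not in ORF", "no change", or
`<refAA><index><altAA>`, with multi-allelic alternatives '/'-joined in
alt order. The initiation codon decodes as methionine whether or not it
is AUG, so codon-0 changes are reported against M. Indels are rejected
with a clear message — no indel consequence model is defined for
dual-coding regions. Residue numbering defaults to start codon =
residue 1; the packaged published POLG ORF-Y table is internally
consistent with the codon containing the start anchor being residue 0
(`numbering_base=0`), and `residue_index` computes indices for
minus-strand single-exon spans by pure coordinate arithmetic,
`floor((anchor_high − pos)/3) + numbering_base`. The convention in
force is surfaced in output headers. Spliced spans (the published
exon-3 row) need an exon structure and transcript-space annotation.

## Synthetic data: what it emulates and what it does not

* **Alignments** evolve on a star phylogeny from a stop-free ancestor:
  Poisson(branch × 3 × L) single-nucleotide proposals per species,
  accepted only if synonymous in frame 0 — and, inside the dual-coded
  segment of `dual_constrained` mode, also synonymous in the
  overlapping frame. Defaults (12 species, branch 0.4, 400 codons,
  100-codon overlap) are the study conditions of the test suite. Not
  emulated: indels, codon-usage bias, rate variation, tree structure
  beyond a star — so passing tests demonstrate calibration and power of
  the scan under its own null, not robustness to phylogenetic
  correlation (the independent-pairs comparison option exists for
  that).
* **Footprints** follow a leaky-scanning/reinitiation flux model:
  scanning ribosomes initiate at each ORF with its `init_fraction`;
  uORFs of ≤30 codons return `reinit_fraction` (default 0.5) of their
  ribosomes to the scanning pool downstream of their stop. Elongating
  reads are Poisson-placed with `frame_fidelity` 0.9 (the aggregate
  phasing of public profiling data is no sharper); initiating reads
  concentrate on start codons with `peak_boost` 50 over a faint
  scanning background. Not emulated: fragment-length geometry, biases
  around pause sites, study-to-study variation.
* **The fixture transcript** (seed 7, ~1 kb, minus-strand single-exon
  anchor) realizes the studied architecture exactly: ORF-Z = 23 codons
  + stop with G at −3/+4; ORF-Y CUG at context GCCAAGCTGG in the +2
  frame with a 6-bp stem whose first paired base is +14 from the G;
  main AUG ORF of 249 codons overlapping ORF-Y; both frames stop-free
  inside their ORFs by constrained resampling. ORF lengths (120/249
  codons) are scaled-down choices keeping every regime (uORF, overlap,
  main-only, UTRs) present at desk scale.

## Numerical choices and degenerate inputs

Poisson tail probabilities come from scipy. Ratio obs/exp is NaN when
exp = 0. `density_drop` reports ∞ when the downstream window is empty
but the upstream is not, NaN when both are. Ties in plurality frames
are reported as `"tie"`, never resolved silently. The Nussinov
traceback prefers leaving the right end unpaired, then the smallest
pairing partner — deterministic for fixed input. All generators are
deterministic under their seed.

## Known limitations

The scan's star-comparison default double-counts shared branches if the
reference is not ancestral to the rows; with deep trees use the
independent-pairs option or supply per-pair weights. The coordinate
model handles splicing for transcripts but `residue_index` alone is
single-exon arithmetic by design. The CLI `run` pipeline demonstrates
the stages on packaged synthetic conditions; real-data runs should
drive the library functions (or stage subcommands) on supplied
alignments, tracks and tables.
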