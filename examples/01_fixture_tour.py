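"""Tour of the packaged dual-coding miniature transcript.

Builds the deterministic POLG-like fixture — a short AUG uORF, a
CUG-initiated ORF in the +2 frame, and a main AUG ORF — and evaluates
the non-AUG start site the way one would a real candidate: initiation
context strength and distance to the downstream stem-loop.
"""

from dualorf.start_eval import fold_window, score_context, stem_distance
from dualorf.synth import make_fixture_transcript

transcript, orfs, extras = make_fixture_transcript(seed=7)
print(f"transcript {transcript.id}: {len(transcript)} nt, strand {transcript.strand}")
for orf in orfs:
    print(f"  {orf.name:6s} {orf.start_tx:4d}..{orf.end_tx:4d}  start {orf.start_codon}"
          f"  frame offset {orf.frame_offset_vs_main:+d}")

orf_y = next(o for o in orfs if o.start_codon == "CTG")
ctx = score_context(transcript.sequence, orf_y.start_tx)
print(f"\ninitiation context {ctx.context} -> strength {ctx.strength} (score {ctx.score})")
print("  (-3 base", ctx.minus3, "/ +4 base", ctx.plus4,
      "- a purine at -3 plus G at +4 is the strong configuration)")

call = stem_distance(extras["stem_structure"], 0)
print(f"stem-loop first paired base at +{call.first_paired_offset} nt "
      f"(G of the start codon = 0); optimal band [12, 17]: {call.optimal_distance}")
print("hairpin fold of the stem window:", fold_window(extras["stem_seq"]))
# A strong context plus a stem ~14 nt downstream is the configuration that
# favors initiation at a near-cognate (non-AUG) codon.
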