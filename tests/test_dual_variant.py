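"""Dual-frame variant re-annotation and the published-table arithmetic."""

import re

import pytest

import oracles
from dualorf.dual_variant import (
    annotate_dual,
    classify_main_effect,
    consequence_kind,
    filter_table,
    residue_index,
)
from dualorf.polg import ORF_Y_ANCHOR_HIGH, load_table1, orf_y_published
from dualorf.seq_io import OrfDefinition, Transcript, VariantRecord, tx_to_genomic


# ---------------------------------------------------------------------------
# residue_index


def test_residue_index_published_spot_values():
    orf_y = orf_y_published()
    assert residue_index(orf_y, 89333254) == 185
    assert residue_index(orf_y, 89333491) == 106
    assert residue_index(orf_y, 89333802) == 2
    assert residue_index(orf_y, ORF_Y_ANCHOR_HIGH) == 0  # anchor is residue 0


def test_residue_index_reproduces_all_exon2_rows():
    """Coordinate arithmetic alone reproduces the printed ORF-Y residue
    number for every exon-2 substitution row of the packaged table."""
    orf_y = orf_y_published()
    exon3_position = 89330213  # the one row needing exon structure
    checked = 0
    for rec in load_table1():
        published = rec.annotations.get("orf_y", "")
        m = re.match(r"^[A-Z*](\d+)[A-Z*]", published)
        if not m or rec.position == exon3_position:
            continue
        assert residue_index(orf_y, rec.position) == int(m.group(1)), rec.rsid
        checked += 1
    assert checked == 40


def test_residue_index_outside_orf():
    orf_y = orf_y_published()
    with pytest.raises(LookupError):
        residue_index(orf_y, 89333821)  # 5' of the CUG on the minus strand
    with pytest.raises(LookupError):
        residue_index(orf_y, 89330213)  # beyond the exon-2 coordinate span


def test_residue_index_matches_codon_walk_oracle():
    """Walking the minus strand codon by codon gives the same index."""
    orf = OrfDefinition(
        name="toy",
        start_tx=0,
        end_tx=60,
        start_codon="CTG",
        genomic_anchor=5000,
        strand="-",
        numbering_base=0,
    )
    # brute-force walk: codon 0 covers 5000,4999,4998; codon 1: 4997... etc.
    walk = {}
    g = 5000
    for codon in range(20):
        for _ in range(3):
            walk[g] = codon
            g -= 1
    for pos, expected in walk.items():
        assert residue_index(orf, pos) == expected


def test_residue_index_plus_strand():
    orf = OrfDefinition(
        name="p", start_tx=0, end_tx=30, genomic_anchor=100, strand="+"
    )
    assert residue_index(orf, 100) == 1  # default numbering: start = residue 1
    assert residue_index(orf, 104) == 2
    with pytest.raises(LookupError):
        residue_index(orf, 130)


# ---------------------------------------------------------------------------
# main-frame classification (plus-strand toy transcript)


TOY_SEQ = "TTTTTT" + "ATG" + "GCT" + "CCA" + "TAA" + "TTTTTT"
TOY = Transcript(id="toy", sequence=TOY_SEQ)
TOY_MAIN = OrfDefinition(name="main", start_tx=6, end_tx=18)


def _variant(pos, ref, alt):
    return VariantRecord(rsid="v", chrom="tx", position=pos, ref=ref, alts=[alt])


def test_classify_wobble_synonymous():
    # GCT -> GCC, third position of codon 1
    assert classify_main_effect(TOY, TOY_MAIN, _variant(11, "T", "C"), "C") == "synonymous"


def test_classify_utr_positions():
    assert classify_main_effect(TOY, TOY_MAIN, _variant(2, "T", "A"), "A") == "utr5"
    assert classify_main_effect(TOY, TOY_MAIN, _variant(19, "T", "G"), "G") == "utr3"


def test_classify_ref_mismatch_names_rsid():
    with pytest.raises(ValueError, match="v"):
        classify_main_effect(TOY, TOY_MAIN, _variant(11, "A", "C"), "C")


def test_classify_indel_rejected():
    var = VariantRecord(rsid="ind", chrom="tx", position=11, ref="TT", alts=["T"])
    with pytest.raises(ValueError, match="single-nucleotide"):
        classify_main_effect(TOY, TOY_MAIN, var, "T")


def test_classify_all_snvs_of_one_codon_match_enumeration():
    """All 9 SNVs of the GCT codon classify per the genetic code."""
    for within, ref_base in enumerate("GCT"):
        tx_pos = 9 + within
        for alt in "ACGT":
            if alt == ref_base:
                continue
            got = classify_main_effect(TOY, TOY_MAIN, _variant(tx_pos, ref_base, alt), alt)
            alt_codon = "GCT"[:within] + alt + "GCT"[within + 1 :]
            if oracles.codon_aa(alt_codon) == "A":
                expected = "synonymous"
            elif oracles.codon_aa(alt_codon) == "*":
                expected = "nonsense"
            else:
                expected = "missense"
            assert got == expected


# ---------------------------------------------------------------------------
# dual annotation on the packaged synthetic transcript


def test_every_snv_on_fixture_matches_bruteforce_oracle(fixture_transcript, fixture_orfs):
    """Exhaustive SNV scan: per-ORF consequences equal an independent
    translate-and-diff oracle, through genomic (minus-strand) coordinates."""
    t = fixture_transcript
    orfs = list(fixture_orfs.values())
    main = fixture_orfs["main"]
    flip = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for tx_pos in range(len(t)):
        ref_tx = t.sequence[tx_pos]
        g_pos = tx_to_genomic(t, tx_pos)
        for alt_tx in "ACGT":
            if alt_tx == ref_tx:
                continue
            # plus-strand (ClinVar dialect) alleles for the minus-strand gene
            var = VariantRecord(
                rsid=f"snv{tx_pos}{alt_tx}",
                chrom="chrS",
                position=g_pos,
                ref=flip[ref_tx],
                alts=[flip[alt_tx]],
            )
            ann = annotate_dual(t, orfs, var, main_orf=main)
            for orf in orfs:
                if orf.name == "main":
                    continue
                expected = oracles.orf_consequence_oracle(
                    t.sequence,
                    orf.start_tx,
                    orf.end_tx,
                    tx_pos,
                    alt_tx,
                    numbering_base=orf.numbering_base,
                )
                assert ann.per_orf[orf.name] == expected, (tx_pos, alt_tx, orf.name)


def test_frame_offset_means_different_codon_position(fixture_transcript, fixture_orfs):
    """In the overlap, a main-frame position never occupies the same
    within-codon slot in the shifted frame."""
    main = fixture_orfs["main"]
    orf_y = fixture_orfs["ORF-Y"]
    for tx_pos in range(max(main.start_tx, orf_y.start_tx), min(main.end_tx, orf_y.end_tx)):
        slot_main = (tx_pos - main.start_tx) % 3
        slot_y = (tx_pos - orf_y.start_tx) % 3
        assert slot_main != slot_y or orf_y.frame_offset_vs_main == 0


def test_multiallelic_consequences_joined(fixture_transcript, fixture_orfs):
    """A multi-allelic variant inside ORF-Y renders one consequence per
    alt, '/'-joined, in alt order."""
    t = fixture_transcript
    orf_y = fixture_orfs["ORF-Y"]
    tx_pos = orf_y.start_tx + 31  # second position of codon 10: all alts nonsyn
    ref_tx = t.sequence[tx_pos]
    flip = {"A": "T", "T": "A", "G": "C", "C": "G"}
    alts_tx = [b for b in "ACGT" if b != ref_tx]
    var = VariantRecord(
        rsid="multi",
        chrom="chrS",
        position=tx_to_genomic(t, tx_pos),
        ref=flip[ref_tx],
        alts=[flip[b] for b in alts_tx],
    )
    ann = annotate_dual(t, list(fixture_orfs.values()), var, main_orf=fixture_orfs["main"])
    parts = ann.per_orf["ORF-Y"].split("/")
    assert len(parts) == 3
    for part, alt_tx in zip(parts, alts_tx):
        assert part == oracles.orf_consequence_oracle(
            t.sequence, orf_y.start_tx, orf_y.end_tx, tx_pos, alt_tx,
            numbering_base=orf_y.numbering_base,
        )


# ---------------------------------------------------------------------------
# summary counts


def test_consequence_kind_parsing():
    assert consequence_kind("A146T/A146S/A146P") == "substitution"
    assert consequence_kind("no change") == "no change"
    assert consequence_kind("not in ORF") == "not in ORF"
    assert consequence_kind("L23V/L23L") == "substitution"  # one real change
    assert consequence_kind("L23L") == "no change"  # printed synonymous alt


def test_published_table_counts():
    counts = filter_table(
        [
            {"ORF-Y": r.annotations.get("orf_y", ""), "ORF-Z": r.annotations.get("orf_z", "")}
            for r in load_table1()
        ]
    )
    assert counts["total"] == 44
    assert counts["orf_y_changed"] == 41
    assert counts["orf_z_changed"] == 1
    assert counts["orf_y_no_change"] == 1
    assert counts["not_in_orf_y"] == 2


def test_filter_table_empty():
    counts = filter_table([])
    assert all(v == 0 for v in counts.values())
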