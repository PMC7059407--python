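"""Config-driven orchestration of the analysis stages.

A run config (YAML) selects stages and parameters; stages execute in
dependency order on either user-supplied inputs or the packaged
synthetic fixture, write their stage-level TSVs, and contribute blocks
to a machine-readable JSON report.  TSVs remain the contract between
stages so each stage stays independently scriptable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .codon_align import map_to_reference, row_quality_report
from .dual_variant import annotate_table, filter_table, write_annotated_table
from .frame_survey import stop_free_region, stop_map, write_frame_map
from .ribo_frame import density_drop, frame_counts, initiation_peaks, write_frame_counts, write_peaks
from .seq_io import read_fasta, read_variant_table, write_fasta, write_track
from .start_eval import context_matrix, score_context, stem_distance, write_context_matrix
from .syn_constraint import count_synonymous_substitutions, fit_neutral_rate, scan_windows, write_window_stats
from .synth import (
    AlignmentSimParams,
    FootprintSimParams,
    make_fixture_transcript,
    simulate_alignment,
    simulate_footprints,
    simulate_variants,
)

log = logging.getLogger("dualorf")

REPORT_SCHEMA_VERSION = 1
ALL_STAGES = ("align", "survey", "synscan", "start", "ribo", "variants")

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "inputs",
    "alignment",
    "synscan",
    "ribo",
    "variants",
    "start",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 7
    out_dir: str = "dualorf_out"
    stages: tuple[str, ...] = ALL_STAGES
    inputs: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)
    synscan: dict = field(default_factory=dict)
    ribo: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    start: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.stages = tuple(cfg.stages)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        for key, path_ in (cfg.inputs or {}).items():
            if not os.path.exists(path_):
                raise ConfigError(f"input {key!r}: path {path_!r} does not exist")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages in dependency order; return the report."""
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    transcript, orfs, extras = make_fixture_transcript(seed=config.seed)
    orf_by_name = {o.name: o for o in orfs}
    log.info("fixture transcript %s (%d nt, %d ORFs)", transcript.id, len(transcript), len(orfs))

    aln = None
    try:
        if "align" in config.stages:
            report["stages"]["align"] = _stage_align(config)
            aln = report["stages"]["align"].pop("_aln")
        if "survey" in config.stages:
            if aln is None:
                aln = _default_alignment(config)
            report["stages"]["survey"] = _stage_survey(config, aln)
        if "synscan" in config.stages:
            if aln is None:
                aln = _default_alignment(config)
            report["stages"]["synscan"] = _stage_synscan(config, aln)
        if "start" in config.stages:
            report["stages"]["start"] = _stage_start(config, transcript, orfs, extras)
        if "ribo" in config.stages:
            report["stages"]["ribo"] = _stage_ribo(config, orf_by_name, extras)
        if "variants" in config.stages:
            report["stages"]["variants"] = _stage_variants(config, transcript, orfs)
    except Exception as exc:
        failed = _first_unfinished(config.stages, report["stages"])
        report["failed_stage"] = failed
        report["error"] = str(exc)
        _write_report(config, report)
        raise
    _write_report(config, report)
    return report


def _first_unfinished(stages, done) -> str:
    for s in stages:
        if s not in done:
            return s
    return "unknown"


def _write_report(config: RunConfig, report: dict) -> None:
    path = os.path.join(config.out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    log.info("report written to %s", path)


def _alignment_params(config: RunConfig) -> AlignmentSimParams:
    p = dict(config.alignment)
    overlap = p.pop("overlap", (60, 160))
    return AlignmentSimParams(
        n_species=p.pop("n_species", 12),
        branch_length=p.pop("branch_length", 0.4),
        orf_len=p.pop("orf_len", 300),
        overlap=tuple(overlap) if overlap else None,
        mode=p.pop("mode", "dual_constrained"),
        seed=config.seed,
    )


def _default_alignment(config: RunConfig):
    if "alignment_fasta" in (config.inputs or {}):
        records = read_fasta(config.inputs["alignment_fasta"])
        from .codon_align import CodonAlignment

        aln = CodonAlignment(reference_id=records[0][0], rows=dict(records))
        return map_to_reference(aln)
    aln, _ = simulate_alignment(_alignment_params(config))
    return map_to_reference(aln)


def _stage_align(config: RunConfig) -> dict:
    aln = _default_alignment(config)
    out = os.path.join(config.out_dir, "alignment.fa")
    write_fasta(out, list(aln.rows.items()))
    qc = row_quality_report(aln)
    qc_path = os.path.join(config.out_dir, "alignment_qc.tsv")
    with open(qc_path, "w") as fh:
        fh.write("species\tgap_fraction\tidentity_to_reference\n")
        for sp, row in qc.items():
            fh.write(f"{sp}\t{row['gap_fraction']:.4f}\t{row['identity_to_reference']:.4f}\n")
    return {
        "n_rows": len(aln.rows),
        "n_codons": aln.n_codons,
        "fasta": out,
        "qc": qc_path,
        "_aln": aln,
    }


def _stage_survey(config: RunConfig, aln) -> dict:
    block = {}
    for frame in (0, 1, 2):
        fmap = stop_map(aln, frame)
        path = os.path.join(config.out_dir, f"stops_frame{frame}.tsv")
        write_frame_map(path, fmap)
        regions = stop_free_region(fmap, min_species_fraction=1.0)
        block[f"frame{frame}"] = {
            "stop_free_regions": regions,
            "tsv": path,
        }
    return block


def _stage_synscan(config: RunConfig, aln) -> dict:
    p = dict(config.synscan)
    w = p.get("window_codons", 25)
    threshold = p.get("threshold", 0.05)
    counts = count_synonymous_substitutions(aln)
    rate = fit_neutral_rate(counts)
    stats = scan_windows(counts, w=w, threshold=threshold)
    path = os.path.join(config.out_dir, "synscan.tsv")
    write_window_stats(path, stats)
    sig = [s.center_codon for s in stats if s.significant]
    return {
        "neutral_rate": rate,
        "window_codons": w,
        "threshold": threshold,
        "n_significant_windows": len(sig),
        "significant_span": [min(sig), max(sig)] if sig else None,
        "tsv": path,
    }


def _stage_start(config: RunConfig, transcript, orfs, extras) -> dict:
    orf_y = next(o for o in orfs if o.start_codon != "ATG")
    ctx = score_context(transcript.sequence, orf_y.start_tx)
    matrix, n_used = context_matrix([ctx.context])
    mpath = os.path.join(config.out_dir, "context_matrix.tsv")
    write_context_matrix(mpath, matrix)
    call = stem_distance(extras["stem_structure"], 0)
    return {
        "orf": orf_y.name,
        "codon": ctx.codon,
        "context": ctx.context,
        "strength": ctx.strength,
        "score": ctx.score,
        "first_paired_offset": call.first_paired_offset,
        "optimal_distance": call.optimal_distance,
        "matrix": mpath,
    }


def _stage_ribo(config: RunConfig, orf_by_name, extras) -> dict:
    p = dict(config.ribo)
    params = FootprintSimParams(
        orf_layout=list(orf_by_name.values()),
        init_fraction=p.get("init_fraction", {"ORF-Z": 0.3, "ORF-Y": 0.6, "main": 1.0}),
        n_reads=p.get("n_reads", 50_000),
        seed=config.seed,
    )
    init_track, elong_track, truth = simulate_footprints(params)
    write_track(os.path.join(config.out_dir, "initiating.bedgraph"), init_track)
    write_track(os.path.join(config.out_dir, "elongating.bedgraph"), elong_track)

    main = orf_by_name["main"]
    orf_y = orf_by_name["ORF-Y"]
    regions = [(n, a, b) for n, a, b in extras["regions"]]
    fc = frame_counts(elong_track, regions, frame_anchor=main.start_tx)
    write_frame_counts(os.path.join(config.out_dir, "frame_counts.tsv"), fc)
    peaks = initiation_peaks(init_track, [o.start_tx for o in orf_by_name.values()])
    write_peaks(os.path.join(config.out_dir, "initiation_peaks.tsv"), peaks)
    drop = density_drop(elong_track, orf_y.end_tx - 3, flank=p.get("flank", 60))
    return {
        "flux": truth["flux"],
        "frame_counts": {
            r.region_name: {"counts": list(r.counts_by_frame), "plurality": r.plurality_frame}
            for r in fc
        },
        "initiation_peaks": {pk.position: pk.enrichment for pk in peaks},
        "density_drop": {
            "stop": drop.stop_pos,
            "up": drop.density_up,
            "down": drop.density_down,
            "ratio": drop.ratio,
            "expected_ratio": truth["drop_ratio_at_stop"].get("ORF-Y"),
        },
    }


def _stage_variants(config: RunConfig, transcript, orfs) -> dict:
    p = dict(config.variants)
    if "variant_table" in (config.inputs or {}):
        records = read_variant_table(config.inputs["variant_table"])
    else:
        records, _ = simulate_variants(
            transcript, orfs, n=p.get("n", 15), seed=config.seed
        )
    main = next(o for o in orfs if o.name == "main")
    annotations = annotate_table(transcript, orfs, records, main_orf=main)
    overlap_names = [o.name for o in orfs if o.name != "main"]
    path = os.path.join(config.out_dir, "variants_annotated.tsv")
    write_annotated_table(path, records, annotations, overlap_names)
    counts = filter_table(annotations)
    return {"n_variants": len(records), "counts": counts, "tsv": path}
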