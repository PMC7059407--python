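"""Ribosome-profiling footprint analysis for overlapping ORFs.

Three complementary signals identify a translated alternative-frame ORF
in per-nucleotide footprint tracks: an initiating-ribosome peak at the
candidate start codon, a shift in the plurality reading frame of
elongating footprints inside the overlap region, and a step drop in
read density immediately downstream of the alternative frame's stop
codon (if a fraction f of ribosomes terminate there, the density ratio
across the stop is 1/(1-f); half the ribosomes terminating gives a
two-fold drop).

Tracks are consumed as already P-site/A-site-assigned per-nucleotide
counts; footprint-length calibration is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import FootprintTrack

__all__ = [
    "RegionFrameCounts",
    "InitiationPeak",
    "DropTest",
    "frame_counts",
    "initiation_peaks",
    "density_drop",
    "write_frame_counts",
    "write_peaks",
]

PEAK_FLANK_CODONS = 1  # codons on each side of a candidate start in the peak window
STOP_BUFFER_NT = 3  # one codon excluded on each side of a stop codon


@dataclass
class RegionFrameCounts:
    region_name: str
    counts_by_frame: tuple[int, int, int]
    plurality_frame: int | str  # argmax frame, or "tie"

    @property
    def total(self) -> int:
        return sum(self.counts_by_frame)


@dataclass
class InitiationPeak:
    position: int
    count: int
    local_background_mean: float
    enrichment: float


@dataclass
class DropTest:
    stop_pos: int
    flank: int
    density_up: float
    density_down: float
    ratio: float  # inf when density_down == 0 and density_up > 0


def _plurality(counts: tuple[int, int, int]) -> int | str:
    top = max(counts)
    winners = [f for f, c in enumerate(counts) if c == top]
    return winners[0] if len(winners) == 1 else "tie"


def frame_counts(
    track: FootprintTrack,
    regions: list[tuple[str, int, int]],
    frame_anchor: int,
    include_total: bool = True,
) -> list[RegionFrameCounts]:
    """Read counts per sub-codon frame for each region.

    A position's frame is ``(pos - frame_anchor) mod 3``, so frame 0 is
    the frame anchored at ``frame_anchor`` (typically an ORF start).
    Regions are half-open transcript intervals and must not overlap —
    they partition an ORF span.  When ``include_total`` is set, a
    synthesized "total" region covering their union is appended.
    """
    spans = sorted((start, end, name) for name, start, end in regions)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"regions {n1!r} and {n2!r} overlap")

    out = []
    total_frames = [0, 0, 0]
    for name, start, end in regions:
        frames = [0, 0, 0]
        for pos, count in track.counts.items():
            if start <= pos < end:
                frames[(pos - frame_anchor) % 3] += count
        out.append(RegionFrameCounts(name, tuple(frames), _plurality(tuple(frames))))
        for f in range(3):
            total_frames[f] += frames[f]
    if include_total:
        tf = tuple(total_frames)
        out.append(RegionFrameCounts("total", tf, _plurality(tf)))
    return out


def initiation_peaks(
    init_track: FootprintTrack,
    candidates: list[int],
    background_window: int = 60,
) -> list[InitiationPeak]:
    """Initiating-read enrichment at candidate start codons.

    The peak window is the candidate codon plus PEAK_FLANK_CODONS codons
    on each side; the background is the mean per-nucleotide count over
    ``background_window`` nt on each side of (and excluding) the peak
    window.  Enrichment is the peak window's per-nucleotide density over
    the background density (infinite for a peak on a silent background).
    """
    peaks = []
    flank_nt = 3 * PEAK_FLANK_CODONS
    for cand in candidates:
        peak_lo, peak_hi = cand - flank_nt, cand + 3 + flank_nt
        count = sum(init_track.get(p) for p in range(peak_lo, peak_hi))
        bg_positions = list(range(peak_lo - background_window, peak_lo)) + list(
            range(peak_hi, peak_hi + background_window)
        )
        bg_total = sum(init_track.get(p) for p in bg_positions)
        background = bg_total / len(bg_positions)
        peak_density = count / (peak_hi - peak_lo)
        if background > 0:
            enrichment = peak_density / background
        else:
            enrichment = float("inf") if count > 0 else 1.0
        peaks.append(InitiationPeak(cand, count, background, enrichment))
    return peaks


def density_drop(track: FootprintTrack, stop_pos: int, flank: int = 60) -> DropTest:
    """Elongating-read density ratio across a stop codon.

    The stop codon's 3 nt plus a one-codon buffer on each side are
    excluded from both windows, because elongating footprints pile up on
    terminating ribosomes at the stop itself and would bias the upstream
    density.  ``flank`` (>= 30 nt) sets both window widths.  The ratio
    upstream/downstream estimates 1/(1 - f) for a terminating fraction f.
    """
    if flank < 30:
        raise ValueError(f"flank must be >= 30 nt, got {flank}")
    lo, hi = track.span()
    up_hi = stop_pos - STOP_BUFFER_NT
    up_lo = up_hi - flank
    down_lo = stop_pos + 3 + STOP_BUFFER_NT
    down_hi = down_lo + flank
    if up_lo < lo or down_hi > hi:
        raise ValueError(
            f"flank {flank} around stop {stop_pos} exceeds track span [{lo}, {hi})"
        )
    density_up = sum(track.get(p) for p in range(up_lo, up_hi)) / flank
    density_down = sum(track.get(p) for p in range(down_lo, down_hi)) / flank
    if density_down > 0:
        ratio = density_up / density_down
    else:
        ratio = float("inf") if density_up > 0 else float("nan")
    return DropTest(stop_pos, flank, density_up, density_down, ratio)


def write_frame_counts(path, results: list[RegionFrameCounts]) -> None:
    with open(path, "w") as fh:
        fh.write("region\tframe0\tframe1\tframe2\tplurality\n")
        for r in results:
            f0, f1, f2 = r.counts_by_frame
            fh.write(f"{r.region_name}\t{f0}\t{f1}\t{f2}\t{r.plurality_frame}\n")


def write_peaks(path, peaks: list[InitiationPeak]) -> None:
    with open(path, "w") as fh:
        fh.write("candidate\tcount\tbackground\tenrichment\n")
        for p in peaks:
            fh.write(
                f"{p.position}\t{p.count}\t{p.local_background_mean:.4f}\t{p.enrichment:.4f}\n"
            )
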