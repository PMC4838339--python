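"""Chromatin-mark metaprofiles and peak topology at pri-/pre-miRNA anchors.

Metaprofiles average a tpm-normalized coverage track over stranded anchor
positions (pri-miRNA TSSs or pre-miRNA 5' ends), flipping minus-strand windows so
offsets read 5'->3'. Peak topology distinguishes pre-miRNAs whose H3K4me3 peak is
independent of the pri-miRNA promoter peak from those covered by one peak that
spans promoter to hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CoverageTrack, GenomicInterval, Peak
from .premirna_catalog import PreMirna
from .promoter_assignment import PromoterAssignment

TOPOLOGY_INDEPENDENT = "independent"
TOPOLOGY_SPANNING = "spanning"
TOPOLOGY_NONE = "none"


@dataclass
class MetaProfile:
    """Average signal at offsets -flank..+flank around n_anchors anchors."""

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int

    @property
    def flank(self) -> int:
        return int(self.offsets[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_signal": self.values})


@dataclass
class PeakTopology:
    pre_mirna: PreMirna
    label: str
    premirna_peaks: tuple[Peak, ...] = ()
    tss_peaks: tuple[Peak, ...] = ()


def anchor_window(track: CoverageTrack, chrom: str, pos: int, strand: str,
                  flank: int) -> np.ndarray:
    """Strand-oriented signal window of length 2*flank+1 centered on pos."""
    win = track.window(chrom, pos - flank, pos + flank + 1)
    return win[::-1].copy() if strand == "-" else win


def metaprofile(track: CoverageTrack,
                anchors: Sequence[GenomicInterval | tuple[str, int, str]],
                flank: int) -> MetaProfile:
    """Per-offset arithmetic mean of the track over stranded anchors.

    Anchors are (chrom, position, strand) tuples or width->=1 intervals anchored
    at their 5' ends; minus-strand windows are reversed before averaging and
    positions without coverage contribute 0.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("metaprofile requires at least one anchor")
    acc = np.zeros(2 * flank + 1, dtype=np.float64)
    for a in anchors:
        if isinstance(a, GenomicInterval):
            chrom, pos, strand = a.chrom, a.five_prime, a.strand
        else:
            chrom, pos, strand = a
        acc += anchor_window(track, chrom, pos, strand, flank)
    return MetaProfile(np.arange(-flank, flank + 1), acc / len(anchors),
                       len(anchors))


def _peak_tree(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p)
    return trees


def _overlapping(trees: dict[str, IntervalTree], chrom: str, start: int,
                 end: int) -> list[Peak]:
    if start >= end:
        return []
    return [h.data for h in trees.get(chrom, IntervalTree()).overlap(start, end)]


def peak_at_premirna(pre_mirna: PreMirna, peaks: Sequence[Peak],
                     flank: int = 500) -> bool:
    """Whether any peak overlaps the hairpin widened by ``flank`` on both sides."""
    h = pre_mirna.hairpin
    trees = _peak_tree(peaks)
    return bool(_overlapping(trees, h.chrom, h.start - flank, h.end + flank))


def classify_peak_topology(pre_mirna: PreMirna, assignment: PromoterAssignment,
                           peaks: Sequence[Peak], flank: int = 500) -> PeakTopology:
    """Independent vs spanning H3K4me3 peak architecture for one assigned locus.

    'spanning': one peak interval overlaps both the TSS window (+-flank) and the
    hairpin window. 'independent': the hairpin has peak(s), none shared with the
    TSS window. 'none': no peak at the hairpin window at all.
    """
    if not assignment.assigned or assignment.tss is None:
        raise ValueError(f"{pre_mirna.name}: topology undefined without an "
                         "assigned promoter")
    h = pre_mirna.hairpin
    trees = _peak_tree(peaks)
    pre_peaks = _overlapping(trees, h.chrom, h.start - flank, h.end + flank)
    tss_peaks = _overlapping(trees, h.chrom, assignment.tss - flank,
                             assignment.tss + flank + 1)
    if not pre_peaks:
        return PeakTopology(pre_mirna, TOPOLOGY_NONE, (), tuple(tss_peaks))
    shared = [p for p in pre_peaks if p in tss_peaks]
    label = TOPOLOGY_SPANNING if shared else TOPOLOGY_INDEPENDENT
    return PeakTopology(pre_mirna, label, tuple(pre_peaks), tuple(tss_peaks))


def heatmap_matrix(track: CoverageTrack, pre_mirnas: Sequence[PreMirna],
                   assignments: Sequence[PromoterAssignment],
                   cgis: Sequence[GenomicInterval], flank: int,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-locus signal matrix around hairpin 5' ends, ordered for display.

    Rows are partitioned into CGI-overlapping (top) and non-overlapping loci,
    each partition sorted by ascending TSS-to-hairpin distance. Returns the
    (n, 2*flank+1) matrix and row metadata (name, distance, cgi flag).
    """
    assign_by_name = {a.pre_mirna.name: a for a in assignments}
    cgi_trees: dict[str, IntervalTree] = {}
    for c in cgis:
        cgi_trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    rows = []
    for pm in pre_mirnas:
        a = assign_by_name.get(pm.name)
        dist = a.distance if (a is not None and a.assigned) else np.inf
        h = pm.hairpin
        cgi = bool(cgi_trees.get(h.chrom, IntervalTree()).overlap(h.start, h.end))
        rows.append((pm, dist, cgi))
    rows.sort(key=lambda r: (not r[2], r[1], r[0].name))
    mat = np.vstack([
        anchor_window(track, pm.hairpin.chrom, pm.five_prime, pm.strand, flank)
        for pm, _, _ in rows
    ]) if rows else np.zeros((0, 2 * flank + 1))
    meta = pd.DataFrame(
        [(pm.name, d if np.isfinite(d) else pd.NA, c) for pm, d, c in rows],
        columns=["name", "distance", "cgi_overlap"],
    )
    return mat, meta


def call_peaks(track: CoverageTrack, fold: float = 4.0,
               min_width: int = 200) -> list[Peak]:
    """Minimal threshold peak caller for self-contained synthetic fixtures:
    runs of coverage >= ``fold`` x global mean spanning >= ``min_width`` bases."""
    values = np.concatenate([
        track.window(c, 0, n) for c, n in sorted(track.chrom_sizes().items())
    ]) if track.chrom_sizes() else np.zeros(0)
    mean = values.mean() if values.size else 0.0
    if mean <= 0:
        return []
    peaks = []
    i = 0
    for chrom in sorted(track.chrom_sizes()):
        arr = track.window(chrom, 0, track.chrom_sizes()[chrom])
        above = arr >= fold * mean
        run_start = None
        for pos, flag in enumerate(above):
            if flag and run_start is None:
                run_start = pos
            elif not flag and run_start is not None:
                if pos - run_start >= min_width:
                    i += 1
                    peaks.append(Peak(GenomicInterval(
                        chrom, run_start, pos, ".", f"peak{i}"),
                        float(arr[run_start:pos].mean())))
                run_start = None
        if run_start is not None and arr.size - run_start >= min_width:
            i += 1
            peaks.append(Peak(GenomicInterval(
                chrom, run_start, arr.size, ".", f"peak{i}"),
                float(arr[run_start:].mean())))
    return peaks
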