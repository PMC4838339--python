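"""Tag-cluster construction from CAGE transcription start sites.

Same-strand CTSSs at most ``max_gap`` nucleotides apart are chained into tag
clusters (TCs), the single-nucleotide-resolution unit of promoter analysis. Each
TC carries a representative CTSS (the position with the highest pooled tpm), an
interquantile-width shape class (sharp vs broad) and an initiator class read from
the -1/+1 dinucleotide at the representative:

* canonical   — pyrimidine at -1, purine at +1 (transcription initiation)
* processing  — G at both -1 and +1 (post-transcriptionally recapped RNA,
                e.g. Drosha cleavage products picked up by CAGE)
* other       — anything else
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import Genome, GenomicInterval

logger = logging.getLogger("primir")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

SHARP = "sharp"
BROAD = "broad"
CANONICAL = "canonical"
PROCESSING = "processing"
OTHER = "other"


@dataclass
class TagCluster:
    """Strand-specific run of CTSSs with per-stage expression.

    ``positions`` is sorted ascending; ``tpm_matrix`` has one row per position and
    one column per stage in ``stages``. ``pooled`` is the across-stage sum per
    position.
    """

    chrom: str
    strand: str
    positions: np.ndarray
    tpm_matrix: np.ndarray
    stages: tuple[str, ...]
    shape_class: str | None = None
    initiator_class: str | None = None
    tc_id: str = ""

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1]) + 1

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.tc_id)

    @property
    def pooled(self) -> np.ndarray:
        return self.tpm_matrix.sum(axis=1)

    @property
    def total_tpm(self) -> float:
        """Pooled (across stages and members) tpm of the cluster."""
        return float(self.tpm_matrix.sum())

    def stage_tpm(self) -> pd.Series:
        """Per-stage total tpm."""
        return pd.Series(self.tpm_matrix.sum(axis=0), index=list(self.stages))

    @property
    def representative(self) -> int:
        return representative_ctss(self)


def cluster_ctss(ctss: pd.DataFrame, max_gap: int = 20,
                 stages: Sequence[str] | None = None) -> list[TagCluster]:
    """Single-linkage chaining of CTSSs into tag clusters.

    Consecutive same-strand CTSSs whose positional difference is <= ``max_gap``
    join one cluster; clusters are maximal. Input must carry tpm (see
    :func:`primir.io_formats.normalize_tpm`). Output is sorted by coordinate with
    stable ids ``TC000001`` onwards.
    """
    if ctss.empty:
        return []
    if ctss["tpm"].isna().any():
        raise ValueError("CTSSs must be tpm-normalized before clustering")
    if stages is None:
        stages = sorted(ctss["stage"].unique())
    stages = tuple(stages)

    # pivot to position x stage tpm, pooled over duplicate rows
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in ctss.groupby(["chrom", "strand"], sort=True):
        mat = (
            grp.pivot_table(index="pos", columns="stage", values="tpm",
                            aggfunc="sum", fill_value=0.0)
            .reindex(columns=list(stages), fill_value=0.0)
            .sort_index()
        )
        positions = mat.index.to_numpy()
        breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
        for block in np.split(np.arange(positions.size), breaks):
            clusters.append(
                TagCluster(
                    chrom=chrom,
                    strand=strand,
                    positions=positions[block].astype(np.int64),
                    tpm_matrix=mat.to_numpy(dtype=np.float64)[block],
                    stages=stages,
                )
            )
    clusters.sort(key=lambda tc: (tc.chrom, tc.start, tc.strand))
    for i, tc in enumerate(clusters, start=1):
        tc.tc_id = f"TC{i:06d}"
    return clusters


def representative_ctss(tc: TagCluster) -> int:
    """Member position with the maximal pooled tpm; ties go to the most 5'
    position (strand-aware)."""
    if tc.positions.size == 0:
        raise ValueError("empty tag cluster has no representative")
    pooled = tc.pooled
    best = pooled.max()
    tied = tc.positions[pooled >= best - 1e-12]
    return int(tied.min() if tc.strand != "-" else tied.max())


def interquantile_width(positions: np.ndarray, weights: np.ndarray,
                        iq_low: float = 0.10, iq_high: float = 0.90) -> int:
    """Width in nt between the cumulative-mass quantiles of a tag distribution.

    The low (high) quantile position is the first member at which the cumulative
    tpm fraction reaches ``iq_low`` (``iq_high``); the width includes both ends.
    """
    total = weights.sum()
    if total <= 0:
        return int(positions[-1] - positions[0] + 1)
    frac = np.cumsum(weights) / total
    lo = positions[np.searchsorted(frac, iq_low, side="left")]
    hi = positions[np.searchsorted(frac, iq_high, side="left")]
    return int(hi - lo + 1)


def classify_shape(tc: TagCluster, iq_low: float = 0.10, iq_high: float = 0.90,
                   sharp_max_width: int = 4, stage: str | None = None) -> str:
    """Sharp/broad promoter-shape call from the interquantile width.

    With ``stage`` given, the width is computed on that stage's tpm alone
    (dynamic shape usage across development); default is pooled tpm.
    """
    if stage is None:
        weights = tc.pooled
    else:
        weights = tc.tpm_matrix[:, tc.stages.index(stage)]
    width = interquantile_width(tc.positions, weights, iq_low, iq_high)
    return SHARP if width <= sharp_max_width else BROAD


def classify_initiator(tc: TagCluster, genome: Genome) -> str:
    """Initiator class from the strand-corrected -1/+1 dinucleotide at the
    representative CTSS. A representative at the chromosome edge (no -1 base)
    is classed 'other' with a warning."""
    rep = representative_ctss(tc)
    if tc.strand == "-":
        # +1 is the representative base, -1 the base genomically downstream
        dinuc = genome.fetch(tc.chrom, rep, rep + 2, strand="-")
    else:
        dinuc = genome.fetch(tc.chrom, rep - 1, rep + 1, strand="+")
    if len(dinuc) < 2:
        logger.warning(
            "tag cluster %s representative %s:%d at chromosome edge; "
            "initiator set to 'other'", tc.tc_id, tc.chrom, rep,
        )
        return OTHER
    minus1, plus1 = dinuc[0], dinuc[1]
    if minus1 == "G" and plus1 == "G":
        return PROCESSING
    if minus1 in PYRIMIDINES and plus1 in PURINES:
        return CANONICAL
    return OTHER


def annotate_clusters(tcs: Iterable[TagCluster], genome: Genome,
                      iq_low: float = 0.10, iq_high: float = 0.90,
                      sharp_max_width: int = 4) -> list[TagCluster]:
    """Fill shape_class and initiator_class on every cluster in place."""
    tcs = list(tcs)
    for tc in tcs:
        tc.shape_class = classify_shape(tc, iq_low, iq_high, sharp_max_width)
        tc.initiator_class = classify_initiator(tc, genome)
    return tcs


def sum_expression_window(tcs: Iterable[TagCluster], chrom: str, strand: str,
                          anchor: int, flank: int = 500) -> pd.Series:
    """Per-stage tpm summed over TCs whose representative lies within
    [anchor - flank, anchor + flank] on the anchor's chrom/strand.

    This is the pri-miRNA promoter-region expression measure.
    """
    stages: tuple[str, ...] | None = None
    total: pd.Series | None = None
    for tc in tcs:
        if stages is None:
            stages = tc.stages
            total = pd.Series(0.0, index=list(stages))
        if tc.chrom != chrom or tc.strand != strand:
            continue
        rep = representative_ctss(tc)
        if anchor - flank <= rep <= anchor + flank:
            total = total.add(tc.stage_tpm(), fill_value=0.0)
    if total is None:
        return pd.Series(dtype=float)
    return total


def cluster_table(tcs: Iterable[TagCluster]) -> pd.DataFrame:
    """Flat TSV-ready table of cluster properties plus per-stage tpm columns."""
    rows = []
    for tc in tcs:
        row = dict(
            tc_id=tc.tc_id, chrom=tc.chrom, start=tc.start, end=tc.end,
            strand=tc.strand, width=tc.width, representative=tc.representative,
            total_tpm=tc.total_tpm, shape_class=tc.shape_class,
            initiator_class=tc.initiator_class,
        )
        for st, v in tc.stage_tpm().items():
            row[f"tpm_{st}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
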