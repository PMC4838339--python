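"""Sequence and developmental features of assigned pri-miRNA promoters.

Covers the maternal/zygotic expression classification, hierarchical clustering
of promoter activity across developmental stages, canonical TATA-box (TATAWA)
scanning, the average G+C metaprofile around TSSs, CpG-island overlap and the
per-stage sharp/broad shape usage of active promoters.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .ctss_clustering import TagCluster, classify_shape, representative_ctss
from .io_formats import Genome, GenomicInterval
from .promoter_assignment import PromoterAssignment

logger = logging.getLogger("primir")

MATERNAL = "maternal_inherited"
ZYGOTIC = "zygotic_only"

TATAWA_RE = re.compile(r"(?=TATA[AT]A)")


def expression_matrix(assignments: Sequence[PromoterAssignment],
                      stages: Sequence[str]) -> pd.DataFrame:
    """Assignments x stages tpm matrix (promoter-region +-500 b sums) for the
    assigned entries, columns in the configured stage order."""
    rows, index = [], []
    for a in assignments:
        if not a.assigned:
            continue
        rows.append([float(a.expression.get(st, 0.0)) for st in stages])
        index.append(a.pre_mirna.name)
    return pd.DataFrame(rows, index=index, columns=list(stages))


def classify_maternal(matrix: pd.DataFrame, maternal_stages: Sequence[str],
                      min_tpm: float = 1.0) -> pd.Series:
    """Maternal-inherited vs zygotic-only promoter activity.

    A promoter is maternally inherited iff its expression reaches ``min_tpm``
    in at least one maternal-flagged stage (pre-zygotic-genome-activation
    library); otherwise zygotic-only.
    """
    maternal_stages = list(maternal_stages)
    if not maternal_stages:
        raise ValueError("maternal stage set must be non-empty")
    missing = set(maternal_stages) - set(matrix.columns)
    if missing:
        raise KeyError(f"maternal stages not in matrix columns: {sorted(missing)}")
    hit = (matrix[maternal_stages] >= min_tpm).any(axis=1)
    return hit.map({True: MATERNAL, False: ZYGOTIC})


def cluster_expression(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray | None]:
    """Hierarchical clustering of promoters on log2(tpm+1) developmental profiles.

    Euclidean distance, complete linkage, deterministic leaf order (rows are
    pre-sorted by name so distance ties resolve stably). Returns (leaf-ordered
    row names, linkage matrix); a single row returns identity order and None.
    """
    matrix = matrix.sort_index()
    if len(matrix) < 2:
        return list(matrix.index), None
    data = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(link)
    return [matrix.index[i] for i in order], link


def scan_tatawa(assignments: Sequence[PromoterAssignment], genome: Genome,
                window: tuple[int, int] = (-40, -20)) -> pd.DataFrame:
    """Canonical TATA-box (TATAWA, W in {A,T}) hits upstream of each TSS.

    The scan is strand-oriented; a hit is counted when the match *starts* inside
    ``window`` (offsets relative to the representative TSS, upstream negative).
    Overlapping matches each count. Returns name, n_hits, hit offsets.
    """
    lo, hi = window
    rows = []
    for a in assignments:
        if not a.assigned or a.tss is None:
            continue
        pm = a.pre_mirna
        chrom_len = genome.chrom_sizes()[pm.hairpin.chrom]
        motif_len = 6
        if pm.strand != "-":
            start, end = a.tss + lo, a.tss + hi + motif_len
        else:
            start, end = a.tss - hi - motif_len + 1, a.tss - lo + 1
        if start < 0 or end > chrom_len:
            logger.warning("%s: TATAWA window truncated at chromosome edge",
                           pm.name)
        seq = genome.fetch(pm.hairpin.chrom, start, end, strand=pm.strand)
        # the fetched window reads 5'->3' on both strands, so a match at string
        # index i starts at offset lo + i relative to the TSS
        offsets = [lo + m.start() for m in TATAWA_RE.finditer(seq)]
        offsets = [o for o in offsets if lo <= o <= hi]
        rows.append(dict(name=pm.name, n_hits=len(offsets),
                         offsets=",".join(map(str, offsets))))
    return pd.DataFrame(rows, columns=["name", "n_hits", "offsets"])


def gc_profile(assignments: Sequence[PromoterAssignment], genome: Genome,
               flank: int = 500) -> np.ndarray:
    """Mean per-offset G+C indicator around TSSs, strand-oriented.

    Returns an array of length 2*flank+1 over offsets -flank..+flank; positions
    beyond chromosome ends contribute 0 (counted as non-GC).
    """
    acc = np.zeros(2 * flank + 1, dtype=np.float64)
    n = 0
    for a in assignments:
        if not a.assigned or a.tss is None:
            continue
        pm = a.pre_mirna
        start, end = a.tss - flank, a.tss + flank + 1
        seq = genome.fetch(pm.hairpin.chrom, max(0, start), end, strand="+")
        window = np.zeros(2 * flank + 1, dtype=np.float64)
        off = max(0, start) - start
        gc = np.frombuffer(seq.encode(), dtype=np.uint8)
        window[off : off + gc.size] = np.isin(gc, np.frombuffer(b"GC", dtype=np.uint8))
        if pm.strand == "-":
            window = window[::-1]
        acc += window
        n += 1
    return acc / n if n else acc


def cgi_overlap(assignments: Sequence[PromoterAssignment],
                cgis: Sequence[GenomicInterval], window: int = 500,
                ) -> tuple[pd.Series, float]:
    """CGI overlap per assigned promoter (TSS +- window) and the fraction of
    distinct promoters (cluster-collapsed) overlapping a CGI."""
    trees: dict[str, IntervalTree] = {}
    for c in cgis:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    flags = {}
    per_gene: dict[str, bool] = {}
    for a in assignments:
        if not a.assigned or a.tss is None:
            continue
        pm = a.pre_mirna
        hit = bool(trees.get(pm.hairpin.chrom, IntervalTree())
                   .overlap(a.tss - window, a.tss + window + 1))
        flags[pm.name] = hit
        gid = pm.cluster_id or pm.name
        per_gene[gid] = per_gene.get(gid, False) or hit
    frac = (sum(per_gene.values()) / len(per_gene)) if per_gene else 0.0
    return pd.Series(flags, dtype=bool), frac


def shape_usage_by_stage(tcs: Sequence[TagCluster],
                         assignments: Sequence[PromoterAssignment],
                         stages: Sequence[str], min_tpm: float = 1.0,
                         **shape_kwargs) -> pd.DataFrame:
    """Per-stage sharp/broad counts of active assigned promoters.

    A promoter is active in a stage when its assigned TC has >= ``min_tpm`` in
    that stage; its shape there is classified on the stage-restricted tag
    distribution.
    """
    counts = {st: {"sharp": 0, "broad": 0} for st in stages}
    for a in assignments:
        if not a.assigned or a.tc is None:
            continue
        stage_tot = a.tc.stage_tpm()
        for st in stages:
            if stage_tot.get(st, 0.0) >= min_tpm:
                shape = classify_shape(a.tc, stage=st, **shape_kwargs)
                counts[st][shape] += 1
    return pd.DataFrame(counts).T.loc[list(stages)]
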