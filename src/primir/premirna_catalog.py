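"""Pre-miRNA catalog: expression filtering, genic context, cluster collapsing.

A catalog entry is a hairpin precursor with optional mature 5p/3p arm intervals.
Entries are filtered on expression (max across stages >= 1 tpm by default),
classified as intergenic or intragenic on a coding/non-coding host, and collapsed
into genomic clusters (polycistrons such as the 59-copy miR-430 repeat count as a
single gene for bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, TranscriptModel, ValidationError

INTERGENIC = "intergenic"
INTRAGENIC_CODING = "intragenic_coding"
INTRAGENIC_NONCODING = "intragenic_noncoding"


@dataclass
class PreMirna:
    """Hairpin precursor with optional mature arms and genic context."""

    name: str
    hairpin: GenomicInterval
    mature_5p: GenomicInterval | None = None
    mature_3p: GenomicInterval | None = None
    family: str = ""
    context: str = INTERGENIC
    host: TranscriptModel | None = None
    host_same_strand: bool | None = None
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        for arm, label in ((self.mature_5p, "5p"), (self.mature_3p, "3p")):
            if arm is None:
                continue
            if arm.strand != self.hairpin.strand or not (
                arm.chrom == self.hairpin.chrom
                and arm.start >= self.hairpin.start
                and arm.end <= self.hairpin.end
            ):
                raise ValidationError(
                    f"{self.name}: mature {label} arm must lie within the hairpin "
                    "on the same strand"
                )
        if self.mature_5p is not None and self.mature_3p is not None:
            if self.hairpin.strand == "-":
                ok = self.mature_5p.start >= self.mature_3p.end - 1
            else:
                ok = self.mature_5p.end - 1 <= self.mature_3p.start
            if not ok:
                raise ValidationError(f"{self.name}: 5p arm must be 5' of 3p arm")

    @property
    def strand(self) -> str:
        return self.hairpin.strand

    @property
    def five_prime(self) -> int:
        return self.hairpin.five_prime

    @property
    def is_intragenic(self) -> bool:
        return self.context != INTERGENIC


def catalog_from_beds(hairpins: Sequence[GenomicInterval],
                      matures: Sequence[GenomicInterval] = ()) -> list[PreMirna]:
    """Assemble PreMirna records from hairpin BED plus mature-arm BED.

    Mature arms attach to the hairpin they fall inside; arm polarity comes from a
    ``-5p``/``-3p`` name suffix, else from position within the hairpin.
    """
    entries = {h.name: PreMirna(h.name, h) for h in hairpins}
    by_chrom: dict[str, IntervalTree] = {}
    for h in hairpins:
        by_chrom.setdefault(h.chrom, IntervalTree()).addi(h.start, h.end, h.name)
    for m in matures:
        hits = by_chrom.get(m.chrom, IntervalTree()).overlap(m.start, m.end)
        for hit in hits:
            pm = entries[hit.data]
            if m.strand != pm.strand or m.start < pm.hairpin.start or m.end > pm.hairpin.end:
                continue
            if m.name.endswith("-5p"):
                arm = "5p"
            elif m.name.endswith("-3p"):
                arm = "3p"
            else:
                mid = (m.start + m.end) / 2
                hp_mid = (pm.hairpin.start + pm.hairpin.end) / 2
                upstream = mid < hp_mid
                arm = "5p" if upstream == (pm.strand != "-") else "3p"
            if arm == "5p":
                pm.mature_5p = m
            else:
                pm.mature_3p = m
            break
    return sorted(entries.values(), key=lambda p: (p.hairpin.chrom, p.hairpin.start))


@dataclass
class ExpressionSummary:
    """Per-stage expression of one pre-miRNA (tpm), with the across-stage max."""

    name: str
    stage_tpm: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.stage_tpm.values()):
            raise ValidationError(f"{self.name}: negative tpm")

    @property
    def max_tpm(self) -> float:
        return max(self.stage_tpm.values(), default=0.0)


def filter_expressed(catalog: Sequence[PreMirna],
                     expression: Mapping[str, ExpressionSummary],
                     min_tpm: float = 1.0) -> list[PreMirna]:
    """Retain entries expressed at >= ``min_tpm`` in at least one stage.

    Every catalog entry must have an expression record; missing names raise.
    """
    missing = [pm.name for pm in catalog if pm.name not in expression]
    if missing:
        raise KeyError(f"missing expression records for: {', '.join(missing)}")
    return [pm for pm in catalog if expression[pm.name].max_tpm >= min_tpm]


def classify_genic_context(catalog: Sequence[PreMirna],
                           host_genes: Sequence[TranscriptModel]) -> list[PreMirna]:
    """Label each entry intergenic / intragenic_coding / intragenic_noncoding.

    Any overlap (>= 1 bp, either strand) of the hairpin with a gene span makes the
    entry intragenic; a coding host wins over a non-coding one when both overlap.
    Returns the same objects, mutated, for chaining.
    """
    trees: dict[str, IntervalTree] = {}
    for g in host_genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    for pm in catalog:
        hits = [h.data for h in trees.get(pm.hairpin.chrom, IntervalTree())
                .overlap(pm.hairpin.start, pm.hairpin.end)]
        if not hits:
            pm.context, pm.host, pm.host_same_strand = INTERGENIC, None, None
            continue
        coding_hits = [g for g in hits if g.coding]
        host = min(coding_hits or hits, key=lambda g: (g.start, g.name))
        pm.host = host
        pm.context = INTRAGENIC_CODING if host.coding else INTRAGENIC_NONCODING
        pm.host_same_strand = host.strand == pm.strand
    return list(catalog)


def collapse_clusters(catalog: Sequence[PreMirna],
                      max_intra_distance: int = 10_000) -> tuple[list[PreMirna], int]:
    """Chain same-strand hairpins <= ``max_intra_distance`` apart into clusters.

    Distance is the gap between hairpin intervals (0 when they touch/overlap).
    Sets ``cluster_id`` on every entry and returns (catalog, gene-level count)
    where each multi-member cluster counts once.
    """
    ordered = sorted(catalog, key=lambda p: (p.hairpin.chrom, p.strand,
                                             p.hairpin.start, p.hairpin.end))
    groups: list[list[PreMirna]] = []
    for pm in ordered:
        if groups:
            last = groups[-1][-1]
            same = (last.hairpin.chrom == pm.hairpin.chrom
                    and last.strand == pm.strand)
            gap = pm.hairpin.start - max(g.hairpin.end for g in groups[-1])
            if same and gap <= max_intra_distance:
                groups[-1].append(pm)
                continue
        groups.append([pm])
    for i, grp in enumerate(groups, start=1):
        cid = f"CL{i:05d}"
        for pm in grp:
            pm.cluster_id = cid
    return list(catalog), len(groups)


def exclude_exonic_predicted(predicted: Sequence[PreMirna],
                             known: Sequence[PreMirna],
                             coding_exons: Sequence[GenomicInterval],
                             min_reciprocal_overlap: float = 0.5) -> list[PreMirna]:
    """Filter a predicted-hairpin set for the Drosha-processing screen.

    Drops predicted hairpins overlapping any coding exon and hairpins matching a
    known entry at >= ``min_reciprocal_overlap`` reciprocal overlap.
    """
    exon_trees: dict[str, IntervalTree] = {}
    for ex in coding_exons:
        exon_trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end)
    known_trees: dict[str, IntervalTree] = {}
    for pm in known:
        known_trees.setdefault(pm.hairpin.chrom, IntervalTree()).addi(
            pm.hairpin.start, pm.hairpin.end)

    kept = []
    for pm in predicted:
        h = pm.hairpin
        if exon_trees.get(h.chrom, IntervalTree()).overlap(h.start, h.end):
            continue
        match = False
        for hit in known_trees.get(h.chrom, IntervalTree()).overlap(h.start, h.end):
            ov = min(h.end, hit.end) - max(h.start, hit.begin)
            if (ov / h.length >= min_reciprocal_overlap
                    and ov / (hit.end - hit.begin) >= min_reciprocal_overlap):
                match = True
                break
        if not match:
            kept.append(pm)
    return kept
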