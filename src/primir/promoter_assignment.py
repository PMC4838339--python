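"""Pri-miRNA promoter assignment by iterative upstream search with evidence tiers.

For an intergenic pre-miRNA the search walks upstream of the hairpin 5' end in
5-kb steps up to 40 kb; an encountered coding gene truncates the region at that
gene's 3' end. Candidate tag clusters (same strand, pooled tpm >= 0.5, not
processing-class, not already used as another gene's promoter) are then chosen by
a tier cascade:

    SINGLE_TC       exactly one candidate in the current window
    RNA_CONCORDANT  candidate whose representative matches a transcript 5' end
                    (within a tolerance) where the transcript reaches the hairpin
    H3K4ME3         candidate under an H3K4me3 peak (+-500 b of the representative)
    EXPRESSION      fallback: highest-tpm candidate within the search bound

Intragenic pre-miRNAs on a non-coding host inherit the host 5' end
(NONCODING_HOST). On a coding host, the same tier logic runs between hairpin and
host 5' end; failing that, a hairpin < 5 kb from the host 5' end is attributed to
the host promoter (HOST_PROMOTER), otherwise the entry stays unassigned.
Members of a collapsed genomic cluster (polycistron) share a single assignment
anchored at the 5'-most hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ctss_clustering import PROCESSING, TagCluster, representative_ctss, \
    sum_expression_window
from .io_formats import Peak, TranscriptModel
from .premirna_catalog import INTRAGENIC_NONCODING, PreMirna

TIER_SINGLE_TC = "SINGLE_TC"
TIER_RNA_CONCORDANT = "RNA_CONCORDANT"
TIER_H3K4ME3 = "H3K4ME3"
TIER_EXPRESSION = "EXPRESSION"
TIER_HOST_PROMOTER = "HOST_PROMOTER"
TIER_NONCODING_HOST = "NONCODING_HOST"
UNASSIGNED = "UNASSIGNED"

INDEPENDENT_TIERS = (TIER_SINGLE_TC, TIER_RNA_CONCORDANT, TIER_H3K4ME3,
                     TIER_EXPRESSION)


@dataclass
class SearchParams:
    """Tunables of the upstream promoter search (distances in nt, tpm in tags
    per million)."""

    max_upstream: int = 40_000
    step: int = 5_000
    min_tc_tpm: float = 0.5
    alt_min_offset: int = 500
    host_proximal: int = 5_000
    concordance_tol: int = 100
    h3k4me3_flank: int = 500
    expression_flank: int = 500

    def __post_init__(self) -> None:
        if self.step > self.max_upstream:
            raise ValueError("step must be <= max_upstream")
        for name in ("max_upstream", "step", "min_tc_tpm", "alt_min_offset",
                     "host_proximal", "concordance_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Candidate:
    tc: TagCluster
    distance: int  # strand-aware nt from hairpin 5' end to the representative

    @property
    def tpm(self) -> float:
        return self.tc.total_tpm


@dataclass
class PromoterAssignment:
    """Outcome of the promoter search for one pre-miRNA."""

    pre_mirna: PreMirna
    tss: int | None = None
    tc: TagCluster | None = None
    distance: int | None = None
    evidence_tier: str = UNASSIGNED
    search_bound: int = 0
    alternatives: list[tuple[TagCluster, int]] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.evidence_tier != UNASSIGNED


def _upstream_distance(pm: PreMirna, pos: int) -> int:
    """Signed nt from the hairpin 5' end to ``pos``; positive means upstream."""
    return pm.five_prime - pos if pm.strand != "-" else pos - pm.five_prime


def candidate_tcs(pre_mirna: PreMirna, tcs: Sequence[TagCluster],
                  genes: Sequence[TranscriptModel], params: SearchParams,
                  used_tc_ids: frozenset[str] | set[str] = frozenset(),
                  ) -> tuple[list[Candidate], int]:
    """Candidate promoter TCs upstream of an intergenic hairpin, nearest first,
    plus the search bound actually applied.

    The bound defaults to ``max_upstream``; a coding gene (either strand)
    overlapping that window moves the bound to its strand-aware 3' end.
    """
    anchor = pre_mirna.five_prime
    bound = params.max_upstream
    # encountered coding genes truncate (or extend) the region at their 3' ends
    best_gene_dist: int | None = None
    for g in genes:
        if not g.coding or g.chrom != pre_mirna.hairpin.chrom:
            continue
        gd_lo = _upstream_distance(pre_mirna, g.end - 1)
        gd_hi = _upstream_distance(pre_mirna, g.start)
        lo, hi = min(gd_lo, gd_hi), max(gd_lo, gd_hi)
        if hi < 1 or lo > params.max_upstream:  # gene body outside the window
            continue
        d3 = _upstream_distance(pre_mirna, g.three_prime_end)
        if d3 < 1:
            continue
        if best_gene_dist is None or d3 < best_gene_dist:
            best_gene_dist = d3
    if best_gene_dist is not None:
        bound = best_gene_dist

    cands = []
    for tc in tcs:
        if (tc.chrom != pre_mirna.hairpin.chrom
                or tc.strand != pre_mirna.strand
                or tc.initiator_class == PROCESSING
                or tc.tc_id in used_tc_ids
                or tc.total_tpm < params.min_tc_tpm):
            continue
        d = _upstream_distance(pre_mirna, representative_ctss(tc))
        if 1 <= d <= bound:
            cands.append(Candidate(tc, d))
    cands.sort(key=lambda c: c.distance)
    return cands, bound


def _is_concordant(cand: Candidate, pre_mirna: PreMirna,
                   transcripts: Sequence[TranscriptModel],
                   params: SearchParams) -> bool:
    rep = representative_ctss(cand.tc)
    for t in transcripts:
        if t.chrom != pre_mirna.hairpin.chrom or t.strand != pre_mirna.strand:
            continue
        if abs(rep - t.five_prime_end) > params.concordance_tol:
            continue
        if t.span.overlaps(pre_mirna.hairpin):  # full-length: reaches the hairpin
            return True
    return False


def _has_h3k4me3(cand: Candidate, peaks: Sequence[Peak],
                 params: SearchParams) -> bool:
    rep = representative_ctss(cand.tc)
    chrom = cand.tc.chrom
    lo, hi = rep - params.h3k4me3_flank, rep + params.h3k4me3_flank + 1
    return any(p.interval.chrom == chrom and p.interval.start < hi
               and p.interval.end > lo for p in peaks)


def _tier_cascade(pre_mirna: PreMirna, cands: Sequence[Candidate], bound: int,
                  transcripts: Sequence[TranscriptModel], peaks: Sequence[Peak],
                  params: SearchParams) -> tuple[Candidate, str] | None:
    """Iterative 5-kb stepping: stop at the first window with a tier (a)-(c)
    winner; otherwise fall back to highest expression within the whole bound."""
    if not cands:
        return None
    n_windows = max(1, -(-bound // params.step))
    prev_n = -1
    for k in range(1, n_windows + 1):
        limit = min(k * params.step, bound)
        window = [c for c in cands if c.distance <= limit]
        if not window or len(window) == prev_n:
            continue
        prev_n = len(window)
        if len(window) == 1:
            return window[0], TIER_SINGLE_TC
        concordant = [c for c in window
                      if _is_concordant(c, pre_mirna, transcripts, params)]
        if concordant:
            return concordant[0], TIER_RNA_CONCORDANT  # nearest-first order
        marked = [c for c in window if _has_h3k4me3(c, peaks, params)]
        if marked:
            return max(marked, key=lambda c: c.tpm), TIER_H3K4ME3
    return max(cands, key=lambda c: c.tpm), TIER_EXPRESSION


def assign_intergenic(pre_mirna: PreMirna, candidates: Sequence[Candidate],
                      bound: int, transcripts: Sequence[TranscriptModel],
                      h3k4me3_peaks: Sequence[Peak],
                      params: SearchParams) -> PromoterAssignment:
    """Tiered promoter choice for an intergenic pre-miRNA (see module docstring).

    With no candidate within the bound the entry is left unassigned.
    """
    pick = _tier_cascade(pre_mirna, candidates, bound, transcripts,
                         h3k4me3_peaks, params)
    if pick is None:
        return PromoterAssignment(pre_mirna, search_bound=bound)
    cand, tier = pick
    return PromoterAssignment(
        pre_mirna, tss=representative_ctss(cand.tc), tc=cand.tc,
        distance=cand.distance, evidence_tier=tier, search_bound=bound,
    )


def assign_intragenic(pre_mirna: PreMirna, tcs: Sequence[TagCluster],
                      transcripts: Sequence[TranscriptModel],
                      h3k4me3_peaks: Sequence[Peak], params: SearchParams,
                      used_tc_ids: frozenset[str] | set[str] = frozenset(),
                      ) -> PromoterAssignment:
    """Promoter choice for an intragenic pre-miRNA.

    Non-coding host: the host transcript is the pri-miRNA, so its 5' end is the
    promoter. Coding host: search hairpin -> host 5' end for independent
    (typically intronic) transcription with the intergenic tier logic; failing
    that, a hairpin < ``host_proximal`` from the host 5' end is assigned the host
    promoter, else left unassigned.
    """
    host = pre_mirna.host
    if host is None:
        raise ValueError(f"{pre_mirna.name}: intragenic entry without host reference")
    host_tss = host.five_prime_end
    host_dist = abs(pre_mirna.five_prime - host_tss)
    if pre_mirna.context == INTRAGENIC_NONCODING:
        return PromoterAssignment(
            pre_mirna, tss=host_tss, distance=host_dist,
            evidence_tier=TIER_NONCODING_HOST, search_bound=host_dist,
        )
    bound = _upstream_distance(pre_mirna, host_tss)
    bound = max(bound, 0)
    cands = []
    for tc in tcs:
        if (tc.chrom != pre_mirna.hairpin.chrom
                or tc.strand != pre_mirna.strand
                or tc.initiator_class == PROCESSING
                or tc.tc_id in used_tc_ids
                or tc.total_tpm < params.min_tc_tpm):
            continue
        d = _upstream_distance(pre_mirna, representative_ctss(tc))
        # strictly inside the region: a TC at the host 5' end itself is the host
        # promoter, not independent transcription
        if 1 <= d < bound:
            cands.append(Candidate(tc, d))
    cands.sort(key=lambda c: c.distance)
    pick = _tier_cascade(pre_mirna, cands, bound, transcripts, h3k4me3_peaks,
                         params) if cands else None
    if pick is not None:
        cand, tier = pick
        return PromoterAssignment(
            pre_mirna, tss=representative_ctss(cand.tc), tc=cand.tc,
            distance=cand.distance, evidence_tier=tier, search_bound=bound,
        )
    if host_dist < params.host_proximal:
        return PromoterAssignment(
            pre_mirna, tss=host_tss, distance=host_dist,
            evidence_tier=TIER_HOST_PROMOTER, search_bound=bound,
        )
    return PromoterAssignment(pre_mirna, search_bound=bound)


def find_alternative_promoters(assignment: PromoterAssignment,
                               tcs: Sequence[TagCluster],
                               params: SearchParams) -> list[tuple[TagCluster, int]]:
    """Intronic TCs strictly between the assigned TSS and the hairpin 5' end,
    more than ``alt_min_offset`` nt from the assigned TSS. Recorded only; the
    main assignment never changes."""
    if not assignment.assigned or assignment.tss is None:
        return []
    pm = assignment.pre_mirna
    alts = []
    for tc in tcs:
        if (tc.chrom != pm.hairpin.chrom or tc.strand != pm.strand
                or tc.initiator_class == PROCESSING):
            continue
        if assignment.tc is not None and tc.tc_id == assignment.tc.tc_id:
            continue
        rep = representative_ctss(tc)
        d = _upstream_distance(pm, rep)
        if not (1 <= d < (assignment.distance or 0)):
            continue
        if abs(rep - assignment.tss) > params.alt_min_offset:
            alts.append((tc, d))
    alts.sort(key=lambda t: t[1])
    return alts


def annotate_promoters(catalog: Sequence[PreMirna], tcs: Sequence[TagCluster],
                       transcripts: Sequence[TranscriptModel],
                       genes: Sequence[TranscriptModel],
                       h3k4me3_peaks: Sequence[Peak],
                       params: SearchParams | None = None,
                       ) -> list[PromoterAssignment]:
    """Run the full promoter search over a catalog.

    Collapsed clusters are processed as units anchored at the 5'-most member; a
    TC assigned to one gene is excluded from later candidacies (one promoter,
    one gene), except that cluster members share theirs. Output order follows the
    catalog; results are deterministic for identical inputs.
    """
    if params is None:
        params = SearchParams()
    groups: dict[str, list[PreMirna]] = {}
    for pm in catalog:
        groups.setdefault(pm.cluster_id or f"__single_{pm.name}", []).append(pm)

    def group_key(members: list[PreMirna]):
        h = members[0].hairpin
        return (h.chrom, min(m.hairpin.start for m in members))

    used: set[str] = set()
    results: dict[str, PromoterAssignment] = {}
    for members in sorted(groups.values(), key=group_key):
        anchor_pm = (min(members, key=lambda m: m.hairpin.start)
                     if members[0].strand != "-"
                     else max(members, key=lambda m: m.hairpin.end))
        if anchor_pm.is_intragenic and anchor_pm.host is not None:
            assignment = assign_intragenic(anchor_pm, tcs, transcripts,
                                           h3k4me3_peaks, params, used)
        else:
            cands, bound = candidate_tcs(anchor_pm, tcs, genes, params, used)
            assignment = assign_intergenic(anchor_pm, cands, bound, transcripts,
                                           h3k4me3_peaks, params)
        if assignment.tc is not None:
            used.add(assignment.tc.tc_id)
        assignment.alternatives = find_alternative_promoters(assignment, tcs, params)
        if assignment.assigned and assignment.tss is not None:
            expr = sum_expression_window(tcs, anchor_pm.hairpin.chrom,
                                         anchor_pm.strand, assignment.tss,
                                         params.expression_flank)
            assignment.expression = {k: float(v) for k, v in expr.items()}
        for pm in members:
            shared = PromoterAssignment(
                pre_mirna=pm, tss=assignment.tss, tc=assignment.tc,
                distance=(abs(pm.five_prime - assignment.tss)
                          if assignment.tss is not None else None),
                evidence_tier=assignment.evidence_tier,
                search_bound=assignment.search_bound,
                alternatives=assignment.alternatives,
                expression=assignment.expression,
            )
            results[pm.name] = shared
    return [results[pm.name] for pm in catalog]


def gene_level_stats(n_premirnas: int, cluster_sizes: Sequence[int],
                     n_assigned_genes: int) -> dict[str, float]:
    """Gene-level bookkeeping: collapse each multi-copy cluster to one gene and
    express the assigned fraction as a percentage of genes."""
    n_genes = n_premirnas - sum(s - 1 for s in cluster_sizes)
    if n_genes <= 0:
        raise ValueError("cluster sizes exceed the pre-miRNA total")
    pct = 100.0 * n_assigned_genes / n_genes
    return {"n_genes": n_genes, "n_assigned_genes": n_assigned_genes,
            "percent_assigned": pct}


def assignment_summary(assignments: Sequence[PromoterAssignment]) -> dict:
    """Bookkeeping over a finished assignment set: per context x tier counts,
    gene-level assigned percentage (clusters collapsed), evidence support counts
    and the TSS-to-hairpin distance distribution."""
    by_tier: dict[str, dict[str, int]] = {}
    distances = []
    genes: dict[str, bool] = {}
    for a in assignments:
        pm = a.pre_mirna
        by_tier.setdefault(pm.context, {}).setdefault(a.evidence_tier, 0)
        by_tier[pm.context][a.evidence_tier] += 1
        gid = pm.cluster_id or pm.name
        genes[gid] = genes.get(gid, False) or a.assigned
        if a.assigned and a.distance is not None:
            distances.append(a.distance)
    n_genes = len(genes)
    n_assigned_genes = sum(genes.values())
    n_assigned = sum(1 for a in assignments if a.assigned)
    return {
        "n_premirnas": len(assignments),
        "n_assigned": n_assigned,
        "counts": by_tier,
        "n_genes": n_genes,
        "n_assigned_genes": n_assigned_genes,
        "percent_assigned_genes": (100.0 * n_assigned_genes / n_genes
                                   if n_genes else float("nan")),
        "n_rna_concordant": sum(
            1 for a in assignments if a.evidence_tier == TIER_RNA_CONCORDANT),
        "n_h3k4me3": sum(
            1 for a in assignments if a.evidence_tier == TIER_H3K4ME3),
        "distances": sorted(distances),
    }
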