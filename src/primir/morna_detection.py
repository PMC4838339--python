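"""Drosha-processing signatures: moRNA detection from CAGE and small-RNA data.

Drosha's 3'-side cut of the pri-miRNA leaves a capped downstream fragment whose
5' end sits one base past the mature 3p miRNA; CAGE picks this up as a CTSS at
exactly that nucleotide. A CAGE moRNA call therefore requires a same-strand CTSS
at the precise 3p Drosha site in at least two developmental stages (same
nucleotide each time). Small-RNA moRNA calls instead count reads whose ends abut
the mature arms: a 5p moRNA ends immediately 5' of the mature 5p arm, a 3p moRNA
starts at the 3p Drosha site. The module also runs the predictive screen over
computationally predicted hairpins, flagging high-confidence Drosha processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .premirna_catalog import PreMirna

ARM_5P = "5p"
ARM_3P = "3p"
METHOD_CAGE = "CAGE"
METHOD_SMALLRNA = "smallRNA"


@dataclass(frozen=True)
class MornaCall:
    """Evidence for a moRNA / Drosha-processing event on one arm."""

    name: str  # pre-miRNA name
    arm: str
    method: str
    site: int
    chrom: str
    strand: str
    stage_support: frozenset[str] = frozenset()
    read_count: int = 0
    threshold: float = 0.0
    high_confidence: bool = False


def drosha_site(pre_mirna: PreMirna, arm: str) -> int:
    """Genomic coordinate of the Drosha-generated fragment boundary for an arm.

    3p: the first nucleotide 3' of the mature 3p arm (strand-aware) — the 5' end
    of the downstream capped fragment. 5p: the nucleotide immediately 5' of the
    mature 5p arm — the last base of the upstream (5p moRNA) fragment.
    """
    if arm == ARM_3P:
        m = pre_mirna.mature_3p
        if m is None:
            raise ValueError(f"{pre_mirna.name}: no mature 3p arm annotated")
        return m.end if pre_mirna.strand != "-" else m.start - 1
    if arm == ARM_5P:
        m = pre_mirna.mature_5p
        if m is None:
            raise ValueError(f"{pre_mirna.name}: no mature 5p arm annotated")
        return m.start - 1 if pre_mirna.strand != "-" else m.end
    raise ValueError(f"unknown arm {arm!r}")


def detect_cage_morna(ctss: pd.DataFrame, catalog: Sequence[PreMirna],
                      min_stages: int = 2,
                      stage_classes: Mapping[str, str] | None = None,
                      ) -> list[MornaCall]:
    """CAGE-based Drosha-site calls at the exact 3p site, >= min_stages stages.

    ``ctss`` is the pooled multi-stage CTSS DataFrame (io_formats columns).
    ``stage_classes`` optionally maps stage -> 'maternal'/'zygotic'; supporting
    stage labels are always recorded on the call for that analysis.
    """
    if ctss.empty:
        return []
    idx = ctss.groupby(["chrom", "pos", "strand"])
    by_site = {key: set(grp.loc[grp["count"] > 0, "stage"])
               for key, grp in idx}
    tpm_by_site = ctss.groupby(["chrom", "pos", "strand"])["tpm"].sum()
    calls = []
    for pm in catalog:
        if pm.mature_3p is None:
            continue
        site = drosha_site(pm, ARM_3P)
        key = (pm.hairpin.chrom, site, pm.strand)
        stages = by_site.get(key, set())
        if len(stages) >= min_stages:
            calls.append(MornaCall(
                name=pm.name, arm=ARM_3P, method=METHOD_CAGE, site=site,
                chrom=pm.hairpin.chrom, strand=pm.strand,
                stage_support=frozenset(stages), threshold=min_stages,
                read_count=int(ctss.loc[
                    (ctss["chrom"] == pm.hairpin.chrom)
                    & (ctss["pos"] == site)
                    & (ctss["strand"] == pm.strand), "count"].sum()),
                high_confidence=bool(
                    len(stages) >= 3
                    and float(tpm_by_site.get(key, 0.0)) >= 1.0),
            ))
    return calls


def detect_smallrna_morna(small_rna: pd.DataFrame, catalog: Sequence[PreMirna],
                          min_reads: int = 1, end_tolerance: int = 1,
                          min_len: int = 18, max_len: int = 30,
                          hairpin_flank: int = 30) -> list[MornaCall]:
    """Small-RNA moRNA calls per arm at a read-count threshold.

    Qualifying reads are same-strand, ``min_len``-``max_len`` nt, fully inside
    hairpin +- ``hairpin_flank``. A 5p call needs reads whose 3' end lies within
    ``end_tolerance`` nt of the base immediately 5' of the mature 5p arm; a 3p
    call needs reads whose 5' end lies within ``end_tolerance`` nt of the 3p
    Drosha site. Read counts at qualifying positions are summed and compared to
    ``min_reads``.
    """
    calls = []
    if small_rna.empty:
        return calls
    lengths = small_rna["end"] - small_rna["start"]
    reads = small_rna[(lengths >= min_len) & (lengths <= max_len)]
    for pm in catalog:
        h = pm.hairpin
        sub = reads[(reads["chrom"] == h.chrom) & (reads["strand"] == h.strand)
                    & (reads["start"] >= h.start - hairpin_flank)
                    & (reads["end"] <= h.end + hairpin_flank)]
        if sub.empty:
            continue
        if h.strand != "-":
            read5, read3 = sub["start"], sub["end"] - 1
        else:
            read5, read3 = sub["end"] - 1, sub["start"]
        for arm, mature in ((ARM_5P, pm.mature_5p), (ARM_3P, pm.mature_3p)):
            if mature is None:
                continue
            site = drosha_site(pm, arm)
            if arm == ARM_5P:
                hit = (read3 - site).abs() <= end_tolerance
            else:
                hit = (read5 - site).abs() <= end_tolerance
            n = int(sub.loc[hit, "count"].sum())
            if n >= min_reads:
                calls.append(MornaCall(
                    name=pm.name, arm=arm, method=METHOD_SMALLRNA, site=site,
                    chrom=h.chrom, strand=h.strand, read_count=n,
                    threshold=min_reads,
                ))
    return calls


def morna_summary(calls: Sequence[MornaCall]) -> dict[str, int]:
    """Per-arm, both-arm and union pre-miRNA counts for one call set."""
    set5 = {c.name for c in calls if c.arm == ARM_5P}
    set3 = {c.name for c in calls if c.arm == ARM_3P}
    return {
        "n_5p": len(set5),
        "n_3p": len(set3),
        "n_both": len(set5 & set3),
        "n_union": len(set5 | set3),
    }


def compare_methods(cage_calls: Sequence[MornaCall],
                    srna_calls: Sequence[MornaCall]) -> dict[str, object]:
    """Cross-method agreement: a match is the same pre-miRNA and the same arm."""
    cage = {(c.name, c.arm) for c in cage_calls}
    srna = {(c.name, c.arm) for c in srna_calls}
    both = cage & srna
    return {
        "n_cage": len(cage),
        "n_smallrna": len(srna),
        "n_both": len(both),
        "both": sorted(both),
        "cage_only": sorted(cage - srna),
        "smallrna_only": sorted(srna - cage),
    }


def screen_predicted_hairpins(predicted: Sequence[PreMirna],
                              ctss: pd.DataFrame, min_stages: int = 2,
                              ) -> list[MornaCall]:
    """Drosha-site CAGE screen over computationally predicted hairpins.

    Hairpins without annotated 3p arms use the hairpin 3' end as the site proxy.
    Calls carry a high-confidence flag (>= 3 supporting stages and pooled tpm at
    the site >= 1).
    """
    proxied = []
    for pm in predicted:
        if pm.mature_3p is None:
            h = pm.hairpin
            if h.strand != "-":
                arm = type(h)(h.chrom, h.end - 2, h.end, h.strand, pm.name + "-3p")
            else:
                arm = type(h)(h.chrom, h.start, h.start + 2, h.strand,
                              pm.name + "-3p")
            pm = PreMirna(pm.name, pm.hairpin, mature_3p=arm,
                          context=pm.context, cluster_id=pm.cluster_id)
        proxied.append(pm)
    return detect_cage_morna(ctss, proxied, min_stages=min_stages)


def calls_table(calls: Sequence[MornaCall]) -> pd.DataFrame:
    rows = [dict(
        name=c.name, arm=c.arm, method=c.method, chrom=c.chrom, site=c.site,
        strand=c.strand, stage_support=",".join(sorted(c.stage_support)),
        read_count=c.read_count, threshold=c.threshold,
        high_confidence=c.high_confidence,
    ) for c in calls]
    return pd.DataFrame(rows, columns=[
        "name", "arm", "method", "chrom", "site", "strand", "stage_support",
        "read_count", "threshold", "high_confidence"])
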