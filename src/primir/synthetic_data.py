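"""Seeded synthetic-data generator: a complete CAGE/RNA-seq/ChIP/small-RNA input
bundle with a truth manifest.

The generator emulates the statistical structure of a multi-stage embryogenesis
CAGE experiment around miRNA loci: planted pri-miRNA promoters with sharp
(point-mass) or broad (uniform 30-80 nt, 5'-dominant) tag-count shapes and
canonical initiator dinucleotides; post-transcriptional Drosha-site CTSSs with a
G/G initiator context, reproducible at the same nucleotide across zygotic
stages; promoter-associated H3K4me3/H2A.Z/RNAPII peaks (plus a subset at
hairpins); maternal vs zygotic expression profiles; per-arm small-RNA read
counts at mature-miRNA and moRNA windows; CpG islands; decoy upstream coding
genes (search-boundary tests) and decoy G/G tag clusters (initiator-exclusion
tests). High-count "filler" promoters away from miRNA loci give each stage a
realistic library size so that stray background tags stay below candidate tpm
thresholds, as in a real CAGE library where miRNA promoters are a small
fraction of the tag mass.

:func:`generate_bundle` samples a bundle from seeded randomness;
:func:`fixture_from_counts` places elements deterministically to hit exact set
sizes (no sampling), for bookkeeping-style checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctss_clustering import TagCluster, annotate_clusters, cluster_ctss
from .io_formats import (
    CoverageTrack, Genome, GenomicInterval, Peak, TranscriptModel,
    normalize_tpm, read_bed, read_bed12, read_bedgraph, read_ctss, read_peaks,
    read_small_rna, write_bed, write_bed12, write_bedgraph, write_ctss,
    write_fasta,
)
from .morna_detection import ARM_3P, ARM_5P, drosha_site
from .premirna_catalog import (
    INTERGENIC, INTRAGENIC_CODING, INTRAGENIC_NONCODING, ExpressionSummary,
    PreMirna,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneratorParams:
    """Study conditions of the synthetic bundle.

    Defaults follow the emulated experiment: 12 developmental stages of which
    the first 4 are maternal, promoter distances log-uniform over 0.2-40 kb,
    broad promoters spread over 30-80 nt, background CTSS noise of 1 tag per
    10 kb per stage, a 10-Mb genome over 2 chromosomes.
    """

    n_premirnas: int = 60
    n_unexpressed: int = 4
    frac_intragenic: float = 0.25
    frac_noncoding_host: float = 0.5      # of the intragenic entries
    frac_host_proximal: float = 0.45      # coding-host entries with no own promoter
    n_stages: int = 12
    n_maternal_stages: int = 4
    frac_maternal: float = 0.10
    promoter_dist_range: tuple[int, int] = (200, 40_000)
    frac_sharp: float = 0.4
    broad_width_range: tuple[int, int] = (30, 80)
    frac_transcript_support: float = 0.5
    frac_h3k4me3_only: float = 0.3        # peak support without a transcript
    frac_premirna_peak: float = 0.4
    frac_cgi: float = 0.5
    frac_decoy_gene: float = 0.2
    frac_gg_decoy: float = 0.3
    morna_cage_frac: float = 0.3
    morna_5p_frac: float = 0.25
    morna_3p_frac: float = 0.20
    promoter_mean_tags: float = 50.0
    drosha_mean_tags: float = 5.0
    morna_mean_reads: float = 4.0
    mature_mean_reads: float = 25.0
    background_rate: float = 1e-4         # tags / base / stage
    n_filler: int = 40
    filler_mean_tags: float = 200_000.0
    genome_size: int = 10_000_000
    n_chroms: int = 2
    gc_background: float = 0.40
    hairpin_len: int = 80
    mature_len: int = 22
    cluster_copies: int = 0
    cluster_spacing: int = 300
    n_predicted: int = 0
    predicted_with_cage: int = 0


@dataclass
class Bundle:
    """In-memory synthetic input bundle plus its truth manifest."""

    seed: int
    stages: list[str]
    maternal_stages: list[str]
    genome: Genome | None = None
    ctss: pd.DataFrame = field(default_factory=pd.DataFrame)
    catalog: list[PreMirna] = field(default_factory=list)
    expression: dict[str, ExpressionSummary] = field(default_factory=dict)
    genes: list[TranscriptModel] = field(default_factory=list)
    transcripts: list[TranscriptModel] = field(default_factory=list)
    h3k4me3: list[Peak] = field(default_factory=list)
    h2az: list[Peak] = field(default_factory=list)
    rnapii: list[Peak] = field(default_factory=list)
    coverage: dict[str, CoverageTrack] = field(default_factory=dict)
    small_rna: pd.DataFrame = field(default_factory=pd.DataFrame)
    cgis: list[GenomicInterval] = field(default_factory=list)
    predicted: list[PreMirna] = field(default_factory=list)
    tcs: list[TagCluster] = field(default_factory=list)  # pre-built TCs (fixtures)
    manifest: dict = field(default_factory=dict)


def _stage_labels(n: int) -> list[str]:
    return [f"st{i:02d}" for i in range(1, n + 1)]


def _mk_premirna(name: str, chrom: str, start: int, strand: str,
                 hairpin_len: int, mature_len: int) -> PreMirna:
    hp = GenomicInterval(chrom, start, start + hairpin_len, strand, name)
    if strand != "-":
        m5 = GenomicInterval(chrom, start, start + mature_len, strand, name + "-5p")
        m3 = GenomicInterval(chrom, start + hairpin_len - mature_len,
                             start + hairpin_len, strand, name + "-3p")
    else:
        m5 = GenomicInterval(chrom, start + hairpin_len - mature_len,
                             start + hairpin_len, strand, name + "-5p")
        m3 = GenomicInterval(chrom, start, start + mature_len, strand, name + "-3p")
    return PreMirna(name, hp, mature_5p=m5, mature_3p=m3)


def _upstream_pos(pm: PreMirna, distance: int) -> int:
    return (pm.five_prime - distance) if pm.strand != "-" else (
        pm.five_prime + distance)


class _TagAccumulator:
    """Collects (chrom, pos, strand, stage) -> count while generating."""

    def __init__(self) -> None:
        self._counts: dict[tuple[str, int, str, str], int] = {}

    def add(self, chrom: str, pos: int, strand: str, stage: str, count: int) -> None:
        if count <= 0:
            return
        key = (chrom, pos, strand, stage)
        self._counts[key] = self._counts.get(key, 0) + int(count)

    def frame(self) -> pd.DataFrame:
        rows = [(c, p, s, st, n) for (c, p, s, st), n in
                sorted(self._counts.items())]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "stage",
                                           "count"])


def _plant_initiator(seqs: dict[str, bytearray], chrom: str, tss: int,
                     strand: str, minus1: str, plus1: str) -> None:
    """Write the -1/+1 bases at a TSS in genome (plus-strand) space."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seq = seqs[chrom]
    if strand != "-":
        if tss - 1 >= 0:
            seq[tss - 1] = ord(minus1)
        seq[tss] = ord(plus1)
    else:
        seq[tss] = ord(comp[plus1])
        if tss + 1 < len(seq):
            seq[tss + 1] = ord(comp[minus1])


def generate_bundle(params: GeneratorParams | None = None, seed: int = 0,
                    out_dir: str | Path | None = None) -> Bundle:
    """Sample a complete input bundle under ``params``; deterministic per seed.

    With ``out_dir`` the bundle is also written to disk in the standard text
    formats (see :func:`write_bundle`).
    """
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(seed)
    stages = _stage_labels(params.n_stages)
    maternal_stages = stages[: params.n_maternal_stages]
    zygotic_stages = stages[params.n_maternal_stages:]
    if len(zygotic_stages) < 3:
        raise ValueError("need at least 3 zygotic stages")

    # ------------------------------------------------------------- genome
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chroms)]
    base_len = params.genome_size // params.n_chroms
    p_gc = params.gc_background
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    seqs = {c: bytearray(rng.choice(BASES, size=base_len, p=probs).tobytes())
            for c in chrom_names}

    # ------------------------------------------------------------- layout
    n_loci = params.n_premirnas + (1 if params.cluster_copies > 0 else 0)
    per_chrom = -(-n_loci // params.n_chroms)
    mirna_zone = int(base_len * 0.8)
    slot = mirna_zone // max(per_chrom, 1)
    need = 2 * (params.promoter_dist_range[1] + 20_000)
    if slot < need:
        raise ValueError(
            f"genome too small: slot {slot} nt < {need} nt required for the "
            "promoter-distance range; enlarge genome_size or reduce n_premirnas")

    tags = _TagAccumulator()
    catalog: list[PreMirna] = []
    genes: list[TranscriptModel] = []
    transcripts: list[TranscriptModel] = []
    h3k4me3: list[Peak] = []
    h2az: list[Peak] = []
    rnapii: list[Peak] = []
    cgis: list[GenomicInterval] = []
    srna_rows: list[tuple] = []
    planted_tags: dict[str, dict[str, int]] = {}
    truth_promoters: dict[str, dict] = {}
    truth_premirnas: dict[str, dict] = {}
    truth_morna: dict[str, dict] = {}

    def plant_promoter_tags(name: str | None, chrom: str, tss: int, strand: str,
                            shape: str, active: list[str]) -> None:
        """Plant promoter-shaped tag counts; ``name=None`` plants signal (e.g. a
        host-gene promoter) without attributing expression to any pre-miRNA."""
        width = (1 if shape == "sharp"
                 else int(rng.integers(*params.broad_width_range)))
        step = 1 if strand != "-" else -1
        positions = [tss + step * i for i in range(width)]
        per_stage = planted_tags.setdefault(name, {}) if name is not None else {}
        for st in active:
            if shape == "sharp":
                counts = [1 + rng.poisson(params.promoter_mean_tags - 1)]
            else:
                boost = 1 + rng.poisson(params.promoter_mean_tags / 2)
                tail_mean = params.promoter_mean_tags / (2 * (width - 1))
                counts = [boost] + list(rng.poisson(tail_mean, size=width - 1))
            for pos, cnt in zip(positions, counts):
                tags.add(chrom, pos, strand, st, int(cnt))
            per_stage[st] = per_stage.get(st, 0) + int(np.sum(counts))

    def read_interval(chrom: str, site: int, strand: str, arm: str,
                      length: int) -> tuple[int, int]:
        """Genomic interval of a moRNA read abutting an arm boundary."""
        if arm == ARM_5P:  # read 3' end at the site
            return ((site - length + 1, site + 1) if strand != "-"
                    else (site, site + length))
        # 3p: read 5' end at the site
        return ((site, site + length) if strand != "-"
                else (site - length + 1, site + 1))

    locus = 0
    for i in range(params.n_premirnas):
        chrom = chrom_names[locus % params.n_chroms]
        slot_idx = locus // params.n_chroms
        locus += 1
        center = slot_idx * slot + slot // 2
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"mir-{i + 1:03d}"
        pm = _mk_premirna(name, chrom, center, strand, params.hairpin_len,
                          params.mature_len)
        catalog.append(pm)
        expressed = i >= params.n_unexpressed
        context = INTERGENIC
        host_dist = None
        planted = None  # (tss, shape, support)
        u = rng.random()
        intragenic = expressed and u < params.frac_intragenic

        active = list(stages) if rng.random() < params.frac_maternal \
            else list(zygotic_stages)
        maternal = active[0] in maternal_stages

        if not expressed:
            planted_tags[name] = {}
        elif intragenic:
            noncoding = rng.random() < params.frac_noncoding_host
            host_dist = int(rng.integers(6_000, 20_000))
            host5 = _upstream_pos(pm, host_dist)
            span_lo = min(host5, pm.hairpin.start - 500)
            span_hi = max(host5 + 1, pm.hairpin.end + 500)
            host = TranscriptModel(f"host-{name}", chrom, span_lo, span_hi,
                                   strand, ((span_lo, span_hi),),
                                   coding=not noncoding)
            genes.append(host)
            if noncoding:
                context = INTRAGENIC_NONCODING
                planted = (host5, "sharp", "host")
                plant_promoter_tags(name, chrom, host5, strand, "sharp", active)
                _plant_initiator(seqs, chrom, host5, strand, "C", "A")
            else:
                context = INTRAGENIC_CODING
                if rng.random() < params.frac_host_proximal:
                    # re-site the host close to the hairpin: host promoter case
                    host_dist = int(rng.integers(1_000, 4_500))
                    host5 = _upstream_pos(pm, host_dist)
                    span_lo = min(host5, pm.hairpin.start - 500)
                    span_hi = max(host5 + 1, pm.hairpin.end + 500)
                    genes[-1] = TranscriptModel(f"host-{name}", chrom, span_lo,
                                                span_hi, strand,
                                                ((span_lo, span_hi),), True)
                    planted = (host5, "sharp", "host_proximal")
                    # the host promoter carries the expression of this hairpin
                    plant_promoter_tags(name, chrom, host5, strand, "sharp",
                                        active)
                    _plant_initiator(seqs, chrom, host5, strand, "C", "A")
                else:
                    d = int(rng.integers(800, min(3_000, host_dist - 500)))
                    tss = _upstream_pos(pm, d)
                    planted = (tss, "sharp", "h3k4me3")
                    plant_promoter_tags(name, chrom, tss, strand, "sharp", active)
                    _plant_initiator(seqs, chrom, tss, strand, "C", "A")
                    h3k4me3.append(Peak(GenomicInterval(
                        chrom, tss - 300, tss + 300, ".", f"pk-{name}"), 10.0))
                    # the host gene's own distal promoter is also active; it
                    # must not be mistaken for independent transcription
                    plant_promoter_tags(None, chrom, host5, strand, "sharp",
                                        active)
                    _plant_initiator(seqs, chrom, host5, strand, "C", "A")
        else:
            lo, hi = params.promoter_dist_range
            d = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            tss = _upstream_pos(pm, d)
            shape = "sharp" if rng.random() < params.frac_sharp else "broad"
            v = rng.random()
            if v < params.frac_transcript_support:
                support = "transcript"
            elif v < params.frac_transcript_support + params.frac_h3k4me3_only:
                support = "h3k4me3"
            else:
                support = "none"
            planted = (tss, shape, support)
            plant_promoter_tags(name, chrom, tss, strand, shape, active)
            _plant_initiator(seqs, chrom, tss, strand, "C", "A")
            if support == "transcript":
                if strand != "-":
                    span_lo, span_hi = tss, pm.hairpin.end + 200
                else:
                    span_lo, span_hi = pm.hairpin.start - 200, tss + 1
                transcripts.append(TranscriptModel(
                    f"tx-{name}", chrom, span_lo, span_hi, strand,
                    ((span_lo, span_hi),), True))
            if support in ("transcript", "h3k4me3") and rng.random() < 0.8:
                h3k4me3.append(Peak(GenomicInterval(
                    chrom, tss - 300, tss + 300, ".", f"pk-{name}"), 10.0))
            if rng.random() < params.frac_decoy_gene:
                g3 = _upstream_pos(pm, d + 2_000)
                g5 = _upstream_pos(pm, d + 12_000)
                glo, ghi = min(g3, g5), max(g3, g5) + 1
                genes.append(TranscriptModel(
                    f"decoy-{name}", chrom, glo, ghi, strand, ((glo, ghi),),
                    True))
            if rng.random() < params.frac_gg_decoy and d >= 1_000:
                dd = d // 2
                dpos = _upstream_pos(pm, dd)
                _plant_initiator(seqs, chrom, dpos, strand, "G", "G")
                for st in zygotic_stages:
                    tags.add(chrom, dpos, strand, st, int(1 + rng.poisson(40)))

        if planted is not None:
            truth_promoters[name] = dict(
                tss=int(planted[0]), shape=planted[1], support=planted[2],
                maternal=bool(maternal), strand=strand, chrom=chrom,
                distance=int(abs(pm.five_prime - planted[0])),
            )
        truth_premirnas[name] = dict(
            chrom=chrom, start=pm.hairpin.start, end=pm.hairpin.end,
            strand=strand, context=context, expressed=bool(expressed),
            cluster_id=None, host_distance=host_dist,
        )

        # chromatin at hairpins, CGIs, small RNA, Drosha CAGE
        if expressed:
            if rng.random() < params.frac_premirna_peak:
                h3k4me3.append(Peak(GenomicInterval(
                    chrom, pm.hairpin.start - 200, pm.hairpin.end + 200, ".",
                    f"pk-pre-{name}"), 6.0))
                truth_premirnas[name]["premirna_peak"] = True
            else:
                truth_premirnas[name]["premirna_peak"] = False
            if planted is not None and rng.random() < params.frac_cgi:
                ctr = planted[0]
                cgis.append(GenomicInterval(chrom, max(0, ctr - 150), ctr + 150,
                                            ".", f"cgi-{name}"))
                lo_c, hi_c = max(0, ctr - 150), ctr + 150
                island = rng.choice(
                    np.frombuffer(b"GC", dtype=np.uint8), size=hi_c - lo_c)
                seqs[chrom][lo_c:hi_c] = island.tobytes()
                _plant_initiator(seqs, chrom, planted[0], strand, "C", "A")

            # mature-arm small RNA reads
            for arm_iv in (pm.mature_5p, pm.mature_3p):
                srna_rows.append((chrom, arm_iv.start, arm_iv.end, strand,
                                  int(1 + rng.poisson(params.mature_mean_reads))))
            morna = dict(cage=False, reads_5p=0, reads_3p=0, stages=[])
            if rng.random() < params.morna_cage_frac:
                site = drosha_site(pm, ARM_3P)
                _plant_initiator(seqs, chrom, site, strand, "G", "G")
                k = int(rng.integers(2, len(zygotic_stages) + 1))
                support = list(rng.choice(zygotic_stages, size=k, replace=False))
                for st in support:
                    tags.add(chrom, site, strand, st,
                             int(1 + rng.poisson(params.drosha_mean_tags)))
                morna["cage"] = True
                morna["stages"] = sorted(support)
            if rng.random() < params.morna_5p_frac:
                site = drosha_site(pm, ARM_5P)
                n = int(1 + rng.poisson(params.morna_mean_reads))
                s, e = read_interval(chrom, site, strand, ARM_5P, 20)
                srna_rows.append((chrom, s, e, strand, n))
                morna["reads_5p"] = n
            if rng.random() < params.morna_3p_frac:
                site = drosha_site(pm, ARM_3P)
                n = int(1 + rng.poisson(params.morna_mean_reads))
                s, e = read_interval(chrom, site, strand, ARM_3P, 20)
                srna_rows.append((chrom, s, e, strand, n))
                morna["reads_3p"] = n
            truth_morna[name] = morna

    # optional multi-copy cluster sharing one promoter (polycistron)
    if params.cluster_copies > 0:
        chrom = chrom_names[locus % params.n_chroms]
        slot_idx = locus // params.n_chroms
        start0 = slot_idx * slot + slot // 2
        strand = "+"
        members = []
        for j in range(params.cluster_copies):
            name = f"mir-cl-{j + 1:03d}"
            s = start0 + j * (params.hairpin_len + params.cluster_spacing)
            pm = _mk_premirna(name, chrom, s, strand, params.hairpin_len,
                              params.mature_len)
            catalog.append(pm)
            members.append(pm)
            truth_premirnas[name] = dict(
                chrom=chrom, start=pm.hairpin.start, end=pm.hairpin.end,
                strand=strand, context=INTERGENIC, expressed=True,
                cluster_id="planted-cluster", host_distance=None,
                premirna_peak=False,
            )
        tss = start0 - 1_100
        plant_promoter_tags("planted-cluster", chrom, tss, strand, "sharp",
                            list(zygotic_stages))
        _plant_initiator(seqs, chrom, tss, strand, "C", "A")
        for pm in members:
            planted_tags[pm.name] = planted_tags["planted-cluster"]
            truth_promoters[pm.name] = dict(
                tss=tss, shape="sharp", support="none", maternal=False,
                strand=strand, chrom=chrom,
                distance=int(abs(pm.five_prime - tss)))
        del planted_tags["planted-cluster"]

    # predicted hairpins in a reserved zone, a few with Drosha-site CAGE
    predicted: list[PreMirna] = []
    if params.n_predicted > 0:
        zone0 = int(base_len * 0.9)
        for j in range(params.n_predicted):
            chrom = chrom_names[j % params.n_chroms]
            s = zone0 + (j // params.n_chroms) * 500
            name = f"pred-{j + 1:04d}"
            pm = _mk_premirna(name, chrom, s, "+", params.hairpin_len,
                              params.mature_len)
            predicted.append(pm)
            if j < params.predicted_with_cage:
                site = drosha_site(pm, ARM_3P)
                _plant_initiator(seqs, chrom, site, "+", "G", "G")
                n_sup = 3 if j == 0 else 2
                for st in zygotic_stages[:n_sup]:
                    tags.add(chrom, site, "+", st,
                             int(1 + rng.poisson(params.drosha_mean_tags)))

    # filler promoters: bulk of the library, away from miRNA loci
    filler_zone0 = int(base_len * 0.8)
    filler_span = int(base_len * 0.1)
    for j in range(params.n_filler):
        chrom = chrom_names[j % params.n_chroms]
        pos = filler_zone0 + (j // params.n_chroms + 1) * (
            filler_span // (params.n_filler // params.n_chroms + 2))
        for st in stages:
            tags.add(chrom, pos, "+", st, int(rng.poisson(params.filler_mean_tags)))

    # background noise: ~background_rate tags per base per stage
    for st in stages:
        for chrom in chrom_names:
            n_bg = rng.poisson(params.background_rate * base_len)
            pos = rng.integers(0, base_len, size=n_bg)
            strands = rng.choice(np.array(["+", "-"]), size=n_bg)
            for p, s in zip(pos, strands):
                tags.add(chrom, int(p), str(s), st, 1)

    ctss = normalize_tpm(tags.frame())

    # per-pre-miRNA expression summaries from planted tags and library totals
    totals = ctss.groupby("stage")["count"].sum().to_dict()
    expression = {}
    for pm in catalog:
        per_stage = planted_tags.get(pm.name, {})
        expression[pm.name] = ExpressionSummary(pm.name, {
            st: (per_stage.get(st, 0) / totals.get(st, 1)) * 1e6
            for st in stages})

    # H2A.Z / RNAPII peaks mirror H3K4me3 promoter peaks with narrower spans,
    # then each peak set becomes a flat coverage track
    for pk in h3k4me3:
        iv = pk.interval
        mid = (iv.start + iv.end) // 2
        h2az.append(Peak(GenomicInterval(iv.chrom, mid - 150, mid + 150, ".",
                                         iv.name + "-z"), pk.score * 0.6))
        rnapii.append(Peak(GenomicInterval(iv.chrom, mid - 100, mid + 100, ".",
                                           iv.name + "-p"), pk.score * 0.5))
    chrom_sizes = {c: base_len for c in chrom_names}
    coverage = {}
    for mark, peaks in (("h3k4me3", h3k4me3), ("h2az", h2az), ("rnapii", rnapii)):
        tr = CoverageTrack(chrom_sizes)
        for pk in peaks:
            tr.add_interval(pk.interval.chrom, pk.interval.start,
                            pk.interval.end, pk.score)
        coverage[mark] = tr

    small_rna = pd.DataFrame(
        sorted(srna_rows), columns=["chrom", "start", "end", "strand", "count"])

    catalog.sort(key=lambda p: (p.hairpin.chrom, p.hairpin.start))
    genome = Genome({c: bytes(b).decode() for c, b in seqs.items()})
    manifest = dict(
        seed=int(seed),
        params=json.loads(json.dumps(asdict(params))),  # JSON-safe (tuples->lists)
        stages=stages,
        maternal_stages=maternal_stages,
        promoters=truth_promoters,
        premirnas=truth_premirnas,
        morna=truth_morna,
        cgis=[[c.chrom, c.start, c.end, c.name] for c in cgis],
    )
    bundle = Bundle(
        seed=seed, stages=stages, maternal_stages=maternal_stages,
        genome=genome, ctss=ctss, catalog=catalog, expression=expression,
        genes=genes, transcripts=transcripts, h3k4me3=h3k4me3, h2az=h2az,
        rnapii=rnapii, coverage=coverage, small_rna=small_rna, cgis=cgis,
        predicted=predicted, manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Constructive fixtures (no sampling)
# ---------------------------------------------------------------------------

def fixture_from_counts(count_spec: Mapping[str, object]) -> Bundle:
    """Deterministic constructive bundle hitting exact set sizes.

    Recognized keys (all optional; an empty spec gives an empty bundle):

    ``expression``: ``{"total": N, "unexpressed": M}`` — catalog of N entries of
        which M have zero expression (the rest sit at 10 tpm).
    ``morna``: ``{"t1": {"n5p","n3p","nboth"}, "t2": {...}}`` — small-RNA read
        counts planted so the per-arm calls at read thresholds 1 and 2 have
        exactly the given sizes; optional ``"n_cage"``/``"n_overlap"`` plant
        CAGE Drosha-site tags on ``n_cage`` hairpins of which ``n_overlap``
        also carry small-RNA 3p moRNA reads.
    ``coding_host``: ``{"independent": I, "proximal": P}`` — I + P pre-miRNAs on
        coding hosts, I with a planted intronic promoter TC (H3K4me3-marked),
        P close (< 5 kb) to the host 5' end with no independent TC.
    ``predicted``: ``{"total": N, "with_cage": K, "high_confidence": H}`` —
        predicted hairpins, K with Drosha-site CTSSs in >= 2 stages, H of those
        with >= 3 supporting stages.

    Raises ValueError for infeasible specs (e.g. more both-arm than per-arm
    moRNAs).
    """
    stages = _stage_labels(12)
    bundle = Bundle(seed=0, stages=stages, maternal_stages=stages[:4])
    hp_len, m_len, spacing = 80, 22, 400
    tags = _TagAccumulator()
    srna_rows: list[tuple] = []

    spec_expr = count_spec.get("expression")
    if spec_expr:
        total, unexpr = int(spec_expr["total"]), int(spec_expr["unexpressed"])
        if unexpr > total:
            raise ValueError("unexpressed exceeds total")
        for i in range(total):
            pm = _mk_premirna(f"emir-{i + 1:04d}", "chrE", 1_000 + i * spacing,
                              "+", hp_len, m_len)
            bundle.catalog.append(pm)
            tpm = 0.0 if i < unexpr else 10.0
            bundle.expression[pm.name] = ExpressionSummary(
                pm.name, {st: tpm for st in stages})

    spec_morna = count_spec.get("morna")
    if spec_morna:
        t1 = spec_morna["t1"]
        n5, n3, nb = int(t1["n5p"]), int(t1["n3p"]), int(t1["nboth"])
        if nb > min(n5, n3):
            raise ValueError("both-arm count exceeds a per-arm count")
        total = n5 + n3 - nb
        a5 = set(range(n5))
        a3 = set(range(n5 - nb, total))
        counts5 = {i: 1 for i in a5}
        counts3 = {i: 1 for i in a3}
        t2 = spec_morna.get("t2")
        if t2:
            m5, m3, mb = int(t2["n5p"]), int(t2["n3p"]), int(t2["nboth"])
            if (m5 > n5 or m3 > n3 or mb > min(m5, m3) or mb > nb
                    or m5 - mb > n5 - nb or m3 - mb > n3 - nb):
                raise ValueError("threshold-2 spec incompatible with threshold-1")
            b_both = set(range(n5 - nb, n5 - nb + mb))
            b5 = b_both | set(range(m5 - mb))
            b3 = b_both | set(range(n5, n5 + (m3 - mb)))
            for i in b5:
                counts5[i] = 2
            for i in b3:
                counts3[i] = 2
        n_cage = int(spec_morna.get("n_cage", 0))
        n_overlap = int(spec_morna.get("n_overlap", 0))
        if n_overlap > n3 or n_overlap > n_cage:
            raise ValueError("CAGE overlap exceeds available 3p moRNA set")
        n_total = total + max(0, n_cage - n_overlap)
        cage_idx = sorted(a3)[:n_overlap] + list(range(total,
                                                       total + n_cage - n_overlap))
        mirs = []
        for i in range(n_total):
            pm = _mk_premirna(f"mmir-{i + 1:04d}", "chrM", 10_000 + i * spacing,
                              "+", hp_len, m_len)
            mirs.append(pm)
            bundle.catalog.append(pm)
            if i in counts5:
                site = drosha_site(pm, ARM_5P)
                srna_rows.append(("chrM", site - 19, site + 1, "+", counts5[i]))
            if i in counts3:
                site = drosha_site(pm, ARM_3P)
                srna_rows.append(("chrM", site, site + 20, "+", counts3[i]))
        for i in cage_idx:
            site = drosha_site(mirs[i], ARM_3P)
            for st in stages[4:6]:
                tags.add("chrM", site, "+", st, 5)

    spec_host = count_spec.get("coding_host")
    tcs: list[TagCluster] = []
    if spec_host:
        n_ind, n_prox = int(spec_host["independent"]), int(spec_host["proximal"])
        slot_h = 50_000
        for i in range(n_ind + n_prox):
            start = 100_000 + i * slot_h
            pm = _mk_premirna(f"hmir-{i + 1:03d}", "chrH", start + 20_000, "+",
                              hp_len, m_len)
            independent = i < n_ind
            host5 = start if independent else pm.hairpin.start - 3_000
            host = TranscriptModel(f"host-{pm.name}", "chrH", host5,
                                   pm.hairpin.end + 1_000, "+",
                                   ((host5, pm.hairpin.end + 1_000),), True)
            pm.context = INTRAGENIC_CODING
            pm.host = host
            pm.host_same_strand = True
            bundle.genes.append(host)
            bundle.catalog.append(pm)
            bundle.expression[pm.name] = ExpressionSummary(
                pm.name, {st: 10.0 for st in stages})
            if independent:
                tss = pm.hairpin.start - 1_100
                tc = TagCluster("chrH", "+", np.array([tss]),
                                np.full((1, len(stages)), 2.0),
                                tuple(stages), shape_class="sharp",
                                initiator_class="canonical",
                                tc_id=f"TCH{i:04d}")
                tcs.append(tc)
                bundle.h3k4me3.append(Peak(GenomicInterval(
                    "chrH", tss - 200, tss + 200, ".", f"pk-{pm.name}"), 8.0))

    spec_pred = count_spec.get("predicted")
    if spec_pred:
        total = int(spec_pred["total"])
        with_cage = int(spec_pred["with_cage"])
        high_conf = int(spec_pred.get("high_confidence", 0))
        if not 0 <= high_conf <= with_cage <= total:
            raise ValueError("need high_confidence <= with_cage <= total")
        for i in range(total):
            pm = _mk_premirna(f"pred-{i + 1:04d}", "chrP", 5_000 + i * spacing,
                              "+", hp_len, m_len)
            bundle.predicted.append(pm)
            if i < with_cage:
                site = drosha_site(pm, ARM_3P)
                n_sup = 3 if i < high_conf else 2
                for st in stages[4:4 + n_sup]:
                    tags.add("chrP", site, "+", st, 5)

    frame = tags.frame()
    bundle.ctss = normalize_tpm(frame) if not frame.empty else frame
    bundle.small_rna = pd.DataFrame(
        sorted(srna_rows), columns=["chrom", "start", "end", "strand", "count"])
    bundle.manifest = dict(seed=0, count_spec=dict(count_spec))
    if tcs:
        bundle.manifest["n_planted_tcs"] = len(tcs)
    bundle.tcs = tcs  # constructed tag clusters for coding-host fixtures
    return bundle


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, out_dir: str | Path) -> None:
    """Write the bundle in the standard text formats plus the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.genome is not None:
        write_fasta(bundle.genome, out / "genome.fa")
    for st in bundle.stages:
        sub = bundle.ctss[bundle.ctss["stage"] == st]
        write_ctss(sub, out / f"ctss_{st}.txt")
    write_bed([pm.hairpin for pm in bundle.catalog], out / "hairpins.bed")
    matures = [iv for pm in bundle.catalog
               for iv in (pm.mature_5p, pm.mature_3p) if iv is not None]
    write_bed(matures, out / "matures.bed")
    write_bed12(bundle.genes, out / "genes.bed12", coding_column=True)
    write_bed12(bundle.transcripts, out / "transcripts.bed12")
    for mark, peaks in (("h3k4me3", bundle.h3k4me3), ("h2az", bundle.h2az),
                        ("rnapii", bundle.rnapii)):
        write_bed([p.interval for p in peaks], out / f"{mark}_peaks.bed",
                  scores=[p.score for p in peaks])
    for mark, track in bundle.coverage.items():
        write_bedgraph(track, out / f"{mark}.bedgraph")
    with open(out / "small_rna.bed", "w") as fh:
        for row in bundle.small_rna.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tread\t"
                     f"{row.count}\t{row.strand}\n")
    write_bed(bundle.cgis, out / "cgi.bed")
    write_bed([pm.hairpin for pm in bundle.predicted], out / "predicted.bed")
    expr = pd.DataFrame({name: s.stage_tpm for name, s in
                         bundle.expression.items()}).T
    expr.index.name = "name"
    expr.to_csv(out / "expression.tsv", sep="\t")
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def run_bundle(bundle: Bundle, search_params=None, min_tpm: float = 1.0,
               morna_min_reads: int = 1) -> dict:
    """Run the full annotation pipeline on a bundle and collect the results.

    Steps: tag-cluster construction and annotation, expression filtering,
    genic-context classification, cluster collapsing, promoter assignment,
    moRNA detection by CAGE and small RNA, and the developmental feature set.
    Returns a dict of intermediate objects and summary tables.
    """
    from .morna_detection import (compare_methods, detect_cage_morna,
                                  detect_smallrna_morna, morna_summary)
    from .premirna_catalog import (classify_genic_context, collapse_clusters,
                                   filter_expressed)
    from .promoter_assignment import (annotate_promoters, assignment_summary)
    from .promoter_features import classify_maternal, expression_matrix

    tcs = cluster_ctss(bundle.ctss, stages=bundle.stages)
    if bundle.genome is not None:
        annotate_clusters(tcs, bundle.genome)
    catalog = filter_expressed(bundle.catalog, bundle.expression,
                               min_tpm=min_tpm)
    classify_genic_context(catalog, bundle.genes)
    catalog, n_genes = collapse_clusters(catalog)
    assignments = annotate_promoters(catalog, tcs, bundle.transcripts,
                                     bundle.genes, bundle.h3k4me3,
                                     search_params)
    summary = assignment_summary(assignments)
    cage_calls = detect_cage_morna(
        bundle.ctss, catalog,
        stage_classes={st: ("maternal" if st in bundle.maternal_stages
                            else "zygotic") for st in bundle.stages})
    srna_calls = detect_smallrna_morna(bundle.small_rna, catalog,
                                       min_reads=morna_min_reads)
    matrix = expression_matrix(assignments, bundle.stages)
    labels = (classify_maternal(matrix, bundle.maternal_stages)
              if not matrix.empty else pd.Series(dtype=object))
    return {
        "tcs": tcs,
        "catalog": catalog,
        "n_genes": n_genes,
        "assignments": assignments,
        "summary": summary,
        "cage_morna": cage_calls,
        "smallrna_morna": srna_calls,
        "morna_summary": morna_summary(srna_calls),
        "morna_comparison": compare_methods(cage_calls, srna_calls),
        "expression_matrix": matrix,
        "maternal_labels": labels,
    }


def read_bundle(in_dir: str | Path) -> Bundle:
    """Re-load a written bundle through the io_formats readers."""
    d = Path(in_dir)
    manifest = read_manifest(d / "truth_manifest.json")
    stages = manifest["stages"]
    maternal = manifest["maternal_stages"]
    genome = Genome.from_fasta(d / "genome.fa") if (d / "genome.fa").exists() \
        else None
    parts = [read_ctss(d / f"ctss_{st}.txt", st) for st in stages]
    ctss = normalize_tpm(pd.concat(parts, ignore_index=True))
    hairpins = read_bed(d / "hairpins.bed")
    matures = read_bed(d / "matures.bed")
    from .premirna_catalog import catalog_from_beds

    catalog = catalog_from_beds(hairpins, matures)
    genes = read_bed12(d / "genes.bed12")
    transcripts = read_bed12(d / "transcripts.bed12")
    peaks = {m: read_peaks(d / f"{m}_peaks.bed")
             for m in ("h3k4me3", "h2az", "rnapii")}
    sizes = genome.chrom_sizes() if genome is not None else {}
    coverage = {m: read_bedgraph(d / f"{m}.bedgraph", sizes)
                for m in ("h3k4me3", "h2az", "rnapii")
                if (d / f"{m}.bedgraph").exists() and sizes}
    small_rna = read_small_rna(d / "small_rna.bed")
    cgis = read_bed(d / "cgi.bed")
    expr_df = pd.read_csv(d / "expression.tsv", sep="\t", index_col="name")
    expression = {name: ExpressionSummary(name, row.to_dict())
                  for name, row in expr_df.iterrows()}
    # genic context back from the manifest
    ctx = {n: rec["context"] for n, rec in manifest.get("premirnas", {}).items()}
    hosts = {g.name: g for g in genes}
    for pm in catalog:
        pm.context = ctx.get(pm.name, INTERGENIC)
        host = hosts.get(f"host-{pm.name}")
        if pm.context != INTERGENIC and host is not None:
            pm.host = host
            pm.host_same_strand = host.strand == pm.strand
    predicted = [PreMirna(iv.name, iv) for iv in read_bed(d / "predicted.bed")]
    return Bundle(
        seed=manifest.get("seed", 0), stages=stages, maternal_stages=maternal,
        genome=genome, ctss=ctss, catalog=catalog, expression=expression,
        genes=genes, transcripts=transcripts, h3k4me3=peaks["h3k4me3"],
        h2az=peaks["h2az"], rnapii=peaks["rnapii"], coverage=coverage,
        small_rna=small_rna, cgis=cgis, predicted=predicted, manifest=manifest,
    )
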