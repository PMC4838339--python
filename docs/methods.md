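# Methods

## Coordinates and data model

All internal coordinates are 0-based half-open; 1-based coordinates exist only
at file boundaries (the 4-column CTSS text format: chrom, 1-based position,
strand, raw tag count). Strand is mandatory on miRNA and tag-cluster records.
CTSS collections are pandas DataFrames (`chrom, pos, strand, stage, count,
tpm`); duplicate (chrom, pos, strand) rows in one stage file are summed rather
than rejected, which tolerates lane-split exports. Tags-per-million are
computed per stage with the library total defined as the sum of counts in that
stage's table, so per-stage tpm sums to 1e6 exactly whenever the library is
non-empty. bedGraph coverage is accepted strandless; strand-specific coverage
is supplied as two files.

## Tag clusters

Same-strand CTSSs are chained by single linkage: consecutive positions at most
`max_gap` (default 20 nt) apart join one cluster, and clusters are maximal.
Clustering runs on tpm pooled across all stages while per-stage sums are
retained; per-stage pooling (rather than clustering each stage separately)
keeps one TC identity per promoter across development, which the promoter
search and the stage-usage analyses both rely on.

The representative CTSS is the member with maximal pooled tpm; ties go to the
most 5' member (strand-aware). The tie-break is a convention — ties are
measure-zero on real data and the synthetic generator avoids them by
construction.

Shape is the 10–90% interquantile width of the cumulative member tpm: the
width between the first members at which the cumulative fraction reaches 0.10
and 0.90, inclusive of both ends. A cluster is *sharp* when that width is
≤ 4 nt (`sharp_max_width`, configurable), else *broad*. The 4-nt cutoff is the
standard promoter-shape convention; the planted fixtures use extremes (point
mass vs ≥ 30 nt uniform) so results are insensitive to the exact value.

Initiator classification reads the strand-corrected bases at −1 (one nt 5' of
the representative) and +1 (the representative itself): pyrimidine/purine is
*canonical*; G/G marks *processing* — 5' ends created by post-transcriptional
cleavage and recapping rather than initiation; anything else is *other*. A
representative at a chromosome edge (no −1 base) is *other* with a warning.
The processing test is evaluated first, but the two rules are disjoint anyway
(G is not a pyrimidine).

Promoter-region expression is the per-stage sum of tpm over TCs whose
representative lies within ±500 nt of an anchor (the assigned TSS).

## Pre-miRNA catalog

Entries are hairpin intervals with optional mature 5p/3p arms (validated to
lie inside the hairpin, same strand, 5p 5' of 3p). The expression filter keeps
entries whose maximum stage tpm is ≥ 1 (aggregation across stages by max; the
threshold sits well away from fixture values, so ≥ vs > is immaterial).
Genic context is any-overlap (≥ 1 bp, either strand) of the hairpin with a
gene span: intragenic on a coding host (coding wins when both overlap) or a
non-coding host, else intergenic; antisense hosts are recorded via a
`host_same_strand` flag. Cluster collapsing chains same-strand hairpins whose
intervals are ≤ 10 kb apart; the 10-kb default is a typical polycistron scale
and is configurable, and gene-level bookkeeping counts each cluster once. For
the predicted-hairpin screen, predicted entries overlapping coding exons or
matching a known hairpin at ≥ 50% reciprocal overlap are removed first.

## Promoter search

For an intergenic hairpin the search region runs upstream of the hairpin 5'
end to 40 kb (`max_upstream`). A coding gene on either strand encountered in
that window moves the boundary to its strand-aware 3' end — this normally
truncates the region at an upstream same-strand gene but can also extend it
slightly past 40 kb when only the gene's 3' end lies beyond. Candidates are
same-strand TCs with pooled tpm ≥ 0.5, excluding processing-class (G/G) TCs
and TCs already assigned as another gene's promoter (one promoter, one gene —
except within a collapsed cluster, whose members share a single assignment
anchored at the 5'-most hairpin).

The search expands in 5-kb steps and stops at the first window with a winner
of the evidence cascade:

* **SINGLE_TC** — exactly one candidate in the current window;
* **RNA_CONCORDANT** — a candidate whose representative lies within 100 nt
  (`concordance_tol`) of a same-strand transcript 5' end *and* whose
  transcript span reaches the hairpin (the stricter "full-length" reading;
  nearest such candidate wins);
* **H3K4ME3** — a candidate with a peak within ±500 nt of its representative
  (highest tpm wins).

If no window produces an (a)–(c) winner the highest-tpm candidate within the
whole bound is assigned (**EXPRESSION**); with no candidates at all the entry
stays unassigned. The stop-at-first-evidence rule operationalizes the
iterative search: it prefers near evidence over far, which matches how
nearest-TSS examples behave, while still letting strong distal evidence win
when the proximal windows are empty.

Intragenic entries: a non-coding host's transcript *is* the pri-miRNA, so its
5' end is the promoter (**NONCODING_HOST**). On a coding host the cascade runs
between hairpin and host 5' end; a TC exactly at the host 5' end is the host
promoter, not independent transcription, and is excluded. Failing independent
evidence, a hairpin < 5 kb (`host_proximal`) from the host 5' end is
attributed to the host promoter (**HOST_PROMOTER**); farther ones stay
unassigned. Alternative promoters are non-processing TCs strictly between the
assigned TSS and the hairpin, more than 500 nt from the assigned TSS; they are
recorded with distances and never replace the main assignment.

## Chromatin profiles

Metaprofiles are per-offset arithmetic means of a tpm-normalized coverage
track over stranded anchors, with minus-strand windows reversed so offsets
read 5'→3'; uncovered positions contribute 0. Peak topology at an assigned
locus uses ±500-nt windows at the TSS and the hairpin: *spanning* when one
peak interval overlaps both, *independent* when the hairpin has peaks sharing
none with the TSS window, *none* otherwise. Heatmap matrices are rows of
signal around hairpin 5' ends, partitioned CGI-overlapping first, each
partition sorted by ascending TSS-to-hairpin distance. Peaks come from input
BED files; a minimal built-in caller (runs of coverage ≥ 4× the global mean
over ≥ 200 contiguous bases) exists only so synthetic fixtures are
self-contained, and makes no claim to production peak-calling quality.

## moRNA detection

The 3p Drosha site is the first nucleotide 3' of the mature 3p arm
(strand-aware, half-open adjacency); the 5p moRNA boundary is the nucleotide
immediately 5' of the mature 5p arm. A CAGE call requires a same-strand CTSS
at *exactly* the 3p site in ≥ 2 stages — the exact-nucleotide rule is what
distinguishes reproducible processing products from noise, and the supporting
stage labels are kept for the maternal/zygotic attribution analysis. The 5p
side is not called from CAGE (capped fragments arise 3' of the cut); 5p moRNAs
come from small RNA only. Small-RNA calls count same-strand reads of 18–30 nt
lying fully inside hairpin ± 30 nt whose relevant end lies within 1 nt of the
arm boundary (the 1-nt tolerance absorbs Drosha cleavage heterogeneity);
summed read counts are compared to `min_reads`. Summaries report per-arm,
both-arm and union pre-miRNA counts (inclusion–exclusion holds by
construction), and cross-method agreement matches on (pre-miRNA, arm). The
predicted-hairpin screen runs the CAGE rule over predicted hairpins (hairpin
3' end as site proxy when arms are unannotated) and flags high confidence at
≥ 3 supporting stages and pooled tpm ≥ 1 at the site — an operationalization
of "high confidence", exposed in the call record.

## Developmental features

Maternal classification: a promoter is maternally inherited iff its ±500-nt
expression reaches 1 tpm in at least one maternal-flagged stage; the maternal
stage set is configuration, not inference. Expression clustering uses
hierarchical complete linkage on Euclidean distances of log2(tpm + 1) profiles
(pseudocount 1 handles zeros), with rows pre-sorted by name so distance ties
resolve deterministically. TATAWA scanning searches the strand-oriented
[−40, −20] window relative to the representative TSS (canonical TATA
positioning; the window is a choice, not an inference), counting every
overlapping match whose start falls inside the window. The G+C profile is the
per-offset mean of a G/C indicator, strand-oriented; CGI overlap tests TSS
± 500 nt against CGI intervals and reports the fraction over distinct
(cluster-collapsed) promoters. Stage-wise shape usage classifies each assigned
TC on its stage-restricted tag distribution, counting stages where the TC has
≥ 1 tpm.

## Synthetic data

The generator emulates a 12-stage embryogenesis CAGE experiment (first 4
stages maternal) on a 10-Mb, 2-chromosome genome: hairpins (80 nt, 22-nt arms)
at well-separated loci; planted promoters at log-uniform 0.2–40 kb upstream
distances; sharp promoters as point masses and broad ones as 30–80-nt uniform
spreads with a dominant 5' base (so the planted TSS is the representative);
canonical C/A initiators written into the genome; Poisson tag counts (mean 50
per stage at promoters); RNA-seq transcript models and/or H3K4me3 peaks at
supported promoters; decoy upstream coding genes exercising the
search-boundary rule and decoy G/G tag clusters exercising the
initiator-exclusion rule; Drosha-site CTSSs (G/G context, zygotic stages only,
≥ 2 stages); per-arm mature and moRNA small-RNA reads; CpG-style GC islands at
a subset of promoters; and Poisson background noise at 1 tag / 10 kb / stage.
A set of high-count "filler" promoters far from the miRNA loci provides the
bulk of each library (as real CAGE libraries are dominated by non-miRNA
promoters), which keeps a stray background tag below the 0.5-tpm candidate
threshold. Everything planted is recorded in a JSON truth manifest that
round-trips through its writer/reader.

What the generator does **not** model: hairpin thermodynamics and true
secondary structure, chromatin autocorrelation, mappability artifacts,
promoter-shape drift between stages, and isomiR/read-length heterogeneity
beyond the fixed read length. Passing recovery tests therefore demonstrates
the correctness of the algorithms under the stated statistical model, not
performance on real libraries.

`fixture_from_counts` builds bundles by deterministic constructive placement
(no sampling) to hit exact set sizes — per-arm moRNA incidences at two read
thresholds (constructed as nested sets with controlled intersections, with
feasibility validated), coding-host independent/proximal splits, expression
totals and predicted-screen compositions — for bookkeeping-style checks.

## Problem sizes and numerical choices

Property suites run the full pipeline on 200 seeded bundles of 6 pre-miRNAs on
0.6-Mb genomes with 6 stages — small enough to iterate quickly while
exercising every code path (strands, contexts, evidence types, decoys);
`scripts/acceptance.py` uses 100 such bundles plus the constructive fixtures
at their printed sizes (346-entry catalog, 227 predicted hairpins, 29
coding-host entries, 101-entry moRNA set). Floating-point ties in
representative selection use a 1e-12 tolerance; tpm conservation is asserted
at 1e-6 relative tolerance. Degenerate inputs are defined rather than
special-cased: empty CTSS files parse to empty collections, a zero-count
library yields zero tpm, an empty tag cluster has no representative (error),
single-row expression matrices return identity orders, and infeasible
generator layouts (genome too small for the promoter-distance range) fail
before writing anything.
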