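"""Input/output layer: genomic domain types and the text formats the pipeline touches.

All internal coordinates are 0-based half-open; 1-based coordinates appear only at
file boundaries (the 4-column CTSS text format and human-readable reports). Strand
is mandatory on every miRNA/tag-cluster record and intervals on different
chromosomes never compare for overlap.

Supported formats: BED3/BED6 (intervals, scored peaks, small-RNA alignments),
BED12 (+ optional 13th coding-flag column) for transcript/gene models, bedGraph
coverage (strandless), FASTA genomes (via pyfaidx or in-memory), the 4-column CTSS
table (chrom, 1-based position, strand, raw tag count), and TSV report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("primir")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: canonical column order of a CTSS DataFrame
CTSS_COLUMNS = ["chrom", "pos", "strand", "stage", "count", "tpm"]


class ParseError(ValueError):
    """A line of an input file could not be parsed; carries the line number."""


class ValidationError(ValueError):
    """A parsed record violates a format or domain contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) with strand and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5'-most base (strand-aware)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Coordinate of the 3'-most base (strand-aware)."""
        return self.end - 1 if self.strand != "-" else self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_one_based(self) -> tuple[str, int, int]:
        """(chrom, first base, last base) in 1-based inclusive coordinates."""
        return self.chrom, self.start + 1, self.end

    @classmethod
    def from_one_based(
        cls, chrom: str, first: int, last: int, strand: str = ".", name: str = ""
    ) -> "GenomicInterval":
        return cls(chrom, first - 1, last, strand, name)


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript/gene model: spliced exon blocks within a genomic span."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"transcript {self.name}: strand required")
        prev_end = self.start - 1
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ValidationError(f"transcript {self.name}: exon [{s},{e}) outside span")
            if s <= prev_end:
                raise ValidationError(f"transcript {self.name}: exons overlap or unsorted")
            prev_end = e

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.name)

    @property
    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Peak:
    """Scored interval from a peak caller; strand may be '.'."""

    interval: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"peak {self.interval.name}: negative score")


class CoverageTrack:
    """Per-base coverage on a genome, normalized to tags per million.

    Backed by dense per-chromosome arrays; lookups outside the covered region
    return 0. Values must be non-negative.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self._arrays: dict[str, np.ndarray] = {
            c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()
        }

    def chrom_sizes(self) -> dict[str, int]:
        return {c: a.size for c, a in self._arrays.items()}

    def add_interval(self, chrom: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValidationError(f"negative coverage value {value} on {chrom}")
        arr = self._arrays.get(chrom)
        if arr is None:
            return
        s, e = max(0, start), min(arr.size, end)
        if s < e:
            arr[s:e] += value

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions outside the chromosome are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        arr = self._arrays.get(chrom)
        if arr is None:
            return out
        s, e = max(0, start), min(arr.size, end)
        if s < e:
            out[s - start : e - start] = arr[s:e]
        return out

    def value(self, chrom: str, pos: int) -> float:
        arr = self._arrays.get(chrom)
        if arr is None or pos < 0 or pos >= arr.size:
            return 0.0
        return float(arr[pos])


class Genome:
    """Sequence access with a uniform fetch() over pyfaidx or in-memory dicts."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end), clipped to the chromosome; reverse-complemented
        for strand '-'. A clipped fetch returns fewer bases than requested."""
        seq = self._seqs.get(chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        sub = seq[max(0, start) : max(0, end)]
        if strand == "-":
            sub = sub.translate(COMPLEMENT)[::-1]
        return sub


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_ctss(path: str | Path, stage_label: str) -> pd.DataFrame:
    """Read a 4-column CTSS table (chrom, 1-based pos, strand, count).

    Positions are converted to 0-based; duplicate (chrom, pos, strand) rows are
    summed. Returns a DataFrame with CTSS_COLUMNS (tpm filled with NaN until
    :func:`normalize_tpm` is applied).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
            try:
                pos1, count = int(f[1]), int(f[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if count < 0:
                raise ValidationError(f"{path}:{lineno}: negative tag count {count}")
            if f[2] not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: invalid strand {f[2]!r}")
            rows.append((f[0], pos1 - 1, f[2], count))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    if not df.empty:
        df = (
            df.groupby(["chrom", "pos", "strand"], as_index=False, sort=True)["count"]
            .sum()
        )
    df["stage"] = stage_label
    df["tpm"] = np.nan
    return df[CTSS_COLUMNS]


def normalize_tpm(ctss: pd.DataFrame) -> pd.DataFrame:
    """Add tags-per-million within each stage library.

    library_total is the sum of counts in the stage's table, so per-stage tpm sums
    to 1e6 whenever the stage has any tags.
    """
    df = ctss.copy()
    totals = df.groupby("stage")["count"].transform("sum").astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["tpm"] = np.where(totals > 0, df["count"] / totals * 1e6, 0.0)
    return df


def write_ctss(ctss: pd.DataFrame, path: str | Path) -> None:
    """Write one stage's CTSSs back to the 4-column 1-based text format."""
    with open(path, "w") as fh:
        for row in ctss.sort_values(["chrom", "pos", "strand"]).itertuples():
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{int(row.count)}\n")


def read_bed(path: str | Path, expect_strand: bool = True) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (half-open, as in BED)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            if expect_strand and len(f) < 6:
                raise ValidationError(f"{path}:{lineno}: strand column required")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            try:
                out.append(GenomicInterval(f[0], start, end, strand, name))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              scores: Sequence[float] | None = None) -> None:
    intervals = list(intervals)
    if scores is None:
        scores = [0.0] * len(intervals)
    with open(path, "w") as fh:
        for iv, sc in zip(intervals, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{sc:g}\t{iv.strand}\n"
            )


def read_peaks(path: str | Path) -> list[Peak]:
    """Read scored BED peaks (strand optional; column 5 is the score)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), strand,
                                 f[3] if len(f) > 3 else "")
            peaks.append(Peak(iv, score))
    return peaks


def read_small_rna(path: str | Path) -> pd.DataFrame:
    """Read small-RNA alignments as BED6 where the score column is a read count.

    Returns a DataFrame with columns chrom, start, end, strand, count.
    """
    peaks = read_peaks(path)
    rows = [
        (p.interval.chrom, p.interval.start, p.interval.end, p.interval.strand,
         int(p.score))
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "count"])
    if (df["strand"] == ".").any():
        raise ValidationError(f"{path}: small-RNA records require a strand")
    return df


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read BED12 transcript models; an optional 13th column flags coding status
    ('coding'/'noncoding', default coding)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            start, end = int(f[1]), int(f[2])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValidationError(
                    f"{path}:{lineno}: blockCount {n_blocks} does not match "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            coding = True
            if len(f) > 12:
                coding = f[12].strip().lower() not in ("noncoding", "non-coding", "nc", "0")
            try:
                out.append(TranscriptModel(f[3], f[0], start, end, f[5], exons, coding))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed12(models: Iterable[TranscriptModel], path: str | Path,
                coding_column: bool = True) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, e in m.exons) + ","
            row = [m.chrom, m.start, m.end, m.name, 0, m.strand, m.start, m.end,
                   "0,0,0", len(m.exons), sizes, starts]
            if coding_column:
                row.append("coding" if m.coding else "noncoding")
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Read a strandless bedGraph into a dense CoverageTrack."""
    track = CoverageTrack(chrom_sizes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            track.add_interval(f[0], int(f[1]), int(f[2]), float(f[3]))
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes()):
            arr = track.window(chrom, 0, track.chrom_sizes()[chrom])
            # run-length encode constant stretches
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.chrom_sizes().items():
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, size)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Assignment report table
# ---------------------------------------------------------------------------

ASSIGNMENT_BASE_COLUMNS = [
    "name", "context", "tss_chrom", "tss_pos", "tss_strand",
    "distance", "evidence_tier", "n_alternatives",
]


def assignment_frame(assignments, stages: Sequence[str]) -> pd.DataFrame:
    """Flatten PromoterAssignment records into the report table."""
    rows = []
    for a in assignments:
        pm = a.pre_mirna
        if a.assigned:
            base = dict(
                name=pm.name, context=pm.context,
                tss_chrom=pm.hairpin.chrom, tss_pos=a.tss,
                tss_strand=pm.hairpin.strand, distance=a.distance,
                evidence_tier=a.evidence_tier,
                n_alternatives=len(a.alternatives),
            )
        else:
            base = dict(
                name=pm.name, context=pm.context,
                tss_chrom=pd.NA, tss_pos=pd.NA, tss_strand=pd.NA,
                distance=pd.NA, evidence_tier="UNASSIGNED", n_alternatives=0,
            )
        for st in stages:
            base[f"expr_{st}"] = float(a.expression.get(st, 0.0)) if a.expression else 0.0
        rows.append(base)
    cols = ASSIGNMENT_BASE_COLUMNS + [f"expr_{st}" for st in stages]
    return pd.DataFrame(rows, columns=cols)


def write_assignment_table(assignments, path: str | Path,
                           stages: Sequence[str]) -> pd.DataFrame:
    """Write the per-pre-miRNA promoter report (one row each, NA when unassigned)."""
    df = assignment_frame(assignments, stages)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_assignment_table(path: str | Path) -> pd.DataFrame:
    """Paired reader for :func:`write_assignment_table`; round-trips losslessly."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "tss_chrom": "string"})
    for col in ("tss_pos", "distance"):
        if col in df:
            df[col] = df[col].astype("Int64")
    return df
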