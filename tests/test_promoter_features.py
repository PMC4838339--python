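import re

import numpy as np
import pandas as pd
import pytest

from primir import (
    Genome, GenomicInterval, PreMirna, cgi_overlap, classify_maternal,
    cluster_expression, gc_profile, scan_tatawa, shape_usage_by_stage,
)
from primir.promoter_assignment import PromoterAssignment
from primir.promoter_features import MATERNAL, ZYGOTIC
from conftest import make_tc


def matrix(rows, stages=("st01", "st02", "st03", "st04")):
    return pd.DataFrame(rows if isinstance(rows, dict) else dict(rows),
                        index=list(stages)).T


def assignment_at(genome_len, tss, strand="+", name="m", chrom="c",
                  hairpin_start=None):
    hp_start = hairpin_start if hairpin_start is not None else (
        tss + 2_000 if strand != "-" else max(0, tss - 2_080))
    pm = PreMirna(name, GenomicInterval(chrom, hp_start, hp_start + 80,
                                        strand, name))
    return PromoterAssignment(pm, tss=tss, distance=abs(pm.five_prime - tss),
                              evidence_tier="SINGLE_TC")


class TestClassifyMaternal:
    def test_examples(self):
        m = matrix({"a": [0, 0, 5, 9], "b": [5, 0, 0, 0], "c": [0.5, 0.5, 3, 3]})
        labels = classify_maternal(m, maternal_stages=["st01", "st02"])
        assert labels["a"] == ZYGOTIC
        assert labels["b"] == MATERNAL
        assert labels["c"] == ZYGOTIC  # below the 1-tpm threshold maternally

    def test_errors(self):
        m = matrix({"a": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            classify_maternal(m, [])
        with pytest.raises(KeyError):
            classify_maternal(m, ["nope"])


class TestClusterExpression:
    def test_identical_rows_adjacent(self):
        m = matrix({"a": [1, 2, 3, 4], "b": [9, 0, 0, 1], "c": [1, 2, 3, 4]})
        order, link = cluster_expression(m)
        ia, ic = order.index("a"), order.index("c")
        assert abs(ia - ic) == 1
        assert link[0, 2] == 0.0  # first merge at distance zero

    def test_permutation_invariant_topology(self):
        m = matrix({"a": [1, 2, 3, 4], "b": [9, 0, 0, 1], "c": [1, 2, 3, 4],
                    "d": [4, 4, 0, 0]})
        order1, link1 = cluster_expression(m)
        order2, link2 = cluster_expression(m.iloc[[3, 1, 0, 2]])
        assert order1 == order2
        assert np.allclose(link1[:, 2], link2[:, 2])

    def test_single_row_identity(self):
        m = matrix({"only": [1, 2, 3, 4]})
        order, link = cluster_expression(m)
        assert order == ["only"] and link is None


class TestScanTatawa:
    def _genome_with(self, insert, offset, length=3_000, tss=1_500):
        # GC-rich background cannot contain TATAWA by construction
        seq = list("GC" * (length // 2))
        start = tss + offset
        seq[start : start + len(insert)] = list(insert)
        return Genome({"c": "".join(seq)}), tss

    def test_gc_background_no_hits(self):
        genome, tss = self._genome_with("", 0)
        df = scan_tatawa([assignment_at(3_000, tss)], genome)
        assert df.loc[0, "n_hits"] == 0

    def test_planted_motif_at_minus_30(self):
        genome, tss = self._genome_with("TATAAA", -30)
        df = scan_tatawa([assignment_at(3_000, tss)], genome)
        assert df.loc[0, "n_hits"] == 1 and df.loc[0, "offsets"] == "-30"

    def test_overlapping_matches_counted(self):
        genome, tss = self._genome_with("TATATATA", -31)
        df = scan_tatawa([assignment_at(3_000, tss)], genome)
        assert df.loc[0, "n_hits"] == 2
        assert df.loc[0, "offsets"] == "-31,-29"

    def test_matches_regex_oracle_on_random_promoters(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=2_000))
            genome = Genome({"c": seq})
            tss = int(rng.integers(200, 1_800))
            strand = rng.choice(["+", "-"])
            a = assignment_at(2_000, tss, strand=strand,
                              hairpin_start=1_900 if strand != "-" else 0)
            df = scan_tatawa([a], genome)
            # oracle: extract each candidate window start and test the motif
            hits = 0
            for off in range(-40, -19):
                if strand != "-":
                    s = tss + off
                    sub = seq[s : s + 6]
                else:
                    s = tss - off - 5
                    sub = seq[s : s + 6]
                    sub = sub.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                if re.fullmatch(r"TATA[AT]A", sub):
                    hits += 1
            assert df.loc[0, "n_hits"] == hits


class TestGcProfile:
    def test_all_at_and_all_gc(self):
        at = Genome({"c": "AT" * 2_000})
        gc = Genome({"c": "GC" * 2_000})
        a = [assignment_at(4_000, 2_000)]
        assert gc_profile(a, at, flank=100).max() == 0.0
        assert gc_profile(a, gc, flank=100).min() == 1.0

    def test_island_plateau(self):
        seq = list("AT" * 2_000)
        seq[1_950:2_050] = list("G" * 100)
        genome = Genome({"c": "".join(seq)})
        prof = gc_profile([assignment_at(4_000, 2_000)], genome, flank=200)
        offs = np.arange(-200, 201)
        inside = (offs >= -50) & (offs <= 49)
        assert prof[inside].min() == 1.0 and prof[~inside].max() == 0.0

    def test_values_in_unit_interval_and_symmetry(self):
        rng = np.random.default_rng(2)
        half = "".join(rng.choice(list("ACGT"), size=500))
        seq = half + "G" + half[::-1]  # palindromic GC content about center
        genome = Genome({"c": seq})
        prof = gc_profile([assignment_at(len(seq), 500)], genome, flank=300)
        assert prof.min() >= 0.0 and prof.max() <= 1.0
        is_gc = np.array([b in "GC" for b in seq])
        assert np.array_equal(prof[:300], is_gc[200:500].astype(float))
        assert np.array_equal(prof, prof[::-1])


class TestCgiOverlap:
    def test_fraction_extremes_and_window(self):
        a = [assignment_at(10_000, 2_000, name="m1"),
             assignment_at(10_000, 6_000, name="m2")]
        flags, frac = cgi_overlap(a, [])
        assert frac == 0.0
        everywhere = [GenomicInterval("c", 0, 10_000, ".")]
        _, frac = cgi_overlap(a, everywhere)
        assert frac == 1.0
        away = [GenomicInterval("c", 2_601, 2_800, ".")]  # 600 b past m1 TSS
        flags, frac = cgi_overlap(a, away)
        assert not flags["m1"] and frac == 0.0


class TestShapeUsage:
    def test_counts_by_stage(self):
        stages = ("st01", "st02")
        sharp_tc = make_tc([100], [0], stages=stages,
                           stage_matrix=[[5.0, 0.0]])
        broad_tc = make_tc(list(range(300, 360)), None, stages=stages,
                           stage_matrix=[[0.0, 1.0]] * 60)
        a1 = PromoterAssignment(
            PreMirna("a", GenomicInterval("chr1", 5_000, 5_080, "+", "a")),
            tss=100, distance=4_900, evidence_tier="SINGLE_TC", tc=sharp_tc)
        a2 = PromoterAssignment(
            PreMirna("b", GenomicInterval("chr1", 9_000, 9_080, "+", "b")),
            tss=300, distance=8_700, evidence_tier="SINGLE_TC", tc=broad_tc)
        out = shape_usage_by_stage([sharp_tc, broad_tc], [a1, a2], stages)
        assert out.loc["st01", "sharp"] == 1 and out.loc["st01", "broad"] == 0
        assert out.loc["st02", "broad"] == 1 and out.loc["st02", "sharp"] == 0

    def test_inactive_stage_zero(self):
        stages = ("st01",)
        tc = make_tc([100], [0], stages=stages, stage_matrix=[[0.2]])
        a = PromoterAssignment(
            PreMirna("a", GenomicInterval("chr1", 5_000, 5_080, "+", "a")),
            tss=100, distance=4_900, evidence_tier="SINGLE_TC", tc=tc)
        out = shape_usage_by_stage([tc], [a], stages)
        assert out.loc["st01"].sum() == 0
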