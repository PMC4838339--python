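import numpy as np
import pandas as pd
import pytest

from primir import (
    GenomicInterval, PreMirna, compare_methods, detect_cage_morna,
    detect_smallrna_morna, drosha_site, morna_summary,
    screen_predicted_hairpins,
)
from primir.io_formats import normalize_tpm
from primir.synthetic_data import fixture_from_counts


def mk_pm(name="m", start=1_000, strand="+", chrom="chr1"):
    hp = GenomicInterval(chrom, start, start + 80, strand, name)
    if strand != "-":
        m5 = GenomicInterval(chrom, start, start + 22, strand)
        m3 = GenomicInterval(chrom, start + 58, start + 80, strand)
    else:
        m5 = GenomicInterval(chrom, start + 58, start + 80, strand)
        m3 = GenomicInterval(chrom, start, start + 22, strand)
    return PreMirna(name, hp, mature_5p=m5, mature_3p=m3)


def ctss_at(entries):
    """entries: (chrom, pos, strand, stage, count)"""
    df = pd.DataFrame(entries, columns=["chrom", "pos", "strand", "stage",
                                        "count"])
    df["tpm"] = np.nan
    return normalize_tpm(df)


def reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "count"])


class TestDroshaSite:
    def test_plus_strand_3p_adjacency(self):
        pm = PreMirna("m", GenomicInterval("c", 80, 160, "+"),
                      mature_3p=GenomicInterval("c", 100, 122, "+"))
        assert drosha_site(pm, "3p") == 122

    def test_minus_strand_reflection(self):
        pm = PreMirna("m", GenomicInterval("c", 80, 160, "-"),
                      mature_3p=GenomicInterval("c", 100, 122, "-"))
        assert drosha_site(pm, "3p") == 99

    def test_missing_arm_names_it(self):
        pm = PreMirna("m", GenomicInterval("c", 80, 160, "+"))
        with pytest.raises(ValueError, match="3p"):
            drosha_site(pm, "3p")


class TestCageMorna:
    def test_no_ctss_no_call(self):
        assert detect_cage_morna(ctss_at([]), [mk_pm()]) == []

    def test_two_stage_same_nucleotide_call(self):
        pm = mk_pm()
        site = drosha_site(pm, "3p")
        df = ctss_at([("chr1", site, "+", "st07", 4),
                      ("chr1", site, "+", "st09", 2)])
        (call,) = detect_cage_morna(df, [pm])
        assert call.stage_support == frozenset({"st07", "st09"})
        assert call.site == site and call.arm == "3p"

    def test_single_stage_rejected(self):
        pm = mk_pm()
        site = drosha_site(pm, "3p")
        df = ctss_at([("chr1", site, "+", "st07", 50)])
        assert detect_cage_morna(df, [pm]) == []

    def test_exact_position_specificity(self):
        """Shifting all planted site CTSSs by +2 nt must give zero calls."""
        pms = [mk_pm(f"m{i}", start=1_000 + i * 500) for i in range(10)]
        exact, shifted = [], []
        for pm in pms:
            site = drosha_site(pm, "3p")
            for st in ("st05", "st06", "st07"):
                exact.append(("chr1", site, "+", st, 5))
                shifted.append(("chr1", site + 2, "+", st, 5))
        assert len(detect_cage_morna(ctss_at(exact), pms)) == 10
        assert detect_cage_morna(ctss_at(shifted), pms) == []

    def test_wrong_strand_ignored(self):
        pm = mk_pm()
        site = drosha_site(pm, "3p")
        df = ctss_at([("chr1", site, "-", "st07", 4),
                      ("chr1", site, "-", "st09", 2)])
        assert detect_cage_morna(df, [pm]) == []


class TestSmallRnaMorna:
    def test_zero_reads(self):
        assert detect_smallrna_morna(reads([]), [mk_pm()]) == []

    def test_3p_threshold_application(self):
        pm = mk_pm()
        site = drosha_site(pm, "3p")
        rr = reads([("chr1", site, site + 20, "+", 3)])
        for t in (1, 2, 3):
            calls = detect_smallrna_morna(rr, [pm], min_reads=t)
            assert [(c.arm, c.read_count) for c in calls] == [("3p", 3)]
        assert detect_smallrna_morna(rr, [pm], min_reads=4) == []

    def test_5p_single_read_threshold(self):
        pm = mk_pm()
        site = drosha_site(pm, "5p")
        rr = reads([("chr1", site - 19, site + 1, "+", 1)])
        assert len(detect_smallrna_morna(rr, [pm], min_reads=1)) == 1
        assert detect_smallrna_morna(rr, [pm], min_reads=2) == []

    def test_length_and_containment_filters(self):
        pm = mk_pm()
        site = drosha_site(pm, "3p")
        too_long = reads([("chr1", site, site + 35, "+", 5)])
        assert detect_smallrna_morna(too_long, [pm]) == []
        outside = reads([("chr1", site, site + 60, "+", 5)])
        assert detect_smallrna_morna(outside, [pm]) == []

    def test_one_nt_offset_tolerated_two_not(self):
        pm = mk_pm()
        site = drosha_site(pm, "3p")
        near = reads([("chr1", site + 1, site + 21, "+", 2)])
        assert len(detect_smallrna_morna(near, [pm])) == 1
        off = reads([("chr1", site + 2, site + 22, "+", 2)])
        assert detect_smallrna_morna(off, [pm]) == []

    def test_minus_strand_geometry(self):
        pm = mk_pm(strand="-")
        site3 = drosha_site(pm, "3p")       # hairpin.start - 1
        rr = reads([("chr1", site3 - 19, site3 + 1, "-", 2)])
        (call,) = detect_smallrna_morna(rr, [pm])
        assert call.arm == "3p"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        pms = [mk_pm(f"m{i}", start=1_000 + i * 500) for i in range(20)]
        rows = []
        for pm in pms:
            for arm in ("5p", "3p"):
                n = int(rng.integers(0, 5))
                if n:
                    site = drosha_site(pm, arm)
                    s, e = ((site - 19, site + 1) if arm == "5p"
                            else (site, site + 20))
                    rows.append(("chr1", s, e, "+", n))
        rr = reads(rows)
        prev = None
        for t in range(1, 6):
            counts = morna_summary(detect_smallrna_morna(rr, pms, min_reads=t))
            if prev is not None:
                assert all(counts[k] <= prev[k] for k in counts)
            assert counts["n_5p"] + counts["n_3p"] - counts["n_both"] \
                == counts["n_union"]
            prev = counts


class TestSummaryAndComparison:
    def test_disjoint_and_identical_sets(self):
        def call(name, arm):
            return type("C", (), {"name": name, "arm": arm})

        disjoint = [call("a", "5p"), call("b", "5p"), call("c", "3p"),
                    call("d", "3p"), call("e", "3p")]
        s = morna_summary(disjoint)
        assert (s["n_5p"], s["n_3p"], s["n_both"], s["n_union"]) == (2, 3, 0, 5)
        identical = [c for n in "wxyz" for c in (call(n, "5p"), call(n, "3p"))]
        s = morna_summary(identical)
        assert (s["n_both"], s["n_union"]) == (4, 4)

    def test_compare_methods(self):
        a = [type("C", (), {"name": n, "arm": "3p"}) for n in "abc"]
        b = [type("C", (), {"name": n, "arm": "3p"}) for n in "cde"]
        assert compare_methods(a, b)["n_both"] == 1
        assert compare_methods(a, a)["n_both"] == 3
        assert compare_methods(a, [])["n_both"] == 0


class TestPredictedScreen:
    def test_empty(self):
        pms = [mk_pm("p1")]
        assert screen_predicted_hairpins(pms, ctss_at([])) == []

    def test_single_stage_excluded(self):
        pm = mk_pm("p1")
        site = drosha_site(pm, "3p")
        df = ctss_at([("chr1", site, "+", "st05", 9)])
        assert screen_predicted_hairpins([pm], df) == []

    def test_hairpin_end_proxy_without_arms(self):
        bare = PreMirna("p1", GenomicInterval("chr1", 1_000, 1_080, "+"))
        df = ctss_at([("chr1", 1_080, "+", "st05", 5),
                      ("chr1", 1_080, "+", "st06", 5)])
        (call,) = screen_predicted_hairpins([bare], df)
        assert call.site == 1_080


def test_zygotic_only_fixture_has_no_maternal_support():
    """Planted Drosha sites live in zygotic libraries; no call may cite a
    maternal stage."""
    bundle = fixture_from_counts(
        {"morna": {"t1": {"n5p": 10, "n3p": 8, "nboth": 4}, "n_cage": 6,
                   "n_overlap": 3}})
    calls = detect_cage_morna(bundle.ctss, bundle.catalog)
    assert len(calls) == 6
    maternal = set(bundle.maternal_stages)
    for c in calls:
        assert not (c.stage_support & maternal)
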