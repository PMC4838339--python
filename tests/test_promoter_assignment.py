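import numpy as np
import pytest

from primir import (
    GenomicInterval, Peak, PreMirna, SearchParams, TranscriptModel,
    assign_intergenic, assign_intragenic, candidate_tcs,
    find_alternative_promoters, gene_level_stats,
)
from primir.premirna_catalog import INTRAGENIC_CODING, INTRAGENIC_NONCODING
from primir.promoter_assignment import (
    TIER_EXPRESSION, TIER_H3K4ME3, TIER_HOST_PROMOTER, TIER_NONCODING_HOST,
    TIER_RNA_CONCORDANT, TIER_SINGLE_TC, UNASSIGNED,
)
from conftest import make_tc

PARAMS = SearchParams()
HAIRPIN_START = 100_000


def mk_pm(strand="+", context=None, host=None, start=HAIRPIN_START):
    pm = PreMirna("mirX", GenomicInterval("chr1", start, start + 80, strand,
                                          "mirX"))
    if context:
        pm.context = context
        pm.host = host
    return pm


def tc_at(distance, tpm=2.0, strand="+", initiator="canonical", tc_id=None,
          pm=None):
    pm = pm or mk_pm(strand)
    pos = pm.five_prime - distance if strand != "-" else pm.five_prime + distance
    return make_tc([pos], [tpm], strand=strand, initiator=initiator,
                   tc_id=tc_id or f"TC{distance}")


class TestCandidates:
    def test_no_tcs_full_bound(self):
        pm = mk_pm()
        cands, bound = candidate_tcs(pm, [], [], PARAMS)
        assert cands == [] and bound == 40_000

    def test_processing_class_excluded(self):
        pm = mk_pm()
        tcs = [tc_at(2_000, initiator="processing"), tc_at(8_000)]
        cands, _ = candidate_tcs(pm, tcs, [], PARAMS)
        assert [c.distance for c in cands] == [8_000]

    def test_coding_gene_truncates_search(self):
        pm = mk_pm()
        # gene 3' end 12 kb upstream; TC at 15 kb is past the boundary
        g3, g5 = HAIRPIN_START - 12_000, HAIRPIN_START - 30_000
        gene = TranscriptModel("g", "chr1", g5, g3, "+", ((g5, g3),), True)
        tcs = [tc_at(15_000)]
        cands, bound = candidate_tcs(pm, tcs, [gene], PARAMS)
        assert bound == 12_001 or bound == 12_000  # gene 3'-most base
        assert cands == []

    def test_noncoding_gene_does_not_truncate(self):
        pm = mk_pm()
        g3, g5 = HAIRPIN_START - 12_000, HAIRPIN_START - 30_000
        gene = TranscriptModel("g", "chr1", g5, g3, "+", ((g5, g3),), False)
        cands, bound = candidate_tcs(pm, [tc_at(15_000)], [gene], PARAMS)
        assert bound == 40_000 and len(cands) == 1

    def test_low_tpm_and_used_excluded(self):
        pm = mk_pm()
        tcs = [tc_at(1_000, tpm=0.2), tc_at(3_000, tc_id="USED")]
        cands, _ = candidate_tcs(pm, tcs, [], PARAMS, used_tc_ids={"USED"})
        assert cands == []

    def test_minus_strand_upstream_is_rightward(self):
        pm = mk_pm(strand="-")
        good = tc_at(5_000, strand="-", pm=pm)
        wrong_side = make_tc([pm.five_prime - 5_000], [5.0], strand="-")
        cands, _ = candidate_tcs(pm, [good, wrong_side], [], PARAMS)
        assert [c.distance for c in cands] == [5_000]


class TestIntergenicTiers:
    def _assign(self, pm, tcs, transcripts=(), peaks=()):
        cands, bound = candidate_tcs(pm, tcs, [], PARAMS)
        return assign_intergenic(pm, cands, bound, list(transcripts),
                                 list(peaks), PARAMS)

    def test_single_candidate(self):
        pm = mk_pm()
        a = self._assign(pm, [tc_at(1_100)])
        assert a.evidence_tier == TIER_SINGLE_TC
        assert a.distance == 1_100 and a.tss == HAIRPIN_START - 1_100

    def test_concordant_transcript_beats_expression(self):
        pm = mk_pm()
        near = tc_at(1_000, tpm=50.0, tc_id="near")
        far = tc_at(4_000, tpm=2.0, tc_id="far")
        tx_start = pm.five_prime - 4_000
        tx = TranscriptModel("tx", "chr1", tx_start, HAIRPIN_START + 40, "+",
                             ((tx_start, HAIRPIN_START + 40),), True)
        a = self._assign(pm, [near, far], transcripts=[tx])
        assert a.evidence_tier == TIER_RNA_CONCORDANT and a.tc.tc_id == "far"

    def test_transcript_must_reach_hairpin(self):
        pm = mk_pm()
        near = tc_at(1_000, tpm=50.0, tc_id="near")
        far = tc_at(4_000, tpm=2.0, tc_id="far")
        tx_start = pm.five_prime - 4_000
        short_tx = TranscriptModel("tx", "chr1", tx_start, tx_start + 500, "+",
                                   ((tx_start, tx_start + 500),), True)
        a = self._assign(pm, [near, far], transcripts=[short_tx])
        assert a.evidence_tier != TIER_RNA_CONCORDANT

    def test_h3k4me3_tier(self):
        pm = mk_pm()
        marked = tc_at(4_000, tpm=2.0, tc_id="marked")
        plain = tc_at(1_000, tpm=50.0, tc_id="plain")
        pk = Peak(GenomicInterval("chr1", pm.five_prime - 4_100,
                                  pm.five_prime - 3_900, "."), 5.0)
        a = self._assign(pm, [plain, marked], peaks=[pk])
        assert a.evidence_tier == TIER_H3K4ME3 and a.tc.tc_id == "marked"

    def test_expression_fallback_and_unassigned(self):
        pm = mk_pm()
        a = self._assign(pm, [tc_at(1_000, tpm=3.0), tc_at(2_000, tpm=9.0)])
        assert a.evidence_tier == TIER_EXPRESSION and a.tc.total_tpm == 9.0
        assert self._assign(pm, []).evidence_tier == UNASSIGNED

    def test_tier_monotonicity_removing_transcript(self):
        pm = mk_pm()
        near = tc_at(1_000, tpm=50.0, tc_id="near")
        far = tc_at(4_000, tpm=2.0, tc_id="far")
        tx_start = pm.five_prime - 4_000
        tx = TranscriptModel("tx", "chr1", tx_start, HAIRPIN_START + 40, "+",
                             ((tx_start, HAIRPIN_START + 40),), True)
        with_tx = self._assign(pm, [near, far], transcripts=[tx])
        without = self._assign(pm, [near, far])
        assert with_tx.evidence_tier == TIER_RNA_CONCORDANT
        assert without.evidence_tier in (TIER_H3K4ME3, TIER_EXPRESSION)
        # SINGLE_TC cases are unaffected by transcript removal
        single_with = self._assign(pm, [near], transcripts=[tx])
        single_without = self._assign(pm, [near])
        assert single_with.evidence_tier == single_without.evidence_tier \
            == TIER_SINGLE_TC
        assert single_with.tss == single_without.tss


class TestIntragenic:
    def _host(self, five_prime_dist, coding=True, pm=None):
        pm = pm or mk_pm()
        h5 = pm.five_prime - five_prime_dist
        return TranscriptModel("host", "chr1", h5, HAIRPIN_START + 1_000, "+",
                               ((h5, HAIRPIN_START + 1_000),), coding)

    def test_noncoding_host_promoter_inherited(self):
        host = self._host(9_000, coding=False)
        pm = mk_pm(context=INTRAGENIC_NONCODING, host=host)
        a = assign_intragenic(pm, [], [], [], PARAMS)
        assert a.evidence_tier == TIER_NONCODING_HOST
        assert a.tss == host.five_prime_end and a.distance == 9_000

    def test_coding_host_independent_intronic_promoter(self):
        host = self._host(20_000)
        pm = mk_pm(context=INTRAGENIC_CODING, host=host)
        tc = tc_at(1_100, pm=pm)
        pk = Peak(GenomicInterval("chr1", pm.five_prime - 1_200,
                                  pm.five_prime - 1_000, "."), 5.0)
        a = assign_intragenic(pm, [tc], [], [pk], PARAMS)
        assert a.evidence_tier == TIER_SINGLE_TC and a.distance == 1_100

    def test_coding_host_proximal_fallback(self):
        host = self._host(3_000)
        pm = mk_pm(context=INTRAGENIC_CODING, host=host)
        a = assign_intragenic(pm, [], [], [], PARAMS)
        assert a.evidence_tier == TIER_HOST_PROMOTER and a.distance == 3_000

    def test_coding_host_distal_unassigned(self):
        host = self._host(9_000)
        pm = mk_pm(context=INTRAGENIC_CODING, host=host)
        a = assign_intragenic(pm, [], [], [], PARAMS)
        assert a.evidence_tier == UNASSIGNED

    def test_host_tss_tc_is_not_independent_evidence(self):
        host = self._host(3_000)
        pm = mk_pm(context=INTRAGENIC_CODING, host=host)
        host_tc = tc_at(3_000, tpm=40.0, pm=pm)  # exactly at host 5' end
        a = assign_intragenic(pm, [host_tc], [], [], PARAMS)
        assert a.evidence_tier == TIER_HOST_PROMOTER

    def test_missing_host_errors(self):
        pm = mk_pm(context=INTRAGENIC_CODING, host=None)
        with pytest.raises(ValueError):
            assign_intragenic(pm, [], [], [], PARAMS)


class TestAlternativePromoters:
    def _assignment(self, distance=10_000):
        pm = mk_pm()
        cand = tc_at(distance, pm=pm)
        cands, bound = candidate_tcs(pm, [cand], [], PARAMS)
        return assign_intergenic(pm, cands, bound, [], [], PARAMS), pm

    def test_offset_rule(self):
        a, pm = self._assignment()
        close = tc_at(9_700, pm=pm, tc_id="close")     # 300 b from TSS
        good = tc_at(4_000, pm=pm, tc_id="good")       # 6 kb from TSS
        outside = tc_at(12_000, pm=pm, tc_id="out")    # beyond assigned TSS
        alts = find_alternative_promoters(a, [a.tc, close, good, outside],
                                          PARAMS)
        assert [tc.tc_id for tc, _ in alts] == ["good"]
        assert alts[0][1] == 4_000

    def test_no_intermediate_tcs(self):
        a, _ = self._assignment()
        assert find_alternative_promoters(a, [a.tc], PARAMS) == []


class TestSearchBoundProperty:
    def test_assignments_respect_brute_force_region(self, small_params):
        """No assignment may fall outside the brute-force search region."""
        from primir import generate_bundle, run_bundle

        for seed in range(5):
            bundle = generate_bundle(small_params, seed=seed)
            res = run_bundle(bundle)
            for a in res["assignments"]:
                if not a.assigned or a.evidence_tier in (
                        TIER_HOST_PROMOTER, TIER_NONCODING_HOST):
                    continue
                pm = a.pre_mirna
                d = (pm.five_prime - a.tss if pm.strand != "-"
                     else a.tss - pm.five_prime)
                assert 1 <= d <= a.search_bound
                # brute force: region never exceeds 40 kb unless a coding
                # gene 3' end extends it
                if a.search_bound > 40_000:
                    ends = [g.three_prime_end for g in bundle.genes if g.coding]
                    assert any(abs(pm.five_prime - e) == a.search_bound
                               for e in ends)


def test_gene_level_percentage_arithmetic():
    stats = gene_level_stats(321, [59], 152)
    assert stats["n_genes"] == 263
    assert round(stats["percent_assigned"]) == 58
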