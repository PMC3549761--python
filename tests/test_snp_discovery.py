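import pytest

from rrsnp.errors import PreconditionError
from rrsnp.io_formats import MaskSet
from rrsnp.pileup import GroupScheme, PileupColumn
from rrsnp.snp_discovery import (
    CandidateSNP,
    FilterParams,
    FilterResult,
    audit_candidate,
    classify_autapomorphy,
    detect_candidates,
    extract_flanks,
    filter_candidate,
    mask_filter,
    pairwise_counts,
    select_one_per_contig,
    window_score,
)

PARAMS = FilterParams()
SCHEME2 = GroupScheme("subspecies", {"a1": "WS", "b1": "YS"})


def column(counts_by_individual, pos=100, contig="c1", indel=0, ambig=0):
    return PileupColumn(contig=contig, pos0=pos,
                       counts_by_individual=counts_by_individual,
                       indel_evidence=indel, ambiguous_evidence=ambig)


def candidate(pooled, group_counts, focal=None, pos=100, contig="c1",
              major=None, minor=None):
    acgt = {b: n for b, n in pooled.items() if b in "ACGT"}
    ranked = sorted(acgt, key=lambda b: (-acgt[b], b))
    return CandidateSNP(contig=contig, pos0=pos,
                        major_allele=major or ranked[0],
                        minor_allele=minor or ranked[1],
                        pooled_counts=pooled, group_counts=group_counts,
                        focal_group=focal)


class TestDetectCandidates:
    def test_monomorphic_skipped(self):
        cols = [column({"a1": {"A": 10}})]
        assert detect_candidates(cols, SCHEME2) == []

    def test_simple_biallelic(self):
        cols = [column({"a1": {"A": 9}, "b1": {"T": 1}})]
        (cand,) = detect_candidates(cols, SCHEME2)
        assert (cand.major_allele, cand.minor_allele) == ("A", "T")
        assert cand.pooled_counts == {"A": 9, "T": 1}
        assert cand.group_counts == {"WS": {"A": 9}, "YS": {"T": 1}}

    def test_tie_break_by_base_order(self):
        cols = [column({"a1": {"A": 5, "C": 5}})]
        (cand,) = detect_candidates(cols, SCHEME2)
        assert (cand.major_allele, cand.minor_allele) == ("A", "C")

    def test_n_calls_never_form_candidates(self):
        cols = [column({"a1": {"A": 5, "N": 5}})]
        assert detect_candidates(cols, SCHEME2) == []


class TestClassifyAutapomorphy:
    def test_unique_to_one_group(self):
        cand = candidate({"A": 30, "T": 19},
                         {"WS": {"T": 19}, "YS": {"A": 30}})
        assert classify_autapomorphy(cand, PARAMS, SCHEME2) == "WS"
        assert cand.focal_group == "WS"

    def test_spread_over_groups_rejected(self):
        cand = candidate({"A": 30, "T": 12},
                         {"WS": {"T": 10, "A": 10}, "YS": {"T": 2, "A": 20}})
        assert classify_autapomorphy(cand, PARAMS, SCHEME2) is None
        assert cand.focal_group is None

    def test_species_level_variant(self):
        scheme = GroupScheme("species", {"r1": "rainbow", "c1": "cutthroat"})
        cand = candidate({"G": 40, "C": 8},
                         {"rainbow": {"C": 8}, "cutthroat": {"G": 40}})
        assert classify_autapomorphy(cand, PARAMS, scheme) == "rainbow"

    def test_tolerance_rescues_stray_read(self):
        cand = candidate({"A": 30, "T": 11},
                         {"WS": {"T": 10}, "YS": {"T": 1, "A": 30}})
        assert classify_autapomorphy(cand, PARAMS, SCHEME2) is None
        relaxed = FilterParams(other_group_tolerance_reads=1)
        assert classify_autapomorphy(cand, relaxed, SCHEME2) == "WS"


def context_for(cand, depth_counts=None, contig_len=1000):
    """Minimal clean context: a single column at the candidate position."""
    counts = depth_counts or {"a1": {cand.major_allele: 10},
                              "b1": {cand.minor_allele: 10}}
    return {cand.pos0: column(counts, pos=cand.pos0)}, contig_len


class TestFilterCandidate:
    def test_requires_focal_group(self):
        cand = candidate({"A": 9, "T": 3}, {"WS": {"T": 3}, "YS": {"A": 9}})
        ctx, clen = context_for(cand)
        with pytest.raises(PreconditionError):
            filter_candidate(cand, ctx, clen, PARAMS)

    def test_c2_depth_boundary(self):
        for depth, expected in ((8, True), (7, False)):
            counts = {"a1": {"A": depth - 3}, "b1": {"T": 3}}
            cand = candidate({"A": depth - 3, "T": 3},
                             {"WS": {"A": depth - 3}, "YS": {"T": 3}},
                             focal="YS")
            ctx = {cand.pos0: column(counts, pos=cand.pos0)}
            result = filter_candidate(cand, ctx, 1000, PARAMS)
            assert result.passed("C2") is expected

    def test_c3_flank_boundaries(self):
        cand = candidate({"A": 9, "T": 3}, {"WS": {"T": 3}, "YS": {"A": 9}},
                         focal="WS", pos=50)
        ctx, _ = context_for(cand)
        assert filter_candidate(cand, ctx, 101, PARAMS).passed("C3")
        assert not filter_candidate(cand, ctx, 100, PARAMS).passed("C3")
        near = candidate({"A": 9, "T": 3}, {"WS": {"T": 3}, "YS": {"A": 9}},
                         focal="WS", pos=49)
        ctx49 = {near.pos0: column({"a1": {"A": 9}, "b1": {"T": 3}}, pos=49)}
        assert not filter_candidate(near, ctx49, 1000, PARAMS).passed("C3")

    def test_c3_dirty_neighborhood(self):
        cand = candidate({"A": 9, "T": 3}, {"WS": {"T": 3}, "YS": {"A": 9}},
                         focal="WS", pos=100)
        ctx = {100: column({"a1": {"A": 9}, "b1": {"T": 3}}, pos=100),
               115: column({"a1": {"A": 5}}, pos=115, indel=1)}
        assert not filter_candidate(cand, ctx, 1000, PARAMS).passed("C3")
        far = {100: column({"a1": {"A": 9}, "b1": {"T": 3}}, pos=100),
               125: column({"a1": {"A": 5}}, pos=125, indel=1)}
        assert filter_candidate(cand, far, 1000, PARAMS).passed("C3")

    def test_c4_exact_threshold_passes(self):
        # 3 / 75 = 4.0% with exactly 3 reads
        cand = candidate({"A": 72, "C": 3}, {"WS": {"C": 3}, "YS": {"A": 72}},
                         focal="WS")
        ctx = {cand.pos0: column({"a1": {"C": 3}, "b1": {"A": 72}},
                                 pos=cand.pos0)}
        assert filter_candidate(cand, ctx, 1000, PARAMS).passed("C4")

    def test_c4_three_percent_fails(self):
        cand = candidate({"A": 97, "C": 3}, {"WS": {"C": 3}, "YS": {"A": 97}},
                         focal="WS")
        ctx = {cand.pos0: column({"a1": {"C": 3}, "b1": {"A": 97}},
                                 pos=cand.pos0)}
        assert not filter_candidate(cand, ctx, 1000, PARAMS).passed("C4")

    def test_c5_identity_boundary_pair(self):
        passing = candidate({"A": 40, "C": 19},
                            {"WS": {"C": 19, "A": 1}, "YS": {"A": 39}},
                            focal="WS")
        ctx, clen = context_for(passing)
        assert filter_candidate(passing, ctx, clen, PARAMS).passed("C5")
        failing = candidate({"A": 40, "C": 18},
                            {"WS": {"C": 18, "A": 2}, "YS": {"A": 38}},
                            focal="WS")
        ctx, clen = context_for(failing)
        assert not filter_candidate(failing, ctx, clen, PARAMS).passed("C5")

    def test_all_verdicts_recorded_independently(self):
        # fails C2 and C4, but C3/C5 verdicts are still present
        cand = candidate({"A": 4, "T": 1}, {"WS": {"T": 1}, "YS": {"A": 4}},
                         focal="WS")
        ctx = {cand.pos0: column({"a1": {"T": 1}, "b1": {"A": 4}},
                                 pos=cand.pos0)}
        result = filter_candidate(cand, ctx, 1000, PARAMS)
        assert set(result.per_criterion) == {"C2", "C3", "C4", "C5"}
        assert not result.passed("C2")
        assert not result.passed("C4")
        assert result.passed("C3")
        assert result.passed("C5")
        assert not result.final


class TestWindowScore:
    def cand(self):
        return candidate({"A": 9, "T": 3}, {"WS": {"T": 3}, "YS": {"A": 9}})

    def test_no_neighbors(self):
        assert window_score(self.cand(), [], PARAMS) == (0, True)

    def test_two_close_neighbors_reject(self):
        score, ok = window_score(self.cand(), [3, 4], PARAMS)
        assert score == 6
        assert not ok

    def test_distant_neighbor_passes(self):
        score, ok = window_score(self.cand(), [12], PARAMS)
        assert score == 1
        assert ok

    def test_band_weights(self):
        assert window_score(self.cand(), [5, 6, 10, 11, 20], PARAMS)[0] == \
            3 + 2 + 2 + 1 + 1

    def test_distance_zero_is_error(self):
        with pytest.raises(PreconditionError):
            window_score(self.cand(), [0], PARAMS)

    def test_distance_beyond_radius_is_error(self):
        with pytest.raises(PreconditionError):
            window_score(self.cand(), [21], PARAMS)


class TestMaskFilter:
    def test_half_open_containment(self):
        masks = MaskSet(intervals={"c1": [(100, 200)]}).normalized()
        inside = candidate({"A": 5, "T": 3}, {}, pos=100)
        outside = candidate({"A": 5, "T": 3}, {}, pos=99)
        assert not mask_filter(inside, masks)
        assert mask_filter(outside, masks)

    def test_mtdna_contig_fails(self):
        masks = MaskSet(mtdna_contigs={"mt1"}).normalized()
        cand = candidate({"A": 5, "T": 3}, {}, contig="mt1", pos=500)
        assert not mask_filter(cand, masks)


def _passing_result(contig, pos, depth):
    n_minor = max(3, depth // 4)
    cand = candidate({"A": depth - n_minor, "T": n_minor},
                     {"WS": {"T": n_minor}, "YS": {"A": depth - n_minor}},
                     focal="WS", pos=pos, contig=contig)
    return FilterResult(candidate=cand)


class TestSelectOnePerContig:
    REF = {"c1": "ACGT" * 200, "c2": "ACGT" * 200, "c3": "ACGT" * 200}

    def test_highest_depth_wins(self):
        results = [_passing_result("c1", 100, 20), _passing_result("c1", 300, 25)]
        loci = select_one_per_contig(results, self.REF, PARAMS)
        assert [l.candidate.pos0 for l in loci] == [300]

    def test_tie_breaks_leftmost(self):
        results = [_passing_result("c1", 400, 20), _passing_result("c1", 50, 20)]
        loci = select_one_per_contig(results, self.REF, PARAMS)
        assert [l.candidate.pos0 for l in loci] == [50]

    def test_one_locus_per_contig(self):
        results = [_passing_result("c1", 100, 10), _passing_result("c1", 200, 12),
                   _passing_result("c2", 100, 10),
                   _passing_result("c3", 100, 10), _passing_result("c3", 200, 11),
                   _passing_result("c3", 300, 12)]
        loci = select_one_per_contig(results, self.REF, PARAMS)
        assert len(loci) == 3
        assert len({l.candidate.contig for l in loci}) == 3


class TestExtractFlanks:
    REF = "".join("ACGT"[i % 4] for i in range(200))

    def test_boundary_placement(self):
        cand = candidate({"A": 5, "G": 3}, {}, pos=50)
        left, right, _ = extract_flanks(cand, self.REF, 50)
        assert left == self.REF[:50]
        assert right == self.REF[51:101]

    def test_bracket_format(self):
        cand = candidate({"A": 5, "G": 3}, {}, pos=100, major="A", minor="G")
        _, _, context = extract_flanks(cand, self.REF, 50)
        assert "[A/G]" in context
        assert context == self.REF[50:100] + "[A/G]" + self.REF[101:151]

    def test_overrun_is_error(self):
        cand = candidate({"A": 5, "G": 3}, {}, pos=49)
        with pytest.raises(PreconditionError):
            extract_flanks(cand, self.REF, 50)


class TestPairwiseCounts:
    SCHEME3 = GroupScheme("subspecies", {"a1": "A", "b1": "B", "c1": "C"})

    def test_single_diagnostic_snp(self):
        cand = candidate({"G": 20, "T": 10},
                         {"A": {"T": 10}, "B": {"G": 10}, "C": {"G": 10}},
                         focal="A")
        matrix = pairwise_counts([cand], self.SCHEME3)
        assert matrix.loc["A", "B"] == 1
        assert matrix.loc["A", "C"] == 1
        assert matrix.values.sum() == 2

    def test_empty_input_zero_matrix(self):
        matrix = pairwise_counts([], self.SCHEME3)
        assert (matrix.values == 0).all()

    def test_row_sums_by_focal_group(self):
        def snp(focal, other_counts):
            gc = {focal: {"T": 10}}
            gc.update(other_counts)
            return candidate({"G": 20, "T": 10}, gc, focal=focal)

        cands = [
            snp("A", {"B": {"G": 10}, "C": {"G": 10}}),
            snp("A", {"B": {"G": 10}, "C": {"G": 10}}),
            snp("B", {"A": {"G": 10}, "C": {"G": 10}}),
        ]
        matrix = pairwise_counts(cands, self.SCHEME3)
        assert matrix.loc["A"].sum() == 4
        assert matrix.loc["B"].sum() == 2
        assert matrix.loc["C"].sum() == 0

    def test_no_coverage_in_other_group_not_counted(self):
        cand = candidate({"G": 20, "T": 10},
                         {"A": {"T": 10}, "B": {"G": 20}}, focal="A")
        matrix = pairwise_counts([cand], self.SCHEME3)
        assert matrix.loc["A", "B"] == 1
        assert matrix.loc["A", "C"] == 0


class TestAuditTrail:
    def test_audit_records_every_criterion(self):
        scheme = SCHEME2
        cand = candidate({"A": 2, "T": 1}, {"WS": {"T": 1}, "YS": {"A": 2}})
        ctx = {cand.pos0: column({"a1": {"T": 1}, "b1": {"A": 2}},
                                 pos=cand.pos0)}
        masks = MaskSet().normalized()
        result = audit_candidate(cand, ctx, 1000, masks, PARAMS, scheme)
        assert set(result.per_criterion) == {"C1", "C2", "C3", "C4", "C5",
                                             "C6", "W"}
        assert result.passed("C1")
        assert not result.passed("C2")
        assert result.passed("C6")
        assert result.passed("W")
        assert not result.final
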