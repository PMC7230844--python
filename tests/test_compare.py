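"""Locus comparator, pair tallies, queue comparison and scope selection."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ssrbank.compare import (
    Assignment,
    LocusClass,
    Mode,
    classify_locus,
    compare_pair,
    fcpp,
    filter_results,
    gca,
    read_assignment,
    results_to_frame,
    select_scope,
)
from ssrbank.core import ComparisonParams, ComparisonResult, LocusGenotype, make_genotype
from conftest import fp


def g(a, b, marker="M1"):
    return make_genotype(marker, [a, b])


def brute_force_gca(g1, g2, n):
    """Independent oracle: enumerate both allele pairings explicitly."""
    a1, b1 = g1.alleles
    a2, b2 = g2.alleles
    for (x1, y1), (x2, y2) in [((a1, b1), (a2, b2)), ((a1, b1), (b2, a2))]:
        if abs(x1 - x2) <= n and abs(y1 - y2) <= n:
            return 0
    return 1


class TestGca:
    @pytest.mark.parametrize("g1,g2,n,expect", [
        (g(100, 102), g(101, 103), 2, 0),   # direct pairing within offset
        (g(100, 104), g(104, 100), 0, 0),   # crossed pairing, exact
        (g(100, 110), g(104, 106), 2, 1),   # every pairing exceeds offset
        (g(150, 150), g(150, 150), 0, 0),   # identity
    ])
    def test_known_cases(self, g1, g2, n, expect):
        assert gca(g1, g2, n) == expect

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError):
            gca(LocusGenotype("M1"), g(100, 102), 2)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            gca(g(100, 102), g(100, 102), -1)

    @given(
        a1=st.integers(100, 110), b1=st.integers(100, 110),
        a2=st.integers(100, 110), b2=st.integers(100, 110),
        n=st.sampled_from([0, 1, 2]),
    )
    @settings(max_examples=300, derandomize=True)
    def test_symmetric_and_matches_bruteforce(self, a1, b1, a2, b2, n):
        g1, g2 = g(a1, b1), g(a2, b2)
        assert gca(g1, g2, n) == gca(g2, g1, n) == brute_force_gca(g1, g2, n)

    @given(
        a1=st.integers(100, 110), b1=st.integers(100, 110),
        a2=st.integers(100, 110), b2=st.integers(100, 110),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_offset(self, a1, b1, a2, b2):
        g1, g2 = g(a1, b1), g(a2, b2)
        # once same at offset n, same at every larger offset
        for n in range(4):
            if gca(g1, g2, n) == 0:
                assert all(gca(g1, g2, n2) == 0 for n2 in range(n, 5))


class TestClassify:
    def test_missing_side_wins(self):
        assert classify_locus(LocusGenotype("M1"), g(100, 102), 2) is LocusClass.MISSING

    def test_same_and_different(self):
        assert classify_locus(g(100, 102), g(101, 103), 2) is LocusClass.SAME
        assert classify_locus(g(100, 100), g(120, 120), 2) is LocusClass.DIFFERENT

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_locus(g(100, 102), g(100, 102, marker="M2"), 2)


class TestComparePair:
    def test_mixed_classes_tally(self):
        f1 = fp("P", {"L1": None, "L2": (100, 100), "L3": (100, 102),
                      "L4": (150, 152), "L5": (200, 204)})
        f2 = fp("R", {"L1": (100, 102), "L2": (120, 120), "L3": (101, 103),
                      "L4": (150, 150), "L5": (200, 204)})
        r = compare_pair(f1, f2, ComparisonParams())
        assert (r.p, r.D, r.S, r.M, r.x) == (5, 1, 3, 1, 0.2)

    def test_identical_fingerprints(self, trio):
        r = compare_pair(trio[0], trio[0])
        assert (r.D, r.M, r.S, r.x) == (0, 0, trio[0].p, 0.0)

    def test_all_missing_one_side(self):
        f1 = fp("P", {"L1": None, "L2": None})
        f2 = fp("R", {"L1": (100, 100), "L2": (100, 100)})
        r = compare_pair(f1, f2)
        assert (r.D, r.S, r.M, r.x) == (0, 0, 2, 0.0)

    def test_panel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            compare_pair(fp("P", {"L1": (100, 100)}), fp("R", {"L2": (100, 100)}))

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_conservation_invariant(self, data):
        markers = [f"L{t}" for t in range(6)]
        def geno(m):
            if data.draw(st.booleans(), label=f"missing-{m}"):
                return None
            a = data.draw(st.integers(100, 110), label=f"a-{m}")
            b = data.draw(st.integers(100, 110), label=f"b-{m}")
            return (a, b)
        f1 = fp("P", {m: geno(m) for m in markers})
        f2 = fp("R", {m: geno(m) for m in markers})
        r = compare_pair(f1, f2)
        assert r.p == r.D + r.S + r.M
        assert r.x == r.D / r.p


class TestFcpp:
    def test_result_count_is_m_times_n(self, trio):
        results = fcpp(trio[:2], trio, ComparisonParams())
        assert len(results) == 2 * 3

    def test_self_comparison_single(self, trio):
        results = fcpp([trio[0]], [trio[0]])
        assert len(results) == 1 and results[0].D == 0

    def test_reference_major_order(self, trio):
        results = fcpp(trio[:2], trio)
        order = [(r.id_pending, r.id_reference) for r in results]
        assert order == [("A", "A"), ("B", "A"), ("A", "B"), ("B", "B"),
                         ("A", "C"), ("B", "C")]

    def test_diffcounts_match_independent_tally(self, trio):
        params = ComparisonParams()
        for r in fcpp(trio, trio, params):
            f1 = next(f for f in trio if f.entity_id == r.id_pending)
            f2 = next(f for f in trio if f.entity_id == r.id_reference)
            diff = sum(
                1
                for m in f1.markers
                if not f1.genotypes[m].is_missing
                and not f2.genotypes[m].is_missing
                and brute_force_gca(f1.genotypes[m], f2.genotypes[m], 2.0) == 1
            )
            assert r.D == diff

    def test_empty_queue_rejected(self, trio):
        with pytest.raises(ValueError):
            fcpp([], trio)


class TestFilter:
    def make(self, p, D, M):
        return ComparisonResult.from_counts("a", "b", p, D, p - D - M, M)

    def test_default_filters(self):
        params = ComparisonParams()
        assert filter_results([self.make(400, 25, 0)], params) == []   # D > 20
        assert filter_results([self.make(40, 0, 30)], params) == []    # p-M < 20
        kept = filter_results([self.make(40, 0, 0)], params)
        assert len(kept) == 1

    def test_fraction_filter(self):
        params = ComparisonParams()
        # D=20 passes the count filter but x=20/100 > 0.05
        assert filter_results([self.make(100, 20, 0)], params) == []


class TestSelectScope:
    def lfd(self):
        base = {"M1": (100, 102)}
        return [
            fp(f"db{t}", base, name=("Golden" if t < 3 else f"var{t}"))
            for t in range(10)
        ]

    def test_homonymy_partitions_database(self):
        lfd = self.lfd()
        pending = [fp("q", {"M1": (100, 102)}, name="Golden")]
        hom = select_scope(Mode.HOMONYMY, lfd, pending)
        non = select_scope(Mode.NON_HOMONYMY, lfd, pending)
        assert len(hom.reference) == 3 and len(non.reference) == 7
        ids = {f.entity_id for f in hom.reference} | {f.entity_id for f in non.reference}
        assert ids == {f.entity_id for f in lfd}
        assert not ({f.entity_id for f in hom.reference}
                    & {f.entity_id for f in non.reference})

    def test_synonym_matching(self):
        lfd = [fp("db0", {"M1": (100, 102)}, name="other", synonyms=["Golden "])]
        pending = [fp("q", {"M1": (100, 102)}, name="Golden")]
        plan = select_scope(Mode.HOMONYMY, lfd, pending)
        assert len(plan.reference) == 1

    def test_database_mode_uses_whole_lfd(self):
        lfd = self.lfd()
        plan = select_scope(Mode.DATABASE, lfd, [fp("q", {"M1": (100, 102)})])
        assert len(plan.reference) == 10

    def test_empty_lfd_rejected(self):
        with pytest.raises(ValueError):
            select_scope(Mode.DATABASE, [], [fp("q", {"M1": (100, 102)})])

    def test_paired_explicit_pairs(self):
        lfd = self.lfd()
        pending = [fp("q1", {"M1": (100, 102)}), fp("q2", {"M1": (100, 104)})]
        a = Assignment(pairs=(("q1", "db0"), ("q1", "db1"), ("q2", "db2"), ("q2", "db3")))
        plan = select_scope(Mode.PAIRED, lfd, pending, a)
        assert len(plan.run()) == 4

    def test_assignment_contract(self):
        lfd = self.lfd()
        with pytest.raises(ValueError, match="requires"):
            select_scope(Mode.PAIRED, lfd, [])
        with pytest.raises(ValueError, match="forbids"):
            select_scope(Mode.DATABASE, lfd, [], Assignment())


class TestAssignmentIO:
    def test_paired_roundtrip(self, tmp_path):
        f = tmp_path / "pairs.csv"
        f.write_text("pending_id,reference_id\nq1,db0\nq2,db1\n")
        a = read_assignment(f, Mode.PAIRED)
        assert a.pairs == (("q1", "db0"), ("q2", "db1"))

    def test_sub_database_roles(self, tmp_path):
        f = tmp_path / "sub.csv"
        f.write_text("member_id,role\nq1,PENDING\ndb0,REFERENCE\ndb1,reference\n")
        a = read_assignment(f, Mode.SUB_DATABASE)
        assert a.pending_ids == ("q1",) and a.reference_ids == ("db0", "db1")


def test_report_frame_columns(trio):
    frame = results_to_frame(fcpp(trio, trio))
    assert list(frame.columns) == [
        "pending_id", "reference_id", "p", "D", "S", "M", "x", "verdict"
    ]
    assert (frame.loc[frame.pending_id == frame.reference_id, "verdict"] == "match").all()
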