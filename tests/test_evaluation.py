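import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from appraise.evaluation import (
    DistanceMatrix,
    DistanceScheme,
    SystemOutput,
    blau_index,
    build_distance_matrix,
    distinct_recommendation_sets,
    evaluation_summary,
    overlap_concordance,
    recset_distance,
    system_distance_matrix,
    upgma_tree,
)


class TestBlau:
    def test_printed_cpg_value(self):
        assert round(blau_index([31, 1]), 2) == 0.06

    def test_single_category_zero(self):
        assert blau_index([32]) == 0.0

    def test_uniform_eight_categories(self):
        assert blau_index([4] * 8) == pytest.approx(0.875)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            blau_index([0, 0])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1).filter(lambda c: sum(c) > 0))
    def test_range_and_relabeling(self, counts):
        b = blau_index(counts)
        assert 0.0 <= b < 1.0
        assert blau_index(list(reversed(counts))) == pytest.approx(b)

    def test_splitting_singleton_increases_diversity(self):
        assert blau_index([31, 1]) > blau_index([32])
        assert blau_index([30, 1, 1]) > blau_index([31, 1])


class TestDistinctSets:
    def test_counting(self):
        out = SystemOutput("s", (frozenset({"A"}), frozenset({"A"}), frozenset({"B"})))
        assert distinct_recommendation_sets(out) == [2, 1]

    def test_all_empty_one_category(self):
        out = SystemOutput("s", (frozenset(),) * 5)
        assert distinct_recommendation_sets(out) == [5]

    def test_permutation_invariance(self):
        sets = (frozenset({"A"}), frozenset({"B"}), frozenset({"A"}), frozenset())
        a = distinct_recommendation_sets(SystemOutput("s", sets))
        b = distinct_recommendation_sets(SystemOutput("s", sets[::-1]))
        assert a == b

    def test_summary_table(self):
        out = SystemOutput("s", tuple(frozenset({"A"}) for _ in range(31)) + (frozenset({"B"}),))
        table = evaluation_summary([out])
        assert table.loc[0, "distinct_recommendations"] == 2
        assert table.loc[0, "blau_index"] == 0.06


class TestOverlap:
    def test_identical_outputs_100(self):
        sets = (frozenset({"A"}), frozenset({"B"}))
        assert overlap_concordance(SystemOutput("x", sets), SystemOutput("y", sets)) == 100.0

    def test_disjoint_outputs_0(self):
        a = SystemOutput("x", (frozenset({"A"}),) * 4)
        b = SystemOutput("y", (frozenset({"B"}),) * 4)
        assert overlap_concordance(a, b) == 0.0

    def test_printed_arithmetic(self):
        # 32 patients, 16 favorable, 7 of those overlapping
        tdapp = SystemOutput(
            "tdapp",
            tuple(frozenset({"M"}) for _ in range(7))
            + tuple(frozenset({"X"}) for _ in range(9))
            + (frozenset(),) * 16,
        )
        cpg = SystemOutput("cpg", (frozenset({"M"}),) * 32)
        assert round(overlap_concordance(tdapp, cpg, "all_patients"), 1) == 21.9
        assert round(overlap_concordance(tdapp, cpg, "favorable_only"), 1) == 43.8

    def test_denominator_identity(self):
        # all = favorable_only * favorable fraction when non-favorable never overlap
        tdapp = SystemOutput(
            "tdapp",
            tuple(frozenset({"M"}) for _ in range(5))
            + tuple(frozenset({"X"}) for _ in range(5))
            + (frozenset(),) * 10,
        )
        cpg = SystemOutput("cpg", (frozenset({"M"}),) * 20)
        all_p = overlap_concordance(tdapp, cpg, "all_patients")
        fav = overlap_concordance(tdapp, cpg, "favorable_only")
        assert all_p == pytest.approx(fav * (10 / 20))

    def test_zero_favorable_error(self):
        a = SystemOutput("x", (frozenset(),) * 3)
        b = SystemOutput("y", (frozenset({"A"}),) * 3)
        with pytest.raises(ValueError, match="favorable"):
            overlap_concordance(a, b, "favorable_only")

    def test_cohort_mismatch(self):
        with pytest.raises(ValueError, match="cohort"):
            overlap_concordance(
                SystemOutput("x", (frozenset(),)), SystemOutput("y", (frozenset(),) * 2)
            )


class TestDistanceMatrix:
    @pytest.fixture(scope="class")
    def matrix(self):
        return build_distance_matrix()

    @pytest.mark.parametrize(
        "other,expected",
        [
            ("dexmethylphenidate", 1.0),
            ("bupropion", 7.0),
            ("atomoxetine", 15.0),
            ("guanfacine", 19.0),
            ("no_treatment", 33.0),
        ],
    )
    def test_anchor_distances(self, matrix, other, expected):
        assert matrix.distance("methylphenidate", other) == expected

    def test_axioms(self, matrix):
        v = matrix.values
        assert np.allclose(np.diag(v), 0.0)
        assert np.allclose(v, v.T)
        assert v.max() == 33.0 and (v >= 0).all()

    def test_no_treatment_maximal(self, matrix):
        for code in matrix.codes:
            if code != "no_treatment":
                assert matrix.distance(code, "no_treatment") == 33.0

    def test_deterministic_regeneration(self, matrix):
        again = build_distance_matrix()
        assert again.codes == matrix.codes
        assert np.array_equal(again.values, matrix.values)

    def test_scheme_bound_enforced(self):
        with pytest.raises(ValueError, match="bound"):
            build_distance_matrix(scheme=DistanceScheme(w_target=40.0))

    def test_csv_round_trip(self, matrix, tmp_path):
        matrix.to_csv(tmp_path / "dist.csv")
        again = DistanceMatrix.from_csv(tmp_path / "dist.csv")
        assert again.codes == matrix.codes
        assert np.allclose(again.values, matrix.values)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(codes=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(codes=["a", "b"], values=np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestRecsetDistance:
    @pytest.fixture(scope="class")
    def matrix(self):
        return build_distance_matrix()

    def test_identity(self, matrix):
        assert recset_distance({"methylphenidate"}, {"methylphenidate"}, matrix) == 0.0

    def test_empty_set_is_no_treatment(self, matrix):
        assert recset_distance(set(), {"methylphenidate"}, matrix) == 33.0
        assert recset_distance(set(), set(), matrix) == 0.0

    def test_hand_computation(self, matrix):
        # brute-force modified Hausdorff over the packaged matrix
        a, b = {"methylphenidate", "atomoxetine"}, {"dexmethylphenidate"}
        fwd = np.mean([min(matrix.distance(x, y) for y in b) for x in a])
        bwd = np.mean([min(matrix.distance(y, x) for x in a) for y in b])
        assert recset_distance(a, b, matrix) == pytest.approx((fwd + bwd) / 2)
        assert recset_distance(a, b, matrix) == pytest.approx(
            ((1.0 + 15.0) / 2 + 1.0) / 2
        )

    def test_symmetry(self, matrix):
        a, b = {"methylphenidate", "guanfacine"}, {"atomoxetine", "clonidine"}
        assert recset_distance(a, b, matrix) == pytest.approx(recset_distance(b, a, matrix))

    def test_unknown_drug_named(self, matrix):
        with pytest.raises(KeyError, match="aspirin"):
            recset_distance({"aspirin"}, {"methylphenidate"}, matrix)


class TestSystemDistance:
    @pytest.fixture(scope="class")
    def matrix(self):
        return build_distance_matrix()

    def test_duplicate_system_zero(self, matrix):
        sets = (frozenset({"methylphenidate"}),) * 4
        m = system_distance_matrix(
            [SystemOutput("a", sets), SystemOutput("b", sets)], matrix
        )
        assert m.distance("a", "b") == 0.0

    def test_single_patient_difference(self, matrix):
        base = [frozenset({"methylphenidate"})] * 32
        other = list(base)
        other[5] = frozenset()  # distance 33 via the no-treatment convention
        m = system_distance_matrix(
            [SystemOutput("a", tuple(base)), SystemOutput("b", tuple(other))], matrix
        )
        assert m.distance("a", "b") == pytest.approx(33.0 / 32)

    def test_patient_permutation_invariance(self, matrix):
        rng = np.random.default_rng(4)
        drugs = ["methylphenidate", "atomoxetine", "guanfacine"]
        sets_a = tuple(frozenset({rng.choice(drugs)}) for _ in range(10))
        sets_b = tuple(frozenset({rng.choice(drugs)}) for _ in range(10))
        perm = rng.permutation(10)
        m1 = system_distance_matrix([SystemOutput("a", sets_a), SystemOutput("b", sets_b)], matrix)
        m2 = system_distance_matrix(
            [SystemOutput("a", tuple(sets_a[i] for i in perm)),
             SystemOutput("b", tuple(sets_b[i] for i in perm))], matrix
        )
        assert m1.distance("a", "b") == pytest.approx(m2.distance("a", "b"))

    def test_cohort_mismatch_rejected(self, matrix):
        with pytest.raises(ValueError, match="cohort"):
            system_distance_matrix(
                [SystemOutput("a", (frozenset(),)), SystemOutput("b", (frozenset(),) * 2)],
                matrix,
            )


class TestUPGMA:
    def test_three_system_manual_agglomeration(self):
        d = DistanceMatrix(
            codes=["A", "B", "C"],
            values=np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]]),
        )
        tree = upgma_tree(d)
        assert tree.heights == [1.0, 10.0]
        assert tree.merges[0].members == {"A", "B"}
        assert tree.newick == "((A:0.5,B:0.5):4.5,C:5);"

    def test_weighted_average_linkage(self):
        # after merging A,B the distance to C is the size-weighted mean
        d = DistanceMatrix(
            codes=["A", "B", "C"],
            values=np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 10.0], [6.0, 10.0, 0.0]]),
        )
        tree = upgma_tree(d)
        assert tree.heights == [2.0, 8.0]  # (6 + 10) / 2

    def test_two_systems(self):
        d = DistanceMatrix(codes=["A", "B"], values=np.array([[0.0, 7.0], [7.0, 0.0]]))
        tree = upgma_tree(d)
        assert tree.heights == [7.0]
        assert tree.newick == "(A:3.5,B:3.5);"

    def test_duplicate_leaf_merges_at_zero(self):
        d = DistanceMatrix(
            codes=["A", "A2", "B"],
            values=np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 5.0], [5.0, 5.0, 0.0]]),
        )
        tree = upgma_tree(d)
        assert tree.heights[0] == 0.0
        assert tree.merges[0].members == {"A", "A2"}

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=7), st.integers(min_value=0, max_value=10_000))
    def test_heights_nondecreasing_on_random_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 33.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        tree = upgma_tree(DistanceMatrix(codes=[f"s{i}" for i in range(n)], values=m))
        heights = tree.heights
        assert all(a <= b + 1e-9 for a, b in zip(heights, heights[1:]))
        assert len(heights) == n - 1

    def test_lexicographic_tie_breaking(self):
        d = DistanceMatrix(
            codes=["C", "B", "A"],
            values=np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]]),
        )
        tree = upgma_tree(d)
        assert tree.merges[0].members == {"A", "B"}
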