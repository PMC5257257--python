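"""IGTIOB score, cross-screen matrix assembly, clustering and median/SEM."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtscreen.annotation import GeneModel
from gtscreen.compare import (
    ComparisonMatrix,
    _complete_linkage_merges,
    build_comparison_matrix,
    clip_for_display,
    cluster_genes,
    complete_linkage_order,
    igtiob,
    median_sem,
)
from gtscreen.mapping import InsertionSite
from gtscreen.stats import analyze_screen


class TestIgtiob:
    def test_no_intronic_insertions_scores_zero(self):
        assert igtiob(0, 0) == 0.0

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_symmetric_counts_score_zero(self, k):
        assert igtiob(k, k) == 0.0

    def test_sense_only_closed_form(self):
        assert igtiob(3, 0) == pytest.approx(math.log2(4) * math.log(4))
        assert igtiob(3, 0) == pytest.approx(2.772589, abs=1e-6)

    def test_antisense_only_is_negated(self):
        assert igtiob(0, 3) == pytest.approx(-2.772589, abs=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50))
    def test_antisymmetry(self, a, b):
        assert igtiob(a, b) == pytest.approx(-igtiob(b, a), abs=1e-12)

    def test_sign_tracks_count_difference(self):
        assert igtiob(5, 2) > 0 > igtiob(2, 5)

    def test_magnitude_increases_with_sense_only_evidence(self):
        scores = [abs(igtiob(s, 0)) for s in range(1, 30)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            igtiob(-1, 0)


class TestMedianSem:
    def test_zero_variance(self):
        assert median_sem([5, 5, 5, 5]) == (5.0, 0.0)

    def test_five_point_example(self):
        med, sem = median_sem([1, 2, 3, 4, 5])
        assert med == 3.0
        assert sem == pytest.approx(1.253 * np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5))
        assert sem == pytest.approx(0.8861, abs=1e-4)

    def test_order_invariance(self):
        assert median_sem([3, 1, 4, 1, 5]) == median_sem([1, 1, 3, 4, 5])

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            median_sem([1.0])


def scipy_leaf_order(rows):
    """Independent complete-linkage/cityblock leaf order via scipy."""
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import pdist

    return list(leaves_list(linkage(pdist(rows, metric="cityblock"), method="complete")))


def scipy_merge_heights(rows):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    return sorted(linkage(pdist(rows, metric="cityblock"), method="complete")[:, 2])


class TestClusterGenes:
    def test_identical_rows_merge_first_at_distance_zero(self):
        rows = np.array([[1.0, 2.0], [5.0, 9.0], [1.0, 2.0]])
        order, merges = _complete_linkage_merges(rows)
        d, a, b = merges[0]
        assert d == 0.0 and {a, b} == {frozenset({0}), frozenset({2})}

    def test_hand_traced_merge_order(self):
        # L1 distances: d(0,1)=3, d(0,2)=20, d(1,2)=17 -> (0,1) merge first
        rows = np.array([[0.0, 0.0], [0.0, 3.0], [10.0, 10.0]])
        order, merges = _complete_linkage_merges(rows)
        assert merges[0][0] == 3.0
        assert merges[0][1] | merges[0][2] == frozenset({0, 1})
        assert order == [0, 1, 2]

    def test_single_row_identity(self):
        assert complete_linkage_order(np.array([[1.0, 2.0]])) == [0]

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_scipy_on_tie_free_inputs(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.normal(size=(rng.integers(3, 9), 4))
        assert scipy_merge_heights(rows) == pytest.approx(
            sorted(m[0] for m in _complete_linkage_merges(rows)[1])
        )
        # merge partitions must coincide when all pairwise distances differ
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        Z = linkage(pdist(rows, metric="cityblock"), method="complete")
        n = rows.shape[0]
        members = {i: frozenset({i}) for i in range(n)}
        scipy_merges = []
        for i, (a, b, d, _) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            scipy_merges.append((round(d, 9), merged))
        ours = [
            (round(d, 9), a | b) for d, a, b in _complete_linkage_merges(rows)[1]
        ]
        assert sorted(scipy_merges) == sorted(ours)

    def test_leaf_order_stable_under_row_permutation(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(7, 3))
        order = complete_linkage_order(rows)
        perm = rng.permutation(7)
        order_p = complete_linkage_order(rows[perm])
        # permuted clustering visits the same leaves grouped identically
        assert sorted(order_p) == list(range(7))
        groups = [frozenset(perm[i] for i in order_p)]
        assert groups == [frozenset(range(7))]
        # adjacency of the first merged pair is preserved up to relabeling
        d0, a0, b0 = _complete_linkage_merges(rows)[1][0]
        dp, ap, bp = _complete_linkage_merges(rows[perm])[1][0]
        assert d0 == pytest.approx(dp)
        assert {frozenset(int(perm[i]) for i in ap | bp)} == {a0 | b0}


def make_screen(screen_id, gene_sites, control_sites, genes):
    return analyze_screen(gene_sites, control_sites, genes, screen_id=screen_id)


@pytest.fixture
def two_screens():
    """Two screens over three genes; GENE_A strongly enriched in screen 1."""
    genes = [
        GeneModel("GENE_A", "chr1", "+", 0, 10_000, ((0, 100),)),
        GeneModel("GENE_B", "chr1", "+", 20_000, 30_000, ((20_000, 20_100),)),
        GeneModel("GENE_C", "chr1", "+", 40_000, 50_000, ((40_000, 40_100),)),
    ]
    control = (
        [InsertionSite("chr1", 500 + 11 * i, "+") for i in range(4)]
        + [InsertionSite("chr1", 25_000 + 11 * i, "+") for i in range(40)]
        + [InsertionSite("chr1", 45_000 + 11 * i, "-") for i in range(40)]
    )
    # screen 1 sorted: many sense-intronic GENE_A insertions
    s1_sorted = [InsertionSite("chr1", 200 + 7 * i, "+") for i in range(30)]
    # screen 2 sorted: a couple of scattered insertions, nothing enriched
    s2_sorted = [InsertionSite("chr1", 25_000, "+"), InsertionSite("chr1", 45_000, "+")]
    return (
        make_screen("s1", s1_sorted, control, genes),
        make_screen("s2", s2_sorted, control, genes),
    )


class TestBuildComparisonMatrix:
    def test_inclusion_requires_one_stringent_screen(self, two_screens):
        s1, s2 = two_screens
        assert s1["GENE_A"].fdr_q < 1e-4
        matrix = build_comparison_matrix([s1, s2])
        assert matrix.gene_ids == ["GENE_A"]
        assert matrix.included_by["GENE_A"] == "s1"
        # score reported for every screen, including the non-qualifying one
        assert matrix.scores.shape == (1, 2)

    def test_gene_above_threshold_everywhere_is_excluded(self, two_screens):
        s1, s2 = two_screens
        strict = build_comparison_matrix([s1, s2], threshold=1e-30)
        assert strict.gene_ids == []

    def test_inclusion_monotone_in_threshold(self, two_screens):
        s1, s2 = two_screens
        loose = build_comparison_matrix([s1, s2], threshold=0.9)
        tight = build_comparison_matrix([s1, s2], threshold=1e-4)
        assert set(tight.gene_ids) <= set(loose.gene_ids)

    def test_absent_gene_scores_zero(self, two_screens):
        s1, s2 = two_screens
        matrix = build_comparison_matrix([s1, s2], threshold=0.9)
        i = matrix.gene_ids.index("GENE_A")
        j = matrix.screen_ids.index("s2")
        a_counts = s2["GENE_A"].counts
        assert (a_counts.S_raw, a_counts.A_raw) == (0, 0)
        assert matrix.scores[i, j] == 0.0

    def test_fewer_than_two_screens_rejected(self, two_screens):
        with pytest.raises(ValueError):
            build_comparison_matrix([two_screens[0]])

    def test_empty_matrix_is_not_an_error(self, two_screens):
        m = build_comparison_matrix(list(two_screens), threshold=1e-30)
        assert m.n_genes == 0 and m.gene_order == []


class TestClipForDisplay:
    def test_negative_scores_displayed_as_zero(self):
        m = ComparisonMatrix(
            ["g1", "g2"], ["s1"], np.array([[-2.77], [2.77]]), {}, [1, 0]
        )
        clipped = clip_for_display(m)
        assert clipped.tolist() == [[0.0], [2.77]]
        # clustering order computed on unclipped values is untouched
        assert m.gene_order == [1, 0]

    def test_all_negative_row_becomes_zero_row(self):
        clipped = clip_for_display(np.array([[-1.0, -3.0]]))
        assert clipped.tolist() == [[0.0, 0.0]]

    def test_ordered_export_uses_clustered_order(self, tmp_path):
        m = ComparisonMatrix(
            ["g1", "g2"], ["s1", "s2"],
            np.array([[-1.0, 2.0], [3.0, 4.0]]), {}, [1, 0],
        )
        assert list(m.ordered().index) == ["g2", "g1"]
        m.write_tsv(tmp_path / "m.tsv", display=True)
        text = (tmp_path / "m.tsv").read_text()
        assert "-1" not in text


class TestClusterGenesOnMatrix:
    def test_distance_on_absolute_flag(self):
        rows = np.array([[5.0, 0.0], [-5.0, 0.0], [20.0, 20.0]])
        signed = cluster_genes(rows, distance_on="signed")
        absolute = cluster_genes(rows, distance_on="absolute")
        # |scores| makes rows 0 and 1 identical -> they must end up adjacent
        i, j = absolute.index(0), absolute.index(1)
        assert abs(i - j) == 1
        assert sorted(signed) == sorted(absolute) == [0, 1, 2]
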