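"""Network set algebra, Jaccard/UPGMA module inference, heatmap scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import upgma_merges
from apmskit.network import (
    build_network,
    interactome_overlap,
    jaccard_matrix,
    paralog_preference,
    standardize_heatmap,
    upgma_cluster,
)


class TestOverlap:
    def test_identical_sets(self):
        s = {f"p{i}" for i in range(18)}
        ov = interactome_overlap(s, set(s))
        assert len(ov.shared) == 18 and not ov.only_a and not ov.only_b

    def test_disjoint_sets(self):
        ov = interactome_overlap({"a"}, {"b"})
        assert not ov.shared

    def test_partition(self):
        ov = interactome_overlap({"A", "B", "C"}, {"B", "C", "D"})
        assert ov.shared == {"B", "C"}
        assert ov.only_a == {"A"} and ov.only_b == {"D"}
        union = {"A", "B", "C", "D"}
        assert ov.shared | ov.only_a | ov.only_b == union
        assert not (ov.shared & ov.only_a or ov.shared & ov.only_b)


class TestJaccard:
    def test_identical_and_disjoint(self):
        J = jaccard_matrix({"a": {"x", "y"}, "b": {"x", "y"}, "c": {"z"}})
        assert J.loc["a", "b"] == 1.0
        assert J.loc["a", "c"] == 0.0
        assert (np.diag(J) == 1).all()

    def test_hand_value(self):
        J = jaccard_matrix({"a": {"A", "B", "C"}, "b": {"B", "C", "D"}})
        assert J.loc["a", "b"] == pytest.approx(0.5)

    def test_empty_sets_warn_and_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            J = jaccard_matrix({"a": set(), "b": set()})
        assert J.loc["a", "b"] == 0.0

    def test_matches_brute_force_on_ten_baits(self, rng):
        sets = {
            f"bait{i:02d}": {f"p{j}" for j in rng.choice(40, size=rng.integers(1, 20),
                                                         replace=False)}
            for i in range(10)
        }
        J = jaccard_matrix(sets)
        for a, b in itertools.combinations(sets, 2):
            expected = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
            assert J.loc[a, b] == pytest.approx(expected)
            assert J.loc[b, a] == pytest.approx(expected)


class TestUpgma:
    def test_identical_sets_merge_at_zero(self):
        J = jaccard_matrix({"a": {"x"}, "b": {"x"}, "c": {"y"}})
        tree = upgma_cluster(J)
        assert tree.heights[0] == pytest.approx(0.0)

    def test_non_symmetric_rejected(self):
        bad = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            upgma_cluster(bad)

    def test_heights_non_decreasing_and_oracle_equivalence(self, rng):
        """UPGMA merges (heights and cluster compositions) match exhaustive
        pair averaging on random matrices of up to 6 leaves."""
        for trial in range(30):
            n = int(rng.integers(3, 7))
            labels = [f"b{i}" for i in range(n)]
            sim = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            sim[iu] = rng.uniform(0, 1, size=len(iu[0]))
            sim = sim + sim.T
            np.fill_diagonal(sim, 1.0)
            J = pd.DataFrame(sim, index=labels, columns=labels)
            tree = upgma_cluster(J)
            assert (np.diff(tree.heights) >= -1e-12).all()

            dist = (1.0 - sim).tolist()
            for i in range(n):
                dist[i][i] = 0.0
            oracle = upgma_merges(dist, labels)
            assert np.allclose(sorted(h for *_, h in oracle), sorted(tree.heights))
            # cluster compositions created by the merges must agree
            impl_sets = _merge_compositions(tree)
            oracle_sets = {frozenset(a | b) for a, b, _ in oracle}
            assert impl_sets == oracle_sets

    def test_newick_contains_all_leaves(self):
        J = jaccard_matrix({"a": {"x"}, "b": {"x", "y"}, "c": {"z"}})
        nwk = upgma_cluster(J).to_newick()
        assert nwk.endswith(";")
        for leaf in "abc":
            assert leaf in nwk


def _merge_compositions(tree):
    n = len(tree.labels)
    members = {i: frozenset([tree.labels[i]]) for i in range(n)}
    out = set()
    for k, row in enumerate(tree.linkage_matrix):
        merged = members[int(row[0])] | members[int(row[1])]
        members[n + k] = merged
        out.add(merged)
    return out


class TestStandardizeHeatmap:
    def test_hand_row(self):
        df = pd.DataFrame([[2.0, 6.0, 10.0]], index=["p"], columns=list("xyz"))
        out = standardize_heatmap(df)
        assert out.loc["p"].tolist() == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_row_all_zeros(self):
        out = standardize_heatmap(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert (out.to_numpy() == 0).all()

    def test_idempotent_and_shift_invariant(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, size=(6, 5)))
        once = standardize_heatmap(df)
        assert standardize_heatmap(once).to_numpy() == pytest.approx(once.to_numpy())
        shifted = standardize_heatmap(df + 3.7)
        assert shifted.to_numpy() == pytest.approx(once.to_numpy())
        assert (once.to_numpy() >= 0).all() and (once.to_numpy() <= 1).all()


class TestParalogPreference:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["bait_id", "prey_id", "run_id", "bdNSAF"])

    def test_prefers_a(self):
        t = self._table([
            ("bait1", "A", "r1", 0.4), ("bait1", "A", "r2", 0.5),
            ("bait1", "B", "r1", 0.1), ("bait1", "B", "r2", 0.2),
        ])
        rep = paralog_preference(t, ("A", "B")).iloc[0]
        assert rep["preference"] == "prefers A"
        assert rep["ratio_a_over_b"] == pytest.approx(0.45 / 0.15)

    def test_equal_vectors_no_preference(self):
        t = self._table([
            ("bait1", "A", "r1", 0.3), ("bait1", "B", "r1", 0.3),
            ("bait1", "A", "r2", 0.2), ("bait1", "B", "r2", 0.2),
        ])
        assert paralog_preference(t, ("A", "B")).iloc[0]["preference"] == "mixed"

    def test_b_never_detected(self):
        t = self._table([("bait1", "A", "r1", 0.3), ("bait1", "A", "r2", 0.1)])
        rep = paralog_preference(t, ("A", "B")).iloc[0]
        assert rep["preference"] == "A only"


def test_build_network_edges_and_classes():
    results = pd.DataFrame(
        {
            "bait_id": ["b1", "b1", "b2"],
            "prey_id": ["p1", "p2", "p1"],
            "log2fc": [4.0, 1.0, 5.0],
            "z_stat": [6.0, 0.5, 7.0],
            "enriched": [True, False, True],
        }
    )
    g = build_network(results, node_classes={"p1": "shared-core"})
    assert set(g.edges) == {("b1", "p1"), ("b2", "p1")}
    assert g.nodes["p1"]["node_class"] == "shared-core"
    assert g.nodes["b1"]["role"] == "bait"
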