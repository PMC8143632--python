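"""Bait-prey network construction and interactome module inference.

Baits are compared by the Jaccard index of their enriched-prey sets and
clustered with UPGMA (average linkage) on the distance 1 - J; cutting the
ultrametric tree recovers interactome modules (e.g. the large-complex,
small-complex and shared-core subgroups of a scaffold-protein network).
Also provides per-prey min-max standardization for abundance heatmaps and a
paralog-preference report on bdNSAF values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class OverlapResult:
    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]


def interactome_overlap(
    set_a: set[str] | frozenset[str], set_b: set[str] | frozenset[str]
) -> OverlapResult:
    """Disjoint partition of two baits' enriched-prey sets: shared, A-only,
    B-only."""
    a, b = frozenset(set_a), frozenset(set_b)
    return OverlapResult(a & b, a - b, b - a)


def jaccard_matrix(enriched: Mapping[str, set[str]]) -> pd.DataFrame:
    """Symmetric bait x bait matrix of Jaccard indexes |A∩B| / |A∪B|.

    The Jaccard of two empty sets is defined as 0 with a warning; the
    diagonal is fixed at 1.  Baits are ordered lexicographically so the
    matrix (and any clustering of it) is deterministic.
    """
    baits = sorted(enriched)
    if len(baits) < 2:
        raise ValueError("need at least two baits")
    J = pd.DataFrame(np.eye(len(baits)), index=baits, columns=baits)
    for i, a in enumerate(baits):
        for b in baits[i + 1:]:
            union = enriched[a] | enriched[b]
            if not union:
                warnings.warn(f"baits {a!r} and {b!r} both have empty enriched sets")
                val = 0.0
            else:
                val = len(enriched[a] & enriched[b]) / len(union)
            J.loc[a, b] = J.loc[b, a] = val
    return J


@dataclass
class Dendrogram:
    """A UPGMA merge tree over bait labels.

    ``linkage_matrix`` is in scipy format; merge heights are the average
    inter-cluster distances and are non-decreasing (ultrametricity).
    """

    labels: list[str]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Label -> cluster id (1..k) from cutting into k flat clusters."""
        assignment = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))

    def leaf_order(self) -> list[str]:
        from scipy.cluster.hierarchy import leaves_list

        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (leaf depth equals
        half the root merge height, the cophenetic convention)."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node_repr(idx: int) -> str:
            if idx < n:
                return self.labels[idx]
            row = self.linkage_matrix[idx - n]
            left, right = int(row[0]), int(row[1])
            h = row[2] / 2.0
            parts = []
            for child in (left, right):
                child_repr = node_repr(child)  # populates heights[child]
                parts.append(f"{child_repr}:{h - heights[child]:.6g}")
            heights[idx] = h
            return "(" + ",".join(parts) + ")"

        root = n + self.linkage_matrix.shape[0] - 1
        return node_repr(root) + ";"


def upgma_cluster(similarity: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of baits on the distance 1 - Jaccard.

    The input must be a symmetric similarity matrix with unit diagonal;
    labels are sorted before clustering so that ties in merge distances are
    broken deterministically (by label order).
    """
    if list(similarity.index) != list(similarity.columns):
        raise ValueError("similarity matrix index and columns disagree")
    arr = similarity.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("similarity matrix is not symmetric")
    if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
        raise ValueError("similarity values must lie in [0, 1]")
    order = np.argsort(similarity.index)
    labels = [similarity.index[i] for i in order]
    dist = 1.0 - arr[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(list(labels), Z)


def standardize_heatmap(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row min-max standardization for abundance heatmaps.

    Each row is shifted by its minimum and divided by the maximum of the
    shifted row, mapping it onto [0, 1]; a constant row maps to all zeros.
    """
    arr = values.to_numpy(dtype=float)
    if arr.size and not np.isfinite(arr).any(axis=1).all():
        raise ValueError("every row needs at least one finite value")
    shifted = arr - np.nanmin(arr, axis=1, keepdims=True)
    denom = np.nanmax(shifted, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, shifted / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def paralog_preference(
    bdnsaf: pd.DataFrame,
    paralog_pair: tuple[str, str],
) -> pd.DataFrame:
    """Which of two paralogous preys each bait prefers, from bdNSAF values.

    ``bdnsaf`` is the long-format table from :func:`apmskit.quant.bdnsaf_table`
    (columns bait_id, prey_id, run_id, bdNSAF).  Per bait the report gives
    each paralog's mean bdNSAF, the ratio of means (A over B), and a call:
    ``"prefers A"``/``"prefers B"`` when one paralog exceeds the other in
    every replicate, ``"A only"``/``"B only"`` when one is never detected,
    ``"undetected"`` when neither is, otherwise ``"mixed"``.
    """
    prot_a, prot_b = paralog_pair
    rows = []
    for bait, grp in bdnsaf.groupby("bait_id"):
        a = grp[grp["prey_id"] == prot_a].set_index("run_id")["bdNSAF"]
        b = grp[grp["prey_id"] == prot_b].set_index("run_id")["bdNSAF"]
        runs = sorted(set(a.index) | set(b.index))
        va = np.array([a.get(r, 0.0) for r in runs])
        vb = np.array([b.get(r, 0.0) for r in runs])
        mean_a, mean_b = float(va.mean()) if len(va) else 0.0, float(vb.mean()) if len(vb) else 0.0
        if mean_a == 0 and mean_b == 0:
            call, ratio = "undetected", np.nan
        elif mean_b == 0:
            call, ratio = "A only", np.inf
        elif mean_a == 0:
            call, ratio = "B only", 0.0
        else:
            ratio = mean_a / mean_b
            if (va > vb).all():
                call = "prefers A"
            elif (vb > va).all():
                call = "prefers B"
            else:
                call = "mixed"
        rows.append((bait, mean_a, mean_b, ratio, call))
    return pd.DataFrame(
        rows,
        columns=["bait_id", f"mean_bdNSAF_{prot_a}", f"mean_bdNSAF_{prot_b}",
                 "ratio_a_over_b", "preference"],
    )


def build_network(
    results: pd.DataFrame,
    bdnsaf: pd.DataFrame | None = None,
    node_classes: Mapping[str, str] | None = None,
    enriched_only: bool = True,
) -> nx.DiGraph:
    """Bait -> prey graph from a scored enrichment table.

    Edges carry log2fc, z_stat, the enriched flag and (when a bdNSAF table
    is given) the aggregated bdNSAF; nodes carry an optional class label
    (e.g. large-complex homolog / small-complex homolog / shared core).
    """
    g = nx.DiGraph()
    bd = None
    if bdnsaf is not None and len(bdnsaf):
        agg_col = [c for c in bdnsaf.columns if c.startswith("bdNSAF_")]
        bd = bdnsaf.drop_duplicates(["bait_id", "prey_id"]).set_index(
            ["bait_id", "prey_id"]
        )[agg_col[0] if agg_col else "bdNSAF"]
    table = results[results["enriched"]] if enriched_only else results
    for row in table.itertuples():
        for node, role in ((row.bait_id, "bait"), (row.prey_id, "prey")):
            if node not in g:
                g.add_node(node, role=role,
                           node_class=(node_classes or {}).get(node, "other"))
            elif role == "bait":
                g.nodes[node]["role"] = "bait"
        attrs = {
            "log2fc": float(row.log2fc),
            "z_stat": float(row.z_stat),
            "enriched": bool(row.enriched),
        }
        if bd is not None and (row.bait_id, row.prey_id) in bd.index:
            attrs["bdNSAF"] = float(bd.loc[(row.bait_id, row.prey_id)])
        g.add_edge(row.bait_id, row.prey_id, **attrs)
    return g
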