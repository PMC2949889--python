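"""Grouping marks by the strength of their pairwise transfer functions.

Each ordered pair (m, k) is summarized by the integral of the absolute
transfer function,

    H^{mk} = integral_0^L | h^{mk}(t) | dt        (L = last knot, 1000 bp),

in units of bp x log-fold-change.  The absolute value prevents excitatory
and inhibitory stretches from cancelling, so mutually repressive marks can
also cluster together.  Each mark is represented by the concatenation of
its row (outgoing weights) and column (incoming weights) of H; pairwise
Euclidean distances between these profiles feed a Ward-linkage
hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .splines import SplineSpec, evaluate_h

__all__ = ["interaction_weight", "interaction_matrix", "cluster_tres", "ClusterResult"]


def interaction_weight(beta: np.ndarray, spec: SplineSpec, step: float = 1.0) -> float:
    """H = integral of |h| over [0, last_knot], midpoint rule at ``step`` bp."""
    upper = spec.last_knot
    lags = np.arange(step / 2.0, upper, step)
    h = evaluate_h(lags, np.asarray(beta, float), spec)
    return float(np.abs(h).sum() * step)


def interaction_matrix(params) -> pd.DataFrame:
    """K x K matrix with H^{mk} in row m, column k."""
    marks = list(params.marks)
    H = np.zeros((len(marks), len(marks)))
    for a, m in enumerate(marks):
        for b, k in enumerate(marks):
            H[a, b] = interaction_weight(params.beta[(m, k)], params.spline)
    return pd.DataFrame(H, index=marks, columns=marks)


@dataclass
class ClusterResult:
    """Ward dendrogram over marks plus a flat cut."""

    marks: list
    linkage: np.ndarray
    labels: dict
    newick: str

    def groups(self) -> list[set]:
        out: dict[int, set] = {}
        for mark, lab in self.labels.items():
            out.setdefault(lab, set()).add(mark)
        return [out[key] for key in sorted(out)]


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_tres(H: pd.DataFrame, n_clusters: int = 2) -> ClusterResult:
    """Hierarchical Ward clustering of marks on (row, column) profiles of H.

    Deterministic given H; requires at least two marks.
    """
    marks = list(H.index)
    if len(marks) < 2:
        raise ValueError("clustering requires at least two marks")
    Hv = H.to_numpy(dtype=float)
    features = np.hstack([Hv, Hv.T])  # outgoing then incoming weights
    Z = hierarchy.linkage(features, method="ward")
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = {m: int(c) for m, c in zip(marks, flat)}
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, marks) + ";"
    return ClusterResult(marks, Z, labels, newick)
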