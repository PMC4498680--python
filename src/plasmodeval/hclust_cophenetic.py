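"""Complete-linkage agglomerative clustering, cophenetic matrices and their correlation.

Complete linkage is used throughout because it is invariant under strictly
monotone transformations of the dissimilarities: measures that rank sample
pairs identically produce identical tree topologies, which removes the linkage
choice as a confounder when comparing dissimilarity measures.

The agglomeration is implemented here (not delegated) so that tie-breaking is
deterministic and documented: among candidate pairs at the minimal distance,
the pair whose clusters have the lexicographically smallest
``(min leaf index, max leaf index)`` key merges first.  scipy's linkage serves
as an independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "complete_linkage",
    "cophenetic_matrix",
    "cophenetic_correlation",
    "cut_tree",
    "write_dendrogram",
    "read_dendrogram",
    "to_newick",
]


@dataclass
class Dendrogram:
    """Merge list from agglomerative clustering.

    Nodes ``0 .. n-1`` are leaves (in ``leaf_ids`` order); merge ``k`` creates
    node ``n + k``.  ``merges`` holds ``n - 1`` tuples
    ``(left_node, right_node, height)`` with nondecreasing heights.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dendrogram):
            return NotImplemented
        return (self.leaf_ids == other.leaf_ids
                and len(self.merges) == len(other.merges)
                and all(a[0] == b[0] and a[1] == b[1] and np.isclose(a[2], b[2])
                        for a, b in zip(self.merges, other.merges)))


def _validate_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("dissimilarity matrix must be nonnegative")
    return d


def complete_linkage(d, sample_ids: list[str] | None = None) -> Dendrogram:
    """Agglomerate samples by complete (maximum) linkage.

    Accepts either a :class:`~plasmodeval.dissimilarity.DissimilarityMatrix`
    or a raw square array plus ``sample_ids``.
    """
    values, ids = _unpack(d, sample_ids)
    values = _validate_square(values)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    # active cluster state: node id, member leaf set, (min leaf, max leaf) key
    dist = values.copy()
    node = list(range(n))
    members: list[set[int]] = [{i} for i in range(n)]
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_node = n
    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = dist[a, b]
                key = (dd, min(min(members[a]), min(members[b])),
                       max(min(members[a]), min(members[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _, _), a, b = best
        merges.append((node[a], node[b], float(height)))
        # complete linkage: distance of the merged cluster to any other is the max
        for c in active:
            if c not in (a, b):
                dist[a, c] = dist[c, a] = max(dist[a, c], dist[b, c])
        members[a] = members[a] | members[b]
        node[a] = next_node
        next_node += 1
        active.remove(b)
    return Dendrogram([str(s) for s in ids], merges)


def _unpack(d, sample_ids):
    values = getattr(d, "values", None)
    ids = getattr(d, "sample_ids", None)
    if values is None or ids is None:
        values = np.asarray(d, dtype=float)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(values.shape[0])]
        ids = sample_ids
    return np.asarray(values, dtype=float), list(ids)


def cophenetic_matrix(t: Dendrogram) -> np.ndarray:
    """Pairwise merge heights: ``c_ij`` is the height at which leaves *i* and *j*
    first share a cluster.  The result is ultrametric with a zero diagonal."""
    n = t.n_leaves
    c = np.zeros((n, n))
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, (left, right, h) in enumerate(t.merges):
        for i in members[left]:
            for j in members[right]:
                c[i, j] = c[j, i] = h
        members[n + k] = members.pop(left) | members.pop(right)
    return c


def cophenetic_correlation(c1: np.ndarray, c2: np.ndarray,
                           leaf_ids1: list[str] | None = None,
                           leaf_ids2: list[str] | None = None) -> float:
    """Pearson correlation of the strictly-lower-triangular entries.

    When leaf ID lists are given the second matrix is re-ordered to match the
    first (alignment is by ID, never by position).  A zero-variance triangle
    has no defined correlation and yields ``nan`` with a warning.
    """
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    if leaf_ids1 is not None or leaf_ids2 is not None:
        if leaf_ids1 is None or leaf_ids2 is None:
            raise ValueError("provide both leaf ID lists or neither")
        if sorted(leaf_ids1) != sorted(leaf_ids2):
            raise ValueError("cophenetic matrices have different leaf sets")
        order = [leaf_ids2.index(s) for s in leaf_ids1]
        c2 = c2[np.ix_(order, order)]
    if c1.shape != c2.shape:
        raise ValueError("cophenetic matrices have different shapes")
    if c1.shape[0] < 3:
        raise ValueError("need at least 3 leaves for a cophenetic correlation")
    tri = np.tril_indices(c1.shape[0], k=-1)
    x, y = c1[tri], c2[tri]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("cophenetic correlation undefined: zero-variance triangle")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def cut_tree(t: Dendrogram, n_clusters: int) -> list[int]:
    """Cluster labels (0-based, by order of appearance) at the *k*-cluster cut."""
    n = t.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    parents: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, (left, right, _h) in enumerate(t.merges[: n - n_clusters]):
        parents[n + k] = parents.pop(left) | parents.pop(right)
    labels = [0] * n
    for lab, group in enumerate(sorted(parents.values(), key=min)):
        for leaf in group:
            labels[leaf] = lab
    return labels


# ---------------------------------------------------------------------------
# serialization: lossless node table + Newick export

def write_dendrogram(t: Dendrogram, path: str | Path) -> None:
    """Write the lossless node-table TSV (leaf rows then merge rows)."""
    rows = [
        {"node": i, "type": "leaf", "left": "", "right": "", "height": "", "label": s}
        for i, s in enumerate(t.leaf_ids)
    ]
    rows += [
        {"node": t.n_leaves + k, "type": "merge", "left": l, "right": r,
         "height": repr(h), "label": ""}
        for k, (l, r, h) in enumerate(t.merges)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dendrogram(path: str | Path) -> Dendrogram:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    leaves = frame[frame["type"] == "leaf"].sort_values("node", key=lambda s: s.astype(int))
    merges_rows = frame[frame["type"] == "merge"].sort_values(
        "node", key=lambda s: s.astype(int))
    merges = [(int(r["left"]), int(r["right"]), float(r["height"]))
              for _, r in merges_rows.iterrows()]
    return Dendrogram(leaves["label"].tolist(), merges)


def to_newick(t: Dendrogram) -> str:
    """Newick string with branch lengths = parent height − child height."""
    n = t.n_leaves
    height = {i: 0.0 for i in range(n)}
    for k, (_l, _r, h) in enumerate(t.merges):
        height[n + k] = h

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{t.leaf_ids[node]}:{bl:.10g}"
        left, right, h = t.merges[node - n]
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = n + len(t.merges) - 1
    left, right, h = t.merges[-1]
    return f"({render(left, h)},{render(right, h)});"
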