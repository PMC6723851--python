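"""Two-way Ward hierarchical clustering of the consumption matrix.

Both axes — participants and food groups — are clustered with Ward's
criterion (Ward.D2: squared Euclidean increments under the Lance-Williams
recurrence) on z-scored consumption.  Internal-node stability is estimated by
bootstrap: the complementary axis is resampled with replacement, the tree is
rebuilt, and each bipartition of the full-data tree is scored by the fraction
of replicate trees that contain it.  Participant clusters (k=3) are labelled
high/medium/low by their mean row z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterTree",
    "ClusterAssignment",
    "BootstrapSupport",
    "zscore_normalize",
    "ward_cluster",
    "cut_tree",
    "bootstrap_cluster_support",
    "consumption_level_labels",
    "tree_to_newick",
]

AXES = ("participants", "food_groups")


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative tree: leaf labels plus a scipy-format linkage matrix."""

    leaf_labels: tuple[str, ...]
    linkage: np.ndarray  # (n-1, 4): child, child, height, size
    axis: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node except the root."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.leaf_labels[i]]) for i in range(n)
        }
        out = []
        for i, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            if len(merged) < n:  # skip the root (trivial bipartition)
                out.append(merged)
        return out


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]  # leaf label -> cluster id 1..k
    k: int
    axis: str

    def members(self, cluster: int) -> list[str]:
        return [l for l, c in self.labels.items() if c == cluster]


@dataclass(frozen=True)
class BootstrapSupport:
    support: dict[frozenset, float]
    n_replicates: int
    n_skipped: int = 0


def zscore_normalize(consumption: pd.DataFrame) -> pd.DataFrame:
    """Per-column standardization to mean 0, sd 1 (sample sd, divisor n-1)."""
    sd = consumption.std(axis=0, ddof=1)
    zero = sd[~(sd > 0)].index.tolist()
    if zero:
        raise ValueError(f"zero-variance food group column(s): {zero}")
    return (consumption - consumption.mean(axis=0)) / sd


def _matrix_for_axis(matrix: pd.DataFrame, axis: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if axis == "participants":
        return matrix.to_numpy(dtype=float), tuple(str(i) for i in matrix.index)
    if axis == "food_groups":
        return matrix.to_numpy(dtype=float).T, tuple(str(c) for c in matrix.columns)
    raise ValueError(f"axis must be one of {AXES}, got {axis!r}")


def ward_cluster(matrix: pd.DataFrame, axis: str = "participants") -> ClusterTree:
    """Ward linkage on Euclidean distances along the chosen axis."""
    X, labels = _matrix_for_axis(matrix, axis)
    if X.shape[0] < 2:
        raise ValueError("clustering requires at least 2 leaves")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    Z = hierarchy.linkage(pdist(X), method="ward")
    return ClusterTree(leaf_labels=labels, linkage=Z, axis=axis)


def cut_tree(tree: ClusterTree, k: int) -> ClusterAssignment:
    """Assignment into exactly k clusters by removing the k-1 highest merges."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    flat = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    # renumber cluster ids to 1..k in order of first appearance
    remap: dict[int, int] = {}
    labels = {}
    for leaf, c in zip(tree.leaf_labels, flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[leaf] = remap[c]
    return ClusterAssignment(labels=labels, k=k, axis=tree.axis)


def bootstrap_cluster_support(
    matrix: pd.DataFrame,
    axis: str = "food_groups",
    B: int = 100,
    seed: int | None = None,
) -> BootstrapSupport:
    """Bipartition support by resampling the complementary axis.

    For the food-group tree, participants (rows) are resampled with
    replacement; for the participant tree, food groups (columns) are.  A
    replicate whose resample degenerates (zero-variance clustering input)
    is skipped with a warning and still counted in the denominator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    full = ward_cluster(matrix, axis)
    targets = {bp: 0 for bp in full.bipartitions()}
    rng = np.random.default_rng(seed)
    n_skipped = 0
    for _ in range(B):
        if axis == "food_groups":
            idx = rng.integers(0, matrix.shape[0], matrix.shape[0])
            resampled = matrix.iloc[idx]
        else:
            idx = rng.integers(0, matrix.shape[1], matrix.shape[1])
            resampled = matrix.iloc[:, idx]
        try:
            arr, _ = _matrix_for_axis(resampled, axis)
            if np.allclose(arr.std(axis=0), 0.0):
                raise ValueError("degenerate resample")
            rep = ClusterTree(
                leaf_labels=full.leaf_labels,
                linkage=hierarchy.linkage(pdist(arr), method="ward"),
                axis=axis,
            )
        except ValueError:
            n_skipped += 1
            warnings.warn("degenerate bootstrap resample skipped", stacklevel=2)
            continue
        rep_bps = set(rep.bipartitions())
        for bp in targets:
            if bp in rep_bps:
                targets[bp] += 1
    return BootstrapSupport(
        support={bp: c / B for bp, c in targets.items()},
        n_replicates=B,
        n_skipped=n_skipped,
    )


def consumption_level_labels(
    assignment: ClusterAssignment, normalized: pd.DataFrame
) -> dict[int, str]:
    """Label k=3 participant clusters high/medium/low by mean row z-score.

    Ties in mean are broken by cluster size: the larger cluster takes the
    lower consumption label.
    """
    if assignment.axis != "participants":
        raise ValueError("labels apply to participant-axis assignments")
    if assignment.k != 3:
        raise ValueError(f"expected k=3 participant clusters, got k={assignment.k}")
    row_mean = normalized.mean(axis=1)
    stats = []
    for c in sorted(set(assignment.labels.values())):
        members = assignment.members(c)
        stats.append((c, float(row_mean.loc[members].mean()), len(members)))
    # descending mean; on ties larger clusters sort later (lower label)
    stats.sort(key=lambda t: (-t[1], t[2]))
    names = ("high", "medium", "low")
    return {c: names[i] for i, (c, _, _) in enumerate(stats)}


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick string with branch lengths from merge heights.

    A child's branch length is its parent's merge height minus its own
    (0 for leaves at height 0), so root-to-leaf distance equals the root
    merge height.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for i, (_, _, h, _) in enumerate(tree.linkage):
        heights[n + i] = float(h)

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < n:
            label = tree.leaf_labels[node].replace(" ", "_").replace(",", "")
            return f"{label}:{bl:.6g}"
        a, b, h, _ = tree.linkage[node - n]
        return f"({render(int(a), h)},{render(int(b), h)}):{bl:.6g}"

    root = n + len(tree.linkage) - 1
    a, b, h, _ = tree.linkage[-1]
    return f"({render(int(a), float(h))},{render(int(b), float(h))});"
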