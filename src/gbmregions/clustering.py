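"""Correlation-distance hierarchical clustering of RoI marker profiles.

This is the pipeline's core computation.  Marker columns are z-transformed
over the whole cohort; the distance between two RoIs is ``1 - r`` where
``r`` is the Pearson correlation of their z-scored nine-marker profiles,
computed over the markers both have observed (a variant ``sqrt(2(1 - r))``
is selectable).  Profiles agglomerate under complete linkage — the distance
between two clusters is the largest distance over all cross-cluster pairs —
and the dendrogram is cut at an absolute height (default 1.75) or into a
requested number of clusters.

The linkage is written from first principles (naive O(n^3) re-scan per
merge) because tie-breaking and merge bookkeeping must be exactly
reproducible; ties in the minimal-linkage search break on the smallest
(left id, right id) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import marker_columns

__all__ = [
    "ClusteringConfig",
    "Merge",
    "MergeTree",
    "NonComputablePairError",
    "ConstantColumnError",
    "zscore_columns",
    "profile_distance",
    "distance_matrix",
    "complete_linkage",
    "cut_tree",
    "cut_tree_k",
    "to_newick",
]

DISTANCE_VARIANTS = ("one-minus-r", "sqrt-2-1-minus-r")


@dataclass(frozen=True)
class ClusteringConfig:
    """Distance and cutting parameters.

    ``cutoff_height`` is an absolute dendrogram height in distance units
    (default 1.75).  ``min_shared_markers`` is the floor on markers jointly
    observed by a pair (default 6 of 9) below which their distance is not
    computable.
    """

    cutoff_height: float = 1.75
    min_shared_markers: int = 6
    distance_variant: str = "one-minus-r"

    def __post_init__(self) -> None:
        if self.cutoff_height <= 0:
            raise ValueError("cutoff_height must be positive")
        if self.min_shared_markers < 3:
            raise ValueError("min_shared_markers must be at least 3")
        if self.distance_variant not in DISTANCE_VARIANTS:
            raise ValueError(
                f"unknown distance_variant {self.distance_variant!r}; "
                f"choose from {DISTANCE_VARIANTS}"
            )


class NonComputablePairError(ValueError):
    """A pair of profiles shares fewer markers than the configured floor."""


class ConstantColumnError(ValueError):
    """A marker column has no variance and cannot be z-scored."""


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each marker column to mean 0, sample sd 1 over non-missing cells.

    Identifier columns pass through unchanged; missing cells stay missing.
    Raises :class:`ConstantColumnError` naming the marker if a column has
    fewer than two distinct non-missing values.
    """
    out = table.copy()
    for m in marker_columns(table):
        col = out[m].to_numpy(dtype=float)
        ok = np.isfinite(col)
        vals = col[ok]
        if len(np.unique(vals)) < 2:
            raise ConstantColumnError(f"marker column {m!r} is constant; cannot z-score")
        sd = vals.std(ddof=1)
        out[m] = (col - vals.mean()) / sd
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return 0.0  # a flat profile is uninformative: treat as uncorrelated
    return float((xc * yc).sum() / denom)


def _r_to_distance(r: float, variant: str) -> float:
    if variant == "one-minus-r":
        return 1.0 - r
    return float(np.sqrt(2.0 * (1.0 - r)))


def profile_distance(
    x: np.ndarray,
    y: np.ndarray,
    config: ClusteringConfig | None = None,
) -> float:
    """Correlation-derived distance between two z-scored marker profiles.

    Computed over markers non-missing in both; default ``1 - r`` with range
    [0, 2].  Raises :class:`NonComputablePairError` below the shared-marker
    floor.
    """
    config = config or ClusteringConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shared = np.isfinite(x) & np.isfinite(y)
    if int(shared.sum()) < config.min_shared_markers:
        raise NonComputablePairError(
            f"profiles share only {int(shared.sum())} markers "
            f"(minimum {config.min_shared_markers})"
        )
    r = _pearson(x[shared], y[shared])
    return _r_to_distance(r, config.distance_variant)


def distance_matrix(
    ztable: pd.DataFrame,
    config: ClusteringConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """All-pairs profile distances for a z-scored cohort table.

    Returns ``(D, shared_counts, non_computable)``: the symmetric distance
    matrix (NaN where not computable), the companion matrix of
    shared-marker counts, and the list of non-computable roi_id pairs.
    """
    config = config or ClusteringConfig()
    profiles = ztable[marker_columns(ztable)].to_numpy(dtype=float)
    roi_ids = ztable["roi_id"].tolist() if "roi_id" in ztable else list(map(str, range(len(ztable))))
    n = len(profiles)
    finite = np.isfinite(profiles)
    d = np.zeros((n, n))
    shared_counts = np.zeros((n, n), dtype=int)
    bad_pairs: list[tuple[str, str]] = []
    for i in range(n):
        shared_counts[i, i] = finite[i].sum()
        for j in range(i + 1, n):
            shared = finite[i] & finite[j]
            k = int(shared.sum())
            shared_counts[i, j] = shared_counts[j, i] = k
            if k < config.min_shared_markers:
                d[i, j] = d[j, i] = np.nan
                bad_pairs.append((roi_ids[i], roi_ids[j]))
                continue
            r = _pearson(profiles[i, shared], profiles[j, shared])
            d[i, j] = d[j, i] = _r_to_distance(r, config.distance_variant)
    return d, shared_counts, bad_pairs


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    node_id: int


@dataclass(frozen=True)
class MergeTree:
    """Agglomeration sequence: leaves 0..n-1, internal nodes n..2n-2.

    ``leaf_names[i]`` is the RoI id of leaf ``i``.  Merge heights are
    non-decreasing (complete linkage is monotone).
    """

    n_leaves: int
    merges: tuple[Merge, ...]
    leaf_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def root_height(self) -> float:
        return self.merges[-1].height if self.merges else 0.0

    def children(self) -> dict[int, tuple[int, int]]:
        return {m.node_id: (m.left, m.right) for m in self.merges}

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices of the dendrogram drawing."""
        kids = self.children()
        order: list[int] = []
        stack = [2 * self.n_leaves - 2] if self.merges else [0]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = kids[node]
                stack.append(right)
                stack.append(left)
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.left, m.right, m.height, m.node_id) for m in self.merges],
            columns=["left", "right", "height", "node_id"],
        )


def complete_linkage(
    d: np.ndarray,
    leaf_names: list[str] | tuple[str, ...] | None = None,
) -> MergeTree:
    """Agglomerate a distance matrix under complete linkage.

    At each step the pair of active clusters with minimal complete-linkage
    distance (the max over cross-cluster leaf pairs, maintained by the
    Lance–Williams max update) merges; ties break on the smallest
    (left id, right id).  NaN entries (non-computable pairs) are refused.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if n < 2:
        raise ValueError("need at least two observations")
    if np.isnan(d).any():
        raise NonComputablePairError(
            "distance matrix contains non-computable pairs; impute the "
            "missing marker values or remove the affected RoIs first"
        )
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if leaf_names is None:
        leaf_names = [str(i) for i in range(n)]
    if len(leaf_names) != n:
        raise ValueError("leaf_names length does not match matrix")

    # slot-based work matrix: a merge reuses the lower slot, frees the other;
    # cluster ids (creation order) live in `ids` and drive the tie-break
    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    alive = np.ones(n, dtype=bool)
    ids = np.arange(n)
    merges: list[Merge] = []
    next_id = n
    for _ in range(n - 1):
        sub = work[np.ix_(alive, alive)]
        h = float(sub.min())
        cand = np.argwhere(np.isclose(sub, h, rtol=0.0, atol=0.0) | (sub == h))
        slots = np.flatnonzero(alive)
        best: tuple[int, int] | None = None
        for si, sj in cand:
            i, j = int(ids[slots[si]]), int(ids[slots[sj]])
            if i > j:
                i, j = j, i
            if best is None or (i, j) < best:
                best = (i, j)
        a, b = best  # type: ignore[misc]
        sa = int(np.flatnonzero(alive & (ids == a))[0])
        sb = int(np.flatnonzero(alive & (ids == b))[0])
        lo, hi = min(sa, sb), max(sa, sb)
        merged = np.maximum(work[lo], work[hi])  # complete linkage: max update
        work[lo, :] = merged
        work[:, lo] = merged
        work[lo, lo] = np.inf
        alive[hi] = False
        ids[lo] = next_id
        merges.append(Merge(left=a, right=b, height=h, node_id=next_id))
        next_id += 1
    return MergeTree(n_leaves=n, merges=tuple(merges), leaf_names=tuple(leaf_names))


def _components_below(tree: MergeTree, n_merges: int) -> list[list[int]]:
    parent = list(range(2 * tree.n_leaves - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in tree.merges[:n_merges]:
        for child in (m.left, m.right):
            parent[find(child)] = find(m.node_id)
    comps: dict[int, list[int]] = {}
    for leaf in range(tree.n_leaves):
        comps.setdefault(find(leaf), []).append(leaf)
    return list(comps.values())


def _number_clusters(tree: MergeTree, comps: list[list[int]]) -> dict[str, int]:
    """Number clusters 1..k by left-to-right dendrogram leaf order."""
    order = tree.leaf_order()
    rank = {leaf: pos for pos, leaf in enumerate(order)}
    comps_sorted = sorted(comps, key=lambda c: min(rank[x] for x in c))
    assignment: dict[str, int] = {}
    for cid, comp in enumerate(comps_sorted, start=1):
        for leaf in comp:
            assignment[tree.leaf_names[leaf]] = cid
    return assignment


def cut_tree(tree: MergeTree, cutoff_height: float) -> dict[str, int]:
    """Cut the dendrogram at an absolute height.

    Clusters are the connected components formed by all merges with height
    strictly below the cutoff; ids run 1..k in left-to-right leaf order.
    """
    if cutoff_height <= 0:
        raise ValueError("cutoff_height must be positive")
    n_merges = sum(1 for m in tree.merges if m.height < cutoff_height)
    return _number_clusters(tree, _components_below(tree, n_merges))


def cut_tree_k(tree: MergeTree, k: int) -> dict[str, int]:
    """Cut the dendrogram into exactly ``k`` clusters (undo the last k-1 merges)."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    return _number_clusters(tree, _components_below(tree, tree.n_leaves - k))


def to_newick(tree: MergeTree) -> str:
    """Serialize as an ultrametric Newick string with branch lengths.

    Node depth from the bottom is ``height / 2`` (leaves at 0), so two
    leaves merging at height h are rendered ``(A:h/2,B:h/2);``.
    """
    kids = tree.children()
    heights = {m.node_id: m.height for m in tree.merges}

    def age(node: int) -> float:
        return heights[node] / 2.0 if node >= tree.n_leaves else 0.0

    def render(node: int, parent_age: float) -> str:
        length = parent_age - age(node)
        if node < tree.n_leaves:
            return f"{tree.leaf_names[node]}:{length:.6f}"
        left, right = kids[node]
        inner = f"({render(left, age(node))},{render(right, age(node))})"
        return f"{inner}:{length:.6f}" if parent_age != age(node) else inner

    if not tree.merges:
        return f"{tree.leaf_names[0]}:0.000000;"
    root = 2 * tree.n_leaves - 2
    return render(root, age(root)) + ";"
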