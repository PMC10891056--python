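"""Hierarchical agglomerative clustering of participant affect features.

Distances are Euclidean; the merge tree is built by a Lance-Williams
agglomeration with a fully specified tie-break (among equally close pairs,
the pair whose smallest original leaf indices sort lowest merges first), so
the dendrogram is deterministic and reproducible across platforms.  Single,
complete, average (UPGMA, the default) and Ward linkages are offered; all
four are monotone, so merge heights never decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError


# --------------------------------------------------------------------------
# Feature and distance matrices
# --------------------------------------------------------------------------

def participant_feature_matrix(
    series_list,
    stages: tuple[str, ...] = ("A", "B", "C"),
    metrics: tuple[str, ...] = ("arousal", "valence"),
) -> pd.DataFrame:
    """Participant-level features: per-stage mean of each affect metric.

    Rows are participant ids; columns are ``{stage}_{metric}`` (e.g.
    ``A_arousal``).  Participants missing a requested stage get NaN, which
    :func:`euclidean_distance_matrix` rejects.
    """
    cells: dict[str, dict[str, float]] = {}
    for s in series_list:
        if s.stage not in stages:
            continue
        row = cells.setdefault(s.participant_id, {})
        for m in metrics:
            row[f"{s.stage}_{m}"] = float(np.mean(s.values(m)))
    cols = [f"{st}_{m}" for st in stages for m in metrics]
    return pd.DataFrame.from_dict(cells, orient="index").reindex(columns=cols).sort_index()


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError(f"distance matrix must be {n} x {n}, got {self.d.shape}")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise DataError("distances must be nonnegative")


def euclidean_distance_matrix(X) -> DistanceMatrix:
    """Pairwise Euclidean distances d(i,j) = sqrt(sum_k (x_ik - x_jk)^2)."""
    if isinstance(X, pd.DataFrame):
        labels = [str(i) for i in X.index]
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        labels = [str(i) for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[0] < 2:
        raise DataError("need a 2-D matrix with at least 2 rows")
    bad = np.flatnonzero(np.isnan(values).any(axis=1))
    if bad.size:
        raise DataError(f"missing values in rows: {[labels[i] for i in bad]}")
    # accumulate feature by feature (sequential order) so results are
    # bit-identical to the element-wise definition sqrt(sum_k (x_ik-x_jk)^2)
    sq = np.zeros((values.shape[0], values.shape[0]))
    for k in range(values.shape[1]):
        diff = values[:, k, None] - values[None, :, k]
        sq += diff * diff
    d = np.sqrt(sq)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


# --------------------------------------------------------------------------
# Agglomeration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Merge:
    """One agglomeration step; node ids follow the usual convention
    (leaves 0..n-1, the i-th merge creates node n+i)."""

    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    merges: list[Merge]
    labels: list[str]
    linkage: str

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """scipy.cluster.hierarchy-compatible (n-1) x 4 linkage matrix."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )

    def leaves_of(self, node: int) -> list[int]:
        if node < self.n:
            return [node]
        m = self.merges[node - self.n]
        return self.leaves_of(m.left) + self.leaves_of(m.right)

    def to_newick(self) -> str:
        """Newick export with branch lengths = parent height - child height."""
        def height_of(node: int) -> float:
            return 0.0 if node < self.n else self.merges[node - self.n].height

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height_of(node)
            if node < self.n:
                return f"{self.labels[node]}:{bl:g}"
            m = self.merges[node - self.n]
            inner = f"({render(m.left, m.height)},{render(m.right, m.height)})"
            return f"{inner}:{bl:g}"

        root = self.n + len(self.merges) - 1
        m = self.merges[-1]
        return f"({render(m.left, m.height)},{render(m.right, m.height)});" if root >= self.n else ";"


LINKAGES = ("single", "complete", "average", "ward")


def agglomerate(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Build the full merge tree with the requested linkage.

    At each of the n-1 steps the pair of active clusters with minimal
    linkage distance merges; ties break toward the pair whose (sorted)
    smallest-member indices are lexicographically lowest.  Ward operates on
    squared distances internally and reports square-rooted heights, matching
    the usual convention for Euclidean input.
    """
    if linkage not in LINKAGES:
        raise DataError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = len(dist.labels)
    W = dist.d.astype(float).copy()
    if linkage == "ward":
        W = W ** 2

    # active cluster id -> (node id, member set, size); working distances in
    # a dict keyed by frozenset of active ids
    active: dict[int, dict] = {
        i: {"node": i, "rep": i, "size": 1} for i in range(n)
    }
    wd = {(i, j): W[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[Merge] = []

    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d_ab = wd[(min(a, b), max(a, b))]
                ra, rb = active[a]["rep"], active[b]["rep"]
                key = (d_ab, min(ra, rb), max(ra, rb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        a, b = best[1], best[2]
        d_ab = wd[(min(a, b), max(a, b))]
        na, nb = active[a]["size"], active[b]["size"]
        node_a, node_b = active[a]["node"], active[b]["node"]
        if active[a]["rep"] > active[b]["rep"]:
            node_a, node_b = node_b, node_a
        height = float(np.sqrt(d_ab)) if linkage == "ward" else float(d_ab)
        new_node = n + step
        merges.append(Merge(node_a, node_b, height, na + nb))

        # Lance-Williams update of distances to the merged cluster
        new_id = min(a, b)
        other_id = max(a, b)
        for k in ids:
            if k in (a, b):
                continue
            d_ka = wd[(min(k, a), max(k, a))]
            d_kb = wd[(min(k, b), max(k, b))]
            nk = active[k]["size"]
            if linkage == "single":
                d_new = min(d_ka, d_kb)
            elif linkage == "complete":
                d_new = max(d_ka, d_kb)
            elif linkage == "average":
                d_new = (na * d_ka + nb * d_kb) / (na + nb)
            else:  # ward, on squared distances
                tot = nk + na + nb
                d_new = ((nk + na) * d_ka + (nk + nb) * d_kb - nk * d_ab) / tot
            wd[(min(k, new_id), max(k, new_id))] = d_new
        active[new_id] = {
            "node": new_node,
            "rep": min(active[a]["rep"], active[b]["rep"]),
            "size": na + nb,
        }
        del active[other_id]

    return Dendrogram(merges, list(dist.labels), linkage)


@dataclass
class ClusterAssignment:
    """Flat cut of a dendrogram into k clusters.

    ``labels[i]`` is the cluster (1..k) of leaf i; clusters are numbered by
    their lowest-index member.
    """

    labels: np.ndarray
    k: int
    leaf_names: list[str]

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for i, c in enumerate(self.labels):
            out[int(c)].append(self.leaf_names[i])
        return out

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"participant_id": self.leaf_names, "cluster": self.labels})


def cut(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Remove the k-1 highest merges and return the induced flat clustering."""
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # union over the first n-k merges (they are height-sorted for monotone linkages)
    node_root = {i: i for i in range(n)}
    for idx, m in enumerate(dend.merges[: n - k]):
        ra, rb = find(node_root[m.left]), find(node_root[m.right])
        parent[max(ra, rb)] = min(ra, rb)
        node_root[n + idx] = min(ra, rb)
    roots = sorted({find(i) for i in range(n)})
    label_of_root = {r: c + 1 for c, r in enumerate(roots)}
    labels = np.array([label_of_root[find(i)] for i in range(n)], dtype=int)
    return ClusterAssignment(labels, k, list(dend.labels))


def suggest_k(dend: Dendrogram) -> int:
    """Number of clusters at the largest relative gap between merge heights.

    With ascending heights h_1..h_{n-1}, the gap after merge i is
    (h_{i+1} - h_i)/max(h_i, tiny); cutting there leaves n - i clusters.
    Deterministic; first occurrence wins on ties.
    """
    n = dend.n
    if n < 3:
        raise DataError(f"suggest_k needs at least 3 leaves, got {n}")
    h = dend.heights
    tiny = max(h.max(), 1.0) * 1e-12
    gaps = (h[1:] - h[:-1]) / np.maximum(h[:-1], tiny)
    i = int(np.argmax(gaps))  # gap between merge i and i+1 (0-based)
    return n - (i + 1)
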