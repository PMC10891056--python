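import math

import numpy as np
import pandas as pd
import pytest

from affectpipe import cluster
from affectpipe.core import DataError


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_distance(X):
    n, p = X.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(p):
                dk = X[i, k] - X[j, k]
                s += dk * dk
            d[i, j] = math.sqrt(s)
    return d


def brute_force_single_linkage(d):
    """Exhaustive single-linkage agglomeration with the lowest-pair tie-break.

    Returns the merge sequence as (sorted frozenset pair of member-leaf
    frozensets, height) records, independent of node numbering.
    """
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
                ra, rb = min(clusters[a]), min(clusters[b])
                key = (dist, min(ra, rb), max(ra, rb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        height = best[0][0]
        merges.append((frozenset([clusters[a], clusters[b]]), height))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return merges


def merges_as_sets(dend):
    out = []
    for m in dend.merges:
        out.append(
            (
                frozenset(
                    [frozenset(dend.leaves_of(m.left)), frozenset(dend.leaves_of(m.right))]
                ),
                m.height,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestDistance:
    def test_three_four_five_triangle(self):
        dm = cluster.euclidean_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert dm.d[0, 1] == pytest.approx(5.0)

    def test_identical_rows_have_zero_distance(self):
        dm = cluster.euclidean_distance_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert dm.d[0, 1] == 0.0

    def test_matches_brute_force_exactly(self, rng):
        X = rng.normal(size=(6, 3))
        dm = cluster.euclidean_distance_matrix(X)
        assert np.array_equal(dm.d, brute_force_distance(X))

    def test_missing_values_rejected_naming_rows(self):
        X = pd.DataFrame([[1.0, 2.0], [np.nan, 0.0]], index=["P01", "P02"])
        with pytest.raises(DataError, match="P02"):
            cluster.euclidean_distance_matrix(X)

    def test_triangle_inequality(self, rng):
        d = cluster.euclidean_distance_matrix(rng.normal(size=(7, 4))).d
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestAgglomerate:
    def three_points(self):
        return cluster.euclidean_distance_matrix(np.array([[0.0], [1.0], [10.0]]))

    @pytest.mark.parametrize("linkage,second_height", [
        ("single", 9.0), ("complete", 10.0), ("average", 9.5),
    ])
    def test_hand_computed_three_point_case(self, linkage, second_height):
        dend = cluster.agglomerate(self.three_points(), linkage)
        assert dend.merges[0].height == pytest.approx(1.0)
        assert set(dend.leaves_of(dend.merges[0].left)
                   + dend.leaves_of(dend.merges[0].right)) == {0, 1}
        assert dend.merges[1].height == pytest.approx(second_height)

    def test_two_points_single_merge(self):
        dm = cluster.euclidean_distance_matrix(np.array([[0.0], [4.0]]))
        dend = cluster.agglomerate(dm)
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_linkage_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 2))
        dm = cluster.euclidean_distance_matrix(X)
        dend = cluster.agglomerate(dm, "single")
        assert merges_as_sets(dend) == brute_force_single_linkage(dm.d)

    @pytest.mark.parametrize("linkage", cluster.LINKAGES)
    def test_heights_match_scipy(self, linkage, rng):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        X = rng.normal(size=(9, 3))
        mine = cluster.agglomerate(cluster.euclidean_distance_matrix(X), linkage)
        Z = scipy_linkage(X, method=linkage)
        assert np.allclose(np.sort(mine.heights), np.sort(Z[:, 2]))

    @pytest.mark.parametrize("linkage", ["complete", "average", "ward"])
    def test_merge_heights_monotone(self, linkage, rng):
        X = rng.normal(size=(12, 4))
        dend = cluster.agglomerate(cluster.euclidean_distance_matrix(X), linkage)
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_permutation_invariance_of_partition(self, rng):
        X = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        d1 = cluster.euclidean_distance_matrix(X)
        d2 = cluster.euclidean_distance_matrix(X[perm])
        a1 = cluster.cut(cluster.agglomerate(d1, "average"), 3)
        a2 = cluster.cut(cluster.agglomerate(d2, "average"), 3)
        # same partition up to label renaming
        groups1 = {frozenset(np.flatnonzero(a1.labels == c)) for c in range(1, 4)}
        groups2 = {
            frozenset(perm[np.flatnonzero(a2.labels == c)]) for c in range(1, 4)
        }
        assert groups1 == groups2

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(DataError):
            cluster.DistanceMatrix(["a", "b"], d)


class TestCut:
    def make_dend(self):
        return cluster.agglomerate(
            cluster.euclidean_distance_matrix(np.array([[0.0], [1.0], [10.0]])), "single"
        )

    def test_k1_puts_everything_together(self):
        assignment = cluster.cut(self.make_dend(), 1)
        assert set(assignment.labels) == {1}

    def test_kn_gives_singletons(self):
        assignment = cluster.cut(self.make_dend(), 3)
        assert assignment.labels.tolist() == [1, 2, 3]

    def test_worked_three_point_partition(self):
        assignment = cluster.cut(self.make_dend(), 2)
        assert assignment.labels.tolist() == [1, 1, 2]  # {{0,1},{10}}

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8])
    def test_sizes_sum_to_n(self, k, rng):
        X = rng.normal(size=(8, 2))
        dend = cluster.agglomerate(cluster.euclidean_distance_matrix(X))
        assignment = cluster.cut(dend, k)
        sizes = [int(np.sum(assignment.labels == c)) for c in range(1, k + 1)]
        assert sum(sizes) == 8
        assert all(s > 0 for s in sizes)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cluster.cut(self.make_dend(), 0)
        with pytest.raises(ValueError):
            cluster.cut(self.make_dend(), 4)


class TestSuggestK:
    def test_two_well_separated_blobs(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, (5, 1)), rng.normal(50, 0.1, (5, 1))])
        dend = cluster.agglomerate(cluster.euclidean_distance_matrix(X))
        assert cluster.suggest_k(dend) == 2

    def test_worked_three_point_case(self):
        dend = cluster.agglomerate(
            cluster.euclidean_distance_matrix(np.array([[0.0], [1.0], [10.0]])), "single"
        )
        assert cluster.suggest_k(dend) == 2

    def test_equally_spaced_points_stable_and_in_range(self):
        X = np.arange(6, dtype=float)[:, None]
        dend = cluster.agglomerate(cluster.euclidean_distance_matrix(X))
        k1 = cluster.suggest_k(dend)
        k2 = cluster.suggest_k(dend)
        assert k1 == k2
        assert 2 <= k1 <= 6


class TestNewick:
    def test_newick_contains_all_leaves_and_parses(self):
        X = np.array([[0.0], [1.0], [10.0]])
        dend = cluster.agglomerate(
            cluster.euclidean_distance_matrix(pd.DataFrame(X, index=["P1", "P2", "P3"]))
        )
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for leaf in ("P1", "P2", "P3"):
            assert leaf in nwk
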