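"""DGCM construction and DGCD-13 / DGCD-6 distances."""

import numpy as np
import pytest
from scipy.stats import rankdata

from dgcd.correlation_distance import (
    DGCD6_ORBITS,
    DGCD13_ORBITS,
    DGCM,
    compute_dgcd,
    compute_dgcm,
    pairwise_dgcd,
)
from dgcd.errors import ValidationError
from dgcd.graphlet_orbits import OrbitCountMatrix, count_orbits, count_orbits_bruteforce

from conftest import bip, random_bipartite


def counts_from_columns(**cols):
    """OrbitCountMatrix with chosen orbit columns, zero elsewhere."""
    n = len(next(iter(cols.values())))
    m = np.zeros((n, 13), dtype=int)
    for orbit, values in cols.items():
        m[:, int(orbit)] = values
    return OrbitCountMatrix("x", tuple(f"n{i}" for i in range(n)), m)


def reference_dgcd(g1, g2, subset):
    """Independent recomputation: brute-force orbit counts, explicit average
    ranks, Pearson of ranks, explicit upper-triangle sum, square root."""
    mats = []
    for g in (g1, g2):
        X = count_orbits_bruteforce(g).counts[:, list(subset)].astype(float)
        X = np.vstack([X, np.ones(len(subset))])  # pseudo-node convention
        R = np.column_stack([rankdata(X[:, j]) for j in range(X.shape[1])])
        C = np.corrcoef(R, rowvar=False)
        C[np.isnan(C)] = 0.0
        np.fill_diagonal(C, 1.0)
        mats.append(C)
    total = 0.0
    k = len(subset)
    for n in range(k):
        for m in range(n + 1, k):
            total += (mats[0][n, m] - mats[1][n, m]) ** 2
    return np.sqrt(total)


class TestDGCM:
    def test_spearman_fixture_minus_half(self):
        m = counts_from_columns(**{"0": [1, 2, 3], "1": [3, 1, 2]})
        g = compute_dgcm(m, (0, 1), zero_policy="zero_correlation")
        assert g.values[0, 1] == pytest.approx(-0.5, abs=1e-12)

    def test_identical_columns_correlate_at_one(self):
        m = counts_from_columns(**{"0": [4, 1, 2], "1": [4, 1, 2]})
        g = compute_dgcm(m, (0, 1))
        assert g.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_unit_diagonal_and_symmetry(self):
        g = compute_dgcm(count_orbits(random_bipartite(2)))
        np.testing.assert_allclose(np.diag(g.values), 1.0)
        np.testing.assert_allclose(g.values, g.values.T)
        assert g.values.shape == (13, 13)

    def test_all_zero_columns_correlate_at_one_under_pseudo_node(self):
        g = compute_dgcm(count_orbits(random_bipartite(4)))
        # orbits 2 and 3 never occur in oriented bipartite graphs
        assert g.values[2, 3] == pytest.approx(1.0, abs=1e-12)

    def test_zero_correlation_policy_zeroes_constant_columns(self):
        g = compute_dgcm(
            count_orbits(random_bipartite(4)), zero_policy="zero_correlation"
        )
        assert g.values[2, 3] == 0.0
        assert g.values[2, 2] == 1.0

    def test_fewer_than_two_nodes_rejected(self):
        m = OrbitCountMatrix("x", ("a",), np.zeros((1, 13), int))
        with pytest.raises(ValidationError, match="2 nodes"):
            compute_dgcm(m)


class TestDGCD:
    def test_identity_distance_zero(self):
        g = compute_dgcm(count_orbits(random_bipartite(7)))
        assert compute_dgcd(g, g) == 0.0

    def test_single_entry_difference_gives_delta(self):
        k = 6
        a = np.eye(k)
        b = a.copy()
        delta = 0.37
        b[0, 1] = b[1, 0] = delta
        d = compute_dgcd(
            DGCM("a", DGCD6_ORBITS, a), DGCM("b", DGCD6_ORBITS, b)
        )
        assert d == pytest.approx(delta, abs=1e-12)

    def test_mismatched_subsets_rejected(self):
        a = DGCM("a", DGCD6_ORBITS, np.eye(6))
        b = DGCM("b", (0, 1, 2, 3, 4, 5), np.eye(6))
        with pytest.raises(ValidationError, match="subsets"):
            compute_dgcd(a, b)

    @pytest.mark.parametrize("subset", [DGCD13_ORBITS, DGCD6_ORBITS])
    def test_end_to_end_matches_independent_recomputation(self, subset):
        g1 = bip("g1", {("a", "x"), ("a", "y"), ("b", "y"), ("b", "z"), ("c", "z")})
        g2 = bip("g2", {("a", "x"), ("b", "x"), ("c", "x"), ("c", "y"), ("c", "z")})
        expected = reference_dgcd(g1, g2, subset)
        got = compute_dgcd(
            compute_dgcm(count_orbits(g1), subset),
            compute_dgcm(count_orbits(g2), subset),
        )
        assert got == pytest.approx(expected, abs=1e-8)


class TestPairwise:
    def test_identical_graphs_at_distance_zero(self):
        g = random_bipartite(1)
        h = random_bipartite(1)
        h.id = "copy"
        d = pairwise_dgcd([g, h])
        assert d.get(g.id, "copy") == pytest.approx(0.0, abs=1e-12)

    def test_consistent_with_individual_calls(self, small_collection):
        graphs = small_collection[:3]
        d = pairwise_dgcd(graphs)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = compute_dgcd(
                    compute_dgcm(count_orbits(graphs[i])),
                    compute_dgcm(count_orbits(graphs[j])),
                )
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_ids_rejected(self):
        g = random_bipartite(1)
        with pytest.raises(ValidationError, match="duplicate"):
            pairwise_dgcd([g, g])

    def test_subset_monotonicity(self, small_collection):
        """The 13-orbit upper triangle is a superset of the 6-orbit one."""
        d13 = pairwise_dgcd(small_collection)
        d6 = pairwise_dgcd(small_collection, DGCD6_ORBITS)
        assert (d13.values >= d6.values - 1e-9).all()

    def test_pseudometric_axioms(self, small_collection):
        d = pairwise_dgcd(small_collection)
        v = d.values
        np.testing.assert_allclose(v, v.T)
        assert (np.diag(v) == 0).all() and (v >= 0).all()
        n = len(small_collection)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-8

    def test_isomorphism_invariance(self, small_collection):
        relabeled = [g.relabel({u: f"zz_{u}" for u in g.nodes}) for g in small_collection]
        d1 = pairwise_dgcd(small_collection)
        d2 = pairwise_dgcd(relabeled)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_convention_invariance_under_global_reversal(self, small_collection):
        """Reversing the orientation of EVERY network permutes all DGCM
        rows/columns identically, leaving every pairwise distance unchanged."""
        d1 = pairwise_dgcd(small_collection)
        d2 = pairwise_dgcd([g.reverse() for g in small_collection])
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)


class TestDistanceMatrixIO:
    def test_csv_round_trip(self, tmp_path, small_collection):
        d = pairwise_dgcd(small_collection[:4])
        p = d.write_csv(tmp_path / "d.csv")
        from dgcd.correlation_distance import DistanceMatrix

        back = DistanceMatrix.read_csv(p)
        assert back.network_ids == d.network_ids
        np.testing.assert_allclose(back.values, d.values, atol=1e-10)

    def test_long_format_covers_all_pairs(self, small_collection):
        d = pairwise_dgcd(small_collection[:5])
        long = d.to_long()
        assert len(long) == 10
        assert (long["dgcd"] >= 0).all()
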