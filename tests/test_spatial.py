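"""Mantel machinery, Rousset's a-hat, and the spatial autocorrelogram."""

from __future__ import annotations

import numpy as np
import pytest

from landgen.distances import DistanceMatrix
from landgen.genotypes import MISSING, StudyCellTable
from landgen.simulate import simulate_lattice_individuals
from landgen.spatial import (
    barrier_indicator,
    geographic_distances,
    mantel,
    partial_mantel,
    rousset_a,
    spatial_autocorrelation,
)

from conftest import dataset_from_calls, make_dataset


def random_dm(rng, n, labels=None):
    v = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    v[iu] = rng.random(iu[0].size)
    v += v.T
    return DistanceMatrix(labels or [f"s{i}" for i in range(n)], v)


class TestGeographicDistances:
    def test_three_four_five(self):
        dm = geographic_distances(["a", "b"], [(0, 0), (3, 4)])
        assert dm.values[0, 1] == 5.0

    def test_identical_points_zero(self):
        dm = geographic_distances(["a", "b"], [(1, 1), (1, 1)])
        assert dm.values[0, 1] == 0.0

    def test_matches_double_loop(self, rng):
        pts = rng.random((10, 2)) * 100
        dm = geographic_distances([f"p{i}" for i in range(10)], pts)
        for i in range(10):
            for j in range(10):
                d = np.hypot(*(pts[i] - pts[j]))
                assert dm.values[i, j] == pytest.approx(d, abs=1e-12)

    def test_duplicate_labels_error(self):
        with pytest.raises(ValueError):
            geographic_distances(["a", "a"], [(0, 0), (1, 1)])


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        A = random_dm(rng, 8)
        r, p = mantel(A, A, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_perfect_reversal(self, rng):
        A = random_dm(rng, 8)
        B = DistanceMatrix(A.labels, A.values.max() + 1 - A.values
                           - np.diag(np.full(8, A.values.max() + 1)))
        r, _ = mantel(A, B, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_r_symmetric_in_arguments(self, rng):
        A, B = random_dm(rng, 9), random_dm(rng, 9)
        assert mantel(A, B, 49, 0)[0] == pytest.approx(mantel(B, A, 49, 0)[0])

    def test_zero_variance_named(self):
        A = DistanceMatrix(list("abcd"), 1 - np.eye(4))
        B = random_dm(np.random.default_rng(0), 4, labels=list("abcd"))
        with pytest.raises(ValueError, match="A"):
            mantel(A, B, 99, 0)

    def test_small_n_rejected(self, rng):
        A = random_dm(rng, 3)
        with pytest.raises(ValueError):
            mantel(A, A, 99, 0)


class TestPartialMantel:
    def test_b_equals_c_gives_zero(self, rng):
        A, B = random_dm(rng, 10), random_dm(rng, 10)
        r, _ = partial_mantel(A, B, B, n_perm=49, seed=0)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_mantel_when_c_uncorrelated(self, rng):
        # average over replicates: with C independent, r_AB.C ~ r_AB
        diffs = []
        for k in range(20):
            g = np.random.default_rng(k)
            A, B, C = (random_dm(g, 12) for _ in range(3))
            r_p, _ = partial_mantel(A, B, C, n_perm=9, seed=0)
            r_m, _ = mantel(A, B, n_perm=9, seed=0)
            diffs.append(r_p - r_m)
        assert abs(np.mean(diffs)) < 0.05

    def test_constructed_signal_detected(self):
        hits = 0
        for k in range(10):
            g = np.random.default_rng(100 + k)
            B, C = random_dm(g, 15), random_dm(g, 15)
            noise = random_dm(g, 15)
            A = DistanceMatrix(B.labels, B.values + C.values + 0.3 * noise.values)
            r, p = partial_mantel(A, B, C, n_perm=199, seed=k)
            hits += (r > 0) and (p < 0.05)
        assert hits >= 8

    def test_affine_covariate_gives_zero_partial(self, rng):
        # C affine in A forces the partial numerator to 0 exactly: the 0/0
        # limit resolves to zero rather than an error
        A, B = random_dm(rng, 8), random_dm(rng, 8)
        r, _ = partial_mantel(A, B, A, n_perm=9, seed=0)
        assert r == 0.0


class TestBarrierIndicator:
    def test_all_same_side_zero(self):
        tab = StudyCellTable(("a", "b", "c"), np.zeros((3, 2)), ("N", "N", "N"))
        assert not barrier_indicator(tab).values.any()

    def test_cross_river_pairs_only(self):
        tab = StudyCellTable(("a", "b", "c"), np.zeros((3, 2)), ("N", "N", "S"))
        m = barrier_indicator(tab).values
        assert m[0, 2] == m[1, 2] == 1 and m[0, 1] == 0

    def test_matches_brute_force(self, rng):
        sides = tuple(rng.choice(["N", "S"], size=12))
        tab = StudyCellTable(tuple(f"c{i}" for i in range(12)),
                             np.zeros((12, 2)), sides)
        m = barrier_indicator(tab).values
        for i in range(12):
            for j in range(12):
                expect = float(sides[i] != sides[j]) if i != j else 0.0
                assert m[i, j] == expect

    def test_missing_side_errors(self):
        tab = StudyCellTable(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            barrier_indicator(tab)


def oracle_rousset(calls):
    """Independent loops over Rousset's identity probabilities."""
    n, L, _ = calls.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0.0
            for l in range(L):
                gi, gj = calls[i, l], calls[j, l]
                if gi[0] == MISSING or gj[0] == MISSING:
                    continue
                qw = (int(gi[0] == gi[1]) + int(gj[0] == gj[1])) / 2.0
                qb = sum(int(a == b) for a in gi for b in gj) / 4.0
                num += qw - qb
                den += 1.0 - qw
            out[i, j] = num / den if den > 0 else (0.0 if num <= 0 else np.inf)
    return out


class TestRoussetA:
    def test_clones_closer_than_fixed_different(self):
        # homozygous clones (degenerate 0) vs individuals fixed for different
        # alleles (degenerate +inf): ordering must hold
        clones = dataset_from_calls(np.array([[[1, 1]] * 2] * 3, dtype=np.int32))
        fixed = dataset_from_calls(
            np.array([[[1, 1]] * 2, [[2, 2]] * 2, [[3, 3]] * 2], dtype=np.int32))
        a_clones = rousset_a(clones).values[0, 1]
        a_fixed = rousset_a(fixed).values[0, 1]
        assert a_clones < a_fixed
        assert a_clones == 0.0 and np.isinf(a_fixed)

    def test_identical_individuals_exchangeable(self):
        calls = np.array([[[1, 2], [2, 3]]] * 5, dtype=np.int32)
        vals = rousset_a(dataset_from_calls(calls)).condensed()
        assert np.allclose(vals, vals[0])

    def test_matches_identity_probability_oracle(self):
        for seed in range(4):
            ds = make_dataset([5], n_loci=2, n_alleles=4, seed=seed)
            got = rousset_a(ds, "A").values
            want = oracle_rousset(ds.calls)
            np.testing.assert_allclose(got, 0.5 * (want + want.T), atol=1e-10)

    def test_lattice_ibd_mantel_positive(self):
        """Kin-structured individuals show positive distance-decay of a-hat."""
        hits = 0
        for k in range(10):
            ds = simulate_lattice_individuals(60, 60.0, L=8, k=6, seed=k)
            a = rousset_a(ds)
            geo = geographic_distances(a.labels, ds.coords)
            r, p = mantel(a, geo, n_perm=199, seed=k)
            hits += (r > 0) and (p < 0.05)
        assert hits >= 8

    def test_needs_three_individuals(self):
        ds = make_dataset([2], seed=0)
        with pytest.raises(ValueError):
            rousset_a(ds)


class TestSpatialAutocorrelation:
    def _clustered_clones(self):
        rng = np.random.default_rng(0)
        g1 = np.array([[1, 1], [2, 2], [1, 2], [3, 3]], dtype=np.int32)
        g2 = np.array([[4, 4], [3, 4], [2, 3], [1, 4]], dtype=np.int32)
        calls = np.array([g1] * 10 + [g2] * 10)
        xy = np.concatenate([rng.normal(0, 20, (10, 2)),
                             rng.normal(1000, 20, (10, 2)) ])
        return dataset_from_calls(calls, coords=xy)

    def test_clusters_exceed_null_envelope_in_first_class(self):
        ds = self._clustered_clones()
        tab = spatial_autocorrelation(ds, class_width_m=100, max_dist_m=2000,
                                      n_perm=199, n_boot=99, seed=1)
        first = tab.iloc[0]
        assert first["n_pairs"] > 0
        assert first["r"] > 0 and first["r"] > first["null_hi"]

    def test_each_pair_in_exactly_one_class(self):
        ds = make_dataset([20], n_loci=4, seed=3)
        ds.coords[:] = np.random.default_rng(0).random((20, 2)) * 1400
        tab = spatial_autocorrelation(ds, class_width_m=100, max_dist_m=2000,
                                      n_perm=49, n_boot=49, seed=0)
        assert tab["n_pairs"].sum() == 20 * 19 // 2

    def test_null_within_envelope_mostly(self):
        inside = total = 0
        for k in range(5):
            ds = make_dataset([25], n_loci=5, n_alleles=5, seed=50 + k)
            ds.coords[:] = np.random.default_rng(k).random((25, 2)) * 1800
            tab = spatial_autocorrelation(ds, class_width_m=500, max_dist_m=2000,
                                          n_perm=199, n_boot=49, seed=k)
            ok = ~np.isnan(tab["r"])
            inside += ((tab["r"] >= tab["null_lo"]) & (tab["r"] <= tab["null_hi"]))[ok].sum()
            total += ok.sum()
        assert inside / total >= 0.75

    def test_requires_ten_individuals(self):
        ds = make_dataset([5], seed=0)
        with pytest.raises(ValueError):
            spatial_autocorrelation(ds, n_perm=49, n_boot=49, seed=0)
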