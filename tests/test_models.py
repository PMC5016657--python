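"""MRDM, PCoA/dbRDA, variable selection, bootstrap CIs, and the CI-overlap
comparison rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from landgen.distances import DistanceMatrix
from landgen.models import (
    BootstrapCI,
    ModelFit,
    adjusted_r2,
    bootstrap_ci,
    compare_surfaces,
    dbrda,
    dbrda_forward_select,
    mrdm,
    mrdm_reduce,
    pcoa,
)
from landgen.spatial import mantel

from conftest import make_dataset


def dm_from_condensed(vec, labels=None, kind="generic"):
    n = int((1 + np.sqrt(1 + 8 * len(vec))) / 2)
    return DistanceMatrix.from_condensed(labels or [f"s{i}" for i in range(n)],
                                         np.asarray(vec, float), kind)


def random_dm(rng, n, labels=None):
    return dm_from_condensed(rng.random(n * (n - 1) // 2), labels)


class TestMRDM:
    def test_exact_linear_recovery(self, rng):
        X = random_dm(rng, 10)
        Y = DistanceMatrix(X.labels, 2 * X.values)
        fit = mrdm(Y, [X], n_perm=99, seed=0, standardize=False)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coef[0] == pytest.approx(2.0, abs=1e-10)

    def test_orthogonal_two_predictor_recovery(self, rng):
        m = 45  # 10 sites
        v1 = rng.random(m)
        v2 = rng.random(m)
        v2 -= (v1 - v1.mean()) @ (v2 - v2.mean()) / ((v1 - v1.mean()) @ (v1 - v1.mean())) * (v1 - v1.mean())
        X1, X2 = dm_from_condensed(v1), dm_from_condensed(v2)
        Y = dm_from_condensed(v1 + 3 * v2)
        fit = mrdm(Y, [X1, X2], n_perm=49, seed=0, standardize=False)
        np.testing.assert_allclose(fit.coef, [1.0, 3.0], atol=1e-10)

    def test_single_predictor_r2_equals_mantel_r_squared(self, rng):
        A, B = random_dm(rng, 12), random_dm(rng, 12)
        fit = mrdm(A, [B], n_perm=49, seed=0)
        r, _ = mantel(A, B, n_perm=9, seed=0)
        assert fit.r2 == pytest.approx(r**2, abs=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        X = random_dm(rng, 10)
        X2 = DistanceMatrix(X.labels, X.values * 2)
        Y = random_dm(rng, 10, labels=X.labels)
        with pytest.raises(ValueError, match="collinear"):
            mrdm(Y, [X, X2], n_perm=9, seed=0)

    def test_adjusted_below_r2(self, rng):
        Y = random_dm(rng, 10)
        X = random_dm(rng, 10, labels=Y.labels)
        fit = mrdm(Y, [X], n_perm=9, seed=0)
        assert fit.adj_r2 < fit.r2 < 1


class TestMRDMReduce:
    def test_significant_single_predictor_is_fixpoint(self, rng):
        X = random_dm(rng, 12)
        Y = DistanceMatrix(X.labels, X.values + 0.01 * random_dm(rng, 12).values)
        fit, retained = mrdm_reduce(Y, [X], ["x"], alpha=0.05, n_perm=199, seed=0)
        assert retained == ["x"]

    def test_noise_dropped_signal_kept(self):
        kept_true = 0
        n_rep = 30
        for k in range(n_rep):
            rng = np.random.default_rng(k)
            X = random_dm(rng, 15)
            noise = random_dm(rng, 15, labels=X.labels)
            Y = DistanceMatrix(X.labels,
                               X.values + 0.25 * random_dm(rng, 15).values)
            fit, retained = mrdm_reduce(Y, [X, noise], ["true", "noise"],
                                        alpha=0.05, n_perm=199, seed=k)
            kept_true += retained == ["true"]
        assert kept_true / n_rep >= 0.75

    def test_all_noise_mostly_empty(self):
        empties = 0
        n_rep = 30
        for k in range(n_rep):
            rng = np.random.default_rng(1000 + k)
            Y = random_dm(rng, 15)
            Xs = [random_dm(rng, 15, labels=Y.labels) for _ in range(3)]
            fit, retained = mrdm_reduce(Y, Xs, list("abc"), alpha=0.05,
                                        n_perm=199, seed=k)
            empties += not retained
        assert empties / n_rep >= 0.7


class TestPCoA:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = DistanceMatrix(list("abc"), np.abs(pts - pts.T))
        axes, w = pcoa(D)
        assert axes.shape[1] == 1
        got = np.abs(axes[:, 0][:, None] - axes[:, 0][None, :])
        np.testing.assert_allclose(got, D.values, atol=1e-10)

    def test_planar_reconstruction(self, rng):
        pts = rng.random((8, 2)) * 10
        from scipy.spatial.distance import pdist, squareform
        D = DistanceMatrix([f"p{i}" for i in range(8)], squareform(pdist(pts)))
        axes, w = pcoa(D)
        assert axes.shape[1] == 2
        back = squareform(pdist(axes))
        np.testing.assert_allclose(back, D.values, atol=1e-8)

    def test_zero_matrix_no_axes(self):
        D = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        axes, w = pcoa(D)
        assert axes.shape[1] == 0

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        D = random_dm(rng, 7)
        _, w = pcoa(D)
        sk = sk_pcoa(skbio.DistanceMatrix(D.values, list(D.labels)))
        sk_pos = sk.eigvals[sk.eigvals > 1e-8 * sk.eigvals.max()]
        np.testing.assert_allclose(np.sort(w), np.sort(sk_pos), atol=1e-8)


class TestDbRDA:
    def test_self_explanation(self, rng):
        pts = rng.random((9, 2))
        from scipy.spatial.distance import pdist, squareform
        D = DistanceMatrix([f"p{i}" for i in range(9)], squareform(pdist(pts)))
        pred = pd.DataFrame(pts, index=list(D.labels), columns=["x", "y"])
        fit = dbrda(D, pred, n_perm=49, seed=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_equivalence_with_multivariate_regression(self, rng):
        # dbRDA on Euclidean distances of Y == RDA of Y on X: R2 from an
        # independent least-squares computation
        n = 12
        Y = rng.random((n, 3))
        X = rng.random((n, 2))
        from scipy.spatial.distance import pdist, squareform
        D = DistanceMatrix([f"p{i}" for i in range(n)], squareform(pdist(Y)))
        pred = pd.DataFrame(X, index=list(D.labels), columns=["a", "b"])
        fit = dbrda(D, pred, n_perm=9, seed=0)
        Yc = Y - Y.mean(0)
        Xc = np.column_stack([np.ones(n), X])
        B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        r2 = 1 - ((Yc - Xc @ B) ** 2).sum() / (Yc**2).sum()
        assert fit.r2 == pytest.approx(r2, abs=1e-8)

    def test_too_many_predictors_error(self, rng):
        D = random_dm(rng, 5)
        pred = pd.DataFrame(rng.random((5, 4)), index=list(D.labels))
        with pytest.raises(ValueError):
            dbrda(D, pred, n_perm=9, seed=0)


class TestForwardSelection:
    def _signal_case(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        strong = rng.random(n)
        from scipy.spatial.distance import pdist, squareform
        D = DistanceMatrix(
            [f"p{i}" for i in range(n)],
            squareform(pdist(strong[:, None])) + 0.2 * squareform(pdist(rng.random((n, 1)))),
        )
        cand = pd.DataFrame({
            "strong": strong,
            "noise1": rng.random(n),
            "noise2": rng.random(n),
        }, index=list(D.labels))
        return D, cand

    def test_strong_predictor_enters(self):
        hits = 0
        for k in range(20):
            D, cand = self._signal_case(k)
            fit = dbrda_forward_select(D, cand, alpha=0.05, n_perm=199, seed=k)
            hits += fit is not None and "strong" in fit.predictors
        assert hits >= 15

    def test_all_noise_null_model(self):
        nulls = 0
        for k in range(20):
            rng = np.random.default_rng(500 + k)
            D = random_dm(rng, 12)
            cand = pd.DataFrame(rng.random((12, 3)), index=list(D.labels),
                                columns=list("abc"))
            fit = dbrda_forward_select(D, cand, alpha=0.05, n_perm=199, seed=k)
            nulls += fit is None
        assert nulls >= 14

    def test_alpha_one_admits_everything(self, rng):
        D = random_dm(rng, 10)
        cand = pd.DataFrame(rng.random((10, 3)), index=list(D.labels),
                            columns=list("abc"))
        fit = dbrda_forward_select(D, cand, alpha=1.0, n_perm=9, seed=0)
        assert set(fit.predictors) == set("abc")


class TestBootstrapCI:
    @staticmethod
    def _stat(ds):
        from landgen.diversity import pairwise_fst
        return {"theta": pairwise_fst(ds).matrix.condensed()[0]}

    def test_deterministic_given_seed(self):
        ds = make_dataset([10, 10], seed=1)
        a = bootstrap_ci(self._stat, ds, n_boot=50, seed=7)
        b = bootstrap_ci(self._stat, ds, n_boot=50, seed=7)
        assert a.mean == b.mean and a.ci_low == b.ci_low

    def test_degenerate_zero_width_flagged(self):
        calls = np.tile(np.array([[1, 2]], dtype=np.int32), (12, 3, 1))
        from conftest import dataset_from_calls
        ds = dataset_from_calls(calls, cells=["A"] * 6 + ["B"] * 6)
        res = bootstrap_ci(self._stat, ds, n_boot=30, seed=0)
        assert res.degenerate

    def test_failing_stat_aborts(self):
        ds = make_dataset([6, 6], seed=2)

        def bad(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="5%"):
            bootstrap_ci(bad, ds, n_boot=30, seed=0)


class TestCompareSurfaces:
    def _fit(self, surface, adj, lo, hi):
        f = ModelFit("FST", surface, "mrdm", ["x"], 1.0, adj, adj, 0.01)
        f.boot_mean = {"adj_r2": adj}
        f.boot_lo = {"adj_r2": lo}
        f.boot_hi = {"adj_r2": hi}
        return f

    def test_disjoint_is_distinct(self):
        fits = [self._fit("IBD", 0.07, 0.06, 0.08),
                self._fit("IBB", 0.07, 0.06, 0.08),
                self._fit("MortH", 0.11, 0.10, 0.12)]
        comp = compare_surfaces(fits)
        assert comp.winner == "MortH"
        assert comp.relation["MortH"] == "distinct"

    def test_overlap_is_competing(self):
        fits = [self._fit("IBD", 0.12, 0.11, 0.13),
                self._fit("IBB", 0.05, 0.04, 0.06),
                self._fit("MortH", 0.11, 0.10, 0.12)]
        comp = compare_surfaces(fits)
        assert comp.relation["MortH"] == "overlapping"
        assert "MortH" in comp.competing or comp.winner == "MortH"

    def test_missing_ci_errors(self):
        f = ModelFit("FST", "IBD", "mrdm", [], np.nan, 0.0, 0.0, np.nan)
        with pytest.raises(ValueError):
            compare_surfaces([f])


def test_adjusted_r2_formula():
    assert adjusted_r2(0.5, 20, 3) == pytest.approx(1 - 0.5 * 19 / 16)
    assert np.isnan(adjusted_r2(0.5, 4, 3))
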