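"""Diversity and differentiation estimators against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from landgen.diversity import (
    allele_count_arrays,
    allelic_richness,
    diversity_table,
    fis,
    heterozygosities,
    jost_d_from_counts,
    jost_d_infinite,
    pairwise_fst,
    pairwise_jost_d,
    theta_from_counts,
)
from landgen.genotypes import MISSING

from conftest import dataset_from_calls, make_dataset


# ---------------------------------------------------------------------------
# Brute-force Weir-Cockerham oracle: plain loops, coded from the published
# variance-component formulas, independent of the vectorized implementation.
# ---------------------------------------------------------------------------

def _oracle_counts(ds, cells):
    per_locus = []
    for l in range(ds.n_loci):
        codes = sorted(int(v) for v in set(ds.calls[:, l, :].ravel()) - {MISSING})
        tab = {}
        for c in cells:
            idx = [i for i in range(ds.n_individuals) if ds.cells[i] == c]
            g = [(int(ds.calls[i, l, 0]), int(ds.calls[i, l, 1]))
                 for i in idx if ds.calls[i, l, 0] != MISSING]
            n = len(g)
            p = {a: sum((x == a) + (y == a) for x, y in g) / (2 * n) if n else 0.0
                 for a in codes}
            h = {a: sum((a in (x, y)) and x != y for x, y in g) / n if n else 0.0
                 for a in codes}
            tab[c] = (n, p, h)
        per_locus.append((codes, tab))
    return per_locus


def oracle_theta(ds, c1, c2):
    num = den = 0.0
    for codes, tab in _oracle_counts(ds, [c1, c2]):
        n1, p1, h1 = tab[c1]
        n2, p2, h2 = tab[c2]
        if n1 < 2 or n2 < 2:
            continue
        nbar = (n1 + n2) / 2
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        for a in codes:
            pbar = (n1 * p1[a] + n2 * p2[a]) / (2 * nbar)
            s2 = (n1 * (p1[a] - pbar) ** 2 + n2 * (p2[a] - pbar) ** 2) / nbar
            hbar = (n1 * h1[a] + n2 * h2[a]) / (2 * nbar)
            A = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
            B = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
            C = hbar / 2
            num += A
            den += A + B + C
    return num / den


def oracle_fis(ds, cell):
    num_c = den_bc = 0.0
    for codes, tab in _oracle_counts(ds, [cell]):
        n, p, h = tab[cell]
        if n < 2:
            continue
        for a in codes:
            b = (n / (n - 1)) * (p[a] * (1 - p[a]) - (2 * n - 1) / (4 * n) * h[a])
            c = h[a] / 2
            num_c += c
            den_bc += b + c
    return 1 - num_c / den_bc


def oracle_jost(ds, c1, c2):
    def ho_of(cell, l):
        idx = [i for i in range(ds.n_individuals) if ds.cells[i] == cell]
        gg = [ds.calls[i, l] for i in idx if ds.calls[i, l, 0] != MISSING]
        return np.mean([x[0] != x[1] for x in gg])

    nums, dens = [], []
    per_locus = _oracle_counts(ds, [c1, c2])
    for l, (codes, tab) in enumerate(per_locus):
        n1, p1, _ = tab[c1]
        n2, p2, _ = tab[c2]
        if n1 < 2 or n2 < 2:
            continue
        nt = 2 / (1 / n1 + 1 / n2)
        ho = (ho_of(c1, l) + ho_of(c2, l)) / 2
        hs_raw = 1 - (sum(v**2 for v in p1.values()) + sum(v**2 for v in p2.values())) / 2
        hs = (nt / (nt - 1)) * (hs_raw - ho / (2 * nt))
        ht_raw = 1 - sum(((p1[a] + p2[a]) / 2) ** 2 for a in codes)
        ht = ht_raw + hs / (4 * nt)
        nums.append(ht - hs)
        dens.append(1 - hs)
    return 2 * sum(nums) / sum(dens)


class TestHeterozygosities:
    def test_all_heterozygotes(self):
        ds = dataset_from_calls(np.array([[[1, 2]]] * 10, dtype=np.int32))
        ho, he = heterozygosities(ds, "A", 0)
        assert ho == 1.0

    def test_monomorphic(self):
        ds = dataset_from_calls(np.array([[[3, 3]]] * 4, dtype=np.int32))
        assert heterozygosities(ds, "A", 0) == (0.0, 0.0)

    def test_hand_unbiased_he(self):
        # genotypes A/A and A/B: counts 3:1, n=2 -> He = (4/3)(1-0.625) = 0.5
        ds = dataset_from_calls(np.array([[[1, 1]], [[1, 2]]], dtype=np.int32))
        ho, he = heterozygosities(ds, "A", 0)
        assert ho == 0.5
        assert he == pytest.approx(0.5)


class TestAllelicRichness:
    def _two_allele_ds(self):
        return dataset_from_calls(np.array([[[1, 2]], [[1, 2]]], dtype=np.int32))

    def test_hand_hypergeometric(self):
        # counts (2, 2), g=2 -> 2 (1 - C(2,2)/C(4,2)) = 5/3
        assert allelic_richness(self._two_allele_ds(), "A", 0, 2) == pytest.approx(5 / 3)

    def test_full_depth_gives_observed_count(self):
        ds = make_dataset([12], n_loci=1, n_alleles=6, seed=4)
        n2 = 2 * 12
        observed = ds.allele_codes(0).size
        assert allelic_richness(ds, "A", 0, n2) == pytest.approx(observed)

    def test_monomorphic_is_one(self):
        ds = dataset_from_calls(np.array([[[1, 1]]] * 5, dtype=np.int32))
        assert allelic_richness(ds, "A", 0, 4) == pytest.approx(1.0)

    def test_g_below_two_errors(self):
        with pytest.raises(ValueError):
            allelic_richness(self._two_allele_ds(), "A", 0, 1)


class TestFis:
    def test_all_homozygous_polymorphic_is_one(self):
        calls = np.array([[[1, 1]]] * 5 + [[[2, 2]]] * 5, dtype=np.int32)
        res = fis(dataset_from_calls(calls), "A", n_boot=100, seed=0)
        assert res.fis == pytest.approx(1.0)

    def test_matches_variance_component_oracle(self):
        for seed in range(5):
            ds = make_dataset([15], n_loci=3, n_alleles=5, seed=seed)
            res = fis(ds, "A", n_boot=50, seed=0)
            assert res.fis == pytest.approx(oracle_fis(ds, "A"), abs=1e-10)

    def test_single_locus_ci_flagged(self):
        ds = make_dataset([10], n_loci=1, seed=1)
        res = fis(ds, "A", n_boot=50, seed=0)
        assert res.single_locus and np.isnan(res.ci_low)


class TestPairwiseFst:
    def test_fixed_alternative_alleles_is_one(self):
        calls = np.array([[[1, 1]]] * 6 + [[[2, 2]]] * 6, dtype=np.int32)
        ds = dataset_from_calls(calls, cells=["A"] * 6 + ["B"] * 6)
        res = pairwise_fst(ds)
        assert res.matrix.condensed()[0] == pytest.approx(1.0)

    def test_matches_oracle_three_cells(self):
        ds = make_dataset([5, 5, 5], n_loci=3, n_alleles=4,
                          cells=("A", "B", "C"), seed=9)
        res = pairwise_fst(ds)
        got = res.matrix
        for i, (c1, c2) in enumerate([("A", "B"), ("A", "C"), ("B", "C")]):
            assert got.condensed()[i] == pytest.approx(oracle_theta(ds, c1, c2),
                                                       abs=1e-10)

    def test_panmictic_pool_near_zero(self):
        ds = make_dataset([50, 50], n_loci=8, n_alleles=6, seed=11)
        theta = pairwise_fst(ds).matrix.condensed()[0]
        assert abs(theta) < 0.02

    def test_symmetry_zero_diagonal(self):
        ds = make_dataset([6, 6, 6], cells=("A", "B", "C"), seed=2)
        m = pairwise_fst(ds).matrix.values
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_permutation_p_valid_under_null(self, rng):
        hits = 0
        n_rep = 120
        for k in range(n_rep):
            ds = make_dataset([12, 12], n_loci=3, n_alleles=4, seed=1000 + k)
            res = pairwise_fst(ds, n_perm=99, seed=k)
            hits += res.pvalues[0] <= 0.05
        assert hits / n_rep <= 0.11

    def test_small_cell_excluded(self):
        ds = make_dataset([6, 6, 1], cells=("A", "B", "C"), seed=3)
        res = pairwise_fst(ds)
        assert res.matrix.labels == ("A", "B")


class TestJostD:
    def test_identical_frequencies_infinite_limit_zero(self):
        p = np.array([0.4, 0.6])
        assert jost_d_infinite(p, p) == pytest.approx(0.0)

    def test_hand_value(self):
        d = jost_d_infinite([0.7, 0.3], [0.3, 0.7])
        assert d == pytest.approx(2 * (0.5 - 0.42) / (1 - 0.42), abs=1e-12)

    def test_fixed_alternative_alleles_is_one(self):
        calls = np.array([[[1, 1]]] * 8 + [[[2, 2]]] * 8, dtype=np.int32)
        ds = dataset_from_calls(calls, cells=["A"] * 8 + ["B"] * 8)
        assert pairwise_jost_d(ds).matrix.condensed()[0] == pytest.approx(1.0)

    def test_matches_oracle(self):
        for seed in (1, 5):
            ds = make_dataset([8, 8], n_loci=3, n_alleles=4, seed=seed)
            got = pairwise_jost_d(ds).matrix.condensed()[0]
            assert got == pytest.approx(oracle_jost(ds, "A", "B"), abs=1e-10)

    def test_ci_clipped_at_zero(self):
        ds = make_dataset([10, 10], n_loci=4, seed=8)
        res = pairwise_jost_d(ds, n_boot=200, seed=0)
        assert np.all(res.ci_low >= 0)


class TestDiversityTable:
    def test_schema_and_ranges(self):
        ds = make_dataset([10, 14], n_loci=4, n_alleles=5, seed=6)
        tab = diversity_table(ds, n_boot=100, seed=0)
        assert list(tab.columns) == ["N", "Na", "AR", "Ho", "He", "Fis",
                                     "Fis_lo", "Fis_hi"]
        assert tab.loc["A", "N"] == 10
        assert ((tab[["Ho", "He"]] >= 0) & (tab[["Ho", "He"]] <= 1)).all().all()
        assert (tab["Fis_lo"] <= tab["Fis_hi"]).all()
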