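"""Isolation-by-distance and barrier tests at cell and individual scales.

Mantel and partial Mantel tests use the standard convention of jointly
permuting rows and columns of the second matrix; p-values are one-tailed
(greater) by default because isolation by distance predicts a positive
association between genetic and geographic distance.

Individual-scale tools: Rousset's a-hat pairwise genetic distance (identity
probability form) and the Smouse-Peakall multivariate spatial autocorrelogram
over half-open distance classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix
from .genotypes import MISSING, GenotypeDataset, StudyCellTable

logger = logging.getLogger(__name__)


def geographic_distances(labels, xy, kind: str = "geographic") -> DistanceMatrix:
    """Pairwise Euclidean distances between labeled planar points (metres)."""
    xy = np.asarray(xy, dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    return DistanceMatrix(tuple(labels), squareform(pdist(xy)), kind)


def _check_conformable(*mats: DistanceMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise ValueError("distance matrices have different labels/order")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance matrix in correlation")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, tail: str = "greater") -> tuple[float, float]:
    """Mantel test: Pearson r of upper triangles; permutation p-value from
    joint row/column permutations of B.  p = (1 + #extreme) / (n_perm + 1)."""
    _check_conformable(A, B)
    n = A.n
    if n < 4:
        raise ValueError("need at least 4 sites")
    a = A.condensed()
    if a.std() == 0:
        raise ValueError("zero-variance matrix: A")
    b = B.condensed()
    if b.std() == 0:
        raise ValueError("zero-variance matrix: B")
    r_obs = _pearson(a, b)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        b_perm = B.values[np.ix_(p, p)][iu]
        r = _pearson(a, b_perm)
        if tail == "greater":
            count += r >= r_obs - 1e-12
        elif tail == "two-sided":
            count += abs(r) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return r_obs, (1 + count) / (n_perm + 1)


def _partial_r(a, b, c) -> float:
    r_ab = _pearson(a, b)
    r_ac = _pearson(a, c)
    r_bc = _pearson(b, c)
    num = r_ab - r_ac * r_bc
    if abs(r_ac) >= 1 - 1e-12 or abs(r_bc) >= 1 - 1e-12:
        if abs(num) < 1e-12:
            return 0.0  # 0/0 limit, e.g. B identical to C
        raise ValueError("degenerate conditioning: |r| = 1 with the covariate")
    return num / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def partial_mantel(A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix,
                   n_perm: int = 999, seed: int | None = None,
                   tail: str = "greater") -> tuple[float, float]:
    """First-order partial Mantel r_AB.C with permutation of B (rows+columns
    jointly), recomputing the partial statistic each time."""
    _check_conformable(A, B, C)
    n = A.n
    a, b, c = A.condensed(), B.condensed(), C.condensed()
    r_obs = _partial_r(a, b, c)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        b_perm = B.values[np.ix_(p, p)][iu]
        try:
            r = _partial_r(a, b_perm, c)
        except ValueError:
            continue
        if tail == "greater":
            count += r >= r_obs - 1e-12
        elif tail == "two-sided":
            count += abs(r) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return float(r_obs), (1 + count) / (n_perm + 1)


def barrier_indicator(cells: StudyCellTable) -> DistanceMatrix:
    """Indicator matrix: 1 for pairs on different sides of the barrier."""
    if cells.side is None:
        raise ValueError("study-cell table carries no side-of-barrier labels")
    side = np.asarray(cells.side, dtype=object)
    v = (side[:, None] != side[None, :]).astype(float)
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(cells.labels, v, "indicator")


# ---------------------------------------------------------------------------
# Rousset's a-hat
# ---------------------------------------------------------------------------

def rousset_a(ds: GenotypeDataset, cell: str | None = None) -> DistanceMatrix:
    """Pairwise Rousset (2000) a-hat between individuals.

    Identity-probability form: per locus, Q_w is the mean probability of
    allelic identity of the two genes *within* each of the two individuals and
    Q_b the identity probability of one gene from each; the multilocus
    estimator is the ratio of sums  sum_l (Qw_l - Qb_l) / sum_l (1 - Qw_l),
    which weights loci by their information content (1 - Qw).  Values may be
    negative; a fully-homozygous pair is degenerate (0/0 -> 0, disjoint
    fixation -> +inf) and flagged via a warning.
    """
    idx = ds.cell_index(cell) if cell is not None else np.arange(ds.n_individuals)
    if idx.size < 3:
        raise ValueError("need >=3 individuals")
    calls = ds.calls[idx]
    n, L = calls.shape[0], calls.shape[1]
    labels = [ds.individuals[i] for i in idx]

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for l in range(L):
        g = calls[:, l, :]
        typed = g[:, 0] != MISSING
        codes = np.unique(g[typed])
        if codes.size == 0:
            continue
        k = codes.size
        # allele-frequency vectors per individual: rows sum to 1
        F = np.zeros((n, k))
        a1 = np.searchsorted(codes, g[typed, 0])
        a2 = np.searchsorted(codes, g[typed, 1])
        rows = np.flatnonzero(typed)
        np.add.at(F, (rows, a1), 0.5)
        np.add.at(F, (rows, a2), 0.5)
        qw_ind = (g[:, 0] == g[:, 1]).astype(float)  # 1 if homozygous
        qb = F @ F.T  # (1/4) sum over the four cross-individual gene pairs
        qw_pair = 0.5 * (qw_ind[:, None] + qw_ind[None, :])
        both = np.outer(typed, typed)
        num += np.where(both, qw_pair - qb, 0.0)
        den += np.where(both, 1.0 - qw_pair, 0.0)
        shared += both.astype(int)

    if np.any(shared[np.triu_indices(n, 1)] == 0):
        raise ValueError("pair with no shared typed locus")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = num / den
    degenerate = den == 0
    if degenerate[np.triu_indices(n, 1)].any():
        logger.warning("fully homozygous pair(s): a-hat degenerate (0 or inf)")
        a = np.where(degenerate & (num <= 0), 0.0, a)
        a = np.where(degenerate & (num > 0), np.inf, a)
    np.fill_diagonal(a, 0.0)
    a = 0.5 * (a + a.T)
    kind = "resistance" if np.isinf(a).any() else "genetic"  # inf allowed only there
    return DistanceMatrix(tuple(labels), a, kind)


# ---------------------------------------------------------------------------
# Smouse-Peakall spatial autocorrelation
# ---------------------------------------------------------------------------

def smouse_peakall_sqdist(calls: np.ndarray) -> np.ndarray:
    """Summed per-locus squared genetic distances between individuals.

    ``calls``: (n, L, 2) sorted allele pairs with MISSING sentinel; loci where
    either individual is untyped contribute 0 (pairs are assumed near-complete
    for autocorrelation use).
    """
    n, L, _ = calls.shape
    D = np.zeros((n, n))
    for l in range(L):
        g = calls[:, l, :]
        typed = g[:, 0] != MISSING
        a, b = g[:, 0], g[:, 1]
        hom = a == b
        # shared allele counts between unordered pairs
        eq = np.zeros((n, n))
        for x in (a, b):
            for y in (a, b):
                eq += (x[:, None] == y[None, :])
        # eq counts ordered matches among the 4 cross pairings (0..4)
        d2 = np.empty((n, n))
        hom_i = hom[:, None]
        hom_j = hom[None, :]
        both_hom = hom_i & hom_j
        both_het = ~hom_i & ~hom_j
        mixed = ~both_hom & ~both_het
        # classify via number of ordered matches
        d2[...] = 0.0
        d2[both_hom & (eq == 0)] = 4.0  # ii-jj
        d2[both_hom & (eq == 4)] = 0.0  # ii-ii
        d2[mixed & (eq == 2)] = 1.0     # ii-ij
        d2[mixed & (eq == 0)] = 3.0     # ii-jk
        d2[both_het & (eq == 4)] = 0.0  # ij-ij
        d2[both_het & (eq == 1)] = 1.0  # ij-ik
        d2[both_het & (eq == 0)] = 2.0  # ij-kl
        ok = np.outer(typed, typed)
        D += np.where(ok, d2, 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def _autocorr_r(C: np.ndarray, pair_sets) -> np.ndarray:
    """r per class: sum of off-diagonal covariances over half the summed
    diagonal terms of the individuals involved (with pair multiplicity)."""
    out = np.full(len(pair_sets), np.nan)
    diag = np.diag(C)
    for k, (ii, jj) in enumerate(pair_sets):
        if ii.size < 2:
            continue
        den = 0.5 * (diag[ii] + diag[jj]).sum()
        out[k] = C[ii, jj].sum() / den if den > 0 else 0.0
    return out


def spatial_autocorrelation(ds: GenotypeDataset, cell: str | None = None,
                            class_width_m: float = 100.0,
                            max_dist_m: float = 2000.0,
                            n_perm: int = 999, n_boot: int = 999,
                            seed: int | None = None) -> pd.DataFrame:
    """Multivariate spatial autocorrelogram (Smouse-Peakall r) per distance
    class.

    Distance classes are half-open [lo, hi) of width ``class_width_m`` up to
    ``max_dist_m`` (the last class includes its upper bound); pairs beyond the
    bound are excluded.  The permutation null (coordinates shuffled among
    individuals) yields a 95% envelope; a bootstrap over pairs within each
    class yields the CI around r.
    """
    if class_width_m <= 0:
        raise ValueError("class width must be positive")
    idx = ds.cell_index(cell) if cell is not None else np.arange(ds.n_individuals)
    if idx.size < 10:
        raise ValueError("need >=10 individuals with coordinates")
    calls = ds.calls[idx]
    xy = ds.coords[idx]
    n = idx.size
    D2 = smouse_peakall_sqdist(calls)
    if not D2.any():
        logger.warning("all individuals genetically identical: r undefined, set 0")
    J = np.eye(n) - np.ones((n, n)) / n
    C = -0.5 * J @ D2 @ J

    geo = squareform(pdist(xy))
    edges = np.arange(0.0, max_dist_m + class_width_m, class_width_m)
    edges = edges[edges <= max_dist_m + 1e-9]
    if edges[-1] < max_dist_m:
        edges = np.append(edges, max_dist_m)
    nclass = len(edges) - 1
    iu = np.triu_indices(n, k=1)
    gd = geo[iu]

    def classify(gd_vec):
        cls = np.floor(gd_vec / class_width_m).astype(int)
        cls[np.isclose(gd_vec, max_dist_m)] = nclass - 1  # upper bound inclusive
        cls[(gd_vec > max_dist_m) | (cls >= nclass)] = -1
        return cls

    cls = classify(gd)
    pair_sets = []
    for k in range(nclass):
        sel = cls == k
        pair_sets.append((iu[0][sel], iu[1][sel]))
    r = _autocorr_r(C, pair_sets)

    rng = np.random.default_rng(seed)
    perm_r = np.full((n_perm, nclass), np.nan)
    for t in range(n_perm):
        p = rng.permutation(n)
        gp = geo[np.ix_(p, p)][iu]
        cp = classify(gp)
        ps = [(iu[0][cp == k], iu[1][cp == k]) for k in range(nclass)]
        perm_r[t] = _autocorr_r(C, ps)
    with np.errstate(invalid="ignore"):
        null_lo = np.nanpercentile(perm_r, 2.5, axis=0)
        null_hi = np.nanpercentile(perm_r, 97.5, axis=0)

    boot_lo = np.full(nclass, np.nan)
    boot_hi = np.full(nclass, np.nan)
    for k, (ii, jj) in enumerate(pair_sets):
        m = ii.size
        if m < 2:
            continue
        draws = rng.integers(0, m, size=(n_boot, m))
        vals = np.empty(n_boot)
        diag = np.diag(C)
        for t in range(n_boot):
            d = draws[t]
            den = 0.5 * (diag[ii[d]] + diag[jj[d]]).sum()
            vals[t] = C[ii[d], jj[d]].sum() / den if den > 0 else 0.0
        boot_lo[k], boot_hi[k] = np.percentile(vals, [2.5, 97.5])

    return pd.DataFrame({
        "class_lo": edges[:-1],
        "class_hi": edges[1:],
        "n_pairs": [s[0].size for s in pair_sets],
        "r": r,
        "null_lo": null_lo,
        "null_hi": null_hi,
        "boot_lo": boot_lo,
        "boot_hi": boot_hi,
    })
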