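"""Genetic diversity and differentiation statistics.

Per study cell: observed/unbiased expected heterozygosity, rarefied allelic
richness, and the Weir-Cockerham inbreeding coefficient F_IS with a
bootstrap-over-loci confidence interval.  Between cells: pairwise
Weir-Cockerham theta (F_ST) and Jost's D_EST (Nei-Chesser unbiased
heterozygosities, ratio-of-averages across loci), with permutation p-values
(individuals shuffled between the two cells) and bootstrap-over-loci CIs.

All estimators work from per-cell x per-locus allele-count arrays
(:func:`allele_count_arrays`), so bootstrap replicates over individuals are a
single bincount away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .distances import DistanceMatrix
from .genotypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Per-cell x locus x allele counts (padded to the widest locus).

    AC[c, l, a]  — allele copies of allele a at locus l in cell c
    HC[c, l, a]  — heterozygous individuals carrying allele a
    N[c, l]      — complete genotypes
    HET[c, l]    — heterozygous individuals
    """

    cells: list[str]
    loci: list[str]
    AC: np.ndarray
    HC: np.ndarray
    N: np.ndarray
    HET: np.ndarray
    codes: list[np.ndarray]  # allele codes per locus (padded columns beyond are unused)


def allele_count_arrays(ds: GenotypeDataset, cells: list[str] | None = None) -> CountTable:
    cells = cells if cells is not None else ds.cell_labels()
    cell_pos = {c: i for i, c in enumerate(cells)}
    cidx = np.array([cell_pos.get(c, -1) for c in ds.cells])
    keep = cidx >= 0
    C, L = len(cells), ds.n_loci
    codes = [ds.allele_codes(l) for l in range(L)]
    K = max((c.size for c in codes), default=1) or 1
    AC = np.zeros((C, L, K))
    HC = np.zeros((C, L, K))
    N = np.zeros((C, L))
    HET = np.zeros((C, L))
    for l in range(L):
        k = codes[l].size
        if k == 0:
            continue
        g = ds.calls[:, l, :]
        ok = keep & (g[:, 0] != MISSING)
        if not ok.any():
            continue
        a1 = np.searchsorted(codes[l], g[ok, 0])
        a2 = np.searchsorted(codes[l], g[ok, 1])
        cc = cidx[ok]
        AC[:, l, :k] = (
            np.bincount(cc * k + a1, minlength=C * k)
            + np.bincount(cc * k + a2, minlength=C * k)
        ).reshape(C, k)
        het = a1 != a2
        if het.any():
            HC[:, l, :k] = (
                np.bincount(cc[het] * k + a1[het], minlength=C * k)
                + np.bincount(cc[het] * k + a2[het], minlength=C * k)
            ).reshape(C, k)
        N[:, l] = np.bincount(cc, minlength=C)
        HET[:, l] = np.bincount(cc[het], minlength=C)
    return CountTable(list(cells), list(ds.loci), AC, HC, N, HET, codes)


# ---------------------------------------------------------------------------
# Per-cell diversity
# ---------------------------------------------------------------------------

def heterozygosities(ds: GenotypeDataset, cell: str, locus: str | int) -> tuple[float, float]:
    """(Ho, He): observed heterozygosity and Nei's unbiased expected
    heterozygosity (2n/(2n-1)) (1 - sum p^2) at one cell x locus."""
    l = locus if isinstance(locus, (int, np.integer)) else ds.locus_index(locus)
    idx = ds.cell_index(cell)
    g = ds.calls[idx, l, :]
    g = g[g[:, 0] != MISSING]
    n = len(g)
    if n == 0:
        raise ValueError(f"no complete genotypes at locus in cell {cell!r}")
    ho = float(np.mean(g[:, 0] != g[:, 1]))
    _, counts = np.unique(g.ravel(), return_counts=True)
    p = counts / (2 * n)
    he = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2)) if n > 1 else 0.0
    return ho, float(he)


def allelic_richness(ds: GenotypeDataset, cell: str, locus: str | int, g: int) -> float:
    """Hypergeometric rarefaction: expected number of alleles in a random
    subsample of ``g`` gene copies."""
    if g < 2:
        raise ValueError("rarefaction gene count g must be >= 2")
    l = locus if isinstance(locus, (int, np.integer)) else ds.locus_index(locus)
    idx = ds.cell_index(cell)
    gg = ds.calls[idx, l, :]
    gg = gg[gg[:, 0] != MISSING]
    n2 = 2 * len(gg)
    if n2 == 0:
        raise ValueError("no complete genotypes")
    if g > n2:
        raise ValueError(f"g={g} exceeds {n2} gene copies in cell {cell!r}")
    _, counts = np.unique(gg.ravel(), return_counts=True)

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.where(
        n2 - counts >= g,
        1.0 - np.exp(log_choose(n2 - counts, g) - log_choose(n2, g)),
        1.0,
    )
    return float(terms.sum())


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_pair_components(AC1, HC1, N1, AC2, HC2, N2):
    """Per-locus Weir-Cockerham (1984) a and a+b+c sums for cell pairs.

    Inputs broadcast over leading pair dimensions; allele axis is last.
    Returns (a_loc, abc_loc) summed over alleles, with loci lacking >=2
    genotypes in either cell masked to 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        n1, n2 = N1, N2
        nbar = (n1 + n2) / 2.0
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        tot = 2 * (n1 + n2)
        pbar = (AC1 + AC2) / tot[..., None]
        p1 = AC1 / (2 * n1[..., None])
        p2 = AC2 / (2 * n2[..., None])
        s2 = (n1[..., None] * (p1 - pbar) ** 2 + n2[..., None] * (p2 - pbar) ** 2) / nbar[..., None]
        hbar = (HC1 + HC2) / (2 * nbar[..., None])
        pq = pbar * (1 - pbar)
        a = (nbar / nc)[..., None] * (
            s2 - (pq - s2 / 2 - hbar / 4) / (nbar - 1)[..., None]
        )
        b = (nbar / (nbar - 1))[..., None] * (
            pq - s2 / 2 - ((2 * nbar - 1) / (4 * nbar))[..., None] * hbar
        )
        c = hbar / 2
        valid = (n1 >= 2) & (n2 >= 2)
        a = np.where(valid[..., None], a, 0.0)
        abc = np.where(valid[..., None], a + b + c, 0.0)
        a = np.nan_to_num(a, nan=0.0, posinf=0.0, neginf=0.0)
        abc = np.nan_to_num(abc, nan=0.0, posinf=0.0, neginf=0.0)
    return a.sum(axis=-1), abc.sum(axis=-1)


def _fis_components(AC, HC, N):
    """Per-locus Weir-Cockerham b+c and c sums for a single population."""
    with np.errstate(divide="ignore", invalid="ignore"):
        n = N[..., None]
        p = AC / (2 * n)
        h = HC / n
        b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * h)
        c = h / 2
        valid = N >= 2
        b = np.where(valid[..., None], b, 0.0)
        c = np.where(valid[..., None], c, 0.0)
        b = np.nan_to_num(b)
        c = np.nan_to_num(c)
    return (b + c).sum(axis=-1), c.sum(axis=-1)


@dataclass(frozen=True)
class FisResult:
    fis: float
    ci_low: float
    ci_high: float
    single_locus: bool = False


def fis(ds: GenotypeDataset, cell: str, n_boot: int = 1000,
        seed: int | None = None) -> FisResult:
    """Multilocus Weir-Cockerham f for one cell with a percentile CI from
    bootstrap resampling over loci.  A single-locus dataset has no
    between-locus variance, so its CI is flagged undefined (NaN bounds)."""
    ct = allele_count_arrays(ds, [cell])
    bc, c = _fis_components(ct.AC[0], ct.HC[0], ct.N[0])  # per locus
    tot_bc, tot_c = bc.sum(), c.sum()
    point = 1.0 - tot_c / tot_bc if tot_bc > 0 else 0.0
    if ds.n_loci < 2:
        logger.warning("single locus: F_IS CI undefined")
        return FisResult(float(point), np.nan, np.nan, single_locus=True)
    rng = np.random.default_rng(seed)
    L = ds.n_loci
    draws = rng.integers(0, L, size=(n_boot, L))
    bc_b = bc[draws].sum(axis=1)
    c_b = c[draws].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_b = 1.0 - c_b / bc_b
    f_b = f_b[np.isfinite(f_b)]
    lo, hi = (np.percentile(f_b, [2.5, 97.5]) if f_b.size else (np.nan, np.nan))
    return FisResult(float(point), float(lo), float(hi))


# ---------------------------------------------------------------------------
# Pairwise differentiation
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    """Pairwise differentiation matrix plus optional inference by pair."""

    matrix: DistanceMatrix
    pvalues: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


def _eligible_cells(ds: GenotypeDataset) -> list[str]:
    cells = []
    for c in ds.cell_labels():
        if ds.cell_index(c).size >= 2:
            cells.append(c)
        else:
            logger.warning("cell %s has <2 individuals: excluded from pairwise stats", c)
    if len(cells) < 2:
        raise ValueError("need >=2 cells with >=2 individuals")
    return cells


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def theta_from_counts(ct: CountTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs multilocus theta; returns (theta condensed, a_loc, abc_loc)
    where the per-locus component arrays have shape (n_pairs, L)."""
    I, J = _pair_indices(len(ct.cells))
    a_loc, abc_loc = _wc_pair_components(
        ct.AC[I], ct.HC[I], ct.N[I], ct.AC[J], ct.HC[J], ct.N[J]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a_loc.sum(axis=1) / abc_loc.sum(axis=1)
    return np.nan_to_num(theta), a_loc, abc_loc


def jost_d_from_counts(ct: CountTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs multilocus Jost D; returns (D condensed, num_loc, den_loc).

    Per locus: Nei-Chesser unbiased Hs and Ht, D_l = 2 (Ht - Hs)/(1 - Hs);
    the multilocus value aggregates 2*mean(num)/mean(den) (ratio of averages).
    """
    I, J = _pair_indices(len(ct.cells))
    n1, n2 = ct.N[I], ct.N[J]  # (P, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        ntilde = 2.0 / (1.0 / n1 + 1.0 / n2)
        p1 = ct.AC[I] / (2 * n1[..., None])
        p2 = ct.AC[J] / (2 * n2[..., None])
        ho = (ct.HET[I] / n1 + ct.HET[J] / n2) / 2.0
        hs_raw = 1.0 - ((p1**2).sum(-1) + (p2**2).sum(-1)) / 2.0
        hs = (ntilde / (ntilde - 1.0)) * (hs_raw - ho / (2.0 * ntilde))
        pbar = (p1 + p2) / 2.0
        ht_raw = 1.0 - (pbar**2).sum(-1)
        ht = ht_raw + hs / (4.0 * ntilde)  # r = 2 demes
        num = ht - hs
        den = 1.0 - hs
        valid = (n1 >= 2) & (n2 >= 2) & np.isfinite(num) & np.isfinite(den)
        num = np.where(valid, num, 0.0)
        den = np.where(valid, den, 0.0)
        D = 2.0 * num.sum(axis=1) / den.sum(axis=1)
    return np.nan_to_num(D), num, den


def jost_d_infinite(p1: np.ndarray, p2: np.ndarray) -> float:
    """Jost's D from known allele frequencies (infinite-sample path)."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    hs = 1.0 - ((p1**2).sum() + (p2**2).sum()) / 2.0
    ht = 1.0 - (((p1 + p2) / 2.0) ** 2).sum()
    if hs >= 1.0:
        raise ValueError("degenerate within-deme heterozygosity")
    return float(2.0 * (ht - hs) / (1.0 - hs))


def _ratio_bootstrap_ci(num_loc: np.ndarray, den_loc: np.ndarray, n_boot: int,
                        rng: np.random.Generator, clip_low: float | None = None):
    """Percentile CI of sum(num)/sum(den) under locus resampling, per pair."""
    P, L = num_loc.shape
    lo = np.zeros(P)
    hi = np.zeros(P)
    draws = rng.integers(0, L, size=(n_boot, L))
    num_b = num_loc[:, draws].sum(axis=2)  # (P, n_boot)
    den_b = den_loc[:, draws].sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num_b / den_b
    r = np.nan_to_num(r)
    lo = np.percentile(r, 2.5, axis=1)
    hi = np.percentile(r, 97.5, axis=1)
    if clip_low is not None:
        lo = np.maximum(lo, clip_low)
        hi = np.maximum(hi, clip_low)
    return lo, hi


def _permutation_pvalues(ds: GenotypeDataset, cells: list[str], stat: str,
                         observed: np.ndarray, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-pair p-values: individuals permuted between the two cells."""
    I, J = _pair_indices(len(cells))
    p = np.zeros(I.size)
    for k, (i, j) in enumerate(zip(I, J)):
        idx = np.concatenate([ds.cell_index(cells[i]), ds.cell_index(cells[j])])
        ni = ds.cell_index(cells[i]).size
        sub = ds.subset(idx)
        ge = 0
        labels = np.array(["a"] * ni + ["b"] * (idx.size - ni), object)
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            sub.cells = perm
            ct = allele_count_arrays(sub, ["a", "b"])
            if stat == "theta":
                val = theta_from_counts(ct)[0][0]
            else:
                val = jost_d_from_counts(ct)[0][0]
            ge += val >= observed[k] - 1e-12
        p[k] = (1 + ge) / (n_perm + 1)
    return p


def _assemble(cells, condensed, kind="genetic") -> DistanceMatrix:
    return DistanceMatrix.from_condensed(cells, condensed, kind)


def pairwise_fst(ds: GenotypeDataset, n_perm: int = 0, n_boot: int = 0,
                 seed: int | None = None) -> DifferentiationResult:
    """Pairwise multilocus Weir-Cockerham theta between study cells.

    Negative point estimates are reported as computed.  ``n_perm`` > 0 adds
    between-cell permutation p-values; ``n_boot`` > 0 adds bootstrap-over-loci
    percentile CIs.
    """
    cells = _eligible_cells(ds)
    ct = allele_count_arrays(ds, cells)
    theta, a_loc, abc_loc = theta_from_counts(ct)
    rng = np.random.default_rng(seed)
    res = DifferentiationResult(_assemble(cells, theta))
    if n_boot:
        res.ci_low, res.ci_high = _ratio_bootstrap_ci(a_loc, abc_loc, n_boot, rng)
    if n_perm:
        res.pvalues = _permutation_pvalues(ds, cells, "theta", theta, n_perm, rng)
    return res


def pairwise_jost_d(ds: GenotypeDataset, n_perm: int = 0, n_boot: int = 0,
                    seed: int | None = None) -> DifferentiationResult:
    """Pairwise multilocus Jost D_EST between study cells (CIs clipped at 0)."""
    cells = _eligible_cells(ds)
    ct = allele_count_arrays(ds, cells)
    D, num_loc, den_loc = jost_d_from_counts(ct)
    rng = np.random.default_rng(seed)
    res = DifferentiationResult(_assemble(cells, D))
    if n_boot:
        lo, hi = _ratio_bootstrap_ci(num_loc, den_loc, n_boot, rng)
        # D is 2 * num/den; CIs clipped at zero per reporting convention
        res.ci_low = np.maximum(2 * lo, 0.0)
        res.ci_high = np.maximum(2 * hi, 0.0)
    if n_perm:
        res.pvalues = _permutation_pvalues(ds, cells, "jost", D, n_perm, rng)
    return res


# ---------------------------------------------------------------------------
# Diversity table
# ---------------------------------------------------------------------------

def diversity_table(ds: GenotypeDataset, g: int | None = None,
                    n_boot: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Per-cell diversity summary: N, Na, A_R, Ho, He, F_IS with 95% CI.

    Allelic richness is rarefied per locus at ``g`` gene copies (default: the
    smallest per-cell gene count at that locus across cells, the most
    conservative common depth).
    """
    cells = ds.cell_labels()
    ct = allele_count_arrays(ds, cells)
    rows = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(cells))
    for ci, cell in enumerate(cells):
        na, ar, ho, he = [], [], [], []
        for l in range(ds.n_loci):
            if ct.N[ci, l] == 0:
                continue
            k = int((ct.AC[ci, l] > 0).sum())
            na.append(k)
            try:
                h_o, h_e = heterozygosities(ds, cell, l)
                ho.append(h_o)
                he.append(h_e)
            except ValueError:
                pass
            gl = g if g is not None else max(2, int(2 * ct.N[:, l][ct.N[:, l] > 0].min()))
            if gl <= 2 * ct.N[ci, l]:
                ar.append(allelic_richness(ds, cell, l, gl))
        f = fis(ds, cell, n_boot=n_boot, seed=cell_seeds[ci].generate_state(1)[0])
        rows.append({
            "cell": cell,
            "N": int(ds.cell_index(cell).size),
            "Na": float(np.mean(na)) if na else np.nan,
            "AR": float(np.mean(ar)) if ar else np.nan,
            "Ho": float(np.mean(ho)) if ho else np.nan,
            "He": float(np.mean(he)) if he else np.nan,
            "Fis": f.fis,
            "Fis_lo": f.ci_low,
            "Fis_hi": f.ci_high,
        })
    return pd.DataFrame(rows).set_index("cell")
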