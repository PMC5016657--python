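"""Synthetic landscapes, study cells, and microsatellite genotypes with known
ground truth.

Two scales of simulation mirror the two scales of analysis:

* Between cells, a deme-level forward Wright-Fisher model: per-generation
  migration proportional to exp(-beta * resistance distance) on the *true*
  surface, followed by binomial drift of 2 N_e gene copies per deme, from a
  shared Dirichlet ancestral frequency spectrum.  Microsatellites are
  k-allele loci without mutation (generations << 1/mu regimes).
* Within a cell, a kin-clustered individual model: family groups share
  ancestry and are spatially dispersed around family centres with scale
  ``dispersal_sigma_m``, producing genotype similarity that decays with
  distance (isolation by distance); sigma -> infinity recovers panmixia on
  the (toroidal) plane.

Scenario presets define the study conditions: ``specialist`` (strong
resistance-driven structure on a high-urban-mortality surface) and
``generalist`` (beta = 0, panmixia).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .distances import DistanceMatrix
from .genotypes import MISSING, GenotypeDataset, StudyCellTable
from .resistance import (
    LANDCOVER_CODES,
    Raster,
    SurfaceHypothesis,
    build_resistance_surface,
    default_hypotheses,
    resistance_distance,
)

logger = logging.getLogger(__name__)

#: Land-cover composition emulating a heavily farmed basin with ~8% forest.
DEFAULT_PROPORTIONS = {
    "forest": 0.08,
    "wetland": 0.04,
    "urban": 0.14,
    "water": 0.02,
    "grassland": 0.08,
    "agriculture": 0.64,
}

#: Quantile-band order of the smoothed field: wet classes at the low end
#: (forest along "drainages", then wetland and open water), built and open
#: upland classes at the high end.  Keeping urban away from the water band
#: stops the two barrier classes from tracing the same filaments.
BAND_ORDER = ("forest", "wetland", "water", "grassland", "urban", "agriculture")


def generate_landscape(n_rows: int, n_cols: int,
                       class_proportions: dict[str, float] | None = None,
                       patchiness: float = 5.0, seed: int | None = None,
                       cell_size: float = 200.0,
                       origin: tuple[float, float] = (0.0, 0.0)) -> Raster:
    """Categorical land-cover raster from a thresholded smoothed random field.

    A Gaussian-filtered white-noise field (sigma = ``patchiness`` pixels) is
    ranked and cut at the cumulative class proportions in :data:`BAND_ORDER`,
    so realized pixel fractions match the targets to within one pixel; larger
    patchiness gives larger mean patch size.
    """
    props = dict(DEFAULT_PROPORTIONS if class_proportions is None else class_proportions)
    vals = np.array([props.get(k, 0.0) for k in BAND_ORDER], dtype=float)
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("class proportions must be non-negative and sum to 1")
    if patchiness <= 0:
        raise ValueError("patchiness must be positive")
    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal((n_rows, n_cols)),
                             sigma=patchiness, mode="wrap")
    order = np.argsort(field_.ravel(), kind="stable")
    n_pix = n_rows * n_cols
    counts = np.floor(vals * n_pix).astype(int)
    counts[-1] = n_pix - counts[:-1].sum()
    out = np.empty(n_pix, dtype=float)
    start = 0
    for name, cnt in zip(BAND_ORDER, counts):
        out[order[start:start + cnt]] = LANDCOVER_CODES[name]
        start += cnt
    return Raster(out.reshape(n_rows, n_cols), cell_size, origin)


def place_cells(raster: Raster, n_cells: int, min_separation_px: float,
                seed: int | None = None, max_tries: int = 20000) -> StudyCellTable:
    """Random focal points on non-nodata pixels with pairwise separation at
    least ``min_separation_px`` pixels; side-of-barrier labels come from a
    horizontal split at the raster's vertical midpoint."""
    rng = np.random.default_rng(seed)
    active = np.argwhere(~raster.nodata_mask)
    if active.size == 0:
        raise ValueError("no usable pixels")
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_cells} cells at separation {min_separation_px}"
            )
        cand = active[rng.integers(0, len(active))]
        if all(np.hypot(*(cand - c)) >= min_separation_px for c in chosen):
            chosen.append(cand)
    labels = [f"c{i + 1:02d}" for i in range(n_cells)]
    xy = np.array([raster.pixel_center(int(r), int(c)) for r, c in chosen])
    mid_y = raster.origin[1] + raster.n_rows * raster.cell_size / 2.0
    side = tuple("N" if y >= mid_y else "S" for _, y in xy)
    return StudyCellTable(tuple(labels), xy, side)


# ---------------------------------------------------------------------------
# Metapopulation simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Everything needed to regenerate a synthetic dataset, and the hidden
    ground truth against which recovery is scored."""

    landcover: Raster
    cells: StudyCellTable
    surface: SurfaceHypothesis
    resistance_d: DistanceMatrix
    beta: float
    m_total: float
    generations: int
    ne: int
    n_loci: int
    n_alleles: int
    sample_sizes: tuple[int, ...]
    missing_rate: float
    coord_jitter_m: float
    seed: int
    scenario: str = "custom"

    def params_json(self) -> str:
        d = {
            "scenario": self.scenario, "surface": self.surface.name,
            "beta": self.beta, "m_total": self.m_total,
            "generations": self.generations, "ne": self.ne,
            "n_loci": self.n_loci, "n_alleles": self.n_alleles,
            "sample_sizes": list(self.sample_sizes),
            "missing_rate": self.missing_rate,
            "coord_jitter_m": self.coord_jitter_m, "seed": self.seed,
            "cells": list(self.cells.labels),
        }
        return json.dumps(d, indent=2, sort_keys=True)


def migration_matrix(D: np.ndarray, beta: float, m_total: float,
                     cap: float = 0.5) -> np.ndarray:
    """Row-stochastic migration matrix with distance-decayed exchange.

    Off-diagonal m_ij = m_total * exp(-beta d_ij): a deme's immigration
    *decreases* with its isolation, which is what lets landscape resistance
    leave a signature in drift (demes behind high-resistance barriers receive
    few migrants and differentiate).  Rows whose total emigration would exceed
    ``cap`` are rescaled to it; the diagonal absorbs the remainder, so rows
    sum to 1.  Demes at infinite distance exchange nothing (a warning notes
    fully isolated demes).
    """
    with np.errstate(over="ignore"):
        w = np.exp(-beta * D)
    w[~np.isfinite(D)] = 0.0
    np.fill_diagonal(w, 0.0)
    M = m_total * w
    rows = M.sum(axis=1)
    over = rows > cap
    if over.any():
        M[over] *= (cap / rows[over])[:, None]
    if np.any(w.sum(axis=1) == 0) and m_total > 0:
        logger.warning("isolated deme(s): no immigration/emigration")
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return M


def simulate_genotypes_from_distance(
    D: DistanceMatrix, beta: float, m_total: float, generations: int, ne: int,
    n_loci: int, n_alleles: int, sample_sizes, missing_rate: float = 0.0,
    cell_xy: np.ndarray | None = None, coord_jitter_m: float = 800.0,
    seed: int | None = None,
) -> GenotypeDataset:
    """Forward deme-level Wright-Fisher simulation over the cells of ``D``."""
    rng = np.random.default_rng(seed)
    cells = list(D.labels)
    C = len(cells)
    if np.isscalar(sample_sizes):
        sizes = np.full(C, int(sample_sizes))
    else:
        sizes = np.broadcast_to(np.asarray(sample_sizes, int), (C,))
    M = migration_matrix(D.values, beta, m_total)
    K, L = n_alleles, n_loci
    anc = rng.dirichlet(np.ones(K), size=L)  # (L, K), shared ancestral pool
    p = np.broadcast_to(anc, (C, L, K)).copy()
    for _ in range(generations):
        p = np.einsum("cd,dlk->clk", M, p)
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=-1, keepdims=True)
        counts = rng.multinomial(2 * ne, p)
        p = counts / (2.0 * ne)

    individuals, cell_col, rows = [], [], []
    coords = []
    if cell_xy is None:
        cell_xy = np.zeros((C, 2))
    for c in range(C):
        n_c = int(sizes[c])
        cum = np.cumsum(p[c], axis=-1)  # (L, K)
        u = rng.random((n_c, L, 2))
        alleles = np.empty((n_c, L, 2), dtype=np.int32)
        for l in range(L):
            alleles[:, l, :] = np.searchsorted(cum[l], u[:, l, :]) + 1
        alleles = np.minimum(alleles, K)
        if missing_rate > 0:
            miss = rng.random((n_c, L)) < missing_rate
            alleles[miss] = MISSING
        rows.append(alleles)
        individuals.extend(f"{cells[c]}_i{t + 1}" for t in range(n_c))
        cell_col.extend([cells[c]] * n_c)
        coords.append(cell_xy[c] + rng.normal(0.0, coord_jitter_m, size=(n_c, 2)))
    return GenotypeDataset(
        individuals, [f"L{l + 1:02d}" for l in range(L)],
        np.concatenate(rows), np.array(cell_col, object), np.concatenate(coords),
    )


def simulate_metapopulation(truth: SimulationTruth) -> GenotypeDataset:
    """Generate the genotype dataset a :class:`SimulationTruth` describes."""
    return simulate_genotypes_from_distance(
        truth.resistance_d, truth.beta, truth.m_total, truth.generations,
        truth.ne, truth.n_loci, truth.n_alleles, truth.sample_sizes,
        truth.missing_rate, truth.cells.xy, truth.coord_jitter_m, truth.seed,
    )


def make_scenario(preset: str = "specialist", seed: int | None = None,
                  n_rows: int = 150, n_cols: int = 150, cell_size: float = 200.0,
                  n_cells: int = 12, n_per_cell: int = 30, n_loci: int = 10,
                  n_alleles: int = 16, patchiness: float = 8.0,
                  min_separation_px: float = 25.0,
                  missing_rate: float = 0.02) -> SimulationTruth:
    """Build a ready-to-simulate scenario.

    ``specialist``: migration follows the high-urban-mortality surface (MortH)
    with beta scaled to 3.5 / median resistance distance — strong landscape-
    driven structure.  ``generalist``: beta = 0 and a large N_e — effective
    panmixia, the null pattern.
    """
    ss = np.random.SeedSequence(seed)
    s_land, s_cells, s_geno = (c.generate_state(1)[0] for c in ss.spawn(3))
    land = generate_landscape(n_rows, n_cols, None, patchiness, s_land,
                              cell_size=cell_size)
    cells = place_cells(land, n_cells, min_separation_px, s_cells)
    hyps = default_hypotheses("specialist")
    if preset == "specialist":
        surface = hyps["MortH"]
        ne, generations, m_total = 100, 150, 0.3
    elif preset == "generalist":
        surface = hyps["IBD"]
        ne, generations, m_total = 2000, 50, 0.3
    else:
        raise ValueError(f"unknown preset {preset!r}")
    res = build_resistance_surface(land, surface)
    D = resistance_distance(res, cells)
    if preset == "specialist":
        finite = D.condensed()
        finite = finite[np.isfinite(finite)]
        beta = 3.5 / float(np.median(finite))
    else:
        beta = 0.0
    return SimulationTruth(
        land, cells, surface, D, beta, m_total, generations, ne,
        n_loci, n_alleles, tuple([n_per_cell] * n_cells), missing_rate,
        coord_jitter_m=0.2 * cell_size * min_separation_px / 5.0,
        seed=int(s_geno), scenario=preset,
    )


# ---------------------------------------------------------------------------
# Within-cell individual model
# ---------------------------------------------------------------------------

def simulate_lattice_individuals(n_individuals: int, dispersal_sigma_m: float,
                                 L: int = 10, k: int = 8,
                                 seed: int | None = None,
                                 extent_m: float = 2000.0,
                                 family_size: int = 5,
                                 copy_prob: float = 0.75) -> GenotypeDataset:
    """Single-cell dataset with isolation by distance at two scales.

    Long range: allele frequencies follow an east-west cline between two
    ancestral pools, with sharpness 1/``dispersal_sigma_m`` (a huge sigma
    flattens the cline).  Short range: individuals belong to kin groups whose
    founders draw Hardy-Weinberg genotypes from their local frequencies;
    members copy each founder allele with probability ``copy_prob`` (else
    redraw locally) and live at the family centre plus an isotropic Gaussian
    displacement of scale ``dispersal_sigma_m``, wrapped on the square so a
    huge sigma yields a uniform, structure-free scatter.
    """
    if n_individuals < 20:
        raise ValueError("need at least 20 individuals")
    if dispersal_sigma_m <= 0:
        raise ValueError("dispersal sigma must be positive")
    rng = np.random.default_rng(seed)
    n_fam = max(2, n_individuals // family_size)
    centers = rng.random((n_fam, 2)) * extent_m
    fam = np.repeat(np.arange(n_fam), int(np.ceil(n_individuals / n_fam)))[:n_individuals]
    pools = rng.dirichlet(np.ones(k), size=(2, L))  # two ancestral pools

    def local_cum(x: np.ndarray) -> np.ndarray:
        """Cumulative local frequencies (len(x), L, k) along the cline."""
        w = 0.5 + 0.5 * np.tanh((x - extent_m / 2.0) / dispersal_sigma_m)
        freq = w[:, None, None] * pools[0] + (1 - w[:, None, None]) * pools[1]
        return np.cumsum(freq, axis=-1)

    def draw_local(cum: np.ndarray) -> np.ndarray:
        """One allele per locus per row of ``cum``."""
        n = cum.shape[0]
        u = rng.random((n, L))
        out = np.empty((n, L), dtype=np.int32)
        for l in range(L):
            for i in range(n):
                out[i, l] = np.searchsorted(cum[i, l], u[i, l]) + 1
        return np.minimum(out, k)

    fam_cum = local_cum(centers[:, 0])
    founders = np.stack([draw_local(fam_cum), draw_local(fam_cum)], axis=-1)
    calls = founders[fam].copy()  # (n, L, 2)
    redraw = rng.random(calls.shape) > copy_prob
    ind_cum = fam_cum[fam]
    fresh = np.stack([draw_local(ind_cum), draw_local(ind_cum)], axis=-1)
    calls[redraw] = fresh[redraw]
    pos = np.mod(centers[fam] + rng.normal(0, dispersal_sigma_m, (n_individuals, 2)),
                 extent_m)
    return GenotypeDataset(
        [f"i{t + 1}" for t in range(n_individuals)],
        [f"L{l + 1:02d}" for l in range(L)],
        calls,
        np.array(["cell"] * n_individuals, object),
        pos,
    )
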