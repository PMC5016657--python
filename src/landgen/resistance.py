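"""Resistance surfaces and circuit-theory effective-resistance distances.

A categorical land-cover raster (ESRI ASCII grid) is mapped to a resistance
surface by a named hypothesis (per-class resistance values, forest = 1 for
the parameterized surfaces).  The raster is then treated as an electrical
network: every pixel is a node, adjacent pixels (8 neighbours by default) are
joined by a resistor whose resistance is the mean of the two pixel values
times the geometric edge length (1 cardinal, sqrt(2) diagonal).  The
effective resistance between study-cell focal pixels integrates all parallel
pathways and is obtained from sparse Laplacian solves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .distances import DistanceMatrix
from .genotypes import StudyCellTable

logger = logging.getLogger(__name__)

#: Land-cover class codes used throughout the package.
LANDCOVER_CODES = {
    "forest": 1,
    "wetland": 2,
    "urban": 3,
    "water": 4,
    "grassland": 5,
    "agriculture": 6,
}
CODE_NAMES = {v: k for k, v in LANDCOVER_CODES.items()}


# ---------------------------------------------------------------------------
# Raster
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """Georeferenced grid; row 0 is the *top* row (ESRI ASCII convention).

    ``origin`` is the (x, y) of the lower-left corner; pixel centres are at
    half-pixel offsets from the corner.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata mask shape mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def world_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing world point (x, y)."""
        col = int(math.floor((x - self.origin[0]) / self.cell_size))
        row_from_bottom = int(math.floor((y - self.origin[1]) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    body = " ".join(lines[i:])
    vals = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    mask = (vals == nodata) if nodata is not None else None
    return Raster(vals, header["cellsize"],
                  (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)), mask)


def write_ascii_grid(raster: Raster, path, nodata_value: float = -9999) -> None:
    vals = np.where(raster.nodata_mask, nodata_value, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata_value}\n")
        for row in vals:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# Surface hypotheses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceHypothesis:
    """Named per-class resistance mapping (class code -> resistance >= 1)."""

    name: str
    resistance: dict[int, float]

    @classmethod
    def from_csv(cls, name: str, path) -> "SurfaceHypothesis":
        df = pd.read_csv(path)
        return cls(name, {int(r["class"]): float(r["resistance"]) for _, r in df.iterrows()})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"class": list(self.resistance), "resistance": list(self.resistance.values())}
        ).to_csv(path, index=False)


# Default parameter tables.  The two null surfaces follow the standard rules
# (IBD all 1; IBB water 500, everything else 1).  The four parameterized
# surfaces encode contrasting forest-relative hypotheses: the mortality family
# treats the agricultural matrix as the dominant hazard, the movement family
# treats open grassland/wetland as the main impediment while crops are
# traversable, and the L/H variants switch the urban class between permeable
# built habitat and near-impassable roaded habitat.  The deliberately strong
# contrasts keep the six hypotheses statistically distinguishable from one
# another on a single landscape; open water is near-impassable throughout.
_SPECIALIST_TABLES = {
    "IBD": {c: 1.0 for c in LANDCOVER_CODES.values()},
    "IBB": {**{c: 1.0 for c in LANDCOVER_CODES.values()}, LANDCOVER_CODES["water"]: 500.0},
    "MortL": {1: 1.0, 2: 2.0, 5: 3.0, 6: 40.0, 3: 15.0, 4: 150.0},
    "MortH": {1: 1.0, 2: 2.0, 5: 3.0, 6: 40.0, 3: 150.0, 4: 150.0},
    "MoveL": {1: 1.0, 2: 5.0, 5: 60.0, 6: 5.0, 3: 15.0, 4: 150.0},
    "MoveH": {1: 1.0, 2: 5.0, 5: 60.0, 6: 5.0, 3: 150.0, 4: 150.0},
}
# A habitat generalist perceives much weaker contrasts between cover types.
_GENERALIST_TABLES = {
    "IBD": {c: 1.0 for c in LANDCOVER_CODES.values()},
    "IBB": {**{c: 1.0 for c in LANDCOVER_CODES.values()}, LANDCOVER_CODES["water"]: 500.0},
    "MortL": {1: 1.0, 2: 1.5, 5: 2.0, 6: 4.0, 3: 8.0, 4: 500.0},
    "MortH": {1: 1.0, 2: 1.5, 5: 2.0, 6: 4.0, 3: 80.0, 4: 500.0},
    "MoveL": {1: 1.0, 2: 2.0, 5: 6.0, 6: 2.0, 3: 8.0, 4: 500.0},
    "MoveH": {1: 1.0, 2: 2.0, 5: 6.0, 6: 2.0, 3: 80.0, 4: 500.0},
}

SURFACE_NAMES = ("IBD", "IBB", "MortL", "MortH", "MoveL", "MoveH")


def default_hypotheses(species: str = "specialist") -> dict[str, SurfaceHypothesis]:
    """The six standard surface hypotheses for a forest specialist or a
    habitat generalist parameterization."""
    tables = {"specialist": _SPECIALIST_TABLES, "generalist": _GENERALIST_TABLES}[species]
    return {n: SurfaceHypothesis(n, dict(t)) for n, t in tables.items()}


def build_resistance_surface(landcover: Raster, hyp: SurfaceHypothesis) -> Raster:
    """Pixel-wise lookup of per-class resistance; every code must be mapped."""
    codes = np.unique(landcover.values[~landcover.nodata_mask]).astype(int)
    unmapped = [int(c) for c in codes if int(c) not in hyp.resistance]
    if unmapped:
        raise ValueError(f"land-cover codes without resistance values: {unmapped}")
    out = np.ones(landcover.values.shape, dtype=float)
    for code, r in hyp.resistance.items():
        if r < 1:
            raise ValueError(f"resistance {r} < 1 for class {code}")
        out[landcover.values == code] = r
    return Raster(out, landcover.cell_size, landcover.origin,
                  landcover.nodata_mask.copy())


# ---------------------------------------------------------------------------
# Effective resistance
# ---------------------------------------------------------------------------

def _build_laplacian(surface: Raster, neighbors: int):
    """Sparse graph Laplacian over non-nodata pixels.

    Edge conductance between adjacent pixels i, j is
    1 / (0.5 (r_i + r_j) w) with w = 1 for cardinal and sqrt(2) for diagonal
    neighbours (geometric edge length).
    """
    active = ~surface.nodata_mask & np.isfinite(surface.values)
    nr, nc = surface.values.shape
    node_id = -np.ones((nr, nc), dtype=np.int64)
    node_id[active] = np.arange(active.sum())
    r = surface.values

    shifts = [((0, 1), 1.0), ((1, 0), 1.0)]
    if neighbors == 8:
        shifts += [((1, 1), math.sqrt(2)), ((1, -1), math.sqrt(2))]
    elif neighbors != 4:
        raise ValueError("neighbors must be 4 or 8")

    rows, cols, data = [], [], []
    for (dr, dc), w in shifts:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = active[r0, c0] & active[r1, c1]
        i = node_id[r0, c0][ok]
        j = node_id[r1, c1][ok]
        g = 1.0 / (0.5 * (r[r0, c0][ok] + r[r1, c1][ok]) * w)
        rows.append(i)
        cols.append(j)
        data.append(g)
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    g = np.concatenate(data)
    n = int(active.sum())
    A = coo_matrix((np.concatenate([g, g]), (np.concatenate([i, j]),
                                             np.concatenate([j, i]))), shape=(n, n))
    A = A.tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    from scipy.sparse import diags

    L = diags(deg) - A
    return L.tocsc(), A, node_id


def resistance_distance(surface: Raster, focal: StudyCellTable,
                        neighbors: int = 8) -> DistanceMatrix:
    """Effective resistance between study-cell focal pixels.

    One sparse LU factorization per connected component; one triangular solve
    per focal node.  Disconnected focal pairs get +inf with a warning.
    """
    if np.all(surface.nodata_mask):
        raise ValueError("all-nodata surface")
    L, A, node_id = _build_laplacian(surface, neighbors)
    focal_nodes = []
    for lbl, (x, y) in zip(focal.labels, focal.xy):
        row, col = surface.world_to_pixel(x, y)
        nid = node_id[row, col]
        if nid < 0:
            raise ValueError(f"focal point of cell {lbl} falls on nodata")
        focal_nodes.append(int(nid))
    focal_nodes = np.asarray(focal_nodes)

    ncomp, comp = connected_components(A, directed=False)
    fcomp = comp[focal_nodes]
    nf = len(focal_nodes)
    R = np.full((nf, nf), np.inf)
    np.fill_diagonal(R, 0.0)

    for cid in np.unique(fcomp):
        members = np.flatnonzero(fcomp == cid)
        if members.size < 2:
            continue
        in_comp = comp == cid
        sub_ids = -np.ones(L.shape[0], dtype=np.int64)
        sub_ids[in_comp] = np.arange(in_comp.sum())
        Lsub = L[in_comp][:, in_comp].tocsc()
        fsub = sub_ids[focal_nodes[members]]
        ground = fsub[0]
        keep = np.ones(Lsub.shape[0], dtype=bool)
        keep[ground] = False
        Lred = Lsub[keep][:, keep].tocsc()
        lu = splu(Lred, permc_spec="MMD_AT_PLUS_A")
        red_index = -np.ones(Lsub.shape[0], dtype=np.int64)
        red_index[keep] = np.arange(keep.sum())
        # potentials for unit current injected at each focal node (ground sink)
        V = np.zeros((members.size, keep.sum()))
        for t, fnode in enumerate(fsub):
            if fnode == ground:
                continue
            e = np.zeros(keep.sum())
            e[red_index[fnode]] = 1.0
            V[t] = lu.solve(e)
        for ti in range(members.size):
            for tj in range(ti + 1, members.size):
                a, b = fsub[ti], fsub[tj]
                if a == ground:
                    val = V[tj][red_index[b]]
                elif b == ground:
                    val = V[ti][red_index[a]]
                else:
                    val = (V[ti][red_index[a]] + V[tj][red_index[b]]
                           - V[ti][red_index[b]] - V[tj][red_index[a]])
                R[members[ti], members[tj]] = R[members[tj], members[ti]] = val

    if np.isinf(R).any():
        logger.warning("disconnected focal pairs: infinite resistance entries")
    return DistanceMatrix(focal.labels, R, "resistance")


def connectivity_index(D: DistanceMatrix, alpha: float) -> pd.Series:
    """Per-cell connectivity S_i = sum_{j != i} exp(-alpha d_ij).

    ``alpha`` is a non-negative scalar inversely related to typical dispersal
    distance; infinite resistance entries contribute 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    v = D.values.copy()
    with np.errstate(over="ignore"):
        w = np.exp(-alpha * v)
    w[np.isinf(v)] = 0.0
    np.fill_diagonal(w, 0.0)
    return pd.Series(w.sum(axis=1), index=list(D.labels), name="S")


def default_connectivity_alpha(D: DistanceMatrix) -> float:
    """1 / median off-diagonal resistance distance (finite entries only)."""
    off = D.condensed()
    off = off[np.isfinite(off) & (off > 0)]
    if off.size == 0:
        raise ValueError("no finite positive distances")
    return float(1.0 / np.median(off))
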