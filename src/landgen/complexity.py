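"""Within-cell landscape pattern metrics: proportion of a focal class, patch
density, and the CLUMPY aggregation index.

Conventions mirror the FRAGSTATS defaults: patch delineation uses the
8-neighbour rule, CLUMPY adjacency uses rook (4-neighbour) double counts with
landscape-boundary segments excluded and the minimum-perimeter correction,
and patch density is expressed as patches per 100 ha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .resistance import Raster

logger = logging.getLogger(__name__)


@dataclass
class CellLandscape:
    """A study cell's clipped raster (cell extent plus buffer) and focal class."""

    label: str
    raster: Raster
    focal_class: int
    buffer_m: float = 0.0

    def __post_init__(self) -> None:
        if self.buffer_m < 0:
            raise ValueError("buffer must be >= 0")
        if self.raster.values.size == 0:
            raise ValueError("empty raster")


def clip_cell(raster: Raster, label: str, center_xy: tuple[float, float],
              half_size_m: float, buffer_m: float = 1600.0,
              focal_class: int = 1) -> CellLandscape:
    """Clip a square window (cell half-size plus buffer) around a focal point.

    The window is truncated at the raster edge; buffer pixels count toward the
    metrics, mirroring analysis of a study cell with its surrounding buffer.
    """
    half = half_size_m + buffer_m
    row, col = raster.world_to_pixel(*center_xy)
    px = max(1, int(round(half / raster.cell_size)))
    r0, r1 = max(0, row - px), min(raster.n_rows, row + px + 1)
    c0, c1 = max(0, col - px), min(raster.n_cols, col + px + 1)
    sub = Raster(
        raster.values[r0:r1, c0:c1].copy(),
        raster.cell_size,
        (raster.origin[0] + c0 * raster.cell_size,
         raster.origin[1] + (raster.n_rows - r1) * raster.cell_size),
        raster.nodata_mask[r0:r1, c0:c1].copy(),
    )
    return CellLandscape(label, sub, focal_class, buffer_m)


def proportion_class(cl: CellLandscape) -> float:
    """Focal-class pixels over non-nodata pixels."""
    valid = ~cl.raster.nodata_mask
    total = int(valid.sum())
    if total == 0:
        raise ValueError("all-nodata landscape")
    return float(((cl.raster.values == cl.focal_class) & valid).sum() / total)


_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def patch_density(cl: CellLandscape, rule: int = 8) -> float:
    """Focal-class patches per 100 ha of (non-nodata) landscape."""
    struct = {8: _STRUCT8, 4: _STRUCT4}[rule]
    focal = (cl.raster.values == cl.focal_class) & ~cl.raster.nodata_mask
    _, n_patches = ndimage.label(focal, structure=struct)
    valid = int((~cl.raster.nodata_mask).sum())
    if valid == 0:
        raise ValueError("all-nodata landscape")
    area_ha = valid * cl.raster.cell_size**2 / 10_000.0
    return float(n_patches / area_ha * 100.0)


def _min_perimeter_segments(n_pixels: int) -> int:
    """Minimum edge length (in pixel sides) of a maximally compact patch of
    ``n_pixels`` cells: 4s, 4s+2, or 4s+4 for s = floor(sqrt(n))."""
    s = int(math.isqrt(n_pixels))
    m = n_pixels - s * s
    if m == 0:
        return 4 * s
    if m <= s:
        return 4 * s + 2
    return 4 * s + 4


def _rook_adjacencies(cl: CellLandscape) -> tuple[int, int]:
    """(like, total) double-count rook adjacencies involving the focal class,
    landscape-boundary and nodata segments excluded."""
    v = cl.raster.values
    valid = ~cl.raster.nodata_mask
    focal = (v == cl.focal_class) & valid
    like = 0
    total = 0
    for axis in (0, 1):
        a = np.take(focal, range(0, focal.shape[axis] - 1), axis=axis)
        b = np.take(focal, range(1, focal.shape[axis]), axis=axis)
        va = np.take(valid, range(0, valid.shape[axis] - 1), axis=axis)
        vb = np.take(valid, range(1, valid.shape[axis]), axis=axis)
        ok = va & vb
        like += int((a & b & ok).sum())
        total += int(((a | b) & ok).sum())
    # double-count convention: like adjacencies are seen from both focal
    # pixels; mixed adjacencies only from their focal side
    return 2 * like, 2 * like + (total - like)


def clumpy(cl: CellLandscape) -> float:
    """FRAGSTATS CLUMPY aggregation index in [-1, 1].

    G = like adjacencies / (all focal adjacencies - min perimeter), with P the
    focal-class proportion; CLUMPY = (G - P)/P when G < P and P < 0.5, else
    (G - P)/(1 - P).  -1 is maximal disaggregation (checkerboard), 0 random,
    1 a single maximally compact patch.
    """
    valid = ~cl.raster.nodata_mask
    focal = (cl.raster.values == cl.focal_class) & valid
    n_focal = int(focal.sum())
    if n_focal == 0:
        raise ValueError("focal class absent: CLUMPY undefined")
    P = proportion_class(cl)
    g_like, g_total = _rook_adjacencies(cl)
    min_e = _min_perimeter_segments(n_focal)
    denom = g_total - min_e
    if denom <= 0:
        # the class is a single compact (or boundary-clipped) blob
        G = 1.0
    else:
        G = min(1.0, g_like / denom)
    if P >= 1.0:
        logger.warning("focal class fills landscape: CLUMPY degenerate, set 1")
        return 1.0
    if G < P and P < 0.5:
        val = (G - P) / P
    else:
        val = (G - P) / (1.0 - P)
    return float(np.clip(val, -1.0, 1.0))


def complexity_metrics(cl: CellLandscape, absent_focal: str = "zero") -> dict[str, float]:
    """prFor, PD, Clumpy for one buffered study-cell landscape.

    When the focal class is absent CLUMPY is undefined; ``absent_focal``
    selects the downstream convention: "zero" substitutes 0 (no aggregation
    information, keeps the cell usable as a model predictor) and "nan"
    propagates NaN.
    """
    p = proportion_class(cl)
    pd_ = patch_density(cl)
    try:
        c = clumpy(cl)
    except ValueError:
        logger.warning("cell %s: focal class absent, Clumpy set per policy %r",
                       cl.label, absent_focal)
        c = 0.0 if absent_focal == "zero" else float("nan")
    return {"prFor": p, "PD": pd_, "Clumpy": c}
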