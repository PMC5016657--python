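"""Diploid multilocus genotype container, file I/O, and quality-control gates.

The central object is :class:`GenotypeDataset`: individuals x loci unordered
diploid allele pairs (positive integer codes), each individual carrying a
study-cell label and planar coordinates in metres.  Missing calls are held as
the in-memory sentinel :data:`MISSING`, never as allele code 0 — zero is a
file-format convention (GENEPOP) that must not leak into statistics.

Quality control follows standard microsatellite practice: per-individual
missingness filtering, Monte-Carlo exact Hardy-Weinberg tests per cell x locus,
Benjamini-Yekutieli false-discovery-rate correction across the test grid, and
a Brookfield null-allele frequency estimate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: In-memory sentinel for a missing allele call (both alleles of a missing
#: genotype are set to this).  Allele codes are strictly positive integers.
MISSING = -1


class GenepopParseError(ValueError):
    """Raised for malformed GENEPOP input; message names the offending line."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its ordered set of allele codes."""

    name: str
    allele_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.allele_codes) < 1:
            raise ValueError(f"locus {self.name!r} has no allele codes")
        if len(set(self.allele_codes)) != len(self.allele_codes):
            raise ValueError(f"locus {self.name!r} has duplicate allele codes")
        if any(a <= 0 for a in self.allele_codes):
            raise ValueError(f"locus {self.name!r} has non-positive allele codes")


@dataclass(frozen=True)
class StudyCellTable:
    """Study-cell focal coordinates and optional side-of-barrier labels."""

    labels: tuple[str, ...]
    xy: np.ndarray  # (n_cells, 2) metres
    side: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate study-cell labels")
        xy = np.asarray(self.xy, dtype=float)
        if xy.shape != (len(self.labels), 2):
            raise ValueError("one (x, y) pair required per cell")
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite study-cell coordinates")
        object.__setattr__(self, "xy", xy)
        if self.side is not None and len(self.side) != len(self.labels):
            raise ValueError("side labels must match cell labels")

    @classmethod
    def from_csv(cls, path) -> "StudyCellTable":
        df = pd.read_csv(path, dtype={"cell": str})
        side = tuple(df["side"].astype(str)) if "side" in df.columns else None
        return cls(tuple(df["cell"]), df[["x", "y"]].to_numpy(float), side)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"cell": self.labels, "x": self.xy[:, 0], "y": self.xy[:, 1]})
        if self.side is not None:
            df["side"] = self.side
        df.to_csv(path, index=False)


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid allele calls with cell labels and coordinates.

    ``calls`` has shape (n_individuals, n_loci, 2); each pair is stored sorted
    (low allele first) so equal genotypes compare equal bit-for-bit.  A missing
    genotype is ``(MISSING, MISSING)``.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    cells: np.ndarray  # (n,) str labels
    coords: np.ndarray  # (n, 2) float metres

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        self.cells = np.asarray(self.cells, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != {(n, L, 2)}")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual identifiers")
        if self.cells.shape != (n,):
            raise ValueError("every individual needs a cell label")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n, 2)")
        # canonicalize pair order; keep MISSING pairs as-is
        self.calls = np.sort(self.calls, axis=2)
        bad = (self.calls[:, :, 0] == MISSING) ^ (self.calls[:, :, 1] == MISSING)
        if np.any(bad):
            raise ValueError("half-missing genotype call")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing genotype calls."""
        return self.calls[:, :, 0] == MISSING

    def cell_labels(self) -> list[str]:
        """Unique cell labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c, None)
        return list(seen)

    def cell_index(self, cell: str) -> np.ndarray:
        idx = np.flatnonzero(self.cells == cell)
        if idx.size == 0:
            raise KeyError(f"no individuals in cell {cell!r}")
        return idx

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def allele_codes(self, locus: str | int) -> np.ndarray:
        l = locus if isinstance(locus, (int, np.integer)) else self.locus_index(locus)
        a = self.calls[:, l, :].ravel()
        return np.unique(a[a != MISSING])

    def subset(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            [self.individuals[i] for i in idx],
            list(self.loci),
            self.calls[idx].copy(),
            self.cells[idx].copy(),
            self.coords[idx].copy(),
        )

    def drop_loci(self, loci: Iterable[str]) -> "GenotypeDataset":
        drop = set(loci)
        keep = [i for i, l in enumerate(self.loci) if l not in drop]
        return GenotypeDataset(
            list(self.individuals),
            [self.loci[i] for i in keep],
            self.calls[:, keep].copy(),
            self.cells.copy(),
            self.coords.copy(),
        )


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path, cells_csv=None) -> GenotypeDataset:
    """Read a GENEPOP file (2- or 3-digit allele codes, 00/000 = missing).

    POP blocks become cell labels ``pop1``, ``pop2``, ... unless ``cells_csv``
    (an individuals CSV with id, cell, x, y columns) overrides labels and
    coordinates.  Raises :class:`GenepopParseError` with a line number on
    malformed allele widths or ragged locus counts.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be GENEPOP")
    # line 0 is the title; locus names run until the first POP line
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")
    L = len(locus_names)

    individuals: list[str] = []
    cells: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    pop = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if _POP_RE.match(line):
            pop += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno + 1}: missing ',' separator")
        ind_id, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != L:
            raise GenepopParseError(
                f"line {lineno + 1}: {len(tokens)} genotypes for {L} loci"
            )
        pair_row = np.empty((L, 2), dtype=np.int32)
        for j, tok in enumerate(tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(
                    f"line {lineno + 1}: malformed allele token {tok!r}"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"line {lineno + 1}: allele width {w} != established {width}"
                )
            a, b = int(tok[:w]), int(tok[w:])
            if a == 0 or b == 0:
                pair_row[j] = (MISSING, MISSING)
            else:
                pair_row[j] = (a, b)
        individuals.append(ind_id.strip())
        cells.append(f"pop{pop}")
        rows.append(pair_row)

    calls = np.stack(rows) if rows else np.empty((0, L, 2), dtype=np.int32)
    coords = np.full((len(individuals), 2), np.nan)
    ds = GenotypeDataset(individuals, locus_names, calls, np.array(cells, object), coords)
    if cells_csv is not None:
        side = pd.read_csv(cells_csv, dtype={"id": str, "cell": str}).set_index("id")
        labels = [side.loc[i, "cell"] for i in ds.individuals]
        xy = np.array([[side.loc[i, "x"], side.loc[i, "y"]] for i in ds.individuals], float)
        ds = replace(ds, cells=np.array(labels, object), coords=xy)
    return ds


def write_genepop(ds: GenotypeDataset, path, title: str = "landgen export") -> None:
    """Write GENEPOP; allele width 3 if any code exceeds 99, else 2."""
    width = 3 if any(ds.allele_codes(l).size and ds.allele_codes(l).max() > 99 for l in range(ds.n_loci)) else 2
    zero = "0" * width
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in ds.loci:
            fh.write(name + "\n")
        order = ds.cell_labels()
        for cell in order:
            fh.write("POP\n")
            for i in ds.cell_index(cell):
                toks = []
                for j in range(ds.n_loci):
                    a, b = ds.calls[i, j]
                    if a == MISSING:
                        toks.append(zero + zero)
                    else:
                        toks.append(f"{a:0{width}d}{b:0{width}d}")
                fh.write(f"{ds.individuals[i]} , " + " ".join(toks) + "\n")


def read_individuals_csv(path) -> GenotypeDataset:
    """Read the CSV dialect: id, cell, x, y, then one column per locus as
    ``a1/a2`` with ``.`` marking a missing genotype."""
    df = pd.read_csv(path, dtype=str)
    meta = ["id", "cell", "x", "y"]
    loci = [c for c in df.columns if c not in meta]
    calls = np.full((len(df), len(loci), 2), MISSING, dtype=np.int32)
    for j, locus in enumerate(loci):
        for i, v in enumerate(df[locus]):
            if isinstance(v, str) and v.strip() and v.strip() != ".":
                a, b = v.split("/")
                calls[i, j] = (int(a), int(b))
    return GenotypeDataset(
        list(df["id"]),
        loci,
        calls,
        df["cell"].to_numpy(object),
        df[["x", "y"]].astype(float).to_numpy(),
    )


def write_individuals_csv(ds: GenotypeDataset, path) -> None:
    cols = {"id": ds.individuals, "cell": ds.cells, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    for j, locus in enumerate(ds.loci):
        col = []
        for i in range(ds.n_individuals):
            a, b = ds.calls[i, j]
            col.append("." if a == MISSING else f"{a}/{b}")
        cols[locus] = col
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def missing_rate(ds: GenotypeDataset, scope: str = "dataset"):
    """Fraction of missing genotype calls, over the whole dataset or per row."""
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("empty dataset")
    m = ds.missing_mask
    if scope == "dataset":
        return float(m.mean())
    if scope == "individual":
        return m.mean(axis=1)
    raise ValueError(f"unknown scope {scope!r}")


def filter_individuals(ds: GenotypeDataset, max_missing: float) -> GenotypeDataset:
    """Retain individuals whose missing fraction is strictly below ``max_missing``.

    The strict inequality mirrors the usual "<30% missing" acceptance rule.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    rates = missing_rate(ds, "individual")
    keep = np.flatnonzero(rates < max_missing)
    dropped = set(range(ds.n_individuals)) - set(keep.tolist())
    for i in sorted(dropped):
        logger.info("dropped individual %s (missing %.3f >= %.3f)",
                    ds.individuals[i], rates[i], max_missing)
    return ds.subset(keep)


@dataclass(frozen=True)
class HWEResult:
    p: float
    statistic: float
    n: int
    monomorphic: bool = False


def _genotype_log_prob(pair_counts: np.ndarray, het_mask: np.ndarray,
                       allele_counts: np.ndarray, n: int) -> float:
    """log P(genotype table | allele counts) under HWE (Levene's conditional
    distribution): n! 2^h prod(c_a!) / ((2n)! prod(n_ij!))."""
    h = int(pair_counts[het_mask].sum())
    return float(
        gammaln(n + 1)
        + h * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
        - gammaln(pair_counts + 1).sum()
    )


def hwe_exact_test(ds: GenotypeDataset, cell: str, locus: str | int,
                   n_perm: int = 999, seed: int | None = None) -> HWEResult:
    """Monte-Carlo exact Hardy-Weinberg test for one cell x locus.

    Alleles observed in the cell are pooled and re-paired at random ``n_perm``
    times; the test statistic is the negative log conditional probability of
    the genotype table given allele counts, and
    p = (1 + #{perm statistic >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    l = locus if isinstance(locus, (int, np.integer)) else ds.locus_index(locus)
    idx = ds.cell_index(cell)
    g = ds.calls[idx, l, :]
    g = g[g[:, 0] != MISSING]
    n = len(g)
    if n < 2:
        raise ValueError(f"<2 non-missing genotypes at locus in cell {cell!r}")
    codes, flat = np.unique(g, return_inverse=True)
    K = codes.size
    if K == 1:
        logger.warning("monomorphic locus in cell %s: HWE p set to 1", cell)
        return HWEResult(1.0, 0.0, n, monomorphic=True)
    pairs = flat.reshape(n, 2)  # sorted within pair already

    tri = np.zeros((K, K), dtype=np.intp)  # index of pair (i<=j) into flat table
    pair_ids = pairs[:, 0] * K + pairs[:, 1]

    def stat_of(pair_ids_arr: np.ndarray) -> float:
        counts = np.bincount(pair_ids_arr, minlength=K * K).reshape(K, K)
        i, j = np.nonzero(counts)
        pc = counts[i, j]
        het = i != j
        ac = np.bincount(pair_ids_arr // K, minlength=K) + np.bincount(
            pair_ids_arr % K, minlength=K)
        return -_genotype_log_prob(pc, het, ac.astype(float), n)

    obs = stat_of(pair_ids)
    rng = np.random.default_rng(seed)
    alleles = pairs.ravel().copy()
    ge = 0
    for _ in range(n_perm):
        rng.shuffle(alleles)
        pp = np.sort(alleles.reshape(n, 2), axis=1)
        ge += stat_of(pp[:, 0] * K + pp[:, 1]) >= obs - 1e-12
    p = (1 + ge) / (n_perm + 1)
    return HWEResult(float(p), float(obs), n)


def fdr_threshold(pvalues: Sequence[float], alpha: float,
                  method: str = "benjamini_yekutieli"):
    """Step-up FDR control; returns (reject boolean array, effective cutoff).

    Benjamini-Yekutieli divides the step-up slopes by c(m) = sum_{i<=m} 1/i,
    which keeps FDR control under arbitrary dependence among tests;
    ``benjamini_hochberg`` is offered for comparison.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if method == "benjamini_yekutieli":
        c = np.sum(1.0 / np.arange(1, m + 1))
    elif method == "benjamini_hochberg":
        c = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p)
    thresholds = np.arange(1, m + 1) * alpha / (m * c)
    below = p[order] <= thresholds
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    k = int(np.max(np.flatnonzero(below)))
    cutoff = float(p[order][k])
    return p <= cutoff, cutoff


def null_allele_freq(ds: GenotypeDataset, cell: str, locus: str | int) -> float:
    """Brookfield (1996) estimator 1: r = (He - Ho) / (1 + He), clipped at 0.

    He is the unbiased expected heterozygosity; a heterozygote deficit relative
    to He is attributed to a non-amplifying allele.
    """
    from .diversity import heterozygosities  # local import avoids a cycle

    l = locus if isinstance(locus, (int, np.integer)) else ds.locus_index(locus)
    if ds.allele_codes(l).size < 2:
        logger.warning("monomorphic locus: null-allele frequency set to 0")
        return 0.0
    ho, he = heterozygosities(ds, cell, l)
    return max(0.0, (he - ho) / (1.0 + he))


@dataclass
class HWEScreenReport:
    """Locus x cell HWE rejection grid and the loci flagged for removal."""

    pvalues: pd.DataFrame  # cells x loci
    reject: pd.DataFrame  # cells x loci booleans after FDR
    cutoff: float
    drop: list[str]
    linkage_note: str = "LE tests not computed"

    def to_tsv(self, path) -> None:
        out = self.pvalues.copy()
        out.to_csv(path, sep="\t")


def hwe_screen(ds: GenotypeDataset, n_perm: int = 999, seed: int | None = None,
               fdr_alpha: float = 0.013, drop_fraction: float = 1.0) -> HWEScreenReport:
    """Run HWE tests on every cell x locus, FDR-correct the grid, and flag loci
    rejected in at least ``drop_fraction`` of the cells where they were testable."""
    cells = ds.cell_labels()
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(len(cells) * ds.n_loci))
    pmat = np.full((len(cells), ds.n_loci), np.nan)
    for ci, cell in enumerate(cells):
        for l in range(ds.n_loci):
            s = next(child)
            try:
                pmat[ci, l] = hwe_exact_test(ds, cell, l, n_perm=n_perm,
                                             seed=s.generate_state(1)[0]).p
            except ValueError:
                continue
    flat = pmat.ravel()
    ok = ~np.isnan(flat)
    reject_flat = np.zeros_like(flat, dtype=bool)
    cutoff = 0.0
    if ok.any():
        rej, cutoff = fdr_threshold(flat[ok], fdr_alpha)
        reject_flat[ok] = rej
    reject = reject_flat.reshape(pmat.shape)
    drop = []
    for l, locus in enumerate(ds.loci):
        tested = ~np.isnan(pmat[:, l])
        if tested.any() and reject[tested, l].mean() >= drop_fraction:
            drop.append(locus)
    pdf = pd.DataFrame(pmat, index=cells, columns=ds.loci)
    rdf = pd.DataFrame(reject, index=cells, columns=ds.loci)
    return HWEScreenReport(pdf, rdf, cutoff, drop)
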