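"""End-to-end orchestration: QC -> diversity/differentiation -> spatial tests
-> landscape (resistance + complexity) -> MRDM/dbRDA model selection ->
bootstrap CIs -> surface comparison.

Every stage derives its random seed deterministically from the master seed,
so a rerun with the same config produces byte-identical outputs.  Inputs are
either simulated from a scenario preset or loaded from the documented file
formats (GENEPOP / individuals CSV, study-cell CSV, ESRI ASCII land cover,
per-hypothesis resistance CSVs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import complexity as cx
from . import diversity as dv
from . import models as md
from . import resistance as rs
from . import simulate as sim
from . import spatial as sp
from .distances import DistanceMatrix
from .genotypes import (
    GenotypeDataset,
    StudyCellTable,
    filter_individuals,
    hwe_screen,
    read_genepop,
    read_individuals_csv,
)

logger = logging.getLogger(__name__)

RESPONSES = ("FST", "DEST")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; validated up front, serialized next to
    the outputs."""

    seed: int = 0
    scenario: str | None = "specialist"  # None -> load from input paths
    species_tables: str = "specialist"
    # inference sizes
    n_perm: int = 999
    n_boot: int = 200
    alpha: float = 0.05
    fdr_alpha: float = 0.013
    max_missing: float = 0.3
    diversity_n_boot: int = 200
    connectivity_alpha: float | None = None  # None -> 1/median(d)
    run_hwe: bool = False
    hwe_n_perm: int = 200
    within_cell: bool = False
    # simulation scale
    n_rows: int = 150
    n_cols: int = 150
    cell_size: float = 200.0
    n_cells: int = 12
    n_per_cell: int = 30
    n_loci: int = 10
    n_alleles: int = 16
    patchiness: float = 8.0
    min_separation_px: float = 25.0
    missing_rate: float = 0.02
    # landscape metrics
    cell_half_size_m: float = 2400.0
    buffer_m: float = 1600.0
    # optional input paths (used when scenario is None)
    genepop: str | None = None
    individuals_csv: str | None = None
    cells_csv: str | None = None
    landcover_asc: str | None = None
    hypothesis_csvs: dict[str, str] | None = None

    def validate(self) -> None:
        if self.scenario is None:
            need = [self.cells_csv, self.landcover_asc]
            if (self.genepop is None and self.individuals_csv is None) or any(
                p is None for p in need
            ):
                raise ValueError("non-simulated runs need genotype, cell, and raster inputs")
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing outside [0, 1]")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    config: RunConfig
    diversity: pd.DataFrame
    differentiation: dict[str, DistanceMatrix]
    mantel: dict[str, dict]
    resistance: dict[str, DistanceMatrix]
    connectivity: pd.DataFrame
    complexity: pd.DataFrame
    mrdm_fits: list[md.ModelFit]
    dbrda_fits: list[md.ModelFit]
    comparisons: dict[str, md.SurfaceComparison]
    accounting: dict[str, int]
    skipped: dict[str, str]
    timings: dict[str, float]
    truth: sim.SimulationTruth | None = None

    def fits(self, method: str, response: str) -> list[md.ModelFit]:
        pool = self.mrdm_fits if method == "mrdm" else self.dbrda_fits
        return [f for f in pool if f.response == response]

    def to_json_dict(self) -> dict:
        def fit_dict(f: md.ModelFit) -> dict:
            return {
                "response": f.response, "surface": f.surface, "method": f.method,
                "predictors": f.predictors, "F": f.F, "r2": f.r2,
                "adj_r2": f.adj_r2, "p": f.p,
                "boot_mean": f.boot_mean, "boot_lo": f.boot_lo, "boot_hi": f.boot_hi,
            }

        return {
            "diversity": json.loads(self.diversity.to_json(orient="index")),
            "differentiation": {k: m.to_frame().to_dict() for k, m in self.differentiation.items()},
            "mantel": self.mantel,
            "resistance": {k: m.to_frame().to_dict() for k, m in self.resistance.items()},
            "connectivity": json.loads(self.connectivity.to_json(orient="index")),
            "complexity": json.loads(self.complexity.to_json(orient="index")),
            "mrdm": [fit_dict(f) for f in self.mrdm_fits],
            "dbrda": [fit_dict(f) for f in self.dbrda_fits],
            "comparisons": {
                k: {"winner": c.winner, "relation": c.relation, "competing": c.competing}
                for k, c in self.comparisons.items()
            },
            "accounting": self.accounting,
            "skipped": self.skipped,
        }


def _mean_metric_matrix(cells: list[str], series: pd.Series, name: str) -> DistanceMatrix:
    """Pairwise matrix of the arithmetic mean of the two cells' metric."""
    v = series.loc[cells].to_numpy(float)
    m = 0.5 * (v[:, None] + v[None, :])
    np.fill_diagonal(m, 0.0)
    dm = DistanceMatrix(tuple(cells), m, "complexity")
    dm.name = name  # type: ignore[attr-defined]
    return dm


def _empty_fit(response: str, surface: str, method: str) -> md.ModelFit:
    return md.ModelFit(response, surface, method, [], np.nan, 0.0, 0.0, np.nan)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    config.validate()
    t0 = time.time()
    timings: dict[str, float] = {}
    skipped: dict[str, str] = {}
    ss = np.random.SeedSequence(config.seed)
    seeds = {k: s.generate_state(1)[0] for k, s in zip(
        ["sim", "hwe", "diversity", "spatial", "mrdm", "dbrda", "boot"], ss.spawn(7)
    )}

    # ---- inputs ---------------------------------------------------------
    truth = None
    if config.scenario is not None:
        truth = sim.make_scenario(
            config.scenario, seed=seeds["sim"], n_rows=config.n_rows,
            n_cols=config.n_cols, cell_size=config.cell_size,
            n_cells=config.n_cells, n_per_cell=config.n_per_cell,
            n_loci=config.n_loci, n_alleles=config.n_alleles,
            patchiness=config.patchiness,
            min_separation_px=config.min_separation_px,
            missing_rate=config.missing_rate,
        )
        ds = sim.simulate_metapopulation(truth)
        cells_tab = truth.cells
        landcover = truth.landcover
        hyps = rs.default_hypotheses(config.species_tables)
    else:
        ds = (read_genepop(config.genepop, config.individuals_csv)
              if config.genepop else read_individuals_csv(config.individuals_csv))
        cells_tab = StudyCellTable.from_csv(config.cells_csv)
        landcover = rs.read_ascii_grid(config.landcover_asc)
        if config.hypothesis_csvs:
            hyps = {n: rs.SurfaceHypothesis.from_csv(n, p)
                    for n, p in config.hypothesis_csvs.items()}
        else:
            hyps = rs.default_hypotheses(config.species_tables)
    missing_cells = set(ds.cells) - set(cells_tab.labels)
    if missing_cells:
        raise ValueError(f"genotype cells missing from cell table: {sorted(missing_cells)}")
    timings["inputs"] = time.time() - t0

    # ---- QC -------------------------------------------------------------
    t = time.time()
    n_before = ds.n_individuals
    ds = filter_individuals(ds, config.max_missing)
    accounting = {
        "individuals_in": n_before,
        "individuals_retained": ds.n_individuals,
        "individuals_dropped_missing": n_before - ds.n_individuals,
    }
    if config.run_hwe:
        screen = hwe_screen(ds, n_perm=config.hwe_n_perm, seed=seeds["hwe"],
                            fdr_alpha=config.fdr_alpha)
        if screen.drop:
            logger.info("dropping loci failing HWE in all cells: %s", screen.drop)
            ds = ds.drop_loci(screen.drop)
        accounting["loci_dropped_hwe"] = len(screen.drop)
    else:
        skipped["hwe_screen"] = "disabled in config (run_hwe=False)"
    timings["qc"] = time.time() - t

    # ---- diversity & differentiation -----------------------------------
    t = time.time()
    div = dv.diversity_table(ds, n_boot=config.diversity_n_boot, seed=seeds["diversity"])
    fst = dv.pairwise_fst(ds).matrix
    dest = dv.pairwise_jost_d(ds).matrix
    differentiation = {"FST": fst, "DEST": dest}
    cells = list(fst.labels)
    timings["popgen"] = time.time() - t

    # ---- spatial tests --------------------------------------------------
    t = time.time()
    tab = cells_tab
    order = [tab.labels.index(c) for c in cells]
    cell_xy = tab.xy[order]
    geo = sp.geographic_distances(cells, cell_xy)
    mantel_out: dict[str, dict] = {}
    rng_sp = np.random.SeedSequence(seeds["spatial"]).spawn(4)
    for i, resp in enumerate(RESPONSES):
        r, p = sp.mantel(differentiation[resp], geo, n_perm=config.n_perm,
                         seed=rng_sp[i].generate_state(1)[0])
        mantel_out[f"ibd_{resp}"] = {"r": float(r), "p": float(p)}
    if tab.side is not None:
        barrier = sp.barrier_indicator(tab).reorder(cells)
        for i, resp in enumerate(RESPONSES):
            r, p = sp.partial_mantel(differentiation[resp], barrier, geo,
                                     n_perm=config.n_perm,
                                     seed=rng_sp[2 + i].generate_state(1)[0])
            mantel_out[f"barrier_{resp}"] = {"r": float(r), "p": float(p)}
    else:
        skipped["barrier_test"] = "no side-of-barrier labels supplied"
    if not config.within_cell:
        skipped["within_cell_ibd"] = "disabled in config (within_cell=False)"
    timings["spatial"] = time.time() - t

    # ---- landscape ------------------------------------------------------
    t = time.time()
    resist: dict[str, DistanceMatrix] = {}
    conn = {}
    focal = StudyCellTable(tuple(cells), cell_xy,
                           tuple(np.asarray(tab.side, object)[order]) if tab.side else None)
    for name in rs.SURFACE_NAMES:
        surf = rs.build_resistance_surface(landcover, hyps[name])
        D = rs.resistance_distance(surf, focal)
        resist[name] = D
        alpha = (config.connectivity_alpha if config.connectivity_alpha is not None
                 else rs.default_connectivity_alpha(D))
        conn[f"S_{name}"] = rs.connectivity_index(D, alpha)
    connectivity = pd.DataFrame(conn)
    metrics_rows = {}
    for c, (x, y) in zip(cells, cell_xy):
        cl = cx.clip_cell(landcover, c, (x, y), config.cell_half_size_m,
                          config.buffer_m)
        metrics_rows[c] = cx.complexity_metrics(cl)
    metrics = pd.DataFrame(metrics_rows).T.loc[cells]
    timings["landscape"] = time.time() - t

    # ---- model selection ------------------------------------------------
    t = time.time()
    cx_names = ["prFor", "PD", "Clumpy"]
    cx_mats = {n: _mean_metric_matrix(cells, metrics[n], n) for n in cx_names}
    dropped_cx = [n for n in cx_names if cx_mats[n].condensed().std() == 0]
    cx_names = [n for n in cx_names if n not in dropped_cx]
    # deduplicate (near-)collinear complexity predictors, keeping the first
    kept: list[str] = []
    for n in cx_names:
        v = cx_mats[n].condensed()
        if any(abs(np.corrcoef(v, cx_mats[k].condensed())[0, 1]) > 0.999
               for k in kept):
            dropped_cx.append(n)
        else:
            kept.append(n)
    cx_names = kept
    if dropped_cx:
        skipped["complexity_predictors"] = (
            f"constant or collinear across cells, excluded: {','.join(dropped_cx)}")
    mrdm_fits: list[md.ModelFit] = []
    mrdm_struct: dict[tuple[str, str], list[str]] = {}
    ss_m = np.random.SeedSequence(seeds["mrdm"]).spawn(len(rs.SURFACE_NAMES) * 2)
    si = 0
    def _well_conditioned(Xs, names):
        """Drop trailing complexity predictors until the design is usable."""
        while len(Xs) > 1:
            cols = np.column_stack([x.condensed() for x in Xs])
            cols = (cols - cols.mean(0)) / np.where(cols.std(0) > 0, cols.std(0), 1)
            if np.linalg.cond(np.column_stack([np.ones(len(cols)), cols])) < 1e9:
                break
            Xs, names = Xs[:-1], names[:-1]
        return Xs, names

    for resp in RESPONSES:
        for name in rs.SURFACE_NAMES:
            Xs, names = _well_conditioned(
                [resist[name]] + [cx_mats[n] for n in cx_names],
                [f"res_{name}"] + cx_names)
            fit, retained = md.mrdm_reduce(
                differentiation[resp], Xs, names, alpha=config.alpha,
                n_perm=config.n_perm, seed=ss_m[si].generate_state(1)[0])
            si += 1
            mrdm_struct[(resp, name)] = retained
            if fit is None:
                mrdm_fits.append(_empty_fit(resp, name, "mrdm"))
            else:
                mrdm_fits.append(md.ModelFit(resp, name, "mrdm", retained,
                                             fit.F, fit.r2, fit.adj_r2, fit.p))
    dbrda_fits: list[md.ModelFit] = []
    dbrda_struct: dict[tuple[str, str], list[str]] = {}
    ss_d = np.random.SeedSequence(seeds["dbrda"]).spawn(len(rs.SURFACE_NAMES) * 2)
    si = 0
    for resp in RESPONSES:
        for name in rs.SURFACE_NAMES:
            cand = pd.concat([connectivity[[f"S_{name}"]], metrics[cx_names]],
                             axis=1)
            cand = cand.loc[:, cand.std(ddof=0) > 0]
            cand = (cand - cand.mean()) / cand.std(ddof=0)
            fit = md.dbrda_forward_select(
                differentiation[resp], cand, alpha=config.alpha,
                n_perm=config.n_perm, seed=ss_d[si].generate_state(1)[0])
            si += 1
            if fit is None:
                dbrda_struct[(resp, name)] = []
                dbrda_fits.append(_empty_fit(resp, name, "dbrda"))
            else:
                dbrda_struct[(resp, name)] = fit.predictors
                dbrda_fits.append(md.ModelFit(resp, name, "dbrda", fit.predictors,
                                              fit.F, fit.r2, fit.adj_r2, fit.p))
    timings["model_selection"] = time.time() - t

    # ---- bootstrap ------------------------------------------------------
    t = time.time()
    mrdm_X = {n: resist[n] for n in rs.SURFACE_NAMES}

    def boot_stats(boot_ds: GenotypeDataset) -> dict[str, float]:
        ct = dv.allele_count_arrays(boot_ds, cells)
        theta = dv.theta_from_counts(ct)[0]
        dvals = dv.jost_d_from_counts(ct)[0]
        mats = {
            "FST": DistanceMatrix.from_condensed(cells, theta, "genetic"),
            "DEST": DistanceMatrix.from_condensed(cells, dvals, "genetic"),
        }
        out: dict[str, float] = {}
        for resp in RESPONSES:
            Dm = mats[resp]
            y = Dm.condensed()
            for name in rs.SURFACE_NAMES:
                retained = mrdm_struct[(resp, name)]
                key = f"mrdm_{resp}_{name}"
                if retained:
                    Xs = []
                    for rname in retained:
                        Xs.append(mrdm_X[name] if rname.startswith("res_") else cx_mats[rname])
                    Xd, _, _ = md._design(Xs, standardize=True)
                    coef, r2, F, _ = md._ols_r2(y, Xd)
                    out[f"{key}_adj_r2"] = md.adjusted_r2(r2, y.size, Xd.shape[1])
                    out[f"{key}_F"] = F
                    out[f"{key}_r2"] = r2
                    for rn, cval in zip(retained, coef[1:]):
                        out[f"{key}_coef_{rn}"] = cval
                else:
                    out[f"{key}_adj_r2"] = 0.0
                cols = dbrda_struct[(resp, name)]
                key = f"dbrda_{resp}_{name}"
                if cols:
                    cand = pd.concat([connectivity[[f"S_{name}"]], metrics], axis=1)
                    cand = (cand - cand.mean()) / cand.std(ddof=0)
                    axes, _ = md.pcoa(Dm)
                    X = cand.loc[cells, cols].to_numpy(float)
                    expl, tot = md._rda_inertia(axes, X)
                    r2 = expl / tot if tot > 0 else 0.0
                    m = X.shape[1]
                    dof = len(cells) - m - 1
                    out[f"{key}_adj_r2"] = md.adjusted_r2(r2, len(cells), m)
                    out[f"{key}_F"] = (expl / m) / ((tot - expl) / dof) if tot > expl else np.inf
                    out[f"{key}_r2"] = r2
                else:
                    out[f"{key}_adj_r2"] = 0.0
        return out

    boot = md.bootstrap_ci(boot_stats, ds, n_boot=config.n_boot, seed=seeds["boot"])
    for fit in mrdm_fits + dbrda_fits:
        prefix = f"{fit.method}_{fit.response}_{fit.surface}_"
        for k in boot.mean:
            if k.startswith(prefix):
                q = k[len(prefix):]
                fit.boot_mean[q] = boot.mean[k]
                fit.boot_lo[q] = boot.ci_low[k]
                fit.boot_hi[q] = boot.ci_high[k]
    timings["bootstrap"] = time.time() - t

    comparisons = {}
    for method, pool in (("mrdm", mrdm_fits), ("dbrda", dbrda_fits)):
        for resp in RESPONSES:
            fits = [f for f in pool if f.response == resp]
            comparisons[f"{method}_{resp}"] = md.compare_surfaces(fits)

    report = RunReport(config, div, differentiation, mantel_out, resist,
                       connectivity, metrics, mrdm_fits, dbrda_fits,
                       comparisons, accounting, skipped, timings, truth)
    if outdir is not None:
        _write_outputs(report, Path(outdir))
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.config.to_yaml(outdir / "config.yaml")
    report.diversity.to_csv(outdir / "diversity.tsv", sep="\t")
    for k, m in report.differentiation.items():
        m.to_tsv(outdir / f"differentiation_{k}.tsv")
    for k, m in report.resistance.items():
        m.to_tsv(outdir / f"resistance_{k}.tsv")
    report.connectivity.to_csv(outdir / "connectivity.tsv", sep="\t")
    report.complexity.to_csv(outdir / "complexity.tsv", sep="\t")
    rows = []
    for f in report.mrdm_fits + report.dbrda_fits:
        rows.append({
            "method": f.method, "response": f.response, "surface": f.surface,
            "predictors": "+".join(f.predictors) or "(null)",
            "F": f.F, "r2": f.r2, "adj_r2": f.adj_r2, "p": f.p,
            "adj_r2_boot_mean": f.boot_mean.get("adj_r2", np.nan),
            "adj_r2_lo": f.boot_lo.get("adj_r2", np.nan),
            "adj_r2_hi": f.boot_hi.get("adj_r2", np.nan),
        })
    pd.DataFrame(rows).to_csv(outdir / "model_fits.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True, default=float)
    if report.truth is not None:
        (outdir / "truth.json").write_text(report.truth.params_json())
    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
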