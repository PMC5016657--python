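"""Distance-matrix regression and constrained ordination with variable
selection, bootstrap confidence intervals, and the CI-overlap rule for
comparing resistance-surface models.

MRDM (multiple regression on distance matrices) regresses the vectorized
upper triangle of a genetic-differentiation matrix on those of candidate
predictor matrices; inference comes from joint row/column permutations of the
response matrix only.  dbRDA first extracts principal-coordinate axes with
positive eigenvalues from the differentiation matrix, then performs a
redundancy analysis of those axes on per-cell predictors; its pseudo-F is
tested by permuting response rows.  Backward elimination (MRDM) and forward
selection (dbRDA) at a permutation alpha produce reduced models; bootstrap
resampling of individuals within cells yields percentile CIs around F,
coefficients, and (adjusted) R-squared; surfaces whose adjusted-R-squared CIs
do not overlap those of the two null surfaces (pure distance and
water-barrier) count as distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .genotypes import GenotypeDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MRDM
# ---------------------------------------------------------------------------

@dataclass
class MRDMFit:
    predictors: list[str]
    coef: np.ndarray  # standardized scale
    coef_raw: np.ndarray
    intercept: float
    coef_p: np.ndarray
    r2: float
    adj_r2: float
    F: float
    p: float
    n_pairs: int

    def as_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coef": [float(c) for c in self.coef],
            "coef_p": [float(c) for c in self.coef_p],
            "r2": self.r2, "adj_r2": self.adj_r2,
            "F": self.F, "p": self.p, "n_pairs": self.n_pairs,
        }


def _design(X: list[DistanceMatrix], standardize: bool):
    cols = [x.condensed() for x in X]
    M = np.column_stack(cols) if cols else np.empty((0, 0))
    mu = M.mean(axis=0) if M.size else np.array([])
    sd = M.std(axis=0) if M.size else np.array([])
    if standardize and M.size:
        if np.any(sd == 0):
            raise ValueError("constant predictor matrix")
        M = (M - mu) / sd
    return M, mu, sd


def _ols_r2(y: np.ndarray, Xd: np.ndarray):
    """OLS with intercept; returns (beta, r2, F, tstats)."""
    n = y.size
    m = Xd.shape[1]
    A = np.column_stack([np.ones(n), Xd])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = n - m - 1
    F = (r2 / m) / ((1 - r2) / dof) if m and r2 < 1 and dof > 0 else np.inf
    if dof > 0 and ss_res > 0:
        sigma2 = ss_res / dof
        XtX_inv = np.linalg.pinv(A.T @ A)
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
        t = coef / se
    else:
        t = np.full(m + 1, np.inf)
    return coef, r2, F, t


def mrdm(Y: DistanceMatrix, X: list[DistanceMatrix], n_perm: int = 999,
         seed: int | None = None, standardize: bool = True) -> MRDMFit:
    """Multiple regression on distance matrices.

    Significance of R-squared (via F) and of each coefficient (via |t|) is
    assessed by jointly permuting the rows and columns of Y only, the
    Legendre 'permute raw response' method.
    """
    for x in X:
        if x.labels != Y.labels:
            raise ValueError("predictor labels do not match response")
    n = Y.n
    y = Y.condensed()
    n_pairs = y.size
    m = len(X)
    if n_pairs < m + 2:
        raise ValueError("need at least 2 more pairs than predictors")
    Xd, mu, sd = _design(X, standardize)
    if m >= 2:
        cond = np.linalg.cond(np.column_stack([np.ones(n_pairs), Xd]))
        if cond > 1e10:
            corr = np.corrcoef(Xd.T)
            i, j = divmod(int(np.argmax(np.abs(corr - np.eye(m)))), m)
            raise ValueError(
                f"collinear predictors (condition {cond:.2g}): "
                f"{X[i].kind}/{i} vs {X[j].kind}/{j}"
            )
    coef, r2, F, t = _ols_r2(y, Xd)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    ge_F = 0
    ge_t = np.zeros(m)
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = Y.values[np.ix_(p, p)][iu]
        _, _, F_p, t_p = _ols_r2(yp, Xd)
        ge_F += F_p >= F - 1e-12
        ge_t += np.abs(t_p[1:]) >= np.abs(t[1:]) - 1e-12
    p_F = (1 + ge_F) / (n_perm + 1)
    p_t = (1 + ge_t) / (n_perm + 1)
    adj = adjusted_r2(r2, n_pairs, m)
    coef_raw = coef[1:] / sd if (standardize and m) else coef[1:].copy()
    return MRDMFit([getattr(x, "name", f"x{i}") for i, x in enumerate(X)],
                   coef[1:], coef_raw, float(coef[0]), p_t, float(r2), adj,
                   float(F), float(p_F), n_pairs)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return np.nan
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))


def mrdm_reduce(Y: DistanceMatrix, X: list[DistanceMatrix], names: list[str],
                alpha: float = 0.05, n_perm: int = 999,
                seed: int | None = None) -> tuple[MRDMFit | None, list[str]]:
    """Backward elimination: repeatedly drop the predictor with the largest
    permutation p > alpha and refit, until every retained p <= alpha.

    Returns (fit, retained names); an empty final model returns (None, [])."""
    ss = np.random.SeedSequence(seed)
    current = list(range(len(X)))
    fit = None
    while current:
        child = ss.spawn(1)[0]
        fit = mrdm(Y, [X[i] for i in current], n_perm=n_perm,
                   seed=child.generate_state(1)[0])
        fit.predictors = [names[i] for i in current]
        worst = int(np.argmax(fit.coef_p))
        if fit.coef_p[worst] > alpha:
            current.pop(worst)
            fit = None
        else:
            break
    return fit, ([names[i] for i in current] if fit is not None else [])


# ---------------------------------------------------------------------------
# PCoA and dbRDA
# ---------------------------------------------------------------------------

def pcoa(D: DistanceMatrix, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix (Gower double-centering).

    Returns (axes, eigenvalues) for eigenvalues > tol * max eigenvalue; axis
    scores are eigenvectors scaled by sqrt(eigenvalue), so Euclidean distances
    between scores reproduce the input when it is Euclidean-embeddable.
    """
    n = D.n
    if n < 3:
        raise ValueError("need at least 3 sites for PCoA")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w.size == 0 or w[0] <= 0:
        return np.empty((n, 0)), np.empty(0)
    keep = w > tol * w[0]
    return V[:, keep] * np.sqrt(w[keep]), w[keep]


@dataclass
class DbRDAFit:
    predictors: list[str]
    r2: float
    adj_r2: float
    F: float
    p: float
    n: int
    m: int

    def as_dict(self) -> dict:
        return {"predictors": list(self.predictors), "r2": self.r2,
                "adj_r2": self.adj_r2, "F": self.F, "p": self.p,
                "n": self.n, "m": self.m}


def _hat_matrix(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    # guard rank deficiency: drop near-zero columns of Q via R diagonal
    return Q @ Q.T


def _rda_inertia(axes: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """(explained, total) inertia of centered PCoA axes regressed on X."""
    Yc = axes - axes.mean(axis=0)
    H = _hat_matrix(X)
    fitted = H @ Yc
    return float((fitted**2).sum()), float((Yc**2).sum())


def dbrda(D: DistanceMatrix, predictors: pd.DataFrame, n_perm: int = 999,
          seed: int | None = None) -> DbRDAFit:
    """Distance-based redundancy analysis of D on per-cell predictors.

    R^2 = explained / total positive inertia; pseudo-F uses residual degrees
    of freedom n - m - 1; the p-value permutes predictor rows.
    """
    pred = predictors.loc[list(D.labels)]
    X = pred.to_numpy(float)
    n, m = X.shape
    if m >= n - 1:
        raise ValueError("too many predictors for the number of cells")
    axes, _ = pcoa(D)
    if axes.shape[1] == 0:
        raise ValueError("no positive PCoA axes")
    expl, tot = _rda_inertia(axes, X)
    r2 = expl / tot if tot > 0 else 0.0
    dof = n - m - 1
    F = (expl / m) / ((tot - expl) / dof) if tot > expl else np.inf
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        e_p, _ = _rda_inertia(axes, Xp)
        F_p = (e_p / m) / ((tot - e_p) / dof) if tot > e_p else np.inf
        ge += F_p >= F - 1e-12
    p = (1 + ge) / (n_perm + 1)
    return DbRDAFit(list(pred.columns), float(r2), adjusted_r2(r2, n, m),
                    float(F), float(p), n, m)


def dbrda_forward_select(D: DistanceMatrix, candidates: pd.DataFrame,
                         alpha: float = 0.05, n_perm: int = 999,
                         seed: int | None = None) -> DbRDAFit | None:
    """Forward selection: at each step add the candidate with the smallest
    permutation p of its marginal (partial) F given the current model, if
    p <= alpha; return None (the null model) if nothing ever enters."""
    cand = candidates.loc[list(D.labels)]
    axes, _ = pcoa(D)
    n = axes.shape[0]
    tot = float(((axes - axes.mean(axis=0)) ** 2).sum())
    selected: list[str] = []
    remaining = list(cand.columns)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.generate_state(1)[0])
    while remaining and len(selected) < n - 2:
        best = None
        for name in remaining:
            cols = selected + [name]
            X = cand[cols].to_numpy(float)
            m = X.shape[1]
            expl_new, _ = _rda_inertia(axes, X)
            if selected:
                expl_cur, _ = _rda_inertia(axes, cand[selected].to_numpy(float))
            else:
                expl_cur = 0.0
            dof = n - m - 1
            if dof <= 0:
                continue
            dF = (expl_new - expl_cur) / ((tot - expl_new) / dof)
            ge = 0
            xnew = cand[name].to_numpy(float)
            for _ in range(n_perm):
                Xp = np.column_stack(
                    [cand[selected].to_numpy(float), xnew[rng.permutation(n)]]
                ) if selected else xnew[rng.permutation(n)][:, None]
                e_p, _ = _rda_inertia(axes, Xp)
                dF_p = (e_p - expl_cur) / ((tot - e_p) / dof) if tot > e_p else np.inf
                ge += dF_p >= dF - 1e-12
            p = (1 + ge) / (n_perm + 1)
            if best is None or p < best[1] or (p == best[1] and dF > best[2]):
                best = (name, p, dF)
        if best is None or best[1] > alpha:
            break
        selected.append(best[0])
        remaining.remove(best[0])
    if not selected:
        return None
    return dbrda(D, cand[selected], n_perm=n_perm,
                 seed=ss.spawn(1)[0].generate_state(1)[0])


# ---------------------------------------------------------------------------
# Bootstrap CIs and surface comparison
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_ok: int
    n_failed: int
    degenerate: bool = False


def bootstrap_ci(stat_fn, ds: GenotypeDataset, n_boot: int = 1000,
                 seed: int | None = None) -> BootstrapCI:
    """Bootstrap the dataset by resampling individuals with replacement
    *within* each cell (cell sizes preserved) and recompute ``stat_fn``.

    ``stat_fn`` maps a GenotypeDataset to a flat dict of named floats.
    Replicates where it raises are logged and skipped; more than 5% failures
    aborts.  Returns per-quantity mean and 2.5/97.5 percentiles; zero-width
    intervals (degenerate data) are flagged.
    """
    cells = ds.cell_labels()
    cell_idx = {c: ds.cell_index(c) for c in cells}
    for c, idx in cell_idx.items():
        if idx.size < 2:
            raise ValueError(f"cell {c} has <2 individuals")
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    failed = 0
    for b in range(n_boot):
        take = np.concatenate([
            cell_idx[c][rng.integers(0, cell_idx[c].size, cell_idx[c].size)]
            for c in cells
        ])
        boot = _resample(ds, take)
        try:
            vals = stat_fn(boot)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            if failed > 0.05 * n_boot:
                raise RuntimeError(">5% bootstrap replicates failed") from exc
            continue
        for k, v in vals.items():
            draws.setdefault(k, []).append(float(v))
    mean, lo, hi = {}, {}, {}
    degenerate = False
    for k, arr in draws.items():
        a = np.asarray(arr)
        a = a[np.isfinite(a)]
        if a.size == 0:
            mean[k], lo[k], hi[k] = np.nan, np.nan, np.nan
            continue
        mean[k] = float(a.mean())
        lo[k], hi[k] = (float(x) for x in np.percentile(a, [2.5, 97.5]))
        if hi[k] - lo[k] == 0:
            degenerate = True
    if degenerate:
        logger.warning("zero-width bootstrap CI: degenerate resampling distribution")
    return BootstrapCI(mean, lo, hi, n_boot - failed, failed, degenerate)


def _resample(ds: GenotypeDataset, take: np.ndarray) -> GenotypeDataset:
    """Subset allowing duplicate rows (bootstrap draws need unique ids)."""
    return GenotypeDataset(
        [f"{ds.individuals[i]}#{k}" for k, i in enumerate(take)],
        list(ds.loci),
        ds.calls[take].copy(),
        ds.cells[take].copy(),
        ds.coords[take].copy(),
    )


@dataclass
class ModelFit:
    """One reduced model (MRDM or dbRDA) with its bootstrap summaries."""

    response: str
    surface: str
    method: str
    predictors: list[str]
    F: float
    r2: float
    adj_r2: float
    p: float
    boot_mean: dict[str, float] = field(default_factory=dict)
    boot_lo: dict[str, float] = field(default_factory=dict)
    boot_hi: dict[str, float] = field(default_factory=dict)

    def ci(self, quantity: str = "adj_r2") -> tuple[float, float]:
        if quantity not in self.boot_lo:
            raise ValueError(f"no bootstrap CI for {quantity!r} on {self.surface}")
        return self.boot_lo[quantity], self.boot_hi[quantity]


@dataclass
class SurfaceComparison:
    response: str
    method: str
    winner: str
    relation: dict[str, str]  # surface -> distinct | overlapping | null-model
    competing: list[str]


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_surfaces(fits: list[ModelFit],
                     null_surfaces: tuple[str, str] = ("IBD", "IBB")) -> SurfaceComparison:
    """CI-overlap comparison rule.

    The winner has the highest adjusted R-squared; a non-null surface is
    'distinct' iff its adjusted-R-squared CI overlaps neither null surface's
    CI; surfaces whose CI overlaps the winner's are listed as competing.
    """
    if not fits:
        raise ValueError("no fits to compare")
    responses = {f.response for f in fits}
    methods = {f.method for f in fits}
    if len(responses) != 1 or len(methods) != 1:
        raise ValueError("fits mix responses or methods")
    by_surface = {f.surface: f for f in fits}
    for f in fits:
        f.ci("adj_r2")  # raises if missing
    winner = max(fits, key=lambda f: (f.adj_r2 if np.isfinite(f.adj_r2) else -np.inf))
    null_cis = [by_surface[s].ci("adj_r2") for s in null_surfaces if s in by_surface]
    relation = {}
    for f in fits:
        if f.surface in null_surfaces:
            relation[f.surface] = "null-model"
        elif all(not _overlap(f.ci("adj_r2"), nc) for nc in null_cis):
            relation[f.surface] = "distinct"
        else:
            relation[f.surface] = "overlapping"
    competing = [
        f.surface for f in fits
        if f.surface != winner.surface and _overlap(f.ci("adj_r2"), winner.ci("adj_r2"))
    ]
    return SurfaceComparison(winner.response, winner.method, winner.surface,
                             relation, competing)
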