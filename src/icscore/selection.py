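"""Cross-validated choice of the trade-off gamma and the reweighting eps_c.

gamma is chosen to maximise mean out-of-fold AUC under stratified 10-fold
cross-validation.  eps_c is then chosen, at the selected gamma, as the
candidate producing the fewest total chart intervals among those whose
5-fold CV AUC, Bernoulli likelihood and Nagelkerke R^2 stay within small
slacks of the unweighted model ("comparable performance, minimal intervals").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .calibration import fit_link, risk_of
from .metrics import auc, r2_adj
from .optimizer import FitConfig, IntervalWeights, fit_reweighted, fit_unweighted
from .scorechart import ScoreTable, normalize_and_round, score_patient
from .variables import IndicatorMatrix

__all__ = ["SelectionResult", "cv_select_gamma", "select_eps_c", "count_intervals"]

#: 13 log-spaced absolute gammas; the hinge is a sum over patients, so the
#: useful trade-off region is essentially size-free (roughly 0.1 .. 10).
DEFAULT_GAMMA_GRID = tuple(np.logspace(-2, 2, 13))


@dataclass
class SelectionResult:
    gamma: float | None = None
    eps_c: float | None = None
    table: list = field(default_factory=list)  # per-candidate diagnostics
    seed: int = 0
    warning: str | None = None


def _subset(Xm: IndicatorMatrix, idx) -> IndicatorMatrix:
    return IndicatorMatrix(
        X=Xm.X[idx],
        y=Xm.y[idx],
        columns=Xm.columns,
        blocks=Xm.blocks,
        specs=Xm.specs,
        grids=Xm.grids,
    )


def _stratified_folds(Xm: IndicatorMatrix, k: int, seed: int, max_redraw: int = 20):
    """Stratified fold index pairs; folds whose training part is single-class
    trigger a redraw with a bumped seed."""
    y01 = (Xm.y > 0).astype(int)
    for attempt in range(max_redraw):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(Xm.X, y01))
        ok = all(len(np.unique(y01[tr])) == 2 and len(np.unique(y01[te])) == 2 for tr, te in folds)
        if ok:
            if attempt:
                warnings.warn(f"folds redrawn {attempt} time(s) to avoid single-class folds")
            return folds
    raise ValueError("could not draw folds with both classes present")


def cv_select_gamma(
    Xm: IndicatorMatrix,
    grid=None,
    k: int = 10,
    seed: int = 0,
    backend: str = "lp",
    ridge: float = 0.0,
) -> SelectionResult:
    """Pick gamma maximizing mean out-of-fold AUC (ties -> larger gamma)."""
    if grid is None:
        grid = list(DEFAULT_GAMMA_GRID)
    grid = sorted(grid)
    if not grid:
        raise ValueError("gamma grid is empty")
    folds = _stratified_folds(Xm, k, seed)

    table = []
    for gamma in grid:
        aucs = []
        for tr, te in folds:
            w = fit_unweighted(_subset(Xm, tr), gamma, backend=backend, ridge=ridge)
            f = Xm.X[te] @ w.values + w.intercept
            aucs.append(auc(f, Xm.y[te]))
        table.append({"gamma": gamma, "cv_auc": float(np.mean(aucs))})

    best = max(table, key=lambda row: (row["cv_auc"], row["gamma"]))
    return SelectionResult(gamma=best["gamma"], table=table, seed=seed)


def _cv_metrics_reweighted(Xm, config: FitConfig, folds):
    """Out-of-fold AUC, mean Bernoulli log-likelihood and R^2 for a config."""
    aucs, lls, r2s = [], [], []
    for tr, te in folds:
        Xtr, Xte = _subset(Xm, tr), _subset(Xm, te)
        w, _ = fit_reweighted(Xtr, config)
        f_tr = Xtr.X @ w.values + w.intercept
        f_te = Xte.X @ w.values + w.intercept
        aucs.append(auc(f_te, Xte.y))
        try:
            link = fit_link(f_tr, (Xtr.y > 0).astype(int), cv_folds=3)
            risks = np.array([risk_of(v, link) for v in f_te])
            y_te = (Xte.y > 0).astype(int)
            p = np.clip(risks, 1e-6, 1 - 1e-6)
            lls.append(float(np.mean(y_te * np.log(p) + (1 - y_te) * np.log(1 - p))))
            r2s.append(r2_adj(risks, y_te))
        except ValueError:
            lls.append(float("-inf"))
            r2s.append(0.0)
    return float(np.mean(aucs)), float(np.mean(lls)), float(np.mean(r2s))


def count_intervals(table: ScoreTable, specs=None) -> int:
    """Total chart intervals across selected variables.

    Each selected variable contributes its full interval count including the
    reference interval (a selected binary variable counts as 2); variables
    with all-zero points contribute nothing.
    """
    total = 0
    for var in table.variables:
        rows = table.entries[var]
        if any(e.points != 0 for e in rows):
            total += len(rows)
    return total


def select_eps_c(
    Xm: IndicatorMatrix,
    gamma: float,
    grid=(0.001, 0.01, 0.1),
    k: int = 5,
    auc_slack: float = 0.01,
    ll_rel_slack: float = 0.02,
    r2_slack: float = 0.02,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 50,
    backend: str = "lp",
    ridge: float = 0.0,
) -> SelectionResult:
    """Fewest total intervals subject to CV performance comparable with the
    unweighted model (additive AUC/R^2 slacks, relative likelihood slack)."""
    grid = sorted(grid)
    if not grid:
        raise ValueError("eps_c grid is empty")
    folds = _stratified_folds(Xm, k, seed)

    # unweighted reference performance
    base_aucs, base_lls, base_r2s = [], [], []
    for tr, te in folds:
        Xtr, Xte = _subset(Xm, tr), _subset(Xm, te)
        w = fit_unweighted(Xtr, gamma, backend=backend, ridge=ridge)
        f_tr = Xtr.X @ w.values + w.intercept
        f_te = Xte.X @ w.values + w.intercept
        base_aucs.append(auc(f_te, Xte.y))
        try:
            link = fit_link(f_tr, (Xtr.y > 0).astype(int), cv_folds=3)
            risks = np.array([risk_of(v, link) for v in f_te])
            y_te = (Xte.y > 0).astype(int)
            p = np.clip(risks, 1e-6, 1 - 1e-6)
            base_lls.append(float(np.mean(y_te * np.log(p) + (1 - y_te) * np.log(1 - p))))
            base_r2s.append(r2_adj(risks, y_te))
        except ValueError:
            base_lls.append(float("-inf"))
            base_r2s.append(0.0)
    base_auc = float(np.mean(base_aucs))
    base_ll = float(np.mean(base_lls))
    base_r2 = float(np.mean(base_r2s))

    table = []
    for eps in grid:
        config = FitConfig(
            gamma=gamma, eps_c=eps, tol=tol, max_iter=max_iter, backend=backend, ridge=ridge
        )
        cv_auc, cv_ll, cv_r2 = _cv_metrics_reweighted(Xm, config, folds)
        w_full, _ = fit_reweighted(Xm, config)
        chart = normalize_and_round(w_full, specs=Xm.specs, grids=Xm.grids)
        n_int = count_intervals(chart)
        ok = (
            cv_auc >= base_auc - auc_slack
            and cv_ll >= base_ll - abs(base_ll) * ll_rel_slack
            and cv_r2 >= base_r2 - r2_slack
        )
        table.append(
            {
                "eps_c": eps,
                "cv_auc": cv_auc,
                "cv_loglik": cv_ll,
                "cv_r2_adj": cv_r2,
                "intervals": n_int,
                "comparable": ok,
            }
        )

    qualifying = [row for row in table if row["comparable"]]
    warning = None
    if qualifying:
        best = min(qualifying, key=lambda row: (row["intervals"], -row["cv_auc"]))
    else:
        best = max(table, key=lambda row: row["cv_auc"])
        warning = "no eps_c candidate met the comparability slacks; fell back to best CV AUC"
        warnings.warn(warning, RuntimeWarning)
    res = SelectionResult(gamma=gamma, eps_c=best["eps_c"], table=table, seed=seed, warning=warning)
    return res
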