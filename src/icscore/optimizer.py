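"""Convex training problem of the interval-coded score model.

The classifier is f(x) = sum_{p,j} w_{p,j} I(x_p in interval j) + b.  Training
minimizes

    sum_i max(0, 1 - y_i f(x_i))  +  gamma * sum_d u_d |delta_d(w)|

where delta_d ranges over adjacent-interval coefficient differences within
each continuous variable (a chain, i.e. the total variation of the step
function) and over non-reference-level coefficients for categorical and
binary variables (each level against the reference).  The reference interval
of every variable is pinned to weight 0, so "all differences zero" is
literally "variable removed".

With unit factors u the problem is an exact linear program (hinge slacks plus
split total-variation auxiliaries) solved with HiGHS.  Iterative reweighting
recomputes u_d = 1 / (|delta_d| + eps_c) and re-solves until the coefficients
stabilise, which drives small spurious intervals to exact fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog, minimize

from .variables import IndicatorMatrix

__all__ = [
    "IntervalWeights",
    "ReweightState",
    "FitConfig",
    "SolverError",
    "objective_value",
    "fit_unweighted",
    "compute_reweight_factors",
    "fit_reweighted",
    "decision_values",
]


class SolverError(RuntimeError):
    """The LP backend reported failure (should not occur: always feasible)."""


@dataclass
class IntervalWeights:
    """Real-valued per-interval coefficients plus intercept.

    ``values`` is aligned with ``columns`` (the (variable, interval) pairs of
    the IndicatorMatrix the model was fitted on).
    """

    values: np.ndarray
    intercept: float
    columns: list
    blocks: dict

    def weight(self, variable: str, j: int) -> float:
        sl = self.blocks[variable]
        return float(self.values[sl.start + j])

    def block_values(self, variable: str) -> np.ndarray:
        return self.values[self.blocks[variable]]

    def as_dict(self) -> dict:
        return {c: float(v) for c, v in zip(self.columns, self.values)}


@dataclass
class ReweightState:
    """Bookkeeping of the iterative reweighting loop."""

    factors: np.ndarray  # aligned with the difference structure
    diff_index: list  # (variable, difference index) per factor
    iteration: int = 0
    converged: bool = False
    last_delta: float = float("inf")


@dataclass
class FitConfig:
    """Hyper-parameters of the reweighted fit.

    gamma : trade-off between hinge loss and total variation.
    eps_c : reweighting constant; small values sharpen sparsity, large
        values make reweighting vanish.
    tol : convergence bound on the max absolute coefficient change.
    max_iter : cap on reweighting iterations (per annealing stage).
    ridge : optional quadratic penalty (ridge/2)*||w||^2 for solution
        uniqueness and graded (non-lattice) coefficients; requires the
        "admm" or "slsqp" backend when non-zero.
    backend : "lp" (exact LP, default), "admm" (operator splitting; the
        only backend that scales with ridge > 0) or "slsqp" (generic NLP
        solver on the same epigraph problem; small instances only).
    anneal : start the reweighting with a coarse eps and tighten it down
        to eps_c; protects ramp-shaped unweighted solutions from being
        wiped out by the first sharp reweight.
    """

    gamma: float = 1.0
    eps_c: float = 0.01
    tol: float = 1e-4
    max_iter: int = 50
    ridge: float = 0.0
    backend: str = "lp"
    anneal: bool = True

    def __post_init__(self):
        if self.gamma <= 0 or self.eps_c <= 0 or self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("gamma, eps_c, tol and max_iter must be strictly positive")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.ridge > 0 and self.backend == "lp":
            raise ValueError('ridge > 0 requires backend "admm" or "slsqp"')


# ---------------------------------------------------------------------------
# difference structure


def _difference_structure(Xm: IndicatorMatrix):
    """Sparse operator D mapping free weights to penalized differences.

    Free weights are every column except each block's reference (index 0).
    Continuous blocks contribute a chain of adjacent differences (with the
    pinned reference as left end); categorical/binary blocks contribute one
    difference per non-reference level.
    """
    free_cols = []  # matrix column index per free weight
    free_of = {}
    for c, (var, j) in enumerate(Xm.columns):
        if j > 0:
            free_of[c] = len(free_cols)
            free_cols.append(c)

    rows, cols, data, diff_index = [], [], [], []
    for var, sl in Xm.blocks.items():
        kind = Xm.specs[var].kind if var in Xm.specs else "continuous"
        k = sl.stop - sl.start
        chain = kind == "continuous"
        for d in range(k - 1):
            r = len(diff_index)
            hi_col = sl.start + d + 1
            rows.append(r)
            cols.append(free_of[hi_col])
            data.append(1.0)
            if chain and d >= 1:
                lo_col = sl.start + d
                rows.append(r)
                cols.append(free_of[lo_col])
                data.append(-1.0)
            diff_index.append((var, d))
    D = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(diff_index), len(free_cols))
    )
    return D, free_cols, diff_index


def _expand_free(Xm: IndicatorMatrix, wf: np.ndarray, free_cols) -> np.ndarray:
    w = np.zeros(Xm.m)
    w[free_cols] = wf
    return w


def _block_differences(Xm: IndicatorMatrix, values: np.ndarray):
    """Penalized differences of a full coefficient vector: adjacent pairs
    within continuous blocks, non-reference-minus-reference otherwise.
    Matches the free-weight operator of `_difference_structure` whenever the
    reference weights are zero, but stays correct for unanchored vectors."""
    diffs, index = [], []
    for var, sl in Xm.blocks.items():
        kind = Xm.specs[var].kind if var in Xm.specs else "continuous"
        cols = range(sl.start, sl.stop)
        ref = sl.start
        prev = ref
        for d, c in enumerate(list(cols)[1:]):
            lo = prev if kind == "continuous" else ref
            diffs.append(values[c] - values[lo])
            index.append((var, d))
            prev = c
    return np.asarray(diffs), index


def decision_values(w: IntervalWeights, Xm: IndicatorMatrix) -> np.ndarray:
    """f(x_i) for every row of the indicator matrix."""
    return Xm.X @ w.values + w.intercept


def objective_value(
    w: IntervalWeights,
    Xm: IndicatorMatrix,
    gamma: float,
    factors: ReweightState | None = None,
) -> float:
    """Hinge loss plus (re)weighted total-variation penalty at ``w``."""
    f = decision_values(w, Xm)
    hinge = np.maximum(0.0, 1.0 - Xm.y * f).sum()
    diffs, index = _block_differences(Xm, w.values)
    u = np.ones(len(index)) if factors is None else np.asarray(factors.factors)
    return float(hinge + gamma * (u * np.abs(diffs)).sum())


# ---------------------------------------------------------------------------
# solvers


def _solve_lp(Xm: IndicatorMatrix, gamma: float, u: np.ndarray, D, free_cols):
    """Exact LP: variables [wf, b, xi, t]; minimize 1'xi + gamma*u't."""
    n, _ = Xm.X.shape
    nf = len(free_cols)
    nd = D.shape[0]
    Xf = sp.csr_matrix(Xm.X[:, free_cols])
    y = Xm.y

    # hinge:  -y_i (Xf_i wf + b) - xi_i <= -1
    Yd = sp.diags(y)
    A_h = sp.hstack(
        [-Yd @ Xf, sp.csr_matrix(-y[:, None]), -sp.identity(n), sp.csr_matrix((n, nd))]
    )
    # TV epigraph:  +/- D wf - t <= 0
    A_p = sp.hstack([D, sp.csr_matrix((nd, 1)), sp.csr_matrix((nd, n)), -sp.identity(nd)])
    A_m = sp.hstack([-D, sp.csr_matrix((nd, 1)), sp.csr_matrix((nd, n)), -sp.identity(nd)])
    A = sp.vstack([A_h, A_p, A_m], format="csr")
    b_ub = np.concatenate([-np.ones(n), np.zeros(2 * nd)])

    c = np.concatenate([np.zeros(nf + 1), np.ones(n), gamma * u])
    bounds = [(None, None)] * (nf + 1) + [(0, None)] * (n + nd)

    res = linprog(c, A_ub=A, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"LP solver failed: {res.message}")
    wf = res.x[:nf]
    b = res.x[nf]
    return wf, float(b)


def _solve_slsqp(Xm: IndicatorMatrix, gamma: float, u: np.ndarray, D, free_cols, ridge=0.0):
    """Generic convex-programming backend on the same epigraph problem."""
    n = Xm.n
    nf = len(free_cols)
    nd = D.shape[0]
    Xf = Xm.X[:, free_cols]
    y = Xm.y
    Dd = D.toarray()

    def split(z):
        return z[:nf], z[nf], z[nf + 1 : nf + 1 + n], z[nf + 1 + n :]

    def fun(z):
        wf, b, xi, t = split(z)
        val = xi.sum() + gamma * (u * t).sum()
        if ridge:
            val += 0.5 * ridge * (wf @ wf)
        return val

    def jac(z):
        wf, b, xi, t = split(z)
        g = np.zeros_like(z)
        g[nf + 1 : nf + 1 + n] = 1.0
        g[nf + 1 + n :] = gamma * u
        if ridge:
            g[:nf] = ridge * wf
        return g

    def cons_hinge(z):
        wf, b, xi, t = split(z)
        return xi - (1.0 - y * (Xf @ wf + b))

    def cons_tv_p(z):
        wf, b, xi, t = split(z)
        return t - Dd @ wf

    def cons_tv_m(z):
        wf, b, xi, t = split(z)
        return t + Dd @ wf

    z0 = np.zeros(nf + 1 + n + nd)
    z0[nf + 1 : nf + 1 + n] = 1.0  # feasible start: w=0, b=0, xi=1, t=0
    bounds = [(None, None)] * (nf + 1) + [(0, None)] * (n + nd)
    res = minimize(
        fun,
        z0,
        jac=jac,
        bounds=bounds,
        constraints=[
            {"type": "ineq", "fun": cons_hinge},
            {"type": "ineq", "fun": cons_tv_p},
            {"type": "ineq", "fun": cons_tv_m},
        ],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        raise SolverError(f"SLSQP backend failed: {res.message}")
    wf = res.x[:nf]
    return wf, float(res.x[nf])


def _solve_admm(
    Xm: IndicatorMatrix,
    gamma: float,
    u: np.ndarray,
    D,
    free_cols,
    ridge: float = 0.0,
    rho: float = 5.0,
    iters: int = 8000,
    tol: float = 1e-5,
    warm=None,
):
    """Operator-splitting solver for (ridge/2)||w||^2 + hinge + gamma*u'|Dw|.

    Splits the margins and the interval differences into auxiliary blocks
    with closed-form proximal updates (a shifted clip for the hinge, a
    soft-threshold for the weighted TV); the coupled (w, b) update is one
    Cholesky solve whose factor is reused until the penalty rho adapts.
    Differences are read off the thresholded auxiliary block, so fusion is
    exact; the intercept is then re-optimized exactly on the hinge.
    """
    from scipy.linalg import cho_factor, cho_solve

    Dd = D.toarray()
    X = Xm.X[:, free_cols]
    y = Xm.y
    n, nf = X.shape
    nd = Dd.shape[0]
    A = np.vstack([np.hstack([X * y[:, None], y[:, None]]), np.hstack([Dd, np.zeros((nd, 1))])])
    AtA = A.T @ A
    G = np.diag([ridge] * nf + [0.0])
    cf = cho_factor(G + rho * AtA)
    if warm is None:
        m = np.ones(n)
        z = np.zeros(nd)
        al = np.zeros(n)
        be = np.zeros(nd)
    else:
        m, z, al, be = (v.copy() for v in warm)
    for it in range(iters):
        rhs = rho * (A.T @ np.concatenate([m - al, z - be]))
        x = cho_solve(cf, rhs)
        Ax = A @ x
        v = Ax[:n] + al
        c = 1.0 / rho
        m_new = np.where(v >= 1.0, v, np.where(v <= 1.0 - c, v + c, 1.0))
        zn = Ax[n:] + be
        z_new = np.sign(zn) * np.maximum(np.abs(zn) - gamma * u / rho, 0.0)
        al += Ax[:n] - m_new
        be += Ax[n:] - z_new
        r_prim = np.sqrt(np.sum((Ax[:n] - m_new) ** 2) + np.sum((Ax[n:] - z_new) ** 2))
        s_dual = rho * np.sqrt(np.sum((m_new - m) ** 2) + np.sum((z_new - z) ** 2))
        m, z = m_new, z_new
        scale = max(float(np.linalg.norm(Ax)), 1.0)
        if r_prim < tol * scale and s_dual < tol * scale * rho:
            break
        if it % 100 == 99:  # residual balancing
            if r_prim > 10 * s_dual / rho and rho < 1e4:
                rho *= 2
                al /= 2
                be /= 2
                cf = cho_factor(G + rho * AtA)
            elif s_dual / rho > 10 * r_prim and rho > 1e-2:
                rho /= 2
                al *= 2
                be *= 2
                cf = cho_factor(G + rho * AtA)

    # exact fused weights from the thresholded differences
    z = z.copy()
    if np.abs(z).max() > 0:
        z[np.abs(z) < 1e-6 * np.abs(z).max()] = 0.0
    wf = np.zeros(nf)
    pos = 0
    for var, sl in Xm.blocks.items():
        kind = Xm.specs[var].kind if var in Xm.specs else "continuous"
        k = sl.stop - sl.start - 1
        zz = z[pos : pos + k]
        wf[pos : pos + k] = np.cumsum(zz) if kind == "continuous" else zz
        pos += k
    # exact 1-D hinge minimization for the intercept given the fused weights
    f0 = X @ wf
    cand = np.unique((1.0 - y * f0) * y)
    _, b = min((float(np.maximum(0.0, 1.0 - y * (f0 + bb)).sum()), float(bb)) for bb in cand)
    return wf, b, (m, z, al, be), rho


def _fit_full(Xm: IndicatorMatrix, gamma: float, u=None, backend="lp", ridge=0.0, warm=None, rho=5.0):
    """Solve one weighted problem; returns (weights, solver state or None)."""
    D, free_cols, diff_index = _difference_structure(Xm)
    if u is None:
        u = np.ones(D.shape[0])
    state = None
    if backend == "lp":
        wf, b = _solve_lp(Xm, gamma, u, D, free_cols)
    elif backend == "admm":
        wf, b, warm_out, rho_out = _solve_admm(
            Xm, gamma, u, D, free_cols, ridge=ridge, warm=warm, rho=rho
        )
        state = (warm_out, rho_out)
    elif backend == "slsqp":
        wf, b = _solve_slsqp(Xm, gamma, u, D, free_cols, ridge=ridge)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    values = _expand_free(Xm, wf, free_cols)
    w = IntervalWeights(values=values, intercept=b, columns=list(Xm.columns), blocks=dict(Xm.blocks))
    return w, state


def _fit(Xm: IndicatorMatrix, gamma: float, u=None, backend="lp", ridge=0.0):
    return _fit_full(Xm, gamma, u=u, backend=backend, ridge=ridge)[0]


def fit_unweighted(
    Xm: IndicatorMatrix, gamma: float, backend: str = "lp", ridge: float = 0.0
) -> IntervalWeights:
    """Global minimizer of the hinge + gamma*TV objective (unit factors)."""
    if Xm.n == 0:
        raise ValueError("empty dataset")
    if gamma <= 0:
        raise ValueError("gamma must be strictly positive")
    return _fit(Xm, gamma, backend=backend, ridge=ridge)


def compute_reweight_factors(
    w: IntervalWeights, Xm: IndicatorMatrix, eps_c: float
) -> ReweightState:
    """u_d = 1 / (|delta_d| + eps_c): small differences get large penalties."""
    if eps_c <= 0:
        raise ValueError("eps_c must be strictly positive")
    diffs, index = _block_differences(Xm, w.values)
    u = 1.0 / (np.abs(diffs) + eps_c)
    return ReweightState(factors=u, diff_index=index)


#: coarse-to-fine ladder for the annealed reweighting schedule
_ANNEAL_LADDER = (1.0, 0.3, 0.1, 0.03)


def fit_reweighted(Xm: IndicatorMatrix, config: FitConfig):
    """Iteratively reweighted fit: solve, recompute factors, repeat.

    Starts from the unweighted solution and alternates factor updates with
    weighted solves until the largest absolute coefficient change drops
    below ``config.tol`` (or ``max_iter`` is hit, which sets a warning flag
    rather than raising).  With ``config.anneal`` the reweighting constant
    is walked down a coarse-to-fine ladder before the final iterations at
    ``eps_c``, so that graded ramps in the initial solution fuse into steps
    instead of being annihilated by the first sharp factor update.
    """
    w, solver_state = _fit_full(Xm, config.gamma, backend=config.backend, ridge=config.ridge)
    warm, rho = solver_state if solver_state else (None, 5.0)
    state = compute_reweight_factors(w, Xm, config.eps_c)

    if config.anneal:
        eps_schedule = [e for e in _ANNEAL_LADDER if e > config.eps_c] + [config.eps_c]
    else:
        eps_schedule = [config.eps_c]

    for eps in eps_schedule:
        final_stage = eps == config.eps_c
        for it in range(1, config.max_iter + 1):
            u = compute_reweight_factors(w, Xm, eps).factors
            w_new, solver_state = _fit_full(
                Xm, config.gamma, u=u, backend=config.backend, ridge=config.ridge,
                warm=warm, rho=rho,
            )
            if solver_state:
                warm, rho = solver_state
            delta = float(np.max(np.abs(w_new.values - w.values))) if Xm.m else 0.0
            w = w_new
            if final_stage:
                state = compute_reweight_factors(w, Xm, config.eps_c)
                state.iteration = it
                state.last_delta = delta
                if delta < config.tol:
                    state.converged = True
            if delta < config.tol:
                break
    if not state.converged:
        warnings.warn(
            f"reweighting did not converge in {config.max_iter} iterations "
            f"(last delta {state.last_delta:.3g})",
            RuntimeWarning,
        )
    return w, state
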