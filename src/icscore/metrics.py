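"""Discrimination, calibration and cutoff diagnostics for risk models.

Covers the usual clinical-validation battery: AUC with a bias-corrected
percentile bootstrap CI, Nagelkerke R^2, grouped calibration plots with the
predicted/observed ratio, and the 2x2-table family (sensitivity, specificity,
likelihood ratios, diagnostic odds ratio) at a sensitivity-constrained
cutoff.  Also builds the classical Sullivan-style points system from a
logistic fit, as a comparison baseline for interval-coded charts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .scorechart import ScoreEntry, ScoreTable

__all__ = [
    "EvalReport",
    "auc",
    "auc_ci_bootstrap",
    "r2_adj",
    "calibration_groups",
    "select_cutoff",
    "confusion_at_cutoff",
    "build_classical_score_system",
]


@dataclass
class EvalReport:
    auc: float = float("nan")
    auc_ci: tuple = (float("nan"), float("nan"))
    r2_adj: float = float("nan")
    calibration: dict = field(default_factory=dict)
    cutoff_block: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "r2_adj": self.r2_adj,
            "calibration": self.calibration,
            "cutoff": self.cutoff_block,
        }


def _check_two_classes(outcomes):
    y = (np.asarray(outcomes) > 0).astype(int)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return y


def auc(predictions, outcomes) -> float:
    """Mann-Whitney concordance probability; ties count one half."""
    y = _check_two_classes(outcomes)
    return float(roc_auc_score(y, np.asarray(predictions, dtype=float)))


def _auc_rank(predictions: np.ndarray, y01: np.ndarray) -> float:
    """Rank-statistic AUC, equivalent to `auc` but cheap inside tight loops."""
    r = stats.rankdata(predictions)
    n1 = int(y01.sum())
    n0 = len(y01) - n1
    return float((r[y01 == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_ci_bootstrap(predictions, outcomes, B: int = 1000, level: float = 0.95, seed: int = 0):
    """Bias-corrected (BC) percentile bootstrap CI for the AUC.

    Rows are resampled with replacement B times; single-class replicates are
    redrawn.  The BC adjustment shifts the percentile levels by twice the
    normal quantile of the fraction of replicates below the point estimate
    (no acceleration term).
    """
    predictions = np.asarray(predictions, dtype=float)
    y = _check_two_classes(outcomes)
    n = len(y)
    point = auc(predictions, y)
    rng = np.random.default_rng(seed)

    reps = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
        reps[b] = _auc_rank(predictions[idx], yb)

    spread = reps.max() - reps.min()
    if point >= 1.0 and spread == 0.0:
        warnings.warn("degenerate bootstrap: AUC = 1 with no replicate spread", RuntimeWarning)
        return (1.0, 1.0)

    frac_below = np.mean(reps < point)
    frac_below = min(max(frac_below, 1.0 / (2 * B)), 1 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(frac_below)
    alpha = 1 - level
    a1 = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
    a2 = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
    lo, hi = np.quantile(reps, [a1, a2])
    return (float(lo), float(hi))


def r2_adj(risks, outcomes) -> float:
    """Nagelkerke-scaled likelihood-ratio R^2 against the prevalence model."""
    y = _check_two_classes(outcomes)
    p = np.clip(np.asarray(risks, dtype=float), 1e-6, 1 - 1e-6)
    n = len(y)
    prev = y.mean()
    ll_model = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    ll_null = float(n * (prev * np.log(prev) + (1 - prev) * np.log(1 - prev)))
    cox_snell = 1.0 - math.exp((2.0 / n) * (ll_null - ll_model))
    max_r2 = 1.0 - math.exp((2.0 / n) * ll_null)
    return float(cox_snell / max_r2)


def calibration_groups(risks, outcomes, min_frac: float = 0.10) -> dict:
    """Grouped calibration: sort by predicted risk, form contiguous
    equal-count groups of at least ceil(min_frac*n) patients (remainder to
    the last group); report per-group mean prediction, observed event
    fraction and exact (Clopper-Pearson) 95% binomial CI, plus the overall
    predicted/observed ratio."""
    risks = np.asarray(risks, dtype=float)
    y = (np.asarray(outcomes) > 0).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations for grouped calibration")
    prev = y.mean()
    if prev == 0:
        raise ValueError("predicted/observed ratio undefined: no events observed")

    order = np.argsort(risks, kind="stable")
    size = math.ceil(min_frac * n)
    n_groups = n // size
    groups = []
    for g in range(n_groups):
        lo = g * size
        hi = (g + 1) * size if g < n_groups - 1 else n
        idx = order[lo:hi]
        k = int(y[idx].sum())
        m = len(idx)
        ci_lo = stats.beta.ppf(0.025, k, m - k + 1) if k > 0 else 0.0
        ci_hi = stats.beta.ppf(0.975, k + 1, m - k) if k < m else 1.0
        groups.append(
            {
                "n": m,
                "mean_predicted": float(risks[idx].mean()),
                "observed": k / m,
                "ci": (float(ci_lo), float(ci_hi)),
            }
        )
    return {"groups": groups, "ratio": float(risks.mean() / prev), "prevalence": float(prev)}


def select_cutoff(scores, outcomes, min_sens: float = 0.90) -> int:
    """Best-specificity cutoff subject to sensitivity >= min_sens.

    Predict an event iff score >= c; among qualifying integer cutoffs the one
    with maximal specificity is returned, ties resolved toward the larger
    (stricter) cutoff.  If no cutoff attains min_sens the minimum score is
    returned with a warning.
    """
    scores = np.asarray(scores)
    y = (np.asarray(outcomes) > 0).astype(int)
    _check_two_classes(y)
    candidates = np.arange(scores.min(), scores.max() + 2)
    best_c, best_spec = None, -1.0
    for c in candidates:
        pred = scores >= c
        sens = pred[y == 1].mean()
        spec = (~pred)[y == 0].mean()
        if sens >= min_sens and spec >= best_spec:
            best_c, best_spec = int(c), spec
    if best_c is None:
        warnings.warn(f"no cutoff attains sensitivity {min_sens}", RuntimeWarning)
        return int(scores.min())
    return best_c


def confusion_at_cutoff(scores, outcomes, cutoff) -> dict:
    """2x2-table metrics at a cutoff: sensitivity, specificity, LR+, LR-,
    DOR with a log-normal 95% CI (0.5 continuity correction on zero cells)."""
    scores = np.asarray(scores)
    y = (np.asarray(outcomes) > 0).astype(int)
    _check_two_classes(y)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    dor = lr_pos / lr_neg if lr_neg > 0 and math.isfinite(lr_pos) else float("inf")

    cells = [tp, fp, fn, tn]
    if 0 in cells:
        a, bb, c, d = (x + 0.5 for x in cells)
    else:
        a, bb, c, d = cells
    log_dor = math.log((a * d) / (bb * c))
    se = math.sqrt(1 / a + 1 / bb + 1 / c + 1 / d)
    ci = (math.exp(log_dor - 1.96 * se), math.exp(log_dor + 1.96 * se))
    return {
        "cutoff": int(cutoff),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": sens,
        "specificity": spec,
        "lr_pos": lr_pos,
        "lr_neg": lr_neg,
        "dor": dor,
        "dor_ci": ci,
    }


def build_classical_score_system(records, outcomes, specs, user_intervals, grids=None) -> ScoreTable:
    """Sullivan-style points system: fit an ordinary logistic regression on
    the raw variables, cut each continuous variable into user-chosen
    fixed-width intervals, apply the effect at each interval midpoint, and
    rescale so the smallest non-zero effect becomes 1 point.

    ``user_intervals`` maps continuous variable names to interval widths.
    """
    import statsmodels.api as sm

    names = [s.name for s in specs]
    cols = []
    for s in specs:
        v = np.array([float(r[s.name]) for r in records], dtype=float)
        cols.append(v)
    Xraw = np.column_stack(cols)
    y = (np.asarray(outcomes) > 0).astype(int)

    model = sm.Logit(y, sm.add_constant(Xraw))
    try:
        res = model.fit(disp=0)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(
            "logistic fit failed (possible separation); consider penalization"
        ) from exc
    if not np.all(np.isfinite(res.bse)):
        raise ValueError("logistic fit shows separation; consider penalization")
    betas = dict(zip(names, res.params[1:]))

    # per-interval effects at the interval midpoint, relative to the first
    # (reference) interval's midpoint
    effects, layout = {}, {}
    for s in specs:
        v = np.array([float(r[s.name]) for r in records], dtype=float)
        if s.kind == "continuous":
            width = float(user_intervals[s.name])
            # cuts at multiples of `width` strictly inside the observed range
            first = math.floor(v.min() / width + 1) * width
            cuts = [c for c in np.arange(first, v.max(), width) if c > v.min()]
            edges = [v.min()] + cuts + [v.max()]
            mids = [(a + b) / 2.0 for a, b in zip(edges[:-1], edges[1:])]
            bounds = [
                (cuts[i - 1] if i > 0 else None, cuts[i] if i < len(cuts) else None)
                for i in range(len(cuts) + 1)
            ]
            ref = mids[0]
            effects[s.name] = [betas[s.name] * (mm - ref) for mm in mids]
            layout[s.name] = bounds
        else:  # binary / categorical treated as 0/1 here
            effects[s.name] = [0.0, betas[s.name]]
            layout[s.name] = None

    all_eff = [e for v in effects.values() for e in v if abs(e) > 1e-12]
    m = min(abs(e) for e in all_eff) if all_eff else 1.0

    entries, kinds = {}, {}
    for s in specs:
        if s.kind == "continuous":
            rows = []
            for (lo, hi), e in zip(layout[s.name], effects[s.name]):
                pts = _round_half_away(e / m)
                if rows and rows[-1].points == pts:
                    rows[-1].upper = hi
                else:
                    rows.append(ScoreEntry(points=pts, lower=lo, upper=hi))
            kinds[s.name] = "continuous"
        else:
            rows = [
                ScoreEntry(points=0, level=0),
                ScoreEntry(points=_round_half_away(effects[s.name][1] / m), level=1),
            ]
            kinds[s.name] = s.kind
        entries[s.name] = rows

    return ScoreTable(
        variables=names,
        entries=entries,
        kinds=kinds,
        metadata={"method": "classical-sullivan", "widths": dict(user_intervals)},
    )


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
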