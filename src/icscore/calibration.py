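"""Monotone link from integer score to event risk, and the risk lookup table.

The score orders patients but is not itself a probability.  The link is a
monotone non-decreasing curve fitted to the empirical (score, outcome) pairs:
by default isotonic regression (the pool-adjacent-violators solution), or a
kernel-smoothed monotone variant whose bandwidth minimizes cross-validated
Bernoulli negative log-likelihood.  Fitted risks are clipped away from 0 and
1 (defaults 0.001 / 0.999) so the extreme table rows read "<0.001" and
">0.999"-style rather than certainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["LinkFunction", "RiskTable", "fit_link", "risk_of", "build_risk_table"]

DEFAULT_CLIP = (0.001, 0.999)


@dataclass
class LinkFunction:
    method: str  # "isotonic" | "smoothed-monotone"
    knots: list  # ordered (score, risk) pairs
    clip: tuple = DEFAULT_CLIP

    def __post_init__(self):
        risks = [r for _, r in self.knots]
        if any(b < a for a, b in zip(risks, risks[1:])):
            raise ValueError("link risks must be non-decreasing in score")


@dataclass
class RiskTable:
    """Ordered (score range, displayed risk) rows covering all scores.

    Each row is a dict with keys ``lo``, ``hi`` (inclusive integer bounds),
    ``risk`` (numeric) and ``display`` (string; extremes rendered as strict
    inequalities against the clip bounds).
    """

    rows: list = field(default_factory=list)

    def lookup(self, score: int) -> float:
        for row in self.rows:
            if row["lo"] <= score <= row["hi"]:
                return row["risk"]
        # constant extrapolation beyond the tabulated range
        if self.rows:
            return self.rows[0]["risk"] if score < self.rows[0]["lo"] else self.rows[-1]["risk"]
        raise ValueError("empty risk table")


def _pav_risks(scores, outcomes, clip):
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(scores, outcomes)
    xs = np.unique(scores)
    risks = np.clip(iso.predict(xs), clip[0], clip[1])
    return xs, risks


def _kernel_monotone_risks(scores, outcomes, bandwidth, clip):
    """Nadaraya-Watson smoothing of per-score event rates, then a PAV
    projection to restore monotonicity."""
    xs, inv = np.unique(scores, return_inverse=True)
    counts = np.bincount(inv)
    events = np.bincount(inv, weights=(np.asarray(outcomes) == 1).astype(float))
    K = np.exp(-0.5 * ((xs[:, None] - xs[None, :]) / bandwidth) ** 2)
    num = K @ events
    den = K @ counts
    smooth = num / den
    iso = IsotonicRegression(out_of_bounds="clip")
    risks = iso.fit_transform(xs, smooth, sample_weight=counts)
    return xs, np.clip(risks, clip[0], clip[1])


def _bernoulli_nll(risks, outcomes):
    p = np.clip(risks, 1e-12, 1 - 1e-12)
    y = (np.asarray(outcomes) == 1).astype(float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def fit_link(
    scores,
    outcomes,
    method: str = "isotonic",
    cv_folds: int = 10,
    clip: tuple = DEFAULT_CLIP,
    seed: int = 0,
) -> LinkFunction:
    """Fit the monotone score->risk curve.

    method="isotonic" is the pool-adjacent-violators least-squares solution;
    method="smoothed-monotone" additionally smooths the per-score event rates
    with a Gaussian kernel whose bandwidth minimizes ``cv_folds``-fold
    cross-validated Bernoulli negative log-likelihood.
    """
    scores = np.asarray(scores, dtype=float)
    y01 = (np.asarray(outcomes) > 0).astype(int)
    if len(np.unique(y01)) < 2:
        raise ValueError("link undefined: outcomes contain a single class")

    if method == "isotonic":
        xs, risks = _pav_risks(scores, y01, clip)
    elif method == "smoothed-monotone":
        span = max(scores.max() - scores.min(), 1.0)
        bandwidths = span * np.array([0.02, 0.05, 0.1, 0.2, 0.4])
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        best_bw, best_nll = bandwidths[0], np.inf
        for bw in bandwidths:
            nll = 0.0
            for tr, te in skf.split(scores.reshape(-1, 1), y01):
                xs_t, r_t = _kernel_monotone_risks(scores[tr], y01[tr], bw, clip)
                pred = np.interp(scores[te], xs_t, r_t)
                nll += _bernoulli_nll(pred, y01[te])
            if nll < best_nll:
                best_nll, best_bw = nll, bw
        xs, risks = _kernel_monotone_risks(scores, y01, best_bw, clip)
    else:
        raise ValueError(f"unknown link method {method!r}")

    knots = [(float(x), float(r)) for x, r in zip(xs, risks)]
    return LinkFunction(method=method, knots=knots, clip=tuple(clip))


def risk_of(score, link: LinkFunction) -> float:
    """Risk at a score: piecewise-linear between knots, constant beyond."""
    xs = np.array([s for s, _ in link.knots])
    rs = np.array([r for _, r in link.knots])
    val = float(np.interp(score, xs, rs))
    return float(np.clip(val, link.clip[0], link.clip[1]))


def build_risk_table(
    link: LinkFunction, score_min: int, score_max: int, display_digits: int = 2
) -> RiskTable:
    """Tabulate the link on every integer score, merging consecutive scores
    with equal displayed risk into ranges (a paper-chart-style lookup table)."""
    if score_min > score_max:
        raise ValueError("score_min must be <= score_max")
    rows = []
    for s in range(score_min, score_max + 1):
        r = round(risk_of(s, link), display_digits)
        if rows and rows[-1]["risk"] == r:
            rows[-1]["hi"] = s
        else:
            rows.append({"lo": s, "hi": s, "risk": r})
    lo_clip, hi_clip = link.clip
    for row in rows:
        if row["risk"] <= lo_clip:
            row["display"] = f"<{lo_clip:g}"
        elif row["risk"] >= round(hi_clip, display_digits):
            row["display"] = f">{hi_clip:g}"
        else:
            row["display"] = f"{row['risk']:.{display_digits}f}"
    return RiskTable(rows=rows)
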