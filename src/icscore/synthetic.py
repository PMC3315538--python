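"""Synthetic cohorts with known piecewise-constant additive log-odds, plus
the packaged adnexal-mass score chart and worked-example patient.

The generator emulates the statistical shape of clinical tabular cohorts:
mixed continuous/categorical covariates, an additive step-function log-odds
model, event prevalence around 0.2-0.35, irrelevant covariates, and optional
interaction terms declared as derived variables.  Because the true step
functions are known, generated data support parameter-recovery and
calibration checks that real cohorts cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .calibration import RiskTable
from .scorechart import ScoreTable
from .serialize import risk_table_from_dict, score_table_from_dict

__all__ = ["VariableModel", "SyntheticSpec", "generate", "bayes_auc", "default_staircase_spec", "adnexal_fixture"]


@dataclass(frozen=True)
class VariableModel:
    """Generative model of one covariate and its true effect on log-odds.

    Continuous: ``dist`` is ("uniform", lo, hi) or ("normal", mean, sd);
    ``breakpoints`` and ``effects`` define the true step function (effects
    has one more entry than breakpoints).  Binary: ``dist`` is ("bernoulli",
    p) with a single-entry ``effects`` for value 1.  Categorical: ``dist``
    is ("categorical", (levels...), (probs...)) with one effect per level.
    """

    name: str
    kind: str
    dist: tuple
    breakpoints: tuple = ()
    effects: tuple = (0.0,)

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if any(a >= b for a, b in zip(bp, bp[1:])):
            raise ValueError(f"breakpoints of {self.name!r} must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "effects", tuple(float(e) for e in self.effects))
        if self.kind == "continuous" and len(self.effects) != len(bp) + 1:
            raise ValueError(f"{self.name!r}: need len(breakpoints)+1 effects")
        if self.kind == "categorical":
            levels, probs = self.dist[1], self.dist[2]
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name!r}: categorical probabilities must sum to 1")
            if len(self.effects) != len(levels):
                raise ValueError(f"{self.name!r}: one effect per level required")


@dataclass(frozen=True)
class SyntheticSpec:
    variables: tuple
    intercept: float = 0.0
    seed: int = 0


def default_staircase_spec(seed: int = 0) -> SyntheticSpec:
    """Two informative step-function continuous variables, one informative
    binary, three irrelevant covariates; intercept tuned for ~0.3 prevalence."""
    return SyntheticSpec(
        variables=(
            VariableModel("stair_a", "continuous", ("uniform", 0.0, 10.0), (3.0, 7.0), (0.0, 1.0, 2.0)),
            VariableModel("stair_b", "continuous", ("normal", 50.0, 15.0), (40.0, 60.0), (0.0, 1.2, 2.5)),
            VariableModel("flag", "binary", ("bernoulli", 0.4), effects=(1.0,)),
            VariableModel("noise_u", "continuous", ("uniform", 0.0, 1.0), (), (0.0,)),
            VariableModel("noise_n", "continuous", ("normal", 0.0, 1.0), (), (0.0,)),
            VariableModel("noise_b", "binary", ("bernoulli", 0.5), effects=(0.0,)),
        ),
        intercept=-3.7,
        seed=seed,
    )


def _draw(vm: VariableModel, rng: np.random.Generator, n: int):
    kind = vm.dist[0]
    if kind == "uniform":
        return rng.uniform(vm.dist[1], vm.dist[2], n)
    if kind == "normal":
        return rng.normal(vm.dist[1], vm.dist[2], n)
    if kind == "bernoulli":
        return (rng.random(n) < vm.dist[1]).astype(int)
    if kind == "categorical":
        levels, probs = vm.dist[1], vm.dist[2]
        idx = rng.choice(len(levels), size=n, p=probs)
        return np.array([levels[i] for i in idx], dtype=object)
    raise ValueError(f"unknown distribution {kind!r} for {vm.name!r}")


def true_effect(vm: VariableModel, values) -> np.ndarray:
    """g_p(x): the declared step-function contribution to the log-odds."""
    if vm.kind == "continuous":
        idx = np.searchsorted(vm.breakpoints, np.asarray(values, dtype=float), side="right")
        return np.asarray(vm.effects)[idx]
    if vm.kind == "binary":
        return np.asarray(values, dtype=float) * vm.effects[0]
    levels = list(vm.dist[1])
    return np.array([vm.effects[levels.index(v)] for v in values])


def generate(spec: SyntheticSpec, n: int, seed: int | None = None):
    """Draw ``n`` patients: covariates per spec, risk = logistic(b0 + sum g_p),
    outcome ~ Bernoulli(risk) in {-1, +1}.  Identical (spec, n, seed) give
    bit-identical output."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cols = {vm.name: _draw(vm, rng, n) for vm in spec.variables}
    eta = np.full(n, spec.intercept)
    for vm in spec.variables:
        eta = eta + true_effect(vm, cols[vm.name])
    risks = 1.0 / (1.0 + np.exp(-eta))
    outcomes = np.where(rng.random(n) < risks, 1, -1)
    records = [{name: cols[name][i] for name in cols} for i in range(n)]
    return records, outcomes, risks


def bayes_auc(spec: SyntheticSpec, n: int = 50000, seed: int = 12345) -> float:
    """Large-sample AUC of the true risks against drawn outcomes — the
    discrimination ceiling any fitted model can approach."""
    from .metrics import auc

    _, outcomes, risks = generate(spec, n, seed=seed)
    return auc(risks, outcomes)


def adnexal_fixture():
    """The packaged adnexal-mass chart, risk lookup and worked example.

    Returns (ScoreTable, RiskTable, patient record, expected score,
    expected risk) — the published 10-variable questionnaire with its
    16-row score-to-risk table and the 56-year-old example patient
    (total score 27, risk 0.96).
    """
    text = resources.files("icscore.data").joinpath("adnexal_chart.json").read_text()
    payload = json.loads(text)
    chart = score_table_from_dict(payload["chart"])
    risk_table = risk_table_from_dict(payload["risk_table"])
    patient = payload["worked_example"]["patient"]
    return (
        chart,
        risk_table,
        patient,
        payload["worked_example"]["expected_score"],
        payload["worked_example"]["expected_risk"],
    )
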