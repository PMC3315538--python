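"""Anchoring, normalize-and-round, and patient scoring."""

import numpy as np
import pytest

from icscore.optimizer import IntervalWeights
from icscore.scorechart import anchor_weights, normalize_and_round, score_patient
from icscore.synthetic import adnexal_fixture
from icscore.variables import ThresholdGrid, VariableSpec, encode_dataset


def weights_for(blocks_values, intercept=0.0):
    """Build IntervalWeights from {var: [values...]} preserving order."""
    columns, values, blocks = [], [], {}
    for var, vals in blocks_values.items():
        start = len(values)
        columns.extend((var, j) for j in range(len(vals)))
        values.extend(vals)
        blocks[var] = slice(start, len(values))
    return IntervalWeights(
        values=np.array(values, dtype=float),
        intercept=intercept,
        columns=columns,
        blocks=blocks,
    )


class TestAnchor:
    def test_reference_shift_moves_to_intercept(self):
        w = anchor_weights(weights_for({"v": [0.5, 0.5, 1.5]}, intercept=0.0))
        assert w.values.tolist() == [0.0, 0.0, 1.0]
        assert w.intercept == pytest.approx(0.5)

    def test_idempotent(self):
        w = weights_for({"a": [0.2, 0.9], "b": [-0.3, 0.0]}, intercept=1.0)
        once = anchor_weights(w)
        twice = anchor_weights(once)
        assert twice.values.tolist() == once.values.tolist()
        assert twice.intercept == once.intercept

    def test_predictions_preserved(self):
        rng = np.random.default_rng(3)
        grid = ThresholdGrid("x", (0.0, 1.0))
        spec = [VariableSpec("x", "continuous"), VariableSpec("b", "binary")]
        recs = [{"x": v, "b": int(u < 0.5)} for v, u in rng.uniform(-1, 2, (100, 2))]
        Xm = encode_dataset(recs, spec, [grid], [1] * 100)
        w = IntervalWeights(
            values=rng.normal(0, 1, Xm.m),
            intercept=rng.normal(),
            columns=list(Xm.columns),
            blocks=dict(Xm.blocks),
        )
        wa = anchor_weights(w)
        f0 = Xm.X @ w.values + w.intercept
        f1 = Xm.X @ wa.values + wa.intercept
        assert f1 == pytest.approx(f0, abs=1e-12)


class TestNormalizeAndRound:
    def test_smallest_nonzero_becomes_one(self):
        w = weights_for({"A": [0.0, 1.5], "B": [0.0, -7.5, 6.0]})
        table = normalize_and_round(w)
        assert [e.points for e in table.entries["A"]] == [0, 1]
        assert [e.points for e in table.entries["B"]] == [0, -5, 4]

    def test_half_rounds_away_from_zero(self):
        table = normalize_and_round(weights_for({"v": [0.0, 0.6, 2.1]}))
        # 2.1/0.6 = 3.5 -> 4
        assert [e.points for e in table.entries["v"]] == [0, 1, 4]

    def test_all_zero_weights_empty_table(self):
        table = normalize_and_round(weights_for({"v": [0.0, 0.0, 0.0]}))
        assert table.is_empty()
        assert table.variables == []

    def test_equal_rounded_points_merge(self):
        grid = ThresholdGrid("x", (1.0, 2.0, 3.0))
        table = normalize_and_round(
            weights_for({"x": [0.0, 1.0, 1.0, 2.0]}),
            specs={"x": VariableSpec("x", "continuous")},
            grids={"x": grid},
        )
        rows = table.entries["x"]
        assert [(e.lower, e.upper, e.points) for e in rows] == [
            (None, 1.0, 0),
            (1.0, 3.0, 1),
            (3.0, None, 2),
        ]


class TestScorePatient:
    def test_worked_example_scores_27(self):
        chart, _, patient, expected, _ = adnexal_fixture()
        assert score_patient(patient, chart) == expected == 27

    def test_all_baseline_patient_scores_zero(self):
        chart, _, patient, _, _ = adnexal_fixture()
        baseline = {
            "age": 30, "lesion_diameter": 20, "solid_ratio": 0.1,
            "papillations_gt3": 0, "papillation_flow": 0, "irregular_wall": 0,
            "acoustic_shadows": 0, "color_score": 1, "ascites": 0,
            "douglas_fluid": 5,
        }
        assert score_patient(baseline, chart) == 0

    def test_acoustic_shadows_alone_scores_minus5(self):
        chart, _, _, _, _ = adnexal_fixture()
        shadows_only = {
            "age": 30, "lesion_diameter": 20, "solid_ratio": 0.1,
            "papillations_gt3": 0, "papillation_flow": 0, "irregular_wall": 0,
            "acoustic_shadows": 1, "color_score": 1, "ascites": 0,
            "douglas_fluid": 5,
        }
        assert score_patient(shadows_only, chart) == -5

    def test_additivity_single_covariate_change(self):
        chart, _, patient, _, _ = adnexal_fixture()
        base = score_patient(patient, chart)
        other = dict(patient)
        other["age"] = 70  # 1 point -> 3 points
        assert score_patient(other, chart) - base == 2

    def test_missing_value_scores_zero_points(self):
        chart, _, patient, _, _ = adnexal_fixture()
        partial = dict(patient)
        partial["age"] = None  # drops the 1 age point
        assert score_patient(partial, chart) == 26
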