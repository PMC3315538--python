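"""Discrimination, calibration, cutoff and classical-score-system metrics."""

import math

import numpy as np
import pytest

from icscore.metrics import (
    auc,
    auc_ci_bootstrap,
    build_classical_score_system,
    calibration_groups,
    confusion_at_cutoff,
    r2_adj,
    select_cutoff,
)
from icscore.scorechart import score_patient
from icscore.variables import VariableSpec


class TestAuc:
    def test_perfect_and_tied(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_enumerated_pairs(self):
        # 4 pos-neg pairs: (2>1), (2<3), (4>1), (4>3) -> 3/4 concordant
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        p = rng.normal(0, 1, 200)
        y = (rng.random(200) < 0.4).astype(int)
        assert auc(np.exp(p), y) == pytest.approx(auc(p, y))
        assert auc(3 * p - 7, y) == pytest.approx(auc(p, y))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])


class TestBootstrapCI:
    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        y = (rng.random(150) < 0.35).astype(int)
        p = y + rng.normal(0, 1.2, 150)
        point = auc(p, y)
        lo, hi = auc_ci_bootstrap(p, y, B=300, seed=1)
        assert lo <= point <= hi

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        y = (rng.random(80) < 0.4).astype(int)
        p = y + rng.normal(0, 1, 80)
        assert auc_ci_bootstrap(p, y, B=200, seed=9) == auc_ci_bootstrap(
            p, y, B=200, seed=9
        )

    def test_degenerate_perfect_auc_warns(self):
        y = [0] * 10 + [1] * 10
        p = list(range(20))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert auc_ci_bootstrap(p, y, B=50, seed=0) == (1.0, 1.0)


class TestR2Adj:
    def test_null_model_is_zero(self):
        y = np.array([0, 1, 0, 1, 0, 0, 1, 0, 0, 1])
        risks = np.full(10, y.mean())
        assert r2_adj(risks, y) == pytest.approx(0.0, abs=1e-12)

    def test_near_perfect_prediction_near_one(self):
        rng = np.random.default_rng(1)
        y = (rng.random(400) < 0.3).astype(int)
        risks = np.where(y == 1, 0.999, 0.001)
        assert r2_adj(risks, y) > 0.97

    def test_matches_textbook_formula(self):
        # independent second implementation of Nagelkerke's formula
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.normal(0, 1, n)
        p_true = 1 / (1 + np.exp(-(x - 0.5)))
        y = (rng.random(n) < p_true).astype(int)
        risks = np.clip(p_true, 1e-6, 1 - 1e-6)
        ll1 = np.sum(y * np.log(risks) + (1 - y) * np.log(1 - risks))
        pbar = y.mean()
        ll0 = n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
        expected = (1 - math.exp(2 * (ll0 - ll1) / n)) / (1 - math.exp(2 * ll0 / n))
        assert r2_adj(p_true, y) == pytest.approx(expected, abs=1e-10)


class TestCalibrationGroups:
    def test_exact_ten_groups_of_ten(self):
        rng = np.random.default_rng(2)
        y = (rng.random(100) < 0.3).astype(int)
        block = calibration_groups(rng.random(100), y, min_frac=0.10)
        assert len(block["groups"]) == 10
        assert all(g["n"] == 10 for g in block["groups"])

    def test_constant_prevalence_prediction_ratio_one(self):
        rng = np.random.default_rng(6)
        y = (rng.random(400) < 0.25).astype(int)
        block = calibration_groups(np.full(400, y.mean()), y)
        assert block["ratio"] == pytest.approx(1.0)

    def test_true_risks_fall_inside_group_cis(self):
        from icscore.synthetic import default_staircase_spec, generate

        _, outcomes, risks = generate(default_staircase_spec(), 5000, seed=5)
        y = (outcomes > 0).astype(int)
        block = calibration_groups(risks, y)
        hits = sum(
            g["ci"][0] <= g["mean_predicted"] <= g["ci"][1] for g in block["groups"]
        )
        assert hits >= 8

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            calibration_groups(np.random.rand(20), np.zeros(20))


class TestCutoff:
    def test_enumerated_example(self):
        scores = [10, 12, 14, 5, 8, 11]
        y = [1, 1, 1, 0, 0, 0]
        c = select_cutoff(scores, y, min_sens=0.9)
        assert c == 10
        block = confusion_at_cutoff(scores, y, c)
        assert block["sensitivity"] == 1.0
        assert block["specificity"] == pytest.approx(2 / 3)

    def test_separated_classes_tie_rule_picks_largest(self):
        scores = [1, 2, 3, 10, 11, 12]
        y = [0, 0, 0, 1, 1, 1]
        c = select_cutoff(scores, y, min_sens=0.9)
        block = confusion_at_cutoff(scores, y, c)
        assert block["sensitivity"] == 1.0 and block["specificity"] == 1.0
        assert c == 10  # largest cutoff with sens 1 within attained range

    def test_unattainable_sensitivity_warns(self):
        with pytest.warns(RuntimeWarning):
            c = select_cutoff([1, 2, 3, 4], [0, 1, 0, 1], min_sens=2.0)
        assert c == 1

    def test_confusion_metrics_2x2(self):
        scores = [1] * 9 + [0] * 1 + [0] * 8 + [1] * 2
        y = [1] * 10 + [0] * 10
        block = confusion_at_cutoff(scores, y, 1)
        assert block["sensitivity"] == pytest.approx(0.9)
        assert block["specificity"] == pytest.approx(0.8)
        assert block["lr_pos"] == pytest.approx(4.5)
        assert block["lr_neg"] == pytest.approx(0.125)
        assert block["dor"] == pytest.approx(36.0)

    def test_dor_equals_lr_ratio(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 10, 200)
        y = (rng.random(200) < (scores / 12)).astype(int)
        block = confusion_at_cutoff(scores, y, 5)
        if math.isfinite(block["lr_pos"]) and block["lr_neg"] > 0:
            assert block["dor"] == pytest.approx(block["lr_pos"] / block["lr_neg"])

    def test_cutoff_below_all_scores(self):
        block = confusion_at_cutoff([3, 4, 5], [1, 0, 1], 0)
        assert block["sensitivity"] == 1.0 and block["specificity"] == 0.0


class TestClassicalScoreSystem:
    @staticmethod
    def _cohort(n=1500, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(20, 80, n)
        flag = (rng.random(n) < 0.4).astype(int)
        eta = 0.06 * (age - 50) + 1.2 * flag - 0.8
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        recs = [{"age": a, "flag": f} for a, f in zip(age, flag)]
        specs = [VariableSpec("age", "continuous"), VariableSpec("flag", "binary")]
        return recs, y, specs

    def test_builds_integer_chart(self):
        recs, y, specs = self._cohort()
        table = build_classical_score_system(recs, y, specs, {"age": 10})
        assert set(table.variables) == {"age", "flag"}
        pts = [e.points for rows in table.entries.values() for e in rows]
        assert any(abs(p) >= 1 for p in pts)

    def test_fine_widths_dominate_coarse_on_test_auc(self):
        recs, y, specs = self._cohort(seed=1)
        fine = build_classical_score_system(recs, y, specs, {"age": 5})
        coarse = build_classical_score_system(recs, y, specs, {"age": 40})
        t_recs, t_y, _ = self._cohort(n=2000, seed=99)
        auc_fine = auc([score_patient(r, fine) for r in t_recs], t_y)
        auc_coarse = auc([score_patient(r, coarse) for r in t_recs], t_y)
        assert auc_fine >= auc_coarse - 1e-9
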