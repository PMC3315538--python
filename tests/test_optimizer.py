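"""TV-hinge optimizer: objective, exact LP solutions, reweighting loop."""

import numpy as np
import pytest

from icscore.optimizer import (
    FitConfig,
    IntervalWeights,
    compute_reweight_factors,
    fit_reweighted,
    fit_unweighted,
    objective_value,
)
from icscore.variables import ThresholdGrid, VariableSpec, encode_dataset


def make_weights(Xm, values, intercept=0.0):
    return IntervalWeights(
        values=np.asarray(values, dtype=float),
        intercept=intercept,
        columns=list(Xm.columns),
        blocks=dict(Xm.blocks),
    )


class TestObjective:
    def test_zero_model_gives_hinge_n(self, simple_1d):
        Xm = simple_1d
        w = make_weights(Xm, np.zeros(Xm.m), 0.0)
        assert objective_value(w, Xm, gamma=1.0) == pytest.approx(Xm.n)

    def test_intercept_one_all_positive_gives_zero(self):
        Xm = encode_dataset(
            [{"b": 0}, {"b": 1}], [VariableSpec("b", "binary")], [], [1, 1]
        )
        w = make_weights(Xm, [0.0, 0.0], 1.0)
        assert objective_value(w, Xm, gamma=1.0) == 0.0

    def test_gauge_invariance_with_compensated_intercept(self, simple_1d):
        Xm = simple_1d
        rng = np.random.default_rng(1)
        w = make_weights(Xm, rng.normal(0, 1, Xm.m), 0.3)
        shifted = make_weights(Xm, w.values + 1.7, w.intercept - 1.7)
        # TV is unchanged by a constant block shift; hinge unchanged when the
        # intercept compensates, so objectives agree.
        assert objective_value(shifted, Xm, 2.0) == pytest.approx(
            objective_value(w, Xm, 2.0)
        )


class TestFitUnweighted:
    def test_all_positive_labels_solved_by_intercept(self):
        Xm = encode_dataset(
            [{"b": 0}, {"b": 1}], [VariableSpec("b", "binary")], [], [1, 1]
        )
        w = fit_unweighted(Xm, gamma=1.0)
        assert objective_value(w, Xm, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_separable_1d_single_step_at_zero(self, simple_1d):
        Xm = simple_1d
        w = fit_unweighted(Xm, gamma=0.05)
        f = Xm.X @ w.values + w.intercept
        assert np.all(np.sign(f) == Xm.y)  # zero training error
        block = w.block_values("x")
        # a single fused step located at the 0.0 cut: intervals 0,1 equal
        # and 2,3 equal with a jump between
        assert block[0] == pytest.approx(block[1], abs=1e-8)
        assert block[2] == pytest.approx(block[3], abs=1e-8)
        assert block[2] - block[1] > 1.0

    def test_huge_gamma_fuses_everything(self, simple_1d):
        Xm = simple_1d
        w = fit_unweighted(Xm, gamma=1e6 * Xm.n)
        assert np.allclose(w.values, 0.0, atol=1e-8)
        f = np.full(Xm.n, w.intercept)
        majority = 1.0 if (Xm.y > 0).sum() >= (Xm.y < 0).sum() else -1.0
        assert np.all(np.sign(f) == majority)

    def test_backends_agree_on_objective(self, simple_1d):
        Xm = simple_1d
        for gamma in (0.1, 1.0):
            o = {
                be: objective_value(fit_unweighted(Xm, gamma, backend=be), Xm, gamma)
                for be in ("lp", "slsqp", "admm")
            }
            assert o["lp"] == pytest.approx(o["slsqp"], abs=1e-6)
            # the splitting backend is iterative; slightly looser bound
            assert o["lp"] == pytest.approx(o["admm"], abs=1e-3)


class TestReweighting:
    def test_factor_formula(self, simple_1d):
        Xm = simple_1d
        w = make_weights(Xm, [0.0, 0.0, 0.99, 0.99], 0.0)
        st = compute_reweight_factors(w, Xm, eps_c=0.01)
        # diffs: w1-w0=0 -> 100; w2-w1=0.99 -> 1; w3-w2=0 -> 100
        assert st.factors == pytest.approx([100.0, 1.0, 100.0])
        assert np.all(st.factors > 0)

    def test_factors_vanish_uniformly_for_huge_eps(self, simple_1d):
        Xm = simple_1d
        w = make_weights(Xm, [0.0, 0.3, 1.2, 1.2], 0.0)
        st = compute_reweight_factors(w, Xm, eps_c=1e9)
        ratios = st.factors / st.factors[0]
        assert ratios == pytest.approx(np.ones_like(ratios), rel=1e-6)

    def test_huge_eps_c_recovers_unweighted_solution(self, simple_1d):
        # On this instance the TV penalty does not bind at small gamma, so
        # vanishing uniform factors leave the same optimum.
        Xm = simple_1d
        gamma = 0.05
        w_un = fit_unweighted(Xm, gamma)
        w_rw, _ = fit_reweighted(Xm, FitConfig(gamma=gamma, eps_c=1e6, anneal=False))
        assert objective_value(w_rw, Xm, gamma) == pytest.approx(
            objective_value(w_un, Xm, gamma), abs=1e-6
        )

    def test_convergence_contract(self, simple_1d):
        Xm = simple_1d
        w, st = fit_reweighted(Xm, FitConfig(gamma=0.1, eps_c=0.01, tol=1e-4))
        assert st.converged
        assert st.last_delta < 1e-4
        assert st.iteration >= 1

    def test_non_convergence_warns_not_raises(self, staircase_small):
        Xm = staircase_small[0]
        cfg = FitConfig(gamma=1.0, eps_c=0.01, tol=1e-12, max_iter=1, anneal=False)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            w, st = fit_reweighted(Xm, cfg)
        assert not st.converged

    def test_inner_solve_optimality(self, staircase_small):
        # the weighted solve at iterate-k factors is at least as good as the
        # previous iterate under those same factors
        Xm = staircase_small[0]
        gamma = 1.0
        w0 = fit_unweighted(Xm, gamma)
        st0 = compute_reweight_factors(w0, Xm, 0.01)
        from icscore.optimizer import _fit

        w1 = _fit(Xm, gamma, u=st0.factors)
        assert objective_value(w1, Xm, gamma, st0) <= objective_value(
            w0, Xm, gamma, st0
        ) + 1e-8


class TestMonotoneFusion:
    def test_distinct_levels_non_increasing_in_gamma(self, staircase_small):
        Xm = staircase_small[0]

        def n_levels(w):
            tot = 0
            for var in Xm.blocks:
                vals = np.round(w.block_values(var), 6)
                tot += len(np.unique(vals))
            return tot

        ladder = [0.2, 1.0, 5.0, 25.0]
        counts = [n_levels(fit_unweighted(Xm, g)) for g in ladder]
        assert all(a >= b for a, b in zip(counts, counts[1:])), counts


class TestGaugeInvariance:
    def test_predictions_unchanged_by_block_shift(self, staircase_small):
        Xm = staircase_small[0]
        w = fit_unweighted(Xm, 1.0)
        shifted_vals = w.values.copy()
        sl = w.blocks["stair_a"]
        shifted_vals[sl] += 0.9
        shifted = IntervalWeights(
            values=shifted_vals,
            intercept=w.intercept - 0.9,
            columns=w.columns,
            blocks=w.blocks,
        )
        f0 = Xm.X @ w.values + w.intercept
        f1 = Xm.X @ shifted.values + shifted.intercept
        assert f1 == pytest.approx(f0, abs=1e-12)
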