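import numpy as np
import pytest
from scipy import stats

from dsdpower import (
    FactorSpec,
    ResponseVector,
    SetPointSample,
    build_candidates,
    fit_terms,
    generate_dsd,
    residual_sd_ratio,
    stepwise_select,
    term_from_name,
)
from dsdpower.design import DesignMatrix
from dsdpower.stepwise import SelectionError


def _ols_pvalues(X, y):
    """Textbook OLS coefficient p-values (independent of the package path)."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    df = len(y) - A.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(A.T @ A)
    t = coef / np.sqrt(np.diag(cov))
    return 2 * stats.t.sf(np.abs(t), df)


def _oracle_stepwise(columns, y, p_enter=0.05, p_exit=0.10):
    """Minimal forward/backward trace used as the reference selection path."""
    selected: list[str] = []
    path: list[str] = []
    names = list(columns)
    while True:
        changed = False
        best_p, best_name = np.inf, None
        for name in names:
            if name in selected:
                continue
            trial = selected + [name]
            p = _ols_pvalues(np.column_stack([columns[t] for t in trial]), y)[-1]
            if p < best_p:
                best_p, best_name = p, name
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            path.append(f"+{best_name}")
            changed = True
        if selected:
            pv = _ols_pvalues(np.column_stack([columns[t] for t in selected]), y)[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > p_exit:
                path.append(f"-{selected[worst]}")
                del selected[worst]
                changed = True
        if not changed:
            return selected, path


class TestBuildCandidates:
    def test_counts_numeric(self):
        factors = tuple(FactorSpec(f"x{i}") for i in range(5))
        assert len(build_candidates(factors)) == 10

    def test_categorical_gets_no_quadratic(self):
        factors = (
            FactorSpec("a"),
            FactorSpec("b"),
            FactorSpec("c"),
            FactorSpec("d", kind="categorical2"),
        )
        cands = build_candidates(factors)
        assert len(cands) == 7
        assert "d^2" not in [t.name for t in cands]

    def test_interactions(self):
        factors = tuple(FactorSpec(f"x{i}") for i in range(3))
        cands = build_candidates(factors, include_interactions=True)
        assert [t.name for t in cands[-3:]] == ["x0:x1", "x0:x2", "x1:x2"]

    def test_order_deterministic(self):
        factors = tuple(FactorSpec(f"x{i}") for i in range(4))
        names = [t.name for t in build_candidates(factors)]
        assert names == ["x0", "x1", "x2", "x3", "x0^2", "x1^2", "x2^2", "x3^2"]


class TestStepwiseSelect:
    def test_noiseless_single_signal(self):
        design = generate_dsd(5)
        y = 3.0 * design.column("x1")
        model = stepwise_select(design, y)
        assert model.term_names == ("x1",)
        assert model.coefs[0] == pytest.approx(3.0)
        assert model.pvalues[0] < 1e-10
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_gives_intercept_only(self):
        design = generate_dsd(4)
        model = stepwise_select(design, np.full(design.n_runs, 2.5))
        assert model.terms == ()
        assert model.intercept == pytest.approx(2.5)

    def test_path_matches_hand_traced_oracle(self):
        design = generate_dsd(5)
        rng = np.random.default_rng(77)
        y = (
            0.4
            + 0.45 * design.column("x2")
            - 0.3 * design.column("x4") ** 2
            + rng.normal(0, 0.15, design.n_runs)
        )
        model = stepwise_select(design, y)
        columns = {
            t.name: t.build_column(design) for t in build_candidates(design.factors)
        }
        oracle_terms, oracle_path = _oracle_stepwise(columns, y)
        assert list(model.term_names) == oracle_terms
        trace_moves = [
            ("+" if e.startswith("enter") else "-") + e.split()[1]
            for e in model.trace
            if e.startswith(("enter", "exit"))
        ]
        assert trace_moves == oracle_path

    def test_final_pvalues_below_exit_threshold(self):
        design = generate_dsd(5)
        rng = np.random.default_rng(5)
        for _ in range(5):
            y = 0.3 * design.column("x1") + rng.normal(0, 0.25, design.n_runs)
            model = stepwise_select(design, y)
            assert (model.pvalues <= 0.10).all()

    def test_refit_reproduces_selected_model(self, cc1_study):
        scenario, response, _sp = cc1_study
        model = stepwise_select(scenario.design, response)
        refit = fit_terms(scenario.design, response, model.terms)
        assert np.allclose(refit.coefs, model.coefs, atol=1e-12)
        assert refit.intercept == pytest.approx(model.intercept, abs=1e-12)

    def test_residuals_sum_to_zero(self, cc1_study):
        scenario, response, _sp = cc1_study
        model = stepwise_select(scenario.design, response)
        assert abs(model.residuals.sum()) < 1e-10

    def test_collinear_candidate_skipped(self):
        values = np.array(
            [[-1, -1], [1, 1], [0, 0], [-1, -1], [1, 1], [0, 0], [1, 1], [-1, -1]],
            dtype=float,
        )
        design = DesignMatrix((FactorSpec("a"), FactorSpec("dup")), values)
        y = 2.0 * values[:, 0] + np.random.default_rng(0).normal(0, 0.05, 8)
        model = stepwise_select(design, y, include_quadratic=False)
        assert model.term_names == ("a",)
        assert any("collinear" in e for e in model.trace)

    def test_length_mismatch(self):
        design = generate_dsd(4)
        with pytest.raises(Exception, match="runs"):
            stepwise_select(design, np.ones(design.n_runs - 1))


class TestFittedModel:
    def test_predict_matches_manual(self):
        design = generate_dsd(4)
        y = (
            0.2
            + 0.5 * design.column("x1")
            - 0.3 * design.column("x2") ** 2
        )
        model = fit_terms(
            design, y, [term_from_name("x1"), term_from_name("x2^2")]
        )
        pts = np.array([[0.5, -0.5, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
        expected = 0.2 + 0.5 * pts[:, 0] - 0.3 * pts[:, 1] ** 2
        assert np.allclose(model.predict(pts), expected, atol=1e-10)

    def test_quadratic_only_factor_counts_significant(self):
        design = generate_dsd(4)
        y = 0.8 * design.column("x3") ** 2 + 0.1
        model = fit_terms(design, y, [term_from_name("x3^2")])
        assert model.significant_factor_names() == frozenset({"x3"})

    def test_residual_sd_conventions(self):
        design = generate_dsd(4)
        rng = np.random.default_rng(3)
        y = 0.5 * design.column("x1") + rng.normal(0, 0.2, design.n_runs)
        model = fit_terms(design, y, [term_from_name("x1")])
        sse = float(model.residuals @ model.residuals)
        n = design.n_runs
        assert model.sigma_residuals == pytest.approx(np.sqrt(sse / (n - 1)))
        assert model.residual_sd("df") == pytest.approx(np.sqrt(sse / (n - 2)))


class TestResidualSdRatio:
    sp = SetPointSample([0.39, 0.41, 0.40, 0.42, 0.38])

    def test_zero_residuals(self):
        design = generate_dsd(4)
        y = 1.5 * design.column("x1")
        model = fit_terms(design, y, [term_from_name("x1")])
        assert residual_sd_ratio(model, self.sp) == pytest.approx(0.0, abs=1e-10)

    def test_equal_sds_give_unity(self):
        design = generate_dsd(4)
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1.0, design.n_runs)
        model = fit_terms(design, y, [])
        assert residual_sd_ratio(model, self.sp) == pytest.approx(
            model.sigma_residuals / self.sp.sd
        )

    def test_inflated_noise_regime_flagged_by_large_ratio(self, cc1_study):
        # DoE residual noise far above the set-point estimate: the hallmark
        # of the case where a priori power was over-optimistic
        scenario, response, sp = cc1_study
        model = stepwise_select(scenario.design, response)
        assert residual_sd_ratio(model, sp) > 3.0
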