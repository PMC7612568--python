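"""Restriction blocks: hand-computed examples and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from cbmsm.design import eval_terms_at_risk
from cbmsm.exceptions import ConfigError, SpecTermError
from cbmsm.panel import PanelSchema, PersonPeriodTable
from cbmsm.process_models import (ProcessModelSpec, fit_binary_treatment_model,
                                  fit_continuous_treatment_model)
from cbmsm.restrictions import (assemble_system, build_censoring_restrictions,
                                build_continuous_restrictions,
                                build_normalization_restrictions,
                                build_treatment_restrictions)

BIN = PanelSchema(treatment_kind="binary", treatment="a",
                  covariates=("x",), baseline=(), outcome="y")


def toy_T1(a_vals, x_vals):
    rows = []
    for i, (a, x) in enumerate(zip(a_vals, x_vals)):
        rows.append(dict(id=i, visit=0, r=1, a=0, x=float(x), y=0.0))
        rows.append(dict(id=i, visit=1, r=1, a=float(a), x=float(x), y=0.0))
    return PersonPeriodTable(pd.DataFrame(rows), BIN, T=1)


class TestTreatmentBlock:
    def test_four_patient_hand_example(self):
        # A=(1,1,0,0), x=(1,-1,1,-1), e^=0.5, X~=(1, x)
        t = toy_T1((1, 1, 0, 0), (1, -1, 1, -1))
        spec = ProcessModelSpec("binary_logistic", ["1", "lag1:x"], ["1"])
        fit = fit_binary_treatment_model(t, spec)
        block = build_treatment_restrictions(t, fit)
        np.testing.assert_allclose(block.columns[:, 0], [0.5, 0.5, -0.5, -0.5], atol=1e-9)
        np.testing.assert_allclose(block.columns[:, 1], [0.5, -0.5, -0.5, 0.5], atol=1e-9)
        np.testing.assert_allclose(block.target, 0.0)
        # unit weights already satisfy this block
        np.testing.assert_allclose(block.columns.T @ np.ones(4), 0.0, atol=1e-9)

    def test_denominator_fit_scores_vanish_at_unit_weights(self):
        # with e^ from the (pooled, T=1) denominator MLE, columns sum to 0 at W=1
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        a = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(float)
        t = toy_T1(a, x)
        spec = ProcessModelSpec("binary_logistic", ["1", "lag1:x"], ["1"])
        fit = fit_binary_treatment_model(t, spec)
        block = build_treatment_restrictions(
            t, fit, e_override={"e_num": fit.fitted["e_den"]})
        np.testing.assert_allclose(block.columns.sum(axis=0), 0.0, atol=1e-6)

    def test_cumulative_residuals_single_patient(self):
        # 1 patient, T=2, A=(1,0), e^=(0.5,0.5): rows carry (0.5, 0.0)
        rows = [dict(id=0, visit=0, r=1, a=0, x=0.0, y=0.0),
                dict(id=0, visit=1, r=1, a=1, x=0.0, y=0.0),
                dict(id=0, visit=2, r=1, a=0, x=0.0, y=0.0)]
        t = PersonPeriodTable(pd.DataFrame(rows), BIN, T=2)
        spec = ProcessModelSpec("binary_logistic", ["1"], ["1"])
        fit = fit_binary_treatment_model(t, spec)
        block = build_treatment_restrictions(t, fit)
        np.testing.assert_allclose(block.columns[:, 0], [0.5, 0.0], atol=1e-8)

    def test_matches_brute_force_weighted_score(self, sim_ordinal_fits):
        """K'w equals the direct double sum over patients and visits."""
        f = sim_ordinal_fits
        t, treat = f["table"], f["treat"]
        block = build_treatment_restrictions(t, treat)
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 2.0, t.m)
        got = block.columns.T @ w

        s = t.schema
        a0w, a1w = t.wide(s.treatment0), t.wide(s.treatment1)
        e0w, e1w = treat.fitted["e0_num"], treat.fitted["e1_num"]
        from cbmsm.design import design_matrix
        X0 = design_matrix(t, treat.spec.den("stage0"))
        X1 = design_matrix(t, treat.spec.den("stage1"))
        ii, jj = t.uncensored_arrays()
        row_of = {(i, j): k for k, (i, j) in enumerate(zip(ii, jj))}
        expected = np.zeros(block.width)
        p0 = X0.shape[1]
        for k, (i, j) in enumerate(zip(ii, jj)):
            acc = np.zeros(block.width)
            for kk in range(1, j + 1):
                kr = row_of[(i, kk)]
                acc[:p0] += (a0w[i, kk] - e0w[i, kk]) * X0[kr]
                acc[p0:] += a0w[i, kk] * (a1w[i, kk] - e1w[i, kk]) * X1[kr]
            expected += w[k] * acc
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-8)


CONT = PanelSchema(treatment_kind="continuous", treatment="a",
                   covariates=("x",), baseline=(), outcome="y")


class TestContinuousBlock:
    def _toy(self, a_visit1):
        rows = [dict(id=0, visit=0, r=1, a=0, x=0.0, y=0.0),
                dict(id=0, visit=1, r=1, a=a_visit1, x=0.0, y=0.0)]
        t = PersonPeriodTable(pd.DataFrame(rows), CONT, T=1)
        spec = ProcessModelSpec("continuous_heteroscedastic",
                                {"mean": ["1"], "var": ["1"]},
                                {"mean": ["1"], "var": ["1"]})
        return t, spec

    def test_plug_in_single_row(self):
        # A=2, mu^=1, s2^=1, X~mu=(1), X~sigma=(1) -> row (1, 0)
        t, spec = self._toy(2.0)
        from cbmsm.process_models import FittedProcessModel
        fit = FittedProcessModel(spec)
        fit.fitted["mu_num"] = np.array([[np.nan, 1.0]])
        fit.fitted["s2_num"] = np.array([[np.nan, 1.0]])
        block = build_continuous_restrictions(t, fit, spec)
        np.testing.assert_allclose(block.columns, [[1.0, 0.0]])

    def test_zero_residuals(self):
        # A identically mu^: mean columns 0, variance column rows -j
        rows = []
        for j in range(3):
            rows.append(dict(id=0, visit=j, r=1, a=0.0 if j == 0 else 1.0,
                             x=0.0, y=0.0))
        t = PersonPeriodTable(pd.DataFrame(rows), CONT, T=2)
        spec = ProcessModelSpec("continuous_heteroscedastic",
                                {"mean": ["1"], "var": ["1"]},
                                {"mean": ["1"], "var": ["1"]})
        from cbmsm.process_models import FittedProcessModel
        fit = FittedProcessModel(spec)
        fit.fitted["mu_num"] = np.array([[np.nan, 1.0, 1.0]])
        fit.fitted["s2_num"] = np.array([[np.nan, 1.0, 1.0]])
        block = build_continuous_restrictions(t, fit, spec)
        np.testing.assert_allclose(block.columns[:, 0], 0.0)
        np.testing.assert_allclose(block.columns[:, 1], [-1.0, -2.0])

    def test_column_sums_clt_scale(self):
        # treatment independent of history: column sums / m are O(1/sqrt(n))
        rng = np.random.default_rng(2)
        n = 5000
        rows = []
        for i in range(n):
            rows.append(dict(id=i, visit=0, r=1, a=0, x=rng.standard_normal(), y=0.0))
            rows.append(dict(id=i, visit=1, r=1, a=rng.standard_normal(),
                             x=rng.standard_normal(), y=0.0))
        t = PersonPeriodTable(pd.DataFrame(rows), CONT, T=1)
        spec = ProcessModelSpec("continuous_heteroscedastic",
                                {"mean": ["1", "lag1:x"], "var": ["1"]},
                                {"mean": ["1"], "var": ["1"]})
        fit = fit_continuous_treatment_model(t, spec)
        block = build_continuous_restrictions(t, fit)
        sums = np.abs(block.columns.sum(axis=0)) / t.m
        assert np.all(sums < 3 / np.sqrt(t.m) * 2.0)  # var of score terms <= ~2


class TestNormalizationBlock:
    def test_targets_count_uncensored(self):
        rows = []
        for i in range(3):
            for j in range(3):
                r = 0 if (i == 0 and j == 2) else 1
                rows.append(dict(id=i, visit=j, r=r, a=0 if j == 0 else r,
                                 x=0.0 if r else np.nan, y=0.0 if r else np.nan))
        t = PersonPeriodTable(pd.DataFrame(rows), BIN, T=2)
        block = build_normalization_restrictions(t)
        np.testing.assert_allclose(block.target, [3, 2])
        # any satisfying weights have per-visit mean 1
        w = np.array([1.2, 0.9, 0.9, 0.7, 1.3])  # visits (1,2),(1,2),(1) order: by patient
        sums = block.columns.T @ w
        _, jj = t.uncensored_arrays()
        for col, j in enumerate((1, 2)):
            assert sums[col] == pytest.approx(w[jj == j].sum())


def eq12_direct(table, terms, w_rows):
    """Independent oracle: the un-telescoped censoring balance sums."""
    ii, jj = table.uncensored_arrays()
    n, T = table.n, table.T
    w_wide = np.zeros((n, T + 1))
    w_wide[:, 0] = 1.0
    w_wide[ii, jj] = w_rows
    R = table.R
    out = np.zeros(len(terms))
    for j in range(1, T + 1):
        at_risk = np.nonzero(R[:, j - 1] == 1)[0]
        H = np.zeros((n, len(terms)))
        H[at_risk] = eval_terms_at_risk(table, terms, j, at_risk)
        bracket = R[:, j] * w_wide[:, j] - R[:, j - 1] * w_wide[:, j - 1]
        out += (T - j + 1) * (bracket[:, None] * H).sum(axis=0)
    return out


class TestCensoringBlock:
    def test_T1_constant_term(self):
        t = toy_T1((1, 0, 1, 0), (0.3, -0.2, 0.1, 0.5))
        block = build_censoring_restrictions(t, ["1"])
        np.testing.assert_allclose(block.columns[:, 0], 1.0)
        assert block.target[0] == pytest.approx(4)  # n

    def test_telescoped_form_equals_direct_sums(self, sim_ordinal_fits):
        """(T-j+1)H_{j-1} - (T-j)H_j telescoping identity, random weights."""
        t = sim_ordinal_fits["table"]
        terms = ["1", "v", "lag1:x", "visit==2", "visit==2*v"]
        block = build_censoring_restrictions(t, terms)
        rng = np.random.default_rng(3)
        w = rng.uniform(0.2, 3.0, t.m)
        lhs = block.columns.T @ w - block.target
        np.testing.assert_allclose(lhs, eq12_direct(t, terms, w), rtol=1e-9, atol=1e-7)

    def test_term_undefined_at_baseline_rejected(self, sim_ordinal_fits):
        with pytest.raises(SpecTermError, match="undefined"):
            build_censoring_restrictions(sim_ordinal_fits["table"], ["1", "lag2:x"])


class TestAssemble:
    def test_widths_add(self, sim_ordinal_fits):
        f = sim_ordinal_fits
        assert f["system"].r == 8 + 3  # two 4-term stages + 3 censoring terms
        assert f["system"].m == f["table"].m

    def test_duplicate_labels_rejected(self, sim_ordinal_fits):
        b = build_censoring_restrictions(sim_ordinal_fits["table"], ["1", "v"])
        with pytest.raises(ConfigError, match="duplicated"):
            assemble_system([b, b])

    def test_normalization_with_censoring_rejected(self, sim_ordinal_fits):
        t = sim_ordinal_fits["table"]
        with pytest.raises(ConfigError, match="redundant"):
            assemble_system([build_censoring_restrictions(t, ["1"]),
                             build_normalization_restrictions(t)])

    def test_treatment_only_system_warns_about_trivial_zeros(self, sim_ordinal_fits):
        f = sim_ordinal_fits
        block = build_treatment_restrictions(f["table"], f["treat"])
        with pytest.warns(UserWarning, match="all-zero"):
            assemble_system([block])

    def test_standardization_preserves_solutions(self, sim_ordinal_fits):
        from cbmsm.calibrate import solve_type1
        f = sim_ordinal_fits
        blocks = [build_treatment_restrictions(f["table"], f["treat"]),
                  build_censoring_restrictions(f["table"], ["1", "lag1:x", "lag1:trt"])]
        plain = solve_type1(f["w0"], assemble_system(blocks))
        scaled = solve_type1(f["w0"], assemble_system(blocks, standardize=True))
        np.testing.assert_allclose(scaled.weights_star, plain.weights_star,
                                   rtol=1e-7, atol=1e-9)
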