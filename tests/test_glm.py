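"""GLM estimation, ROI summaries, winsorisation and behavioural statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfconn.glm import (
    contrast_estimate,
    fit_glm,
    greenhouse_geisser,
    paired_t,
    rm_anova,
    roi_eigenvariate,
    roi_mean_timecourse,
    winsorise,
)
from lfconn.task_design import Contrast, assemble_design


def _design(n_scans, rng, n_cond=3):
    regs = {f"stage_{i + 1}": rng.normal(size=n_scans) for i in range(n_cond)}
    return assemble_design(regs, rng.normal(size=(n_scans, 6)), 2.0, n_scans)


class TestFitGLM:
    def test_exact_recovery_without_noise(self, rng):
        X = _design(60, rng)
        b = rng.normal(size=len(X.columns))
        y = X.values @ b
        fit = fit_glm(y, X)
        assert np.allclose(fit.beta_vector(X.columns), b, atol=1e-10)

    def test_constant_only_design_estimates_the_mean(self):
        X = assemble_design({}, None, 2.0, 25)
        fit = fit_glm(np.full(25, 5.0), X)
        assert np.isclose(fit.betas["constant"], 5.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = _design(50, rng)
        y = rng.normal(size=50)
        fit = fit_glm(y, X)
        Xv = X.values
        oracle = np.linalg.solve(Xv.T @ Xv, Xv.T @ y)
        assert np.allclose(fit.beta_vector(X.columns), oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        X = _design(80, rng)
        fit = fit_glm(rng.normal(size=80), X)
        assert np.max(np.abs(X.values.T @ fit.residuals)) < 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        X = _design(40, rng, n_cond=1)
        X.frame["dup"] = X.frame["stage_1"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm(np.zeros(40), X)

    def test_nan_data_rejected(self, rng):
        X = _design(40, rng)
        y = np.zeros(40)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_glm(y, X)


class TestContrastEstimate:
    def test_zero_weights_give_zero(self, rng):
        X = _design(40, rng)
        fit = fit_glm(rng.normal(size=40), X)
        est, _ = contrast_estimate(fit, Contrast("null", np.zeros(3)))
        assert est == 0.0

    def test_task_contrast_sums_stage_betas(self, rng):
        X = _design(60, rng, n_cond=6)
        b = np.zeros(len(X.columns))
        b[:6] = 2.0
        y = X.values @ b
        fit = fit_glm(y, X)
        est, _ = contrast_estimate(fit, Contrast("task", np.ones(6)))
        assert np.isclose(est, 12.0)

    def test_t_statistic_matches_textbook_oracle(self, rng):
        X = _design(40, rng)
        y = rng.normal(size=40)
        fit = fit_glm(y, X)
        w_named = np.array([1.0, -1.0, 0.0])
        est, t = contrast_estimate(fit, Contrast("c", w_named))
        Xv = X.values
        beta = np.linalg.solve(Xv.T @ Xv, Xv.T @ y)
        r = y - Xv @ beta
        dof = 40 - Xv.shape[1]
        s2 = r @ r / dof
        w = np.zeros(Xv.shape[1])
        w[:3] = w_named
        t_oracle = (w @ beta) / np.sqrt(s2 * w @ np.linalg.inv(Xv.T @ Xv) @ w)
        assert np.isclose(t, t_oracle, atol=1e-10)

    def test_missing_column_rejected(self, rng):
        X = _design(40, rng, n_cond=2)
        fit = fit_glm(rng.normal(size=40), X)
        with pytest.raises(KeyError):
            contrast_estimate(fit, Contrast("c", np.ones(3)))


class TestROISummaries:
    def test_single_voxel_identity(self, rng):
        v = rng.normal(size=(50, 1))
        assert np.allclose(roi_mean_timecourse(v), v[:, 0])
        e = roi_eigenvariate(v)
        c = np.corrcoef(e, v[:, 0])[0, 1]
        assert c > 0.999

    def test_two_identical_voxels(self, rng):
        v = rng.normal(size=50)
        Y = np.column_stack([v, v])
        assert np.allclose(roi_mean_timecourse(Y), v)
        e = roi_eigenvariate(Y)
        assert np.corrcoef(e, v)[0, 1] > 0.999

    def test_eigenvariate_recovers_rank1_signal(self, rng):
        signal = np.sin(np.linspace(0, 8 * np.pi, 200))
        loadings = rng.uniform(0.5, 1.5, 10)
        Y = np.outer(signal, loadings) + rng.normal(0, 0.05, (200, 10))
        e = roi_eigenvariate(Y)
        assert np.corrcoef(e, signal)[0, 1] > 0.99

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            roi_mean_timecourse(np.zeros((10, 0)))
        with pytest.raises(ValueError):
            roi_eigenvariate(np.zeros((10, 0)))


class TestWinsorise:
    def test_all_equal_unchanged(self):
        v = np.full(6, 3.0)
        assert np.array_equal(winsorise(v), v)

    def test_outlier_replaced_by_boundary(self):
        # direct arithmetic oracle: with enough well-behaved values a single
        # extreme point exceeds mean + 2.5 SD and is clipped to that boundary
        v = np.concatenate([np.ones(30), [100.0]])
        w = winsorise(v)
        mu, sd = v.mean(), v.std(ddof=1)
        assert sd * 2.5 + mu < 100.0
        assert np.isclose(w[-1], mu + 2.5 * sd)
        assert np.array_equal(w[:-1], v[:-1])

    def test_small_sample_extreme_value_is_within_bound(self):
        # in n=5 the largest attainable z-score is (n-1)/sqrt(n) < 2.5, so
        # even a huge value is mathematically inside the winsorisation bound
        v = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        assert np.array_equal(winsorise(v), v)

    def test_no_outliers_unchanged(self, rng):
        v = rng.uniform(0, 1, 20)
        if np.all(np.abs(v - v.mean()) <= 2.5 * v.std(ddof=1)):
            assert np.array_equal(winsorise(v), v)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_never_increases_range(self, values):
        v = np.asarray(values)
        w = winsorise(v)
        assert w.max() <= v.max() + 1e-12
        assert w.min() >= v.min() - 1e-12

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            winsorise(np.array([1.0]))


class TestRepeatedMeasures:
    def test_identical_conditions_give_zero_F(self, rng):
        col = rng.normal(size=12)
        X = np.column_stack([col, col, col])
        F, _, _ = rm_anova(X)
        assert np.isclose(F, 0.0, atol=1e-20)

    def test_two_condition_F_equals_paired_t_squared(self, rng):
        a, b = rng.normal(size=(2, 15))
        F, (df1, df2), p_f = rm_anova(np.column_stack([a, b]))
        t, p_t = paired_t(a, b)
        assert np.isclose(F, t**2, atol=1e-10)
        assert (df1, df2) == (1, 14)
        assert np.isclose(p_f, p_t, atol=1e-12)

    def test_dof_structure(self, rng):
        X = rng.normal(size=(10, 4))
        _, (df1, df2), _ = rm_anova(X)
        assert (df1, df2) == (3, 27)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        X = rng.normal(size=(12, 5)) + np.linspace(0, 1, 5)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 5),
                "cond": np.tile(np.arange(5), 12),
                "y": X.ravel(),
            }
        )
        res = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        F, _, p = rm_anova(X)
        assert np.isclose(F, res["F"].iloc[0], rtol=1e-6)
        assert np.isclose(p, res["p_unc"].iloc[0], rtol=1e-6)

    def test_greenhouse_geisser_shrinks_dof(self, rng):
        # epsilon lies in [1/(k-1), 1]; with a real effect (F > 1) the
        # corrected p-value is never smaller than the uncorrected one
        X = rng.normal(size=(9, 4)) @ np.diag([1, 2, 3, 4.0]) + np.arange(4)
        F, _, p = rm_anova(X)
        Fg, (d1, d2), pg = greenhouse_geisser(X)
        assert np.isclose(F, Fg)
        assert 1.0 / 3 - 1e-12 <= d1 / 3 <= 1 + 1e-12
        if F > 1:
            assert pg >= p - 1e-12

    def test_missing_cells_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(X)

    def test_explicit_tail_argument(self, rng):
        a, b = rng.normal(size=(2, 12))
        t2, p2 = paired_t(a, b, tail="two-sided")
        tg, pg_ = paired_t(a, b, tail="greater")
        assert np.isclose(t2, tg)
        expected = p2 / 2 if t2 > 0 else 1 - p2 / 2
        assert np.isclose(pg_, expected, atol=1e-12)
        with pytest.raises(ValueError):
            paired_t(a, b, tail="one-sided")
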