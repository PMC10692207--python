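"""OLS engine, multiplicity adjustments, coefficient normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

import sleepsig as ss
from sleepsig.associations import (_multi_ols_phenotype_stats,
                                   adjust_bonferroni, adjust_fdr_bh,
                                   design_matrix, fit_ols, significant)
from sleepsig.errors import InvalidArgumentError, SingularDesignError


class TestFitOls:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"intercept": np.ones(10), "x": x})
        fit = fit_ols(2 * x + 1, X)
        assert fit.beta[1] == pytest.approx(2.0)
        assert np.allclose(fit.residuals, 0, atol=1e-12)

    def test_hand_computed_five_point_slope(self):
        # closed-form normal equations for x=1..5, y=[2,4,5,4,5] give 0.6
        x = np.arange(1.0, 6.0)
        y = np.array([2.0, 4.0, 5.0, 4.0, 5.0])
        X = pd.DataFrame({"intercept": np.ones(5), "x": x})
        assert fit_ols(y, X).beta[1] == pytest.approx(0.6)

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)),
                         columns=["a", "b", "c", "d"])
        X.insert(0, "intercept", 1.0)
        y = rng.normal(size=60)
        A = X.to_numpy()
        want = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(fit_ols(y, X).beta, want, atol=1e-8)

    def test_rank_deficiency_names_column(self, rng):
        a = rng.normal(size=30)
        X = pd.DataFrame({"intercept": np.ones(30), "a": a, "dup": a})
        with pytest.raises(SingularDesignError, match="dup"):
            fit_ols(rng.normal(size=30), X)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(1000):
            X = pd.DataFrame({"intercept": np.ones(50),
                              "x": rng.normal(size=50)})
            ps.append(fit_ols(rng.normal(size=50), X).p[1])
        assert sp_stats.kstest(ps, "uniform").pvalue > 0.01

    def test_vectorised_path_equals_single_fits(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        Y = rng.normal(size=(40, 6))
        b, se, t, p, _ = _multi_ols_phenotype_stats(Y, X, coef_index=1)
        for u in range(6):
            f = fit_ols(Y[:, u], X)
            assert b[u] == pytest.approx(f.beta[1], abs=1e-12)
            assert se[u] == pytest.approx(f.se[1], abs=1e-12)
            assert p[u] == pytest.approx(f.p[1], abs=1e-12)

    def test_planted_slope_ci_coverage(self):
        """95% t-intervals for a planted coupling cover it ~95% of the time."""
        rng = np.random.default_rng(9)
        covered = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=200)
            y = 0.3 * x + rng.normal(size=200)
            X = pd.DataFrame({"intercept": np.ones(200), "x": x})
            f = fit_ols(y, X)
            tcrit = sp_stats.t.ppf(0.975, f.df_resid)
            lo = f.beta[1] - tcrit * f.se[1]
            hi = f.beta[1] + tcrit * f.se[1]
            covered += lo <= 0.3 <= hi
        assert 0.90 <= covered / n_sim <= 0.99


def _bh_stepup_oracle(p):
    """Direct step-up definition, independent of the implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestAdjustments:
    def test_bh_textbook_example(self):
        got = adjust_fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_and_tied_inputs(self):
        assert adjust_fdr_bh([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(adjust_fdr_bh([0.3, 0.3, 0.3]), 0.3)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_matches_stepup_oracle(self, ps):
        got = adjust_fdr_bh(ps)
        assert np.allclose(got, _bh_stepup_oracle(ps), atol=1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(got[order]) >= -1e-12)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            adjust_fdr_bh([0.5, 1.2])

    def test_bonferroni_examples_and_loop_oracle(self, rng):
        assert adjust_bonferroni([0.01], 5)[0] == pytest.approx(0.05)
        assert adjust_bonferroni([0.5], 10)[0] == 1.0
        p = rng.uniform(size=30)
        got = adjust_bonferroni(p, 7)
        want = np.array([min(1.0, v * 7) for v in p])
        assert np.allclose(got, want)
        with pytest.raises(InvalidArgumentError):
            adjust_bonferroni([0.1], 0)


class TestMapAssociation:
    def test_beta_normalisation_and_floor(self, cohort200, rng):
        outcome = pd.DataFrame(
            {"u1": rng.normal(size=200), "u2": rng.normal(size=200)})
        acc = np.array([0.6, 1.0])
        m = ss.map_association(outcome, cohort200, "phq2", modality="task",
                               accuracy_by_unit=acc, n_samples=60)
        b = m.set_index("unit")
        assert b.loc["u1", "beta_normalized"] == pytest.approx(
            b.loc["u1", "beta"] / 0.4)
        # perfect accuracy hits the floor 1/120 and stays finite
        assert np.isfinite(b.loc["u2", "beta_normalized"])
        assert b.loc["u2", "beta_normalized"] == pytest.approx(
            b.loc["u2", "beta"] * 120)

    def test_zero_coupling_null_rate(self, atlas20):
        from sleepsig.synthetic import CouplingSpec
        c = CouplingSpec.null()
        t = ss.generate_phenotypes(300, c, seed=21)
        th = ss.generate_thickness(t, atlas20, c, seed=21)
        m = ss.map_association(th.drop(columns="subject_id"), t,
                               "sleep_bout_h", modality="anat")
        frac = float((m["p"] < 0.05).mean())
        lo, hi = sp_stats.binom.interval(0.99, 20, 0.05)
        assert lo / 20 <= frac <= hi / 20

    def test_significance_convention(self):
        df = pd.DataFrame({"p_adjusted": [0.009, 0.011, 0.5]})
        assert significant(df).tolist() == [True, False, False]

    def test_modality_covariate_sets_differ(self, cohort200):
        task = ss.modality_design(cohort200, "task", "phq2")
        rest = ss.modality_design(cohort200, "rest", "phq2")
        anat = ss.modality_design(cohort200, "anat", "phq2")
        assert "task_rt_mean" in task.columns
        assert "task_rt_mean" not in rest.columns
        assert "head_motion" in rest.columns
        assert "head_motion" not in anat.columns
        assert "sex:age" in task.columns
        sleep = ss.modality_design(cohort200, "task", "sleep_bout_h")
        assert "accel_time_offset" in sleep.columns
        assert "accel_time_offset" not in task.columns


def test_design_matrix_one_hot_drops_reference(cohort200):
    X = design_matrix(cohort200, numeric=("age",),
                      categorical=("site",))
    site_cols = [c for c in X.columns if c.startswith("site_")]
    assert len(site_cols) == cohort200["site"].nunique() - 1
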