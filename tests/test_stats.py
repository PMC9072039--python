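"""Covariate-adjusted group models, corrections, correlations, demographics."""

import numpy as np
import pytest
from scipy import integrate, stats as sps

import structconn as sc
from structconn.stats import SingularDesignError, design_matrix

from conftest import make_cohort


def phenos_balanced(n_per_group, rng):
    out = []
    for g in ("case", "control"):
        for i in range(n_per_group):
            out.append(
                sc.Phenotype(
                    f"{g}-{i}", g,
                    age=float(rng.uniform(11, 19)),
                    sex="M" if i % 2 == 0 else "F",
                    blind_duration=float(rng.uniform(100, 220)) if g == "case" else None,
                )
            )
    return out


class TestFitGroupModel:
    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        phenos = phenos_balanced(10, rng)
        y = rng.normal(size=20)
        ours = sc.fit_group_model(y, phenos)
        X = design_matrix(phenos)
        fit = sm.OLS(y, X).fit()
        assert ours.t == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert ours.p == pytest.approx(fit.pvalues[1], abs=1e-12)

    def test_null_case_t_near_zero(self, rng):
        phenos = phenos_balanced(30, rng)
        y = np.tile(rng.normal(size=30), 2)  # identical distribution per group
        res = sc.fit_group_model(y, phenos)
        assert abs(res.t) < 2.5

    def test_six_subject_hand_example(self):
        # y = group indicator exactly, ages balanced across groups, all male:
        # residuals vanish yet variance is estimated from dof; with zero
        # residual the group t diverges, so add one deviating observation
        # and solve the normal equations independently with numpy
        phenos = [
            sc.Phenotype("c1", "case", 12.0, "M", 100.0),
            sc.Phenotype("c2", "case", 14.0, "M", 100.0),
            sc.Phenotype("c3", "case", 16.0, "F", 100.0),
            sc.Phenotype("n1", "control", 12.0, "M"),
            sc.Phenotype("n2", "control", 14.0, "M"),
            sc.Phenotype("n3", "control", 16.0, "F"),
        ]
        y = np.array([1.0, 1.2, 1.0, 0.0, 0.0, 0.1])
        X = design_matrix(phenos)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 4)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        expected_t = beta[1] / se
        res = sc.fit_group_model(y, phenos)
        assert res.t == pytest.approx(expected_t, rel=1e-12)

    def test_collinear_design_raises(self):
        # constant age makes [intercept, age] collinear
        phenos = [
            sc.Phenotype(f"c{i}", "case", 15.0, "M", 100.0) for i in range(3)
        ] + [sc.Phenotype(f"n{i}", "control", 15.0, "M") for i in range(3)]
        with pytest.raises(SingularDesignError):
            sc.fit_group_model(np.arange(6.0), phenos)

    def test_reduces_to_two_sample_t_without_covariate_variation(self, rng):
        # when age and sex carry no information the group coefficient's t
        # equals the pooled two-sample t
        phenos = [
            sc.Phenotype(f"c{i}", "case", 15.0, "M", 100.0) for i in range(8)
        ] + [sc.Phenotype(f"n{i}", "control", 15.0, "M") for i in range(8)]
        y = rng.normal(size=16)
        # drop collinear columns: model with intercept + group only
        X = np.column_stack([np.ones(16), [1.0] * 8 + [0.0] * 8])
        from structconn.stats import _ols_group_t

        t_model, _ = _ols_group_t(X, y[:, None])
        t_pooled, _ = sc.two_sample_t(y[:8], y[8:])
        assert t_model[0] == pytest.approx(t_pooled, abs=1e-9)


class TestBonferroni:
    def test_family_of_ninety(self):
        mk = lambda p: sc.GroupComparisonResult("m", 0.0, p, 43)
        sig, not_sig = sc.bonferroni_correct(
            [mk(0.0004), mk(0.001)], alpha=0.05, family_size=90
        )
        assert sig.significant and sig.p_threshold == pytest.approx(0.05 / 90)
        assert not not_sig.significant

    def test_family_of_one_is_alpha(self):
        (res,) = sc.bonferroni_correct(
            [sc.GroupComparisonResult("m", 0.0, 0.04, 10)], family_size=1
        )
        assert res.significant and res.p_threshold == 0.05


class TestPartialCorrelation:
    def test_orthogonal_covariates_reduce_to_pearson(self, rng):
        n = 40
        x, y = rng.normal(size=n), rng.normal(size=n)
        x -= x.mean()
        y -= y.mean()
        z = np.ones((n, 1))  # intercept-only extra covariate: no-op
        res = sc.partial_correlation(x, y, None)
        plain = sps.pearsonr(x, y)
        assert res.r == pytest.approx(plain.statistic, abs=1e-12)

    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=25)
        res = sc.partial_correlation(x, x.copy(), rng.normal(size=(25, 2)))
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_p_matches_t_density_integration(self, rng):
        n, k = 21, 2
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        cov = rng.normal(size=(n, k))
        res = sc.partial_correlation(x, y, cov)
        assert res.df == n - 2 - k == 17
        t = res.r * np.sqrt(res.df / (1 - res.r**2))
        tail, _ = integrate.quad(lambda u: sps.t.pdf(u, res.df), abs(t), np.inf)
        assert res.p == pytest.approx(2 * tail, rel=1e-6)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 30
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
            }
        )
        df["y"] += 0.4 * df["x"] + 0.3 * df["a"]
        res = sc.partial_correlation(df["x"], df["y"], df[["a", "b"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_affine_invariance(self, rng):
        n = 24
        x, y = rng.normal(size=n), rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        r0 = sc.partial_correlation(x, y, cov).r
        r1 = sc.partial_correlation(3 * x - 7, -2 * y + 4, 5 * cov + 1).r
        assert abs(r1) == pytest.approx(abs(r0), abs=1e-10)
        assert r1 == pytest.approx(-r0, abs=1e-10)  # y sign flip flips r

    def test_zero_variance_rejected(self, rng):
        x = np.ones(20)
        with pytest.raises(ValueError, match="residual variance"):
            sc.partial_correlation(x, rng.normal(size=20), None)


class TestTwoSampleT:
    def test_identical_samples(self):
        assert sc.two_sample_t([1.0, 2, 3], [1.0, 2, 3]) == (0.0, 1.0)

    def test_closed_form_shifted_samples(self):
        # both samples have sd=1, means differ by 10, n=3 each:
        # t = -10 / (1 * sqrt(2/3))
        t, p = sc.two_sample_t([0.0, 1, 2], [10.0, 11, 12])
        assert t == pytest.approx(-10 / np.sqrt(2 / 3))
        assert p < 1e-3

    def test_swap_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=11)
        t1, p1 = sc.two_sample_t(a, b)
        t2, p2 = sc.two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_summary_statistics_input(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=14)
        direct = sc.two_sample_t(a, b)
        summary = sc.two_sample_t(
            (a.mean(), a.std(ddof=1), len(a)), (b.mean(), b.std(ddof=1), len(b))
        )
        assert direct == pytest.approx(summary)


class TestChiSquare:
    def test_study_sex_table(self):
        stat, p = sc.chi_square_2x2([[13, 8], [11, 11]])
        assert stat == pytest.approx(0.617, abs=1e-3)

    def test_perfect_independence(self):
        stat, _ = sc.chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0

    def test_perfect_association(self):
        stat, _ = sc.chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            sc.chi_square_2x2([[5, 0], [7, 0]])


class TestDescribe:
    def test_two_point_closed_form(self):
        mean, sd = sc.describe([0.0, 2.0])
        assert mean == 1.0 and sd == pytest.approx(np.sqrt(2))

    def test_constant_vector(self):
        assert sc.describe([4.0] * 5) == (4.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.describe([])


class TestNodalComparison:
    def test_row_count_and_annotation(self, rng):
        cohort = make_cohort(rng, n_nodes=12, n_case=6, n_control=6)
        Y = rng.normal(size=(12, 12))
        df = sc.run_nodal_comparison(cohort, Y, metric="Ne")
        assert len(df) == 12
        assert set(df["system"]) <= {"default-mode", "visual", "limbic", "other"}
        assert (df["p_threshold"] == 0.05 / 12).all()

    def test_nan_subjects_excluded_pairwise(self, rng):
        cohort = make_cohort(rng, n_nodes=6, n_case=6, n_control=6)
        Y = rng.normal(size=(12, 6))
        Y[3, 2] = np.nan
        df = sc.run_nodal_comparison(cohort, Y, metric="NLp")
        assert df.loc[2, "n_excluded"] == 1
        assert df.loc[2, "n_used"] == 11
        assert (df.loc[df.index != 2, "n_excluded"] == 0).all()
        # the nan-column fit must equal a clean fit on the reduced cohort
        keep = np.ones(12, dtype=bool)
        keep[3] = False
        from structconn.stats import _ols_group_t

        t_ref, _ = _ols_group_t(
            design_matrix([p for p, k in zip(cohort.phenotypes, keep) if k]),
            Y[keep, 2][:, None],
        )
        assert df.loc[2, "t"] == pytest.approx(t_ref[0])
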