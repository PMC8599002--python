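"""Statistical battery: correlation/regression oracles, proportional odds,
incremental R², cognitive factor, FDR and report round-trips."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import dnamproxy as dp
from dnamproxy.validate import ValidationError


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p, n = dp.pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_orthogonal_contrasts(self):
        r, _, _ = dp.pearson_test(
            np.array([1.0, -1.0, 1.0, -1.0]), np.array([1.0, 1.0, -1.0, -1.0])
        )
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_permutation_null(self):
        rng = np.random.default_rng(41)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p, _ = dp.pearson_test(x, y)
        perm_r = np.empty(10_000)
        yc = y - y.mean()
        xc = x - x.mean()
        for i in range(perm_r.size):
            perm = rng.permutation(20)
            perm_r[i] = abs(
                xc @ yc[perm] / np.sqrt((xc @ xc) * (yc @ yc))
            )
        p_perm = (1 + np.sum(perm_r >= abs(r))) / (1 + perm_r.size)
        assert abs(p - p_perm) < 0.02

    def test_pairwise_complete_and_constant_errors(self):
        x = pd.Series([1.0, np.nan, 2.0, 3.0])
        y = pd.Series([2.0, 5.0, 4.0, 6.0])
        _, _, n = dp.pearson_test(x, y)
        assert n == 3
        with pytest.raises(ValidationError, match="constant"):
            dp.pearson_test(np.ones(5), np.arange(5.0))


class TestLinearAssoc:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        n = 40
        x = rng.normal(size=n)
        c = rng.normal(size=(n, 2))
        y = 0.5 * x + c @ [0.3, -0.2] + rng.normal(size=n)
        res = dp.fit_linear_assoc(
            pd.Series(y), pd.Series(x),
            pd.DataFrame(c, columns=["c1", "c2"]), standardize=False,
        )
        X = np.column_stack([np.ones(n), x, c])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        assert res.estimate == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)

    def test_null_exposure_calibrated(self):
        rng = np.random.default_rng(43)
        n = 10_000
        res = dp.fit_linear_assoc(
            pd.Series(rng.normal(size=n)), pd.Series(rng.normal(size=n))
        )
        assert abs(res.estimate) < 3 * res.se

    def test_perfect_fit_is_error(self):
        x = pd.Series(np.arange(10.0))
        with pytest.raises(ValidationError, match="residual"):
            dp.fit_linear_assoc(x, x, standardize=False)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(44)
        a = rng.normal(size=30)
        with pytest.raises(ValidationError, match="dup"):
            dp.fit_linear_assoc(
                pd.Series(rng.normal(size=30)),
                pd.Series(a),
                pd.DataFrame({"dup": 2 * a}),
            )


def ordinal_loglik(codes, x, thresholds, slope):
    """Independent proportional-odds log-likelihood for the grid oracle."""
    eta = slope * x
    cum = np.concatenate([[-np.inf], thresholds, [np.inf]])

    def F(z):
        return 1.0 / (1.0 + np.exp(-z))

    ll = 0.0
    for yi, ei in zip(codes, eta):
        ll += np.log(F(cum[yi + 1] - ei) - F(cum[yi] - ei))
    return ll


class TestOrdinalAssoc:
    def test_two_level_outcome_collapses_to_logistic(self):
        rng = np.random.default_rng(45)
        n = 300
        x = rng.normal(size=n)
        pr = 1 / (1 + np.exp(-(0.8 * x - 0.3)))
        y = (rng.random(n) < pr).astype(int)
        res = dp.fit_ordinal_assoc(
            pd.Series(y), pd.Series(x), standardize=False
        )
        logit_res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert res.estimate == pytest.approx(logit_res.params[1], abs=1e-6)
        assert res.se == pytest.approx(logit_res.bse[1], abs=1e-5)

    def test_mle_beats_local_grid(self):
        rng = np.random.default_rng(46)
        n = 60
        x = rng.normal(size=n)
        latent = 0.7 * x + rng.logistic(size=n)
        codes = np.digitize(latent, [-0.5, 0.8])
        res = dp.fit_ordinal_assoc(
            pd.Series(codes), pd.Series(x), standardize=False
        )
        # recover fitted thresholds by refitting the statsmodels model
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        m = OrderedModel(
            pd.Series(pd.Categorical(codes, ordered=True)),
            pd.DataFrame({"x": x}),
            distr="logit",
        )
        fit = m.fit(method="bfgs", maxiter=1000, disp=False)
        theta = m.transform_threshold_params(fit.params)[1:-1]
        ll_hat = ordinal_loglik(codes, x, theta, res.estimate)
        for d_slope in (-0.01, 0.0, 0.01):
            for d0 in (-0.01, 0.0, 0.01):
                for d1 in (-0.01, 0.0, 0.01):
                    ll = ordinal_loglik(
                        codes, x,
                        np.array([theta[0] + d0, theta[1] + d1]),
                        res.estimate + d_slope,
                    )
                    assert ll <= ll_hat + 1e-9

    def test_null_exposure_calibrated(self):
        rng = np.random.default_rng(47)
        n = 10_000
        codes = rng.integers(0, 4, size=n)
        res = dp.fit_ordinal_assoc(
            pd.Series(codes), pd.Series(rng.normal(size=n))
        )
        assert abs(res.estimate) < 3 * res.se

    def test_empty_level_rejected(self):
        y = pd.Series(pd.Categorical([0, 0, 2, 2], categories=[0, 1, 2], ordered=True))
        with pytest.raises(ValidationError, match="zero count"):
            dp.fit_ordinal_assoc(y, pd.Series([1.0, 2.0, 3.0, 4.0]))


class TestIncrementalR2:
    def test_spanned_addition_changes_nothing(self):
        rng = np.random.default_rng(48)
        n = 50
        base = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        added = pd.DataFrame({"c": base["a"] * 2 - base["b"]})
        y = pd.Series(rng.normal(size=n))
        with pytest.raises(ValidationError):
            # adding a spanned column makes the full design rank-deficient
            dp.incremental_r2(y, base, added)

    def test_nonnegative_on_nested_fits(self):
        rng = np.random.default_rng(49)
        for _ in range(5):
            n = 40
            base = pd.DataFrame(rng.normal(size=(n, 2)))
            added = pd.DataFrame(rng.normal(size=(n, 3)))
            y = pd.Series(rng.normal(size=n))
            _, _, delta = dp.incremental_r2(y, base, added)
            assert delta >= -1e-12

    def test_orthogonal_predictor_equals_squared_semipartial(self):
        rng = np.random.default_rng(50)
        n = 200
        a = rng.normal(size=n)
        z = rng.normal(size=n)
        # orthogonalize z against [1, a]
        X = np.column_stack([np.ones(n), a])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        y = 0.5 * a + 0.3 * z + rng.normal(size=n)
        r2b, r2f, delta = dp.incremental_r2(
            pd.Series(y), pd.DataFrame({"a": a}), pd.DataFrame({"z": z})
        )
        semipartial = (z @ (y - y.mean())) ** 2 / ((z @ z) * ((y - y.mean()) @ (y - y.mean())))
        assert delta == pytest.approx(semipartial, abs=1e-10)

    def test_invariant_to_base_reparameterization(self):
        rng = np.random.default_rng(51)
        n = 60
        base = rng.normal(size=(n, 3))
        added = rng.normal(size=(n, 2))
        y = pd.Series(rng.normal(size=n))
        T = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
        a = dp.incremental_r2(y, pd.DataFrame(base), pd.DataFrame(added))
        b = dp.incremental_r2(y, pd.DataFrame(base @ T), pd.DataFrame(added))
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestInteractionTrend:
    def test_recovers_simulated_slope_difference(self):
        rng = np.random.default_rng(52)
        n = 5000
        age = rng.uniform(30, 75, size=n)
        sex = rng.binomial(1, 0.5, size=n)
        slope = np.where(sex == 1, 0.036, 0.02)
        y = slope * age + rng.normal(0, 0.5, size=n)
        res = dp.fit_interaction_trend(pd.Series(y), pd.Series(age), pd.Series(sex))
        assert abs(res.estimate - 0.016) < 3 * res.se

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(53)
        n = 5000
        age = rng.uniform(30, 75, size=n)
        sex = rng.binomial(1, 0.5, size=n)
        y = 0.02 * age + 0.3 * sex + rng.normal(0, 0.5, size=n)
        res = dp.fit_interaction_trend(pd.Series(y), pd.Series(age), pd.Series(sex))
        assert abs(res.estimate) < 3 * res.se

    def test_constant_sex_rejected(self):
        rng = np.random.default_rng(54)
        with pytest.raises(ValidationError):
            dp.fit_interaction_trend(
                pd.Series(rng.normal(size=30)),
                pd.Series(rng.uniform(30, 75, 30)),
                pd.Series(np.ones(30)),
            )


class TestCognitiveFactor:
    def test_identical_columns_explain_everything(self):
        rng = np.random.default_rng(55)
        col = rng.normal(size=100)
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        scores, loadings, varexp = dp.general_cognitive_factor(df)
        assert varexp == pytest.approx(1.0)
        np.testing.assert_allclose(loadings, loadings.iloc[0], atol=1e-12)
        assert scores.std(ddof=1) == pytest.approx(1.0)

    def test_uncorrelated_columns_isotropy_limit(self):
        rng = np.random.default_rng(56)
        df = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
        _, _, varexp = dp.general_cognitive_factor(df)
        assert abs(varexp - 1 / 3) < 0.02

    def test_loadings_match_eigendecomposition_oracle(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 0.8], [3.0, 5.0, 0.1], [4.0, 3.0, 0.9]],
            columns=list("abc"),
        )
        _, loadings, varexp = dp.general_cognitive_factor(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        evals, evecs = np.linalg.eigh(np.corrcoef(Z.to_numpy(), rowvar=False))
        v = evecs[:, -1]
        if (v < 0).sum() > (v > 0).sum() or ((v < 0).sum() == (v > 0).sum() and v.sum() < 0):
            v = -v
        np.testing.assert_allclose(loadings.to_numpy(), v, atol=1e-10)
        assert varexp == pytest.approx(evals[-1] / 3, abs=1e-12)

    def test_fewer_than_three_columns_rejected(self):
        with pytest.raises(ValidationError):
            dp.general_cognitive_factor(pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}))


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min over j ≥ i of m·p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[order[i]] = min(1.0, min(m * sorted_p[j] / (j + 1) for j in range(i, m)))
    return q


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            dp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged_and_equal_ps_fixed_point(self):
        np.testing.assert_allclose(dp.bh_adjust([0.37]), [0.37])
        np.testing.assert_allclose(dp.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(57)
        for _ in range(200):
            p = rng.random(rng.integers(1, 25))
            np.testing.assert_allclose(dp.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_bounded_by_bonferroni_and_monotone(self):
        rng = np.random.default_rng(58)
        p = rng.random(50)
        q = dp.bh_adjust(p)
        assert np.all(q <= np.minimum(1.0, p * 50) + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dp.bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def signal_report(small_cohort):
    cohort = small_cohort
    truth = cohort.truth
    cells = dp.estimate_proportions(cohort.beta, truth.reference_used)
    causal_w = dp.ProbeWeights(
        weights=pd.Series(truth.causal_effects, index=list(truth.causal_probe_ids))
    )
    smoking_w = dp.ProbeWeights(
        weights=pd.Series(truth.smoking_effects, index=list(truth.smoking_probe_ids))
    )
    episcore = dp.project_score(cohort.beta, causal_w)
    smk_score = dp.project_score(cohort.beta, smoking_w)
    report = dp.run_battery(
        cohort.phenotypes, episcore, cells, smk_score, dp.BatteryConfig()
    )
    return cohort, report


class TestBattery:
    def test_signal_cohort_recovers_directions(self, signal_report):
        cohort, report = signal_report
        # the causal-probe score tracks the latent trait, which the serum
        # readout shares: their correlation must be significant and positive
        corr = report.correlations[0]
        assert corr["x"] == "log_serum" and corr["y"] == "episcore"
        assert corr["r"] > 0.3
        assert corr["p_fdr"] < 0.05
        # bmi was simulated with positive loading on the latent trait
        bmi = [
            a for a in report.associations
            if a.outcome == "bmi" and a.exposure == "episcore"
        ][0]
        assert bmi.estimate > 0
        assert bmi.p_fdr < 0.05

    def test_incremental_r2_block_consistency(self, signal_report):
        _, report = signal_report
        for block in report.incremental:
            assert block["delta_r2"] == pytest.approx(
                block["r2_full"] - block["r2_base"], abs=1e-12
            )
            assert block["delta_r2"] >= -1e-12

    def test_correlation_block_r2_identity(self, signal_report):
        _, report = signal_report
        for c in report.correlations:
            assert c["r2"] == pytest.approx(c["r"] ** 2, abs=1e-12)

    def test_report_round_trips_through_json(self, signal_report):
        _, report = signal_report
        back = dp.ValidationReport.from_json(report.to_json())
        assert back.to_json() == report.to_json()

    def test_missing_columns_listed(self, small_cohort):
        ph = small_cohort.phenotypes.drop(columns=["bmi"])
        with pytest.raises(ValidationError, match="bmi"):
            dp.run_battery(
                ph,
                pd.Series(0.0, index=ph.index),
                None,
                None,
                dp.BatteryConfig(),
            )
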