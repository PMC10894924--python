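import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimnet import differential
from stimnet.io_formats import (BINARY_COVARIATES, CONTINUOUS_COVARIATES,
                                ClinicalTable)

from conftest import make_response


def bh_oracle(p):
    """Textbook step-up: sort, multiply by n/rank, cumulative minimum, cap."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _clin(n, dbp=None, seed=0):
    rng = np.random.default_rng(seed)
    data = {c: rng.integers(0, 2, n).astype(float) for c in BINARY_COVARIATES}
    data.update({c: rng.uniform(1, 100, n) for c in CONTINUOUS_COVARIATES})
    if dbp is not None:
        data["dbp"] = np.asarray(dbp, dtype=float)
    return ClinicalTable(pd.DataFrame(data, index=[f"P{i:03d}" for i in range(n)]))


class TestModeratedDe:
    def test_equal_variances_pool_to_ordinary_t(self, rng):
        """Homogeneous variances: prior df -> inf, but the moderated t still
        equals the ordinary t because the pooled variance matches each gene's."""
        X = rng.standard_normal((500, 38))
        X /= X.std(axis=1, ddof=1, keepdims=True)  # identical sample variances
        de = differential.moderated_de(make_response(X))
        t_ref = stats.ttest_1samp(X, 0, axis=1).statistic
        np.testing.assert_allclose(de.table["t"], t_ref, atol=1e-6)

    def test_zero_prior_df_recovers_ordinary_t_exactly(self, rng):
        X = rng.standard_normal((200, 20)) * rng.uniform(0.5, 3, (200, 1))
        de = differential.moderated_de(make_response(X), prior_df=0)
        ref = stats.ttest_1samp(X, 0, axis=1)
        np.testing.assert_allclose(de.table["t"], ref.statistic, atol=1e-12)
        np.testing.assert_allclose(de.table["p"], ref.pvalue, atol=1e-12)

    def test_type_one_error_calibrated_on_null(self):
        rates = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            X = rng.standard_normal((2000, 38)) * rng.uniform(0.5, 2, (2000, 1))
            de = differential.moderated_de(make_response(X))
            rates.append((de.table["p"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_zero_variance_gene_handled_by_shrinkage(self, rng):
        X = rng.standard_normal((50, 10))
        X[0] = 1.0  # constant nonzero response
        de = differential.moderated_de(make_response(X))
        assert np.isfinite(de.table["t"]).all()
        assert de.table["p"].iloc[0] < 0.01  # strong shrunk evidence

    def test_flags_respect_thresholds(self, rng):
        X = rng.standard_normal((300, 38)) * 0.3
        X[:10] += 3.0
        de = differential.moderated_de(make_response(X))
        t = de.table
        assert set(t.index[t["significant"]]) == set(
            t.index[(t["mean_log2fc"].abs() > 1) & (t["padj"] < 0.01)])
        assert (t["padj"] >= t["p"] - 1e-12).all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            differential.moderated_de(make_response(np.ones((5, 2))))


class TestAdjustFdr:
    def test_worked_example_step_up(self):
        np.testing.assert_allclose(
            differential.adjust_fdr([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert differential.adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            np.testing.assert_allclose(differential.adjust_fdr(p), bh_oracle(p),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            differential.adjust_fdr([0.5, 1.2])


class TestTraitCorrelation:
    def test_perfect_correlation_with_dbp(self):
        n = 20
        dbp = np.linspace(60, 100, n)
        clin = _clin(n, dbp=dbp)
        feats = pd.DataFrame([dbp], index=["f"], columns=clin.patient_ids)
        out = differential.trait_correlation(feats, clin, covariates=["dbp"])
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-9)
        assert row["p"] < 1e-10

    def test_closed_form_p_for_r_minus_04_n_38(self):
        """r = -0.4 at n = 38: t = -2.618, two-sided p ~ 0.0128."""
        r, n = -0.4, 38
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert t == pytest.approx(-2.618, abs=1e-3)
        assert p == pytest.approx(0.0128, abs=5e-4)
        # and the implementation reproduces it on constructed data
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            r_emp = np.corrcoef(x, y)[0, 1]
            clin = _clin(n, dbp=60 + 10 * (y - y.min() + 0.1))
            feats = pd.DataFrame([x], index=["f"], columns=clin.patient_ids)
            out = differential.trait_correlation(feats, clin, covariates=["dbp"])
            t_exp = r_emp * np.sqrt(n - 2) / np.sqrt(1 - r_emp ** 2)
            assert out.iloc[0]["t"] == pytest.approx(t_exp, abs=1e-9)

    def test_permuted_covariate_p_uniform(self):
        rng = np.random.default_rng(3)
        n = 40
        clin = _clin(n, dbp=rng.permutation(np.linspace(60, 100, n)))
        feats = pd.DataFrame(rng.standard_normal((300, n)),
                             index=[f"f{i}" for i in range(300)],
                             columns=clin.patient_ids)
        out = differential.trait_correlation(feats, clin, covariates=["dbp"])
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_constant_feature_reported_missing(self):
        clin = _clin(10)
        feats = pd.DataFrame([np.ones(10)], index=["f"], columns=clin.patient_ids)
        out = differential.trait_correlation(feats, clin, covariates=["dbp"])
        assert np.isnan(out.iloc[0]["r"])

    def test_pairwise_complete_n_reported(self):
        clin = _clin(10)
        clin.data.loc[clin.patient_ids[0], "dbp"] = np.nan
        rng = np.random.default_rng(1)
        feats = pd.DataFrame([rng.standard_normal(10)], index=["f"],
                             columns=clin.patient_ids)
        out = differential.trait_correlation(feats, clin, covariates=["dbp"])
        assert out.iloc[0]["n"] == 9


class TestCovariateRegression:
    def test_planted_target_effect_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            clin = _clin(n, seed=seed)
            y = 2.0 * clin.covariate("dbp") + rng.standard_normal(n) * 5
            resp = pd.DataFrame([y.to_numpy()], index=["m"],
                                columns=clin.patient_ids)
            out = differential.covariate_regression(
                resp, clin, "dbp", ["glucose", "hdl"])
            dbp_p = out[out["term"] == "dbp"]["p"].iloc[0]
            glu_p = out[out["term"] == "glucose"]["p"].iloc[0]
            hits += (dbp_p < 0.05) and (glu_p > 0.05)
        assert hits >= 18  # >= 90% of seeds

    def test_exact_recovery_without_noise(self):
        clin = _clin(30)
        y = 3.0 * clin.covariate("dbp") - 0.5 * clin.covariate("hdl") + 1.0
        resp = pd.DataFrame([y.to_numpy()], index=["m"], columns=clin.patient_ids)
        out = differential.covariate_regression(resp, clin, "dbp", ["hdl"])
        coef = out.set_index("term")["coef"]
        assert coef["dbp"] == pytest.approx(3.0, abs=1e-8)
        assert coef["hdl"] == pytest.approx(-0.5, abs=1e-8)

    def test_collinear_design_named(self):
        clin = _clin(30)
        clin.data["sbp"] = clin.data["dbp"]  # duplicate column content
        resp = pd.DataFrame([np.arange(30.0)], index=["m"],
                            columns=clin.patient_ids)
        with pytest.raises(ValueError, match="collinear"):
            differential.covariate_regression(resp, clin, "dbp", ["sbp"])


class TestGroupComparison:
    def _setup(self, damp=0.3, seed=0, n=38):
        rng = np.random.default_rng(seed)
        dbp = np.concatenate([rng.uniform(60, 79, n // 2),
                              rng.uniform(80, 110, n - n // 2)])
        clin = _clin(n, dbp=dbp)
        X = np.zeros((100, n))
        X[:50] = -2.0 + 0.2 * rng.standard_normal((50, n))   # down genes
        X[50:] = 2.0 + 0.2 * rng.standard_normal((50, n))
        high = dbp >= 80
        X[:50, high] *= damp  # dampened downregulation in the high group
        X[50:, high] *= damp
        resp = make_response(X)
        de = differential.moderated_de(resp)
        return resp, de, clin

    def test_dampened_down_response_detected_directionally(self):
        resp, de, clin = self._setup()
        out = differential.group_response_comparison(resp, de, clin, "dbp", 80.0)
        down = out["down"]
        assert down["median_high"] > down["median_low"]  # closer to zero
        assert down["p"] < 0.01
        assert out["n_high"] + out["n_low"] == 38

    def test_cutoff_splits_by_ge_rule(self):
        resp, de, clin = self._setup()
        out = differential.group_response_comparison(resp, de, clin, "dbp", 80.0)
        dbp = clin.covariate("dbp")
        assert out["n_high"] == int((dbp >= 80).sum())

    def test_null_groups_not_significant_usually(self):
        ps = []
        for seed in range(10):
            resp, de, clin = self._setup(damp=1.0, seed=seed)
            out = differential.group_response_comparison(resp, de, clin, "dbp", 80.0)
            ps.append(out["down"]["p"])
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_small_group_rejected(self):
        resp, de, clin = self._setup()
        with pytest.raises(ValueError, match="3 patients"):
            differential.group_response_comparison(resp, de, clin, "dbp", 200.0)

    def test_empty_significant_set_rejected(self, rng):
        X = rng.standard_normal((50, 20)) * 0.1
        resp = make_response(X)
        de = differential.moderated_de(resp)
        clin = _clin(20, dbp=np.linspace(60, 100, 20))
        with pytest.raises(ValueError, match="significant"):
            differential.group_response_comparison(resp, de, clin, "dbp", 80.0)
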