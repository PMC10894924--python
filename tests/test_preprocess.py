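import numpy as np
import pandas as pd
import pytest

from stimnet import preprocess
from stimnet.io_formats import ExpressionMatrix
from stimnet.preprocess import PipelineError, ResponseMatrix

from conftest import make_response


def _expr(values, samples=None, genes=None):
    n_g, n_s = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = samples or [f"P{j}_baseline" for j in range(n_s)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    cond = {s: s.rsplit("_", 1)[1] for s in samples}
    pat = {s: s.rsplit("_", 1)[0] for s in samples}
    return ExpressionMatrix(df, cond, pat)


class TestDetectionFilter:
    def test_threshold_is_strictly_below_min_detected(self):
        """A sample at 8,999 detectable genes drops; exactly 9,000 stays."""
        n_genes = 10_000
        controls = np.full(500, 5.0)  # 95th percentile = 5.0
        vals = np.full((n_genes, 2), 12.0)
        vals[:1001, 0] = 4.0   # sample 0: 8,999 detectable
        vals[:1000, 1] = 4.0   # sample 1: 9,000 detectable
        expr = _expr(vals)
        kept, report = preprocess.filter_samples_by_detection(
            expr, controls, min_detected=9000)
        assert kept.sample_ids == ["P1_baseline"]
        assert report.dropped_samples[0]["reason"] == "low_detection"
        assert report.dropped_samples[0]["detected"] == 8999

    def test_all_detectable_when_controls_low(self):
        expr = _expr(np.full((20, 3), 12.0))
        kept, report = preprocess.filter_samples_by_detection(
            expr, np.full(100, 5.0), min_detected=20)
        assert kept.sample_ids == expr.sample_ids
        assert not report.dropped_samples

    def test_all_samples_dropped_raises(self):
        expr = _expr(np.full((10, 2), 4.0))
        with pytest.raises(PipelineError):
            preprocess.filter_samples_by_detection(expr, np.full(50, 5.0),
                                                   min_detected=5)


class TestGeneFilters:
    def _paired(self, vals):
        n_g = vals.shape[0]
        samples = ["A_baseline", "A_stimulated", "B_baseline", "B_stimulated"]
        return _expr(vals, samples=samples)

    def test_borderline_gene_removed_only_if_low_everywhere(self):
        vals = np.array([
            [7.4, 7.4, 7.2, 7.0],    # below 7.5 in all samples -> removed
            [7.6, 7.0, 7.0, 7.0],    # 7.6 once -> retained by intensity filter
            [12.0, 14.0, 12.0, 14.5],
        ])
        expr = self._paired(vals)
        kept, report = preprocess.filter_genes(expr, min_log2=7.5, min_sd=0.0)
        assert "g0" not in kept.gene_ids and "g1" in kept.gene_ids
        assert report.dropped_genes["borderline_intensity"] == 1

    def test_constant_response_gene_removed_by_sd_filter(self):
        vals = np.array([
            [10.0, 11.0, 10.0, 11.0],   # log2FC constant 1 -> SD 0 -> removed
            [10.0, 14.0, 10.0, 8.0],    # responsive
        ])
        kept, report = preprocess.filter_genes(self._paired(vals), min_sd=0.5)
        assert kept.gene_ids == ["g1"]
        assert report.dropped_genes["low_variance"] == 1

    def test_sd_computed_on_response_scale_when_paired(self):
        # g0: intensities vary a lot but responses are constant -> removed
        vals = np.array([[8.0, 9.0, 14.0, 15.0],
                         [10.0, 14.0, 10.0, 8.0]])
        kept, report = preprocess.filter_genes(self._paired(vals), min_sd=0.5)
        assert kept.gene_ids == ["g1"]
        assert report.dropped_genes["low_variance"] == 1

    def test_filters_idempotent(self, small_cohort):
        baseline, stimulated, _, _ = small_cohort
        from stimnet.pipeline import _concat

        both = _concat(baseline, stimulated)
        once, _ = preprocess.filter_genes(both)
        twice, rep = preprocess.filter_genes(once)
        assert twice.gene_ids == once.gene_ids
        assert rep.dropped_genes["borderline_intensity"] == 0
        assert rep.dropped_genes["low_variance"] == 0


class TestBuildResponseMatrix:
    def test_identical_conditions_give_exact_zero(self, small_cohort):
        baseline, _, _, _ = small_cohort
        stim_clone = ExpressionMatrix(
            baseline.values.copy().rename(
                columns=lambda s: s.replace("baseline", "stimulated")),
            {s.replace("baseline", "stimulated"): "stimulated"
             for s in baseline.sample_ids},
            {s.replace("baseline", "stimulated"): baseline.patient_id[s]
             for s in baseline.sample_ids},
        )
        resp, _ = preprocess.build_response_matrix(baseline, stim_clone)
        assert (resp.log2fc.to_numpy() == 0).all()

    def test_only_shared_patients_kept_and_unpaired_logged(self):
        base = _expr(np.ones((5, 3)), samples=["A_baseline", "B_baseline", "C_baseline"])
        stim = _expr(np.ones((5, 2)) * 2,
                     samples=["B_stimulated", "D_stimulated"])
        resp, report = preprocess.build_response_matrix(base, stim)
        assert resp.patient_ids == ["B"]
        unpaired = {d["patient"] for d in report.dropped_samples}
        assert unpaired == {"A", "C", "D"}

    def test_gene_set_mismatch_lists_difference(self):
        base = _expr(np.ones((3, 1)), samples=["A_baseline"])
        stim = _expr(np.ones((3, 1)), samples=["A_stimulated"],
                     genes=["g0", "g1", "gX"])
        with pytest.raises(ValueError, match="gX"):
            preprocess.build_response_matrix(base, stim)


class TestDetectOutliers:
    def test_shifted_patient_flagged(self, rng):
        X = rng.standard_normal((200, 12))
        X[:, 0] += 10.0
        resp = make_response(X)
        kept, report = preprocess.detect_outliers(resp, k=3)
        assert report.outlier_patients == ["P000"]
        assert "P000" not in kept.patient_ids

    def test_homogeneous_cohort_rarely_flags(self):
        flagged = 0
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((200, 30))
            _, report = preprocess.detect_outliers(make_response(X), k=3)
            flagged += bool(report.outlier_patients)
        assert flagged <= 1  # <= 5% of null cohorts

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            preprocess.detect_outliers(make_response(np.ones((5, 3))), k=3)

    def test_mass_flagging_warns_and_keeps(self, rng):
        X = rng.standard_normal((50, 8))
        X[:, :4] += 8.0  # half the cohort "outlying"
        with pytest.warns(UserWarning, match="not removing"):
            kept, _ = preprocess.detect_outliers(make_response(X), k=0.5)
        assert kept.log2fc.shape[1] == 8


class TestPcaTopExpressed:
    def _cohort_expr(self, rng, n_genes=200, n_pat=10, shift=0.0):
        samples = ([f"P{i}_baseline" for i in range(n_pat)]
                   + [f"P{i}_stimulated" for i in range(n_pat)])
        vals = rng.standard_normal((n_genes, 2 * n_pat)) + 10
        vals[:, n_pat:] += shift
        return _expr(vals, samples=samples)

    def _clin(self, n_pat):
        from stimnet.io_formats import (BINARY_COVARIATES, CONTINUOUS_COVARIATES,
                                        ClinicalTable)

        rng = np.random.default_rng(0)
        data = {c: rng.integers(0, 2, n_pat).astype(float) for c in BINARY_COVARIATES}
        data.update({c: rng.uniform(50, 100, n_pat) for c in CONTINUOUS_COVARIATES})
        return ClinicalTable(pd.DataFrame(data, index=[f"P{i}" for i in range(n_pat)]))

    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.linspace(-1, 1, 8)
        v = np.linspace(1, 2, 50)
        expr = _expr(np.outer(v, u) + 10,
                     samples=[f"P{i}_baseline" for i in range(8)])
        out = preprocess.pca_top_expressed(expr, self._clin(8), top_fraction=1.0)
        assert out["variance_fractions"][0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sorted_and_bounded(self, rng):
        expr = self._cohort_expr(rng)
        out = preprocess.pca_top_expressed(expr, self._clin(10))
        vf = out["all_variance_fractions"]
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1 + 1e-9

    def test_condition_independent_data_shows_no_separation(self, rng):
        expr = self._cohort_expr(rng, shift=0.0)
        out = preprocess.pca_top_expressed(expr, self._clin(10))
        cor = out["pc_trait_correlation"]
        pc_cond = cor[(cor["covariate"] == "condition")]
        assert (pc_cond["padj"].dropna() > 0.16).all()

    def test_too_few_samples_rejected(self, rng):
        expr = _expr(rng.standard_normal((30, 2)) + 10,
                     samples=["A_baseline", "A_stimulated"])
        with pytest.raises(ValueError):
            preprocess.pca_top_expressed(expr, self._clin(2))
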