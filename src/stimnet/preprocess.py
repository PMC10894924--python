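"""Quality control, pairing, response-matrix construction, and cohort PCA.

The pipeline starts from normalized log2 expression. QC proceeds in the
study's order: drop samples with too few detectable genes (detection call =
exceeding the 95th percentile of negative-control intensities), drop
borderline/low-variance genes, pair baseline with stimulated samples per
patient into a log2 fold-change response matrix, and flag outlying patients
by their mean Euclidean distance in response space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist, squareform

from .io_formats import ClinicalTable, ExpressionMatrix

__all__ = [
    "ResponseMatrix",
    "QcReport",
    "PipelineError",
    "filter_samples_by_detection",
    "filter_genes",
    "build_response_matrix",
    "detect_outliers",
    "pca_top_expressed",
]


class PipelineError(RuntimeError):
    """A QC step left nothing to analyze (thresholds need review)."""


@dataclass
class ResponseMatrix:
    """Genes × patients log2 fold-change (stimulated − baseline)."""

    log2fc: pd.DataFrame  # genes × patients

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc.to_numpy(dtype=float)).all():
            raise ValueError("log2fc must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.log2fc.columns)


@dataclass
class QcReport:
    """What each filter removed and why."""

    dropped_samples: list[dict] = field(default_factory=list)
    dropped_genes: dict[str, int] = field(default_factory=dict)
    outlier_patients: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_samples": self.dropped_samples,
            "dropped_genes": self.dropped_genes,
            "outlier_patients": self.outlier_patients,
            "thresholds": self.thresholds,
            "notes": self.notes,
        }


def filter_samples_by_detection(
    expr: ExpressionMatrix,
    neg_control,
    min_detected: int = 9000,
    alpha: float = 0.05,
) -> tuple[ExpressionMatrix, QcReport]:
    """Drop samples whose detectable-gene count falls below ``min_detected``.

    A gene is detectable in a sample when its intensity exceeds the
    (1 − alpha) quantile of the negative-control distribution.
    """
    controls = np.asarray(neg_control, dtype=float).ravel()
    threshold = float(np.quantile(controls, 1 - alpha))
    detected = (expr.values.to_numpy() > threshold).sum(axis=0)
    report = QcReport(thresholds={"detection_intensity": threshold,
                                  "min_detected": float(min_detected)})
    keep = []
    for s, count in zip(expr.sample_ids, detected):
        if count < min_detected:
            report.dropped_samples.append(
                {"sample": s, "reason": "low_detection", "detected": int(count)}
            )
        else:
            keep.append(s)
    if not keep:
        raise PipelineError(
            "all samples dropped by the detection filter; review min_detected "
            f"({min_detected}) and the control distribution"
        )
    return expr.subset_samples(keep), report


def filter_genes(
    expr: ExpressionMatrix,
    min_log2: float = 7.5,
    min_sd: float = 0.5,
) -> tuple[ExpressionMatrix, QcReport]:
    """Remove borderline-intensity genes, then low-variance genes.

    The intensity filter removes genes below ``min_log2`` in *every* sample.
    The variance filter removes genes whose SD across samples is below
    ``min_sd``; when both conditions are paired, the SD is computed on the
    per-patient log2 fold-change (the response scale), otherwise on
    intensities.
    """
    report = QcReport(thresholds={"min_log2": min_log2, "min_sd": min_sd})
    vals = expr.values
    keep_intensity = (vals >= min_log2).any(axis=1)
    report.dropped_genes["borderline_intensity"] = int((~keep_intensity).sum())
    vals = vals.loc[keep_intensity]

    paired = _paired_patients(expr)
    if paired:
        base = {p: s for s, p in expr.patient_id.items() if expr.condition[s] == "baseline"}
        stim = {p: s for s, p in expr.patient_id.items() if expr.condition[s] == "stimulated"}
        fc = pd.DataFrame(
            {p: vals[stim[p]] - vals[base[p]] for p in paired}, index=vals.index
        )
        sds = fc.std(axis=1, ddof=1)
        report.notes.append("variance filter computed on paired log2 fold-changes")
    else:
        sds = vals.std(axis=1, ddof=1)
        report.notes.append("variance filter computed on intensities (no pairing)")
    keep_var = sds >= min_sd
    report.dropped_genes["low_variance"] = int((~keep_var).sum())
    vals = vals.loc[keep_var]
    if vals.empty:
        raise PipelineError("no genes survive the intensity/variance filters")
    return expr.subset_genes(vals.index), report


def _paired_patients(expr: ExpressionMatrix) -> list[str]:
    base = {expr.patient_id[s] for s in expr.samples_for("baseline")}
    stim = {expr.patient_id[s] for s in expr.samples_for("stimulated")}
    order = []
    for s in expr.sample_ids:
        p = expr.patient_id[s]
        if p in base and p in stim and p not in order:
            order.append(p)
    return order


def build_response_matrix(
    baseline: ExpressionMatrix, stimulated: ExpressionMatrix
) -> tuple[ResponseMatrix, QcReport]:
    """Per-patient log2FC (stimulated − baseline) for patients with both arms."""
    if list(baseline.values.index) != list(stimulated.values.index):
        diff = set(baseline.values.index) ^ set(stimulated.values.index)
        raise ValueError(
            f"baseline and stimulated gene sets differ (symmetric difference: "
            f"{sorted(diff)[:10]}{'...' if len(diff) > 10 else ''})"
        )
    base_by_patient = {
        baseline.patient_id[s]: s for s in baseline.samples_for("baseline")
    }
    stim_by_patient = {
        stimulated.patient_id[s]: s for s in stimulated.samples_for("stimulated")
    }
    shared = [p for p in base_by_patient if p in stim_by_patient]
    report = QcReport()
    for p in base_by_patient:
        if p not in stim_by_patient:
            report.dropped_samples.append({"sample": base_by_patient[p], "reason": "unpaired",
                                           "patient": p})
    for p in stim_by_patient:
        if p not in base_by_patient:
            report.dropped_samples.append({"sample": stim_by_patient[p], "reason": "unpaired",
                                           "patient": p})
    if not shared:
        raise PipelineError("no patient has both baseline and stimulated samples")
    fc = pd.DataFrame(
        {
            p: stimulated.values[stim_by_patient[p]] - baseline.values[base_by_patient[p]]
            for p in shared
        },
        index=baseline.values.index,
    )
    return ResponseMatrix(fc), report


def detect_outliers(
    resp: ResponseMatrix, k: float = 3.0, force: bool = False
) -> tuple[ResponseMatrix, QcReport]:
    """Flag outlier patients by mean Euclidean distance in response space.

    Average-linkage clustering of the patient–patient Euclidean distances is
    computed (the dendrogram heights are reported); a patient is flagged when
    its mean distance to all others exceeds median + k × MAD (normal-
    consistent MAD, on the log scale) of the per-patient mean distances. If
    more than 20% of
    patients would be flagged, nothing is removed unless ``force``.
    """
    n = len(resp.patient_ids)
    if n < 4:
        raise ValueError(f"outlier detection needs >= 4 patients, got {n}")
    X = resp.log2fc.to_numpy().T  # patients × genes
    condensed = pdist(X, metric="euclidean")
    linkage = average(condensed)
    dist = squareform(condensed)
    mean_dist = dist.sum(axis=1) / (n - 1)
    # mean distances are right-skewed; the robust z-score is taken on the
    # log scale so the MAD rule is calibrated on homogeneous cohorts
    log_dist = np.log(mean_dist)
    med = float(np.median(log_dist))
    mad = 1.4826 * float(np.median(np.abs(log_dist - med)))
    cutoff = med + k * mad
    flagged = [p for p, d in zip(resp.patient_ids, log_dist) if d > cutoff]
    cutoff = float(np.exp(cutoff))
    report = QcReport(
        thresholds={"outlier_k": k, "mean_distance_cutoff": cutoff},
        outlier_patients=flagged,
    )
    report.notes.append(f"linkage_max_height={float(linkage[-1, 2]):.6g}")
    if len(flagged) > 0.2 * n and not force:
        warnings.warn(
            f"{len(flagged)} of {n} patients flagged as outliers; not removing "
            "(pass force=True to override)",
            stacklevel=2,
        )
        report.notes.append("flagging exceeded 20% of patients; nothing removed")
        return resp, report
    for p in flagged:
        report.dropped_samples.append({"sample": p, "reason": "outlier"})
    keep = [p for p in resp.patient_ids if p not in set(flagged)]
    return ResponseMatrix(resp.log2fc[keep]), report


def pca_top_expressed(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    top_fraction: float = 0.25,
    n_components: int = 2,
) -> dict:
    """PCA on the top-expressed genes, with PC–trait correlations.

    Genes are ranked by mean expression; the centered top-fraction submatrix
    (samples as observations) is decomposed. PC scores are correlated
    (Pearson) with each clinical covariate and with the stimulation
    condition, BH-adjusted per PC.
    """
    from .differential import trait_correlation  # local import avoids cycle

    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    if len(expr.sample_ids) < 3:
        raise ValueError("PCA needs at least 3 samples")
    means = expr.values.mean(axis=1)
    n_top = max(2, int(round(top_fraction * len(means))))
    top_genes = means.sort_values(ascending=False).index[:n_top]
    X = expr.values.loc[top_genes].to_numpy().T  # samples × genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    var_frac = var / var.sum()
    k = min(n_components, len(S))
    scores = pd.DataFrame(
        (U[:, :k] * S[:k]),
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )

    condition_code = pd.Series(
        {s: 1.0 if expr.condition[s] == "stimulated" else 0.0 for s in expr.sample_ids}
    )
    # per-sample covariates inherited from the sample's patient
    feature_mat = scores.T  # PCs × samples
    sample_clin = clin.data.reindex([expr.patient_id[s] for s in expr.sample_ids])
    sample_clin.index = expr.sample_ids
    sample_clin = sample_clin.assign(condition=condition_code)
    cor = trait_correlation(
        feature_mat, ClinicalTableView(sample_clin), method="pearson"
    )
    return {
        "scores": scores,
        "variance_fractions": var_frac[:k],
        "all_variance_fractions": var_frac,
        "pc_trait_correlation": cor,
        "n_top_genes": int(n_top),
    }


class ClinicalTableView:
    """Duck-typed clinical table over an arbitrary covariate frame.

    Used where per-sample (rather than per-patient) covariates are needed,
    e.g. correlating PC scores with the stimulation condition.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def covariate(self, name: str) -> pd.Series:
        return self.data[name]
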