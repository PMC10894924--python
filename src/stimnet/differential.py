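"""Differential response statistics: moderated one-sample tests, FDR,
trait correlations, covariate-adjusted regression, and group comparisons.

The moderated test treats each gene's per-patient log2 fold-changes as a
one-sample problem and shrinks residual variances toward a common prior by
empirical Bayes: the observed variances are modeled as scaled F draws around
a scaled inverse-chi-square prior whose moments are fit from the variance
distribution itself, and the moderated t statistic gains the prior degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalTable
from .preprocess import ResponseMatrix

__all__ = [
    "DeResult",
    "moderated_de",
    "adjust_fdr",
    "trait_correlation",
    "covariate_regression",
    "group_response_comparison",
]


@dataclass
class DeResult:
    """Per-gene differential-response table.

    ``significant`` flags |log2FC| > lfc_cutoff and Padj < padj_cutoff.
    """

    table: pd.DataFrame  # index gene; mean_log2fc, sd, t, df, p, padj, significant
    prior_df: float
    prior_var: float
    lfc_cutoff: float = 1.0
    padj_cutoff: float = 0.01

    @property
    def up_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"] & (t["mean_log2fc"] > 0)])

    @property
    def down_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"] & (t["mean_log2fc"] < 0)])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of a scaled inverse-chi-square prior (d0, s0^2).

    Works on log variances: E[log s^2] and Var[log s^2] have closed forms in
    terms of digamma/trigamma, so the prior df solves a trigamma equation.
    Degenerate (homogeneous) variance distributions give d0 = inf.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # homogeneous variances: infinite prior df; the pooled value is the
        # geometric mean so that identical variances are a fixed point
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_de(
    resp: ResponseMatrix,
    prior_df: float | None = None,
    lfc_cutoff: float = 1.0,
    padj_cutoff: float = 0.01,
) -> DeResult:
    """Empirical-Bayes moderated one-sample test on each gene's log2FC.

    ``prior_df`` overrides the fitted prior degrees of freedom (0 recovers
    the ordinary one-sample t test exactly).
    """
    X = resp.log2fc.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError(f"moderated test needs >= 3 patients, got {n}")
    df = n - 1
    mean = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    padj = adjust_fdr(p)
    table = pd.DataFrame(
        {
            "mean_log2fc": mean,
            "sd": np.sqrt(s2),
            "t": t,
            "df": df_total,
            "p": p,
            "padj": padj,
            "significant": (np.abs(mean) > lfc_cutoff) & (padj < padj_cutoff),
        },
        index=resp.log2fc.index,
    )
    return DeResult(table, prior_df=float(d0), prior_var=float(s0_sq),
                    lfc_cutoff=lfc_cutoff, padj_cutoff=padj_cutoff)


def adjust_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trait_correlation(
    features: pd.DataFrame,
    clin: ClinicalTable,
    method: str = "pearson",
    covariates: list[str] | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlate each feature (row) with each clinical covariate.

    Pairwise-complete observations; two-sided p from t = r·sqrt(n−2)/
    sqrt(1−r²); BH adjustment per covariate across features. Constant pairs
    yield missing (not zero) correlations.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    cov_names = covariates if covariates is not None else list(clin.data.columns)
    rows = []
    patients = [p for p in features.columns if p in set(clin.patient_ids)]
    if len(patients) < min_n:
        raise ValueError(f"need >= {min_n} shared patients, got {len(patients)}")
    F = features[patients]
    for cov in cov_names:
        y_full = clin.covariate(cov).reindex(patients).to_numpy(dtype=float)
        for feat in F.index:
            x_full = F.loc[feat].to_numpy(dtype=float)
            ok = np.isfinite(x_full) & np.isfinite(y_full)
            n = int(ok.sum())
            if n < min_n:
                rows.append((feat, cov, np.nan, np.nan, np.nan, n))
                continue
            x, y = x_full[ok], y_full[ok]
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((feat, cov, np.nan, np.nan, np.nan, n))
                continue
            if method == "spearman":
                x, y = stats.rankdata(x), stats.rankdata(y)
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                t_stat, p = np.inf * np.sign(r), 0.0
            else:
                t_stat = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
                p = 2.0 * stats.t.sf(abs(t_stat), n - 2)
            rows.append((feat, cov, r, t_stat, p, n))
    out = pd.DataFrame(rows, columns=["feature", "covariate", "r", "t", "p", "n"])
    out["padj"] = np.nan
    for cov in cov_names:
        mask = (out["covariate"] == cov) & out["p"].notna()
        if mask.any():
            out.loc[mask, "padj"] = adjust_fdr(out.loc[mask, "p"].to_numpy())
    return out


def covariate_regression(
    response: pd.DataFrame | pd.Series,
    clin: ClinicalTable,
    target: str,
    covariates: list[str],
) -> pd.DataFrame:
    """OLS of each feature on the target covariate plus adjustment covariates.

    Returns a long table of per-term coefficients with two-sided t tests,
    BH-adjusted across features per term. Collinear designs raise with the
    offending columns named.
    """
    import statsmodels.api as sm

    if isinstance(response, pd.Series):
        response = response.to_frame().T
    terms = [target] + list(covariates)
    patients = [p for p in response.columns if p in set(clin.patient_ids)]
    design = clin.data.loc[patients, terms].astype(float)
    complete = design.notna().all(axis=1)
    design = design[complete]
    X = sm.add_constant(design)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(design.to_numpy().T)
        bad = [
            (terms[i], terms[j])
            for i in range(len(terms))
            for j in range(i + 1, len(terms))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    rows = []
    for feat in response.index:
        y = response.loc[feat].reindex(design.index).astype(float)
        fit = sm.OLS(y, X, missing="drop").fit()
        for term in terms:
            rows.append(
                (feat, term, float(fit.params[term]), float(fit.tvalues[term]),
                 float(fit.pvalues[term]))
            )
    out = pd.DataFrame(rows, columns=["feature", "term", "coef", "t", "p"])
    out["padj"] = np.nan
    for term in terms:
        mask = out["term"] == term
        out.loc[mask, "padj"] = adjust_fdr(out.loc[mask, "p"].to_numpy())
    return out


def group_response_comparison(
    resp: ResponseMatrix,
    de: DeResult,
    clin: ClinicalTable,
    trait: str = "dbp",
    cutoff: float = 80.0,
) -> dict:
    """Compare per-patient median responses of significant genes between
    high-trait (>= cutoff) and low-trait (< cutoff) patient groups.

    Per direction (down- and up-regulated significant genes separately) the
    per-patient median log2FC is computed; the Shapiro–Wilk normality check
    is reported (advisory only) and a two-sample t test compares groups.
    """
    up, down = de.up_genes, de.down_genes
    if not up and not down:
        raise ValueError(
            "no significant genes at the current thresholds; relax "
            f"|log2FC|>{de.lfc_cutoff} / Padj<{de.padj_cutoff}"
        )
    trait_vals = clin.covariate(trait).reindex(resp.patient_ids)
    ok = trait_vals.notna()
    high = list(trait_vals.index[ok & (trait_vals >= cutoff)])
    low = list(trait_vals.index[ok & (trait_vals < cutoff)])
    if len(high) < 3 or len(low) < 3:
        raise ValueError(
            f"each group needs >= 3 patients (high={len(high)}, low={len(low)})"
        )
    result: dict = {"trait": trait, "cutoff": cutoff,
                    "n_high": len(high), "n_low": len(low)}
    for direction, genes in (("down", down), ("up", up)):
        if not genes:
            result[direction] = {"note": "no significant genes in this direction"}
            continue
        medians = resp.log2fc.loc[genes].median(axis=0)
        hi, lo = medians[high].to_numpy(), medians[low].to_numpy()
        sw_hi = stats.shapiro(hi)
        sw_lo = stats.shapiro(lo)
        t_stat, p = stats.ttest_ind(hi, lo)
        result[direction] = {
            "n_genes": len(genes),
            "median_high": float(np.mean(hi)),
            "median_low": float(np.mean(lo)),
            "shapiro": {"high": (float(sw_hi.statistic), float(sw_hi.pvalue)),
                        "low": (float(sw_lo.statistic), float(sw_lo.pvalue))},
            "t": float(t_stat),
            "p": float(p),
            "per_patient_medians": medians,
        }
    return result
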