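"""Per-patient transcription-factor activity from regulons and the response.

Each patient's response profile is rank-transformed onto standard-normal
quantiles; a TF's enrichment score is the MoR- and confidence-weighted mean
of its targets' quantile scores, normalized so that it is exactly standard
normal when the targets are independent null draws (a single-tail analytic
rank-based enrichment, without pleiotropy or shadow corrections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_fdr
from .grn import RegulonSet
from .io_formats import ClinicalTable
from .preprocess import ResponseMatrix

__all__ = ["TfActivityMatrix", "rank_signature", "regulon_enrichment",
           "tf_trait_correlation"]


@dataclass
class TfActivityMatrix:
    """TFs × patients normalized enrichment scores with p/Padj tables."""

    nes: pd.DataFrame  # TFs × patients
    p: pd.DataFrame
    padj: pd.DataFrame  # BH across TFs, per patient
    skipped: dict[str, str] = field(default_factory=dict)


def rank_signature(resp: ResponseMatrix) -> pd.DataFrame:
    """Per-patient normal-quantile scores of the log2FC ranks.

    Ranks (mid-ranks for ties) are mapped through Φ⁻¹((rank − 0.5)/n); the
    transform is monotone in log2FC within each patient.
    """
    fc = resp.log2fc
    if fc.shape[0] < 10:
        raise ValueError("signature needs >= 10 genes")
    n = fc.shape[0]
    out = np.empty(fc.shape)
    X = fc.to_numpy(dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            raise ValueError(f"patient {fc.columns[j]!r} has an all-equal response")
        ranks = stats.rankdata(col)
        out[:, j] = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(out, index=fc.index, columns=fc.columns)


def regulon_enrichment(
    sig: pd.DataFrame,
    regulons: RegulonSet,
    min_regulon_size: int = 10,
) -> TfActivityMatrix:
    """Weighted-mean enrichment of each regulon in each patient's signature.

    ES = Σ_i MoR_i·w_i·q_i over targets i; NES = ES / sqrt(Σ_i (MoR_i·w_i)²),
    standard normal under an independent-null signature. Two-sided normal p,
    BH across TFs per patient. Regulons smaller than ``min_regulon_size``
    after intersecting with the signature are skipped.
    """
    skipped: dict[str, str] = {}
    genes = set(sig.index)
    Q = sig.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(sig.index)}
    nes_rows, names = [], []
    for tf in regulons.tfs:
        targets = regulons.targets(tf)
        present = {g: wm for g, wm in targets.items() if g in genes}
        dropped = len(targets) - len(present)
        if dropped:
            skipped.setdefault(tf, "")
            skipped[tf] = f"{dropped} target(s) absent from signature"
        if len(present) < min_regulon_size:
            skipped[tf] = (
                f"regulon size {len(present)} below minimum {min_regulon_size}; skipped"
            )
            continue
        idx = np.array([pos[g] for g in present])
        wm = np.array([w * (m if np.isfinite(m) else 0.0) for (w, m) in present.values()])
        denom = np.sqrt(np.sum(wm ** 2))
        if denom == 0:
            skipped[tf] = "all modes of regulation are zero/missing; skipped"
            continue
        nes_rows.append((wm @ Q[idx]) / denom)
        names.append(tf)
    if not nes_rows:
        raise ValueError("no regulon was large enough to score")
    nes = pd.DataFrame(np.vstack(nes_rows), index=names, columns=sig.columns)
    p = pd.DataFrame(2.0 * stats.norm.sf(np.abs(nes.to_numpy())),
                     index=names, columns=sig.columns)
    padj = p.copy()
    for c in padj.columns:
        padj[c] = adjust_fdr(p[c].to_numpy())
    return TfActivityMatrix(nes, p, padj, skipped)


def tf_trait_correlation(
    act: TfActivityMatrix, clin: ClinicalTable, trait: str | None = None
) -> pd.DataFrame:
    """Pearson correlation of TF activities with clinical covariates."""
    from .differential import trait_correlation

    covs = [trait] if trait is not None else None
    return trait_correlation(act.nes, clin, method="pearson", covariates=covs)
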