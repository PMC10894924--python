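"""QC the cohort and build the per-patient stimulation-response matrix.

Applies the intensity and response-variance gene filters, pairs baseline
with stimulated samples per patient into a log2 fold-change matrix, flags
outlying patients by their mean Euclidean distance, and runs the PCA of the
top-expressed genes against the clinical covariates (expect: stimulation
state does NOT separate on PC1/PC2 — responses are per-patient shifts, not
global ones).
"""

import json
from pathlib import Path

from stimnet import io_formats, preprocess
from stimnet.pipeline import _concat

OUT = Path("results/analysis")


def main() -> None:
    baseline = io_formats.read_expression_matrix(OUT / "baseline.tsv",
                                                 OUT / "samples.tsv")
    stimulated = io_formats.read_expression_matrix(OUT / "stimulated.tsv")
    clin = io_formats.read_clinical_table(OUT / "clinical.tsv")

    both = _concat(baseline, stimulated)
    filtered, gene_report = preprocess.filter_genes(both)
    base_f = filtered.subset_samples(filtered.samples_for("baseline"))
    stim_f = filtered.subset_samples(filtered.samples_for("stimulated"))
    resp, pair_report = preprocess.build_response_matrix(base_f, stim_f)
    resp, outlier_report = preprocess.detect_outliers(resp)

    resp.log2fc.to_csv(OUT / "response_matrix.tsv", sep="\t",
                       float_format="%.10g")
    with open(OUT / "qc_report.json", "w") as fh:
        json.dump({"genes": gene_report.to_dict(),
                   "pairing": pair_report.to_dict(),
                   "outliers": outlier_report.to_dict()}, fh, indent=2)

    pca = preprocess.pca_top_expressed(filtered, clin)
    cond = pca["pc_trait_correlation"]
    cond = cond[cond["covariate"] == "condition"]
    cond.to_csv(OUT / "pca_condition_correlation.tsv", sep="\t", index=False)
    print(f"response matrix: {resp.log2fc.shape[0]} genes x "
          f"{resp.log2fc.shape[1]} patients")
    print(f"genes dropped: {gene_report.dropped_genes}")
    print(f"outliers: {outlier_report.outlier_patients or 'none'}")
    print("PC-vs-stimulation adjusted p-values:",
          [round(p, 3) for p in cond["padj"].tolist()])


if __name__ == "__main__":
    main()
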