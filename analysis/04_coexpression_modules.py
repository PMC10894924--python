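"""Co-expression module detection and module-trait association.

Builds the soft-thresholded adjacency (power 5) on the response matrix,
clusters the topological-overlap dissimilarity (minimum module size 50,
eigengene merge height 0.2), summarizes each module by its eigengene, tests
eigengene-trait correlations, runs gene-set over-representation per module,
and scores recovery against the planted partition.
"""

import warnings
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from stimnet import coexpression, differential, enrichment, io_formats, synthetic
from stimnet.preprocess import ResponseMatrix

OUT = Path("results/analysis")


def main() -> None:
    resp = ResponseMatrix(pd.read_csv(OUT / "response_matrix.tsv", sep="\t",
                                      index_col=0))
    clin = io_formats.read_clinical_table(OUT / "clinical.tsv")
    truth = synthetic.GroundTruth.from_json(OUT / "ground_truth.json")

    adj = coexpression.soft_adjacency(resp, power=5)
    diss = coexpression.topological_overlap(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        partition, eigen = coexpression.detect_modules(diss, resp)
    pd.Series(partition.labels, name="module").rename_axis("gene").to_csv(
        OUT / "module_labels.tsv", sep="\t")
    eigen.values.to_csv(OUT / "eigengenes.tsv", sep="\t", float_format="%.6g")

    truth_lab = pd.Series(truth.module_labels).reindex(diss.index)
    pred = pd.Series(partition.labels).reindex(diss.index)
    ari = adjusted_rand_score(truth_lab, pred)
    print(f"{len(partition.modules)} modules, sizes {partition.module_sizes}")
    print(f"adjusted Rand index vs planted partition: {ari:.3f}")

    mt = coexpression.module_trait_matrix(eigen, clin)
    mt.to_csv(OUT / "module_trait.tsv", sep="\t", index=False,
              float_format="%.6g")
    dbp = mt[(mt["covariate"] == "dbp") & mt["padj"].notna()]
    best = dbp.sort_values("p").iloc[0]
    print(f"strongest DBP module: {best['feature']} "
          f"(r = {best['r']:.3f}, Padj = {best['padj']:.2e} {best['stars']})")

    de = differential.moderated_de(resp)
    collection = io_formats.read_gmt(OUT / "gene_sets.gmt")
    background = set(resp.gene_ids)
    tables = []
    for module in partition.modules:
        res = enrichment.overrepresentation(set(partition.genes_in(module)),
                                            de, collection, background)
        res.table.insert(0, "module", module)
        tables.append(res.table)
    enr = pd.concat(tables, ignore_index=True)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    top = enr.sort_values("padj").iloc[0]
    print(f"top enrichment: module {top['module']} {top['direction']} in "
          f"{top['set']} (overlap {top['overlap']}, Padj = {top['padj']:.2e})")


if __name__ == "__main__":
    main()
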