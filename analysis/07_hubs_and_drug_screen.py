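"""Hub genes of the trait-linked module and connectivity-score drug screen.

Extracts the module subnetwork at adjacency > 0.4, ranks five centralities,
aggregates them by Robust Rank Aggregation (Bonferroni < 0.05 = hub), builds
the signed hub query from the hubs' mean responses, and screens the drug
library on myeloid cell lines with the weighted bidirectional K-S
connectivity score. The planted mimic should rank first and the planted
reversal last.
"""

import warnings
from pathlib import Path

import pandas as pd

from stimnet import (coexpression, connectivity, differential, hubs,
                     io_formats, synthetic)
from stimnet.preprocess import ResponseMatrix

OUT = Path("results/analysis")


def main() -> None:
    resp = ResponseMatrix(pd.read_csv(OUT / "response_matrix.tsv", sep="\t",
                                      index_col=0))
    labels = pd.read_csv(OUT / "module_labels.tsv", sep="\t",
                         index_col=0)["module"]
    partition = coexpression.ModulePartition(labels.to_dict())
    truth = synthetic.GroundTruth.from_json(OUT / "ground_truth.json")
    mt = pd.read_csv(OUT / "module_trait.tsv", sep="\t")

    dbp = mt[(mt["covariate"] == "dbp") & mt["p"].notna()]
    focus = str(dbp.sort_values("p").iloc[0]["feature"])

    adj = coexpression.soft_adjacency(resp, power=5)
    report, subnet = hubs.hub_report(adj, partition, focus, weight_cutoff=0.4)
    report.table.to_csv(OUT / f"hubs_{focus}.tsv", sep="\t",
                        float_format="%.6g")
    io_formats.write_edge_table(subnet, OUT / f"subnetwork_{focus}.tsv")
    print(f"module {focus}: {subnet.number_of_nodes()} nodes, "
          f"{subnet.number_of_edges()} edges above 0.4; "
          f"{len(report.hub_genes)} hub genes")

    de = differential.moderated_de(resp)
    hub_resp = de.table.loc[report.hub_genes, "mean_log2fc"]
    n_down = int((hub_resp < 0).sum())
    print(f"hub responses: {n_down}/{len(hub_resp)} down-regulated "
          f"(mean log2FC {hub_resp.mean():.2f})")

    library = io_formats.read_drug_library(OUT / "drug_library.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = connectivity.drug_screen(
            hub_resp, library,
            cell_line_filter=list(synthetic.MYELOID_CELL_LINES),
            n_perm=1000, seed=1)
    screen.table.to_csv(OUT / "drug_screen.tsv", sep="\t",
                        float_format="%.6g")
    print("top of the screen:")
    print(screen.table.head(3)[["score", "p", "padj", "effective"]]
          .to_string())
    print(f"planted mimic: {truth.mimic_drug}; planted reversal: "
          f"{truth.reversal_drug} "
          f"(score {screen.table.loc[truth.reversal_drug, 'score']:.3f})")


if __name__ == "__main__":
    main()
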