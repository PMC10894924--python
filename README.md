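# stimnet

Network analysis of paired stimulation-response expression cohorts.

`stimnet` asks how a clinical covariate modulates a cell's transcriptional
response to a stimulus, using the design of ex-vivo monocyte LPS-stimulation
studies: each patient contributes a baseline and a stimulated expression
profile, and every analysis works on the per-patient response

```
log2FC(g, p) = log2 expression(g, p, stimulated) − log2 expression(g, p, baseline)
```

for gene *g* and patient *p*. On that response matrix the pipeline runs, in
order:

1. **QC and pairing** — detection-call sample filter, intensity
   (log2 < 7.5 everywhere) and response-variance (SD < 0.5) gene filters,
   per-patient pairing, Euclidean-distance outlier flagging.
2. **Moderated differential response** — one-sample empirical-Bayes test per
   gene: variances shrink toward a scaled inverse-chi-square prior fit by
   moments, t̃ = mean / (s̃/√n) with augmented degrees of freedom; BH FDR.
3. **Co-expression modules** — soft adjacency a_ij = |cor(i,j)|^5,
   topological-overlap dissimilarity 1 − TOM, average-linkage clustering
   with a simplified branch cut (minimum size 50, eigengene merge height
   0.2), module eigengenes (first PC over patients), eigengene–trait
   correlations.
4. **Bayesian consensus network** — per bootstrap iteration, 20 random
   genes per module are averaged and a DAG over modules + trait is learned
   by BIC hill climbing; edge strength = appearance frequency, orientation
   by the ≥50% direction rule, threshold at the elbow of the strength CDF
   (floored at majority, 0.5).
5. **Regulatory network** — rank-binned mutual information between TFs and
   genes over 100 bootstraps, MI < 0.5 removal, data-processing-inequality
   pruning, Poisson-Bonferroni consensus (Padj < 0.05), Spearman-signed
   modes of regulation (MoR).
6. **TF activities** — per patient, responses map to normal quantiles and
   each TF scores NES = Σ MoR·w·q / √Σ(MoR·w)², standard normal under the
   null; FDR across TFs.
7. **Hub genes** — module subnetwork at adjacency > 0.4; degree,
   betweenness, closeness, eigenvector and PageRank centralities; Robust
   Rank Aggregation (rho = min_k P(Bin(K, r_(k)) ≥ k), Bonferroni < 0.05).
8. **Drug repurposing** — weighted bidirectional Kolmogorov–Smirnov
   connectivity between the signed hub query and each drug signature;
   permutation p-values, BH; effective = Padj < 0.05 and score > 0.7.

Real cohorts of this kind are small and have no ground truth, so the
package ships a first-class synthetic-cohort generator
(`stimnet.synthetic`) that plants co-expressed modules (one coupled to
diastolic blood pressure), signed TF regulons, a module→trait dependency,
and a drug library with one signature mirroring and one reversing the
trait-module response — every stage is tested against that ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (seed 1) and write their tables to `results/analysis/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_response.py
...
python analysis/07_hubs_and_drug_screen.py
```

Selected output, as printed:

```
response matrix: 1965 genes x 38 patients
significant genes (|log2FC|>1, Padj<0.01): 434 (172 up, 262 down); prior df 26.1
down-set medians, high vs low DBP: -1.278 vs -1.909 (p = 5.89e-04)
6 modules, sizes {'M1': 135, 'M2': 120, 'M3': 88, 'M4': 79, 'M5': 65, 'M6': 58}
adjusted Rand index vs planted partition: 0.992
strongest DBP module: M1 (r = 0.694, Padj = 8.11e-06 ***)
consensus edges (4):
  M1 -> dbp (strength 1.00, direction 1.00)
regulatory network: 980 edges, 40 TFs (precision 1.000, recall 0.980)
TF-activity recovery: median Spearman vs planted activities 0.983 across 40 TFs
module M1: 135 nodes, 2005 edges above 0.4; 14 hub genes
hub responses: 14/14 down-regulated (mean log2FC -2.28)
top of the screen:
            score         p     padj  effective
drug001  0.987552  0.000999  0.03996       True
```

Reading the numbers: the planted DBP-linked module (M1) is recovered almost
exactly (ARI 0.992), its eigengene correlates with DBP (r = 0.69), the
consensus Bayesian network orients M1 → DBP with strength 1.0, the planted
regulons and TF activities are recovered (precision 1.0 / recall 0.98;
median activity correlation 0.98), all hub genes are down-regulated by the
stimulus, and the planted mimic drug tops the screen with an effective
flag, while the planted reversal scores −0.99.

The same pipeline runs end to end with one command
(`stimnet run --simulate --seed 7`) or on your own files
(`stimnet preprocess/de/modules/bn/grn/activity/hubs/screen`, see
`stimnet --help`).

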