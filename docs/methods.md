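# Methods

This note documents the models behind each `stimnet` stage, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish.

## Response matrix and QC

All inference operates on per-patient log2 fold-changes (stimulated −
baseline), restricted to patients with both arms. Detection calls declare a
gene detectable in a sample when its intensity exceeds the 95th percentile
of a negative-control distribution; samples with fewer than 9,000 detectable
genes are dropped. Gene filters remove genes below log2 intensity 7.5 in
*every* sample, then genes whose response SD falls below 0.5 — on the
response scale when pairing exists, because the downstream network stages
consume responses; on intensities otherwise. Filters are idempotent and
every removal is logged in a `QcReport`.

Outlier flagging is an explicit stand-in for a by-eye dendrogram call: a
patient is flagged when its mean Euclidean distance to all other patients
exceeds median + k·MAD (k = 3, normal-consistent MAD) — computed on the
*log* of the mean distances, which are right-skewed; on the raw scale the
same rule flags ~10% of homogeneous cohorts, on the log scale ~5%. If more
than 20% of patients would be flagged nothing is removed (a cohort-level
problem, not an outlier).

## Moderated differential response

Each gene is a one-sample problem over n patients. Sample variances s²_g
are modeled as draws around a scaled inverse-chi-square prior (d₀, s₀²) fit
by the standard moments method on log s² (digamma/trigamma identities;
the trigamma equation is inverted by Newton iteration). The posterior
variance (d₀s₀² + d·s²)/(d₀+d) gives a moderated t with d + d₀ degrees of
freedom. Degenerate fits (homogeneous variances) send d₀ → ∞ with the
pooled value set to the geometric mean of s², making identical variances an
exact fixed point — the moderated and ordinary t then agree. `prior_df=0`
disables shrinkage entirely. Type-I error is calibrated to 0.05 ± 0.02 on
heteroscedastic nulls (acceptance suite, 50 × 2,000 genes × 38 patients).

## Co-expression modules

Unsigned soft adjacency a_ij = |cor|⁵ (power 5; a signed variant is a
flag), topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) +
1 − a_ij), clustering of 1 − TOM by average linkage. The reference
implementation's dynamic tree cut is replaced by a simplified branch cut:

* static pre-cut at 0.995 of the maximum merge height;
* recursive splitting of each component at merges whose two children carry
  dissimilar eigengenes (1 − |cor| ≥ `split_height`, default 0.35) — a pure
  static cut cannot work here, since at 38 patients unrelated tight blocks
  join well below any near-root cut while the 0.995 parameter belongs to a
  branch-analysis algorithm. Planted-partition ARI is ~1.0 for split
  thresholds in 0.3–0.4 and collapses outside that band (toward
  module-shredding below, block-merging above);
* kME pruning: members with |cor(gene, eigengene)| < 0.5 are dropped
  (iterated), because average-linkage chaining accretes noise leaves onto
  real branches;
* minimum module size 50; branches whose eigengene explains < 0.25 of the
  standardized variance (pure noise plateaus at ≈ 0.07–0.09 for 50–100
  genes × 38 patients, coherent modules at ≈ within-module correlation)
  become unassigned;
* iterative merging of modules with eigengene dissimilarity < 0.2.

Eigengenes are first right singular vectors of the standardized module
submatrix, sign-fixed to correlate positively with the module mean profile.
`deepSplit` is accepted and ignored with a warning.

## Bayesian consensus network

Observations are module summaries: per iteration, 20 genes per module
sampled without replacement and averaged per patient, plus the raw trait
column. Structure learning is greedy hill climbing (add/delete/reverse)
under the linear-Gaussian BIC (loglik − k/2·log n), with lexicographic
tie-breaking plus six seeded random-restart climbs — single-start greedy
search misorients collider structures in ~10–15% of three-variable
instances; with restarts it matches exhaustive search over all 25
three-node DAGs.

Only genes are resampled by default (the trait enters unsampled);
`resample_patients=True` additionally bootstraps rows. Strength = fraction
of iterations containing the edge in either direction; direction confidence
= conditional majority frequency (≥ 50% rule). The retention threshold is
the elbow of the strength CDF — the point of maximum vertical deviation
from the chord, placed inside the gap when the deviation lies below the
chord so that a separated strong cluster is retained — and never below 0.5:
an edge absent from most bootstrap networks has no place in a consensus,
mirroring the direction rule. Residual cycles (possible after independent
majority orientations) are broken at their weakest edge.

At 38 patients a cohort with coherent modules but independent latent
factors is *not* a usable null: across ~22 node pairs the median maximum
spurious |r| is ≈ 0.38, indistinguishable from an attenuated planted
effect for any consensus rule. Calibration is therefore demonstrated on
node-independent nulls (within-module correlation 0), where gene resampling
decorrelates the summaries across iterations and the consensus is empty.

## Regulatory network and TF activity

Mutual information uses a rank-binned plug-in estimator: both vectors are
rank-transformed, cut into B = max(2, ⌊√(n/5)⌋) equal-frequency bins, and
the joint-histogram MI receives the Miller–Madow correction
(K_x + K_y − K_xy − 1)/(2n), clipped at zero. It is symmetric, invariant
under monotone transforms, near zero on independent samples, and within
±0.15 of the Gaussian closed form −½ln(1−ρ²) at ρ = 0.9, n = 5,000. At the
cohort size (n = 38, B = 2) the absolute retention floor MI < 0.5 nats is
close to the two-bin maximum ln 2 ≈ 0.69, so only near-deterministic
couplings clear it — the planted regulons are correspondingly tight
(target = MoR × activity + noise with noise SD 0.15), emulating the
high-confidence interactions a consensus network is meant to keep.

Per bootstrap (patients resampled with replacement) edges must clear
max(0.5, the 95th permutation-null percentile); the DPI removes the strict
weakest edge of every fully connected triangle, weakest <
(1 − tolerance)·min(others), simultaneously against the unpruned graph.
Consensus: edge appearance counts are tested against Poisson(λ) with λ =
total retained edge slots / all testable TF–gene pairs — the expected
appearances of a *random* pair; normalizing by observed edges instead (an
alternative reading) makes λ the true edges' own rate under strong planted
signal and empties the network. Bonferroni over observed edges, Padj <
0.05. Regulators are restricted to the declared TF list; no self-loops.
MoR = Spearman correlation of TF and target responses.

TF activity is a single-tail analytic rank-based enrichment: responses map
to normal quantiles Φ⁻¹((rank − ½)/n) per patient; NES = Σ MoR·w·q /
√Σ(MoR·w)², exactly standard normal for independent null targets (verified:
mean 0 ± 0.05, SD 1 ± 0.05 over 2,000 null draws). Two-sided normal p, BH
across TFs per patient; regulons below 10 usable targets are skipped. The
pleiotropy/shadow corrections and two-tail mode of full enrichment-based
activity inference are deliberately out of scope; planted-activity recovery
(median Spearman ≈ 0.98) is the contract.

## Hubs and drug screen

Module subnetworks keep adjacency > 0.4 (raw adjacency, not TOM; a
`use_tom` choice would be equally defensible — adjacency is what the weight
threshold is quoted against). Centralities: weighted degree; betweenness
and harmonic closeness on 1/weight distances; principal-eigenvector
centrality of the weight matrix; PageRank at damping 0.85. Ranks descend in
centrality with average ties. Robust Rank Aggregation: for sorted
normalized ranks r₍₁₎ ≤ … ≤ r₍K₎, p_k = P(Bin(K, r₍k₎) ≥ k), rho = min_k
p_k, corrected ×K within gene (Bonferroni over order statistics) and ×n
across genes; hubs at adjusted p < 0.05.

The connectivity score walks a drug's ranked signature: hits advance the
running sum by |score|/Σ|score| (weighted; 1/t unweighted), misses by
1/(n−t); ES is the signed maximal deviation. Bidirectional combination:
0 when ES_up and ES_down share a sign, else (ES_up − ES_down)/2; a
single-direction query scores ES_up or −ES_down, so positive always means
the drug pushes the query genes the way the query states (a mimic of the
stimulus response). Permutation p-values rescore random gene sets of
matched sizes (one-sided); BH across drugs; effective = Padj < 0.05 and
score > 0.7.

## Synthetic cohorts

The generator emulates the study design, not array technology: 2,000 genes
× 38 patients (configurable), baseline log2 intensities around gene means
in 6–14, stimulated = baseline + planted response. Six modules (sizes
150…60) share patient-level latent factors; per-gene loadings vary
uniformly ±0.2 around the nominal within-module correlation 0.7, giving a
core–periphery structure, and response amplitudes grow with loading so the
most connected (hub) genes respond strongest. The first module's factor
correlates with DBP at 0.6. Clinical covariates match the cohort table's
moments (DBP ~ N(74.78, 11.88²) truncated to [40, 130]; SBP = DBP + a
positive offset; four binaries at the cohort frequencies). Forty TFs carry
25-target regulons (30% repressors, MoR −1 for all their targets). The drug
library spans a 978-gene landmark panel (the size of the standard
landmark-gene set) containing the trait module; the mimic signature equals
the planted trait-module response with moderate off-module noise (SD 0.5 —
exact zeros make the permutation null degenerate), and the reversal is its
exact negative, so their correlation is −1 by construction.

What passing tests show: every algorithm recovers the structure it is
designed to find, at the study's sample size, under Gaussian latent-factor
data with planted effects. What they do not show: robustness to array
artifacts, batch effects, non-Gaussian heavy tails, overlapping modules,
combinatorial regulation, or the weak, pleiotropic couplings of real
regulatory networks — real-data performance claims need real data.

## Problem sizes and determinism

Test and acceptance runs use the generator's study-scale defaults (2,000
genes × 38 patients) for single-cohort checks and 500–700-gene cohorts for
multi-seed recovery loops (25 seeds for module recovery, 10 + 10 for the
Bayesian consensus), with 200 bootstrap iterations where the full pipeline
default is 1,000 — the Monte-Carlo SE of a strength at 200 iterations is
below 0.04, immaterial against the 0.8/0.5 thresholds. All randomness flows
through explicit integer seeds; pipeline reruns are byte-identical.

## Known limitations

* The static-plus-recursive branch cut approximates, not reproduces, the
  reference dynamic tree cut; `deepSplit` has no effect.
* Absolute MI thresholds are estimator-specific; with two bins at n = 38
  the 0.5-nat floor admits only near-deterministic couplings. The
  permutation-quantile gate is the scale-free safeguard.
* Consensus-network calibration at n = 38 cannot separate coherent but
  independent modules from weak true effects (see above).
* The drug screen scores single signatures; replicate aggregation across
  cell lines and touchstone-style normalization are out of scope.
* Shapiro–Wilk normality checks are reported, never acted on automatically.
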