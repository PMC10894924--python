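"""Weighted co-expression module detection on the response matrix.

A soft-thresholded adjacency (|Pearson r|^power) is turned into a
topological-overlap dissimilarity and clustered by average linkage. The tree
is pre-cut near the top, components are recursively split wherever two
sub-branches carry dissimilar eigengenes, weakly attached members are
pruned, and branches below the minimum size or without a coherent leading
component become unassigned. Each module is summarized by an eigengene
(first principal component over patients) and modules with near-identical
eigengenes are merged iteratively. This simplified branch cut replaces the
dynamic tree cut of the reference WGCNA implementation; planted-module
recovery tests are the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .io_formats import ClinicalTable
from .preprocess import ResponseMatrix

__all__ = [
    "AdjacencyMatrix",
    "ModulePartition",
    "EigengeneMatrix",
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "module_trait_matrix",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass
class AdjacencyMatrix:
    """Symmetric gene–gene adjacency in [0, 1] with unit diagonal."""

    values: pd.DataFrame
    power: int
    signed: bool = False

    def __post_init__(self) -> None:
        a = self.values.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModulePartition:
    """Gene → module labels plus the merge history of the dendrogram."""

    labels: dict[str, str]
    dendrogram: np.ndarray | None = None
    merge_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for m in self.labels.values():
            if m != UNASSIGNED:
                sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    @property
    def modules(self) -> list[str]:
        return sorted(self.module_sizes, key=lambda m: (-self.module_sizes[m], m))


@dataclass
class EigengeneMatrix:
    """Module × patient eigengene scores with variance-explained fractions."""

    values: pd.DataFrame  # modules × patients
    variance_explained: dict[str, float]

    def __post_init__(self) -> None:
        for m, v in self.variance_explained.items():
            if not (0 < v <= 1 + 1e-9):
                raise ValueError(f"variance explained for {m} outside (0, 1]: {v}")


def soft_adjacency(
    resp: ResponseMatrix, power: int = 5, signed: bool = False
) -> AdjacencyMatrix:
    """Soft-thresholded co-expression adjacency.

    Unsigned: a_ij = |cor(i, j)|^power. Signed: a_ij = ((1 + cor)/2)^power.
    """
    X = resp.log2fc.to_numpy(dtype=float)
    if X.shape[1] < 4:
        raise ValueError("adjacency needs >= 4 patients")
    sds = X.std(axis=1)
    constant = [g for g, s in zip(resp.gene_ids, sds) if s == 0]
    if constant:
        raise ValueError(
            f"constant genes have undefined correlations; filter first: "
            f"{constant[:10]}{'...' if len(constant) > 10 else ''}"
        )
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    if signed:
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(
        pd.DataFrame(adj, index=resp.gene_ids, columns=resp.gene_ids),
        power=power,
        signed=signed,
    )


def topological_overlap(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Topological-overlap dissimilarity 1 − TOM.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) where
    l_ij = Σ_{u ∉ {i,j}} a_iu a_uj and k_i = Σ_{u≠i} a_iu.
    """
    A = adj.values.to_numpy(dtype=float).copy()
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(A, 0.0)
    L = A @ A  # with zero diagonal, sums automatically exclude u = i and u = j
    k = A.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    return pd.DataFrame(diss, index=adj.gene_ids, columns=adj.gene_ids)


def module_eigengenes(
    resp: ResponseMatrix, partition: ModulePartition
) -> EigengeneMatrix:
    """First principal component over patients, per module.

    Genes are standardized across patients; the eigengene is the first right
    singular vector, sign-fixed to correlate positively with the module's
    mean standardized profile.
    """
    eig: dict[str, np.ndarray] = {}
    var_exp: dict[str, float] = {}
    for module in partition.modules:
        genes = partition.genes_in(module)
        X = resp.log2fc.loc[genes].to_numpy(dtype=float)
        if X.shape[0] == 1:
            warnings.warn(f"module {module} has a single gene; returning its profile",
                          stacklevel=2)
            prof = X[0]
            eig[module] = (prof - prof.mean()) / prof.std()
            var_exp[module] = 1.0
            continue
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        e = Vt[0]
        mean_profile = Z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[module] = e
        var_exp[module] = float(S[0] ** 2 / (S ** 2).sum())
    values = pd.DataFrame(eig, index=resp.patient_ids).T
    return EigengeneMatrix(values, var_exp)


def _merge_pass(
    resp: ResponseMatrix, partition: ModulePartition, merge_height: float
) -> tuple[ModulePartition, bool]:
    """Merge the closest eigengene pair if within merge_height; one pass."""
    modules = partition.modules
    if len(modules) < 2:
        return partition, False
    eig = module_eigengenes(resp, partition)
    E = eig.values.to_numpy()
    cor = np.corrcoef(E)
    diss = 1.0 - cor
    np.fill_diagonal(diss, np.inf)
    i, j = np.unravel_index(np.argmin(diss), diss.shape)
    if diss[i, j] >= merge_height:
        return partition, False
    keep, absorb = sorted((modules[i], modules[j]))
    labels = {g: (keep if m == absorb else m) for g, m in partition.labels.items()}
    new = ModulePartition(labels, partition.dendrogram,
                          partition.merge_log + [(absorb, keep)])
    return new, True


def _eigengene_of(Z_resp: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector and variance-explained of standardized rows."""
    sub = Z_resp[rows]
    if sub.shape[0] == 1:
        return sub[0], 1.0
    U, S, Vt = np.linalg.svd(sub, full_matrices=False)
    return Vt[0], float(S[0] ** 2 / (S ** 2).sum())


def _split_branches(
    root, Z_resp: np.ndarray, min_size: int, split_height: float
) -> list:
    """Recursively split a dendrogram branch into co-expression-coherent
    sub-branches.

    A branch is split at its top merge when its two children carry
    dissimilar eigengenes (1 − |cor| ≥ split_height), so unrelated blocks
    joined near the root separate (recursively, down to sub-threshold
    fragments that the minimum-size filter then discards) while halves of a
    genuine module stay together.
    """
    out = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            out.append(node)
            continue
        left, right = node.get_left(), node.get_right()
        e_l, _ = _eigengene_of(Z_resp, np.array(left.pre_order()))
        e_r, _ = _eigengene_of(Z_resp, np.array(right.pre_order()))
        diss = 1.0 - abs(float(np.corrcoef(e_l, e_r)[0, 1]))
        if diss >= split_height:
            stack.extend((left, right))
        else:
            out.append(node)
    return out


def detect_modules(
    tom_diss: pd.DataFrame,
    resp: ResponseMatrix,
    cut_height: float = 0.995,
    min_size: int = 50,
    merge_height: float = 0.2,
    split_height: float = 0.35,
    min_coherence: float = 0.25,
    kme_min: float = 0.5,
    deep_split: int | None = None,
) -> tuple[ModulePartition, EigengeneMatrix]:
    """Average-linkage clustering of the TOM dissimilarity.

    The tree is pre-cut at ``cut_height`` of the maximum merge height; each
    resulting component is then recursively split at merges joining two
    branches of at least ``min_size`` whose eigengenes are dissimilar
    (≥ ``merge_height``). Branches below ``min_size``, and branches whose
    eigengene explains less than ``min_coherence`` of their standardized
    variance (pure noise), become unassigned. Finally, modules whose
    eigengene dissimilarity falls below ``merge_height`` are merged
    iteratively until stable. ``deep_split`` is accepted for interface
    compatibility and ignored with a warning.
    """
    if deep_split is not None:
        warnings.warn("deep_split is accepted but ignored (simplified cut in use)",
                      stacklevel=2)
    D = tom_diss.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if D.min() < -1e-9 or D.max() > 1 + 1e-9:
        raise ValueError("dissimilarity entries must lie in [0, 1]")
    genes = list(tom_diss.index)
    condensed = squareform(np.clip(D, 0, None), checks=False)
    Z = average(condensed)
    max_height = Z[-1, 2]
    cut = cut_height * max_height

    # standardized response rows for eigengene computations during splitting
    X = resp.log2fc.loc[genes].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z_resp = (X - mu) / sd

    root = to_tree(Z)
    components = []
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf() and node.dist > cut:
            stack.extend((node.get_left(), node.get_right()))
        else:
            components.append(node)

    clusters: list[np.ndarray] = []
    n_pat = Z_resp.shape[1]
    for comp in components:
        for branch in _split_branches(comp, Z_resp, min_size, split_height):
            rows = np.array(branch.pre_order())
            if rows.size < min_size:
                continue
            # prune weakly attached members (|cor with eigengene| < kme_min);
            # noise leaves accrete onto branches during chained merges
            for _ in range(3):
                e, _ = _eigengene_of(Z_resp, rows)
                e_z = (e - e.mean()) / e.std()
                kme = np.abs(Z_resp[rows] @ e_z) / n_pat
                keep = kme >= kme_min
                if keep.all() or keep.sum() < 2:
                    break
                rows = rows[keep]
            if rows.size < min_size:
                continue
            _, var_exp = _eigengene_of(Z_resp, rows)
            if var_exp >= min_coherence:
                clusters.append(rows)

    # name modules by decreasing size for determinism
    clusters.sort(key=lambda rows: (-rows.size, int(rows.min())))
    labels = {g: UNASSIGNED for g in genes}
    rename = {}
    for i, rows in enumerate(clusters):
        rename[i] = f"M{i + 1}"
        for r in rows:
            labels[genes[r]] = rename[i]
    partition = ModulePartition(labels, dendrogram=Z)
    if not rename:
        warnings.warn("no cluster reached the minimum module size; all genes "
                      "unassigned", stacklevel=2)
        empty = EigengeneMatrix(pd.DataFrame(columns=resp.patient_ids), {})
        return partition, empty

    changed = True
    while changed:
        partition, changed = _merge_pass(resp, partition, merge_height)
    # renumber after merging, again by size
    order = partition.modules
    rename2 = {m: f"M{i + 1}" for i, m in enumerate(order)}
    partition = ModulePartition(
        {g: rename2.get(m, UNASSIGNED) for g, m in partition.labels.items()},
        partition.dendrogram,
        partition.merge_log,
    )
    return partition, module_eigengenes(resp, partition)


def module_trait_matrix(
    eig: EigengeneMatrix, clin: ClinicalTable, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Module–trait Pearson correlations with BH stars.

    Delegates to :func:`stimnet.differential.trait_correlation` with the
    eigengenes as features (BH across modules per trait) and annotates the
    standard significance stars.
    """
    from .differential import trait_correlation

    out = trait_correlation(eig.values, clin, method="pearson", covariates=covariates)
    def star(padj: float) -> str:
        if not np.isfinite(padj):
            return ""
        if padj < 0.001:
            return "***"
        if padj < 0.01:
            return "**"
        if padj < 0.05:
            return "*"
        return ""
    out["stars"] = [star(v) for v in out["padj"]]
    return out
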