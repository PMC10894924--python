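"""Mutual-information regulatory-network reconstruction with bootstrapping.

TF–gene associations are scored by a rank-binned plug-in mutual-information
estimator (equal-frequency bins on ranks, Miller–Madow bias correction).
Per bootstrap (patients resampled with replacement) edges below the MI
retention floor — and below a permutation-null quantile — are dropped, the
data-processing inequality prunes the weakest edge of every fully connected
triangle, and edge appearances are accumulated. The consensus keeps edges
whose appearance count is Bonferroni-significant under a Poisson null whose
rate is the average appearance count expected for a random pair. Modes of
regulation are signed afterwards by Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ResponseMatrix

__all__ = [
    "RegulonSet",
    "estimate_mi",
    "aracne_network",
    "apply_dpi",
    "mode_of_regulation",
]


@dataclass
class RegulonSet:
    """TF → target table with bootstrap confidence and signed MoR."""

    table: pd.DataFrame  # columns: tf, target, weight, mor
    tf_list: list[str]
    n_bootstrap: int
    notes: list[str] = field(default_factory=list)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.table["tf"].unique())

    def targets(self, tf: str) -> dict[str, tuple[float, float]]:
        sub = self.table[self.table["tf"] == tf]
        return {
            row.target: (float(row.weight), float(row.mor))
            for row in sub.itertuples()
        }

    def as_dict(self) -> dict[str, dict[str, float]]:
        """TF -> {target: MoR} view (confidence dropped)."""
        out: dict[str, dict[str, float]] = {}
        for row in self.table.itertuples():
            out.setdefault(row.tf, {})[row.target] = float(row.mor)
        return out

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.table.itertuples():
            g.add_edge(row.tf, row.target, weight=float(row.weight),
                       sign="-" if row.mor < 0 else "+")
        return g


# ---------------------------------------------------------------------------
# MI estimation


def _n_bins(n: int) -> int:
    return max(2, int(np.floor(np.sqrt(n / 5.0))))


def _bin_labels(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels of each row's ranks (ordinal tie-break)."""
    n = X.shape[-1]
    order = np.argsort(X, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    idx = np.arange(n)
    if X.ndim == 1:
        ranks[order] = idx
    else:
        np.put_along_axis(ranks, order, np.broadcast_to(idx, order.shape), axis=-1)
    return (ranks * n_bins) // n


def _mi_from_labels(lx: np.ndarray, ly: np.ndarray, n_bins: int) -> float:
    n = lx.size
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (lx, ly), 1.0)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(
        np.sum(joint[nz] / n * (np.log(joint[nz] * n) - np.log(px[:, None] * py[None, :])[nz]))
    )
    k_joint = int(nz.sum())
    k_x = int((px > 0).sum())
    k_y = int((py > 0).sum())
    mi += (k_x + k_y - k_joint - 1) / (2.0 * n)
    return max(mi, 0.0)


def estimate_mi(x, y, estimator: str = "rank_binned") -> float:
    """Mutual information (nats) between two samples.

    Rank-transforms both vectors, bins them into B = floor(sqrt(n/5))
    equal-frequency bins (minimum 2), and applies the Miller–Madow-corrected
    plug-in estimate, clipped at zero. Symmetric and invariant under
    monotone transforms of either argument.
    """
    if estimator != "rank_binned":
        raise ValueError(f"unknown estimator {estimator!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 20:
        raise ValueError("MI estimation needs >= 20 observations")
    B = _n_bins(x.size)
    return _mi_from_labels(_bin_labels(x, B), _bin_labels(y, B), B)


def _mi_matrix(LX: np.ndarray, LY: np.ndarray, n_bins: int, n: int) -> np.ndarray:
    """MI (with Miller–Madow correction) for all row pairs of LX × LY."""
    a, b = LX.shape[0], LY.shape[0]
    IX = [(LX == bx).astype(float) for bx in range(n_bins)]
    IY = [(LY == by).astype(float) for by in range(n_bins)]
    px = np.stack([ix.sum(axis=1) for ix in IX], axis=0) / n  # bins × a
    py = np.stack([iy.sum(axis=1) for iy in IY], axis=0) / n  # bins × b
    mi = np.zeros((a, b))
    k_joint = np.zeros((a, b))
    for bx in range(n_bins):
        for by in range(n_bins):
            N = IX[bx] @ IY[by].T  # a × b joint counts
            marg = np.outer(px[bx], py[by])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = (N / n) * (np.log(N / n) - np.log(marg))
            mi += np.where(N > 0, term, 0.0)
            k_joint += N > 0
    k_x = (px > 0).sum(axis=0)
    k_y = (py > 0).sum(axis=0)
    mi += (k_x[:, None] + k_y[None, :] - k_joint - 1) / (2.0 * n)
    return np.maximum(mi, 0.0)


# ---------------------------------------------------------------------------
# DPI


def _dpi_removals(
    mi: dict[tuple[str, str], float], tolerance: float
) -> set[tuple[str, str]]:
    """Edges to drop: the strict-weakest edge of each fully connected
    triangle, when below (1 − tolerance) × the smaller of the other two.
    Computed simultaneously against the original graph."""
    neighbors: dict[str, set[str]] = {}
    for a, b in mi:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    removals: set[tuple[str, str]] = set()
    for a, b in mi:
        common = neighbors[a] & neighbors[b]
        for c in common:
            e_ab = mi[(a, b)]
            e_ac = mi[_key(a, c)]
            e_bc = mi[_key(b, c)]
            weakest = min(e_ab, e_ac, e_bc)
            others = sorted((e_ab, e_ac, e_bc))[1]
            if weakest < (1.0 - tolerance) * others:
                if e_ab == weakest:
                    removals.add((a, b))
                elif e_ac == weakest:
                    removals.add(_key(a, c))
                else:
                    removals.add(_key(b, c))
    return removals


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def apply_dpi(edges: nx.Graph, tolerance: float = 0.0) -> nx.Graph:
    """Data-processing-inequality pruning of a weighted MI graph."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    mi = {_key(u, v): float(d["weight"]) for u, v, d in edges.edges(data=True)}
    removals = _dpi_removals(mi, tolerance)
    pruned = edges.copy()
    pruned.remove_edges_from(removals)
    return pruned


# ---------------------------------------------------------------------------
# bootstrapped network


def aracne_network(
    resp: ResponseMatrix,
    tfs: list[str],
    n_boot: int = 100,
    mi_floor: float = 0.5,
    dpi_tolerance: float = 0.0,
    alpha: float = 0.05,
    consensus_alpha: float = 0.05,
    n_null_pairs: int = 2000,
    seed: int = 0,
) -> RegulonSet:
    """Bootstrap consensus TF→target network.

    Edges must clear max(``mi_floor``, the (1 − alpha) quantile of a
    permutation null) in a bootstrap to count; DPI is applied within each
    bootstrap; the consensus keeps edges whose appearance count is
    Bonferroni-significant (Padj < ``consensus_alpha``) under a Poisson null
    with rate λ = total retained edge slots / number of testable TF–gene
    pairs. Confidence weight is the appearance fraction.
    """
    rng = np.random.default_rng(seed)
    genes = resp.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    tfs_in = [t for t in tfs if t in gene_pos]
    if not tfs_in:
        raise ValueError("no transcription factor overlaps the response matrix")
    X = resp.log2fc.to_numpy(dtype=float)
    n = X.shape[1]
    B = _n_bins(n)
    tf_rows = np.array([gene_pos[t] for t in tfs_in])
    tf_set = set(tfs_in)

    # permutation-null MI quantile on the original data
    pair_tf = rng.integers(0, len(tf_rows), n_null_pairs)
    pair_gene = rng.integers(0, len(genes), n_null_pairs)
    labels0 = _bin_labels(X, B)
    null_mis = np.empty(n_null_pairs)
    for i in range(n_null_pairs):
        lx = labels0[tf_rows[pair_tf[i]]]
        ly = labels0[pair_gene[i]][rng.permutation(n)]
        null_mis[i] = _mi_from_labels(lx, ly, B)
    threshold = max(mi_floor, float(np.quantile(null_mis, 1 - alpha)))

    edge_counts: dict[tuple[str, str], int] = {}
    total_slots = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        labels = _bin_labels(X[:, idx], B)
        mi = _mi_matrix(labels[tf_rows], labels, B, n)
        sig = mi > threshold
        mi_edges: dict[tuple[str, str], float] = {}
        for ti, tf in enumerate(tfs_in):
            cols = np.nonzero(sig[ti])[0]
            for gi in cols:
                g = genes[gi]
                if g == tf:
                    continue
                key = _key(tf, g) if g in tf_set else (tf, g)
                prev = mi_edges.get(key)
                if prev is None or mi[ti, gi] > prev:
                    mi_edges[key] = float(mi[ti, gi])
        if dpi_tolerance < 1:
            mi_edges = {
                k: v
                for k, v in mi_edges.items()
                if k not in _dpi_removals(mi_edges, dpi_tolerance)
            }
        total_slots += len(mi_edges)
        for key in mi_edges:
            edge_counts[key] = edge_counts.get(key, 0) + 1

    notes = [f"mi_threshold={threshold:.4f}", f"n_bins={B}"]
    n_possible = len(tfs_in) * (len(genes) - 1)
    lam = total_slots / max(n_possible, 1)
    rows = []
    m_distinct = len(edge_counts)
    for (a, b), k in sorted(edge_counts.items()):
        p = float(stats.poisson.sf(k - 1, lam))
        if p * m_distinct < consensus_alpha:
            tf, target = (a, b) if a in tf_set else (b, a)
            rows.append((tf, target, k / n_boot, np.nan))
    table = pd.DataFrame(rows, columns=["tf", "target", "weight", "mor"])
    if table.empty:
        import warnings

        warnings.warn("no edge survived the bootstrap consensus", stacklevel=2)
    return RegulonSet(table, tf_list=list(tfs), n_bootstrap=n_boot, notes=notes)


def mode_of_regulation(regulons: RegulonSet, resp: ResponseMatrix) -> RegulonSet:
    """Sign each TF–target edge by the Spearman correlation of their
    responses across patients (activation > 0, repression < 0)."""
    fc = resp.log2fc
    ranked: dict[str, np.ndarray] = {}

    def _std_rank(g: str) -> np.ndarray | None:
        if g not in fc.index:
            return None
        if g not in ranked:
            r = stats.rankdata(fc.loc[g].to_numpy())
            sd = r.std()
            ranked[g] = (r - r.mean()) / sd if sd > 0 else None  # type: ignore
        return ranked[g]

    mors = []
    for row in regulons.table.itertuples():
        zx, zy = _std_rank(row.tf), _std_rank(row.target)
        if zx is None or zy is None:
            mors.append(np.nan)
        else:
            mors.append(float(np.mean(zx * zy)))
    table = regulons.table.copy()
    table["mor"] = mors
    return RegulonSet(table, regulons.tf_list, regulons.n_bootstrap, regulons.notes)
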