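"""Connectivity-map-style drug screening with a weighted bidirectional K-S
enrichment statistic.

A query signature (up- and down-regulated gene sets) is compared against
each drug's ranked differential signature. Walking the drug ranking from the
most up- to the most down-regulated gene, hits increment a running sum by
|score|^p / Σ|score|^p (weighted) or 1/t (unweighted) and misses by
1/(n − t); the enrichment score is the signed maximal deviation. The
connectivity score combines the two directions: zero when both enrichment
scores share a sign (no coherent relationship), else (ES_up − ES_down)/2.
Positive scores mean the drug signature mimics the query response; negative
scores mean it reverses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import adjust_fdr

__all__ = ["ConnectivityReport", "ks_enrichment", "connectivity_score", "drug_screen"]


@dataclass
class ConnectivityReport:
    """Per-drug connectivity score, permutation p, Padj, effective flag."""

    table: pd.DataFrame  # index drug; score, p, padj, effective, cell_line
    score_cutoff: float = 0.7
    padj_cutoff: float = 0.05
    notes: list[str] = field(default_factory=list)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> float:
    """Signed maximal deviation of the K-S running sum.

    ``positions`` are 0-based hit indices into the ranked list (sorted
    ascending), ``weights`` the hit increments (already normalized to sum 1).
    Candidate extrema occur just after each hit and just before each hit.
    """
    m = positions.size
    miss_inc = 1.0 / (n - m)
    hit_cum = np.cumsum(weights)
    after = hit_cum - (positions + 1 - np.arange(1, m + 1)) * miss_inc
    before = np.concatenate(([0.0], hit_cum[:-1])) - (positions - np.arange(m)) * miss_inc
    candidates = np.concatenate((after, before))
    i = int(np.argmax(np.abs(candidates)))
    return float(np.clip(candidates[i], -1.0, 1.0))


def ks_enrichment(
    reference: pd.Series,
    gene_set: set[str],
    weighted: bool = True,
    weight_power: float = 1.0,
) -> float:
    """Enrichment score of a gene set in a score-ranked reference list.

    ``reference`` maps genes to signature scores; the list is walked in
    decreasing score order. Returns ES in [−1, 1]: positive when the set
    concentrates at the top.
    """
    ranked = reference.sort_values(ascending=False, kind="mergesort")
    n = len(ranked)
    is_hit = ranked.index.isin(gene_set)
    positions = np.nonzero(is_hit)[0]
    if positions.size == 0:
        raise ValueError("gene set does not intersect the reference list")
    if positions.size == n:
        raise ValueError("gene set covers the whole reference list")
    if weighted:
        w = np.abs(ranked.to_numpy()[positions]) ** weight_power
        total = w.sum()
        w = w / total if total > 0 else np.full(positions.size, 1.0 / positions.size)
    else:
        w = np.full(positions.size, 1.0 / positions.size)
    return _es_from_positions(positions.astype(float), w, n)


def connectivity_score(
    query_up: set[str],
    query_down: set[str],
    drug_signature: pd.Series,
    weighted: bool = True,
    weight_power: float = 1.0,
) -> float:
    """Bidirectional connectivity of an up/down query with a drug ranking.

    With both sets present: 0 when ES_up and ES_down share a sign, else
    (ES_up − ES_down)/2. A single-direction query scores ES_up (up set) or
    −ES_down (down set), keeping the sign convention that positive means the
    drug pushes the query genes the way the query states.
    """
    if query_up & query_down:
        raise ValueError("query up and down sets must be disjoint")
    if not query_up and not query_down:
        raise ValueError("both query sets are empty")
    es_up = (
        ks_enrichment(drug_signature, query_up, weighted, weight_power)
        if query_up else None
    )
    es_down = (
        ks_enrichment(drug_signature, query_down, weighted, weight_power)
        if query_down else None
    )
    if es_up is None:
        return -es_down  # type: ignore[operator]
    if es_down is None:
        return es_up
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def drug_screen(
    hub_response: pd.Series,
    library: pd.DataFrame,
    cell_line_filter: list[str] | None = None,
    n_perm: int = 1000,
    weighted: bool = True,
    weight_power: float = 1.0,
    score_cutoff: float = 0.7,
    padj_cutoff: float = 0.05,
    seed: int = 0,
) -> ConnectivityReport:
    """Screen a drug-signature library against a signed hub-gene query.

    ``hub_response`` maps hub genes to their mean log2FC; genes with
    negative response form the down query, positive the up query. Per drug
    the connectivity score is computed, and a permutation p-value is
    obtained by rescoring ``n_perm`` random gene sets of matched sizes
    (one-sided: permuted score ≥ observed). BH across drugs; drugs with
    Padj < ``padj_cutoff`` and score > ``score_cutoff`` are flagged
    effective. Sorted by decreasing score.
    """
    notes: list[str] = []
    rng = np.random.default_rng(seed)
    lib = library
    if cell_line_filter is not None:
        lib = lib[lib["cell_line"].isin(set(cell_line_filter))]
        notes.append(f"{len(lib)} of {len(library)} drugs on the requested cell lines")
        if lib.empty:
            raise ValueError("no drug remains after the cell-line filter")
    scores_mat = lib.drop(columns="cell_line")
    lib_genes = list(scores_mat.columns)
    covered = [g for g in hub_response.index if g in set(lib_genes)]
    coverage = len(covered) / len(hub_response)
    if not covered:
        raise ValueError("no hub gene is present in the drug library")
    if coverage < 0.5:
        import warnings

        warnings.warn(
            f"only {coverage:.0%} of hub genes covered by the library", stacklevel=2
        )
    notes.append(f"query coverage {len(covered)}/{len(hub_response)}")
    query = hub_response.loc[covered]
    up = set(query.index[query > 0])
    down = set(query.index[query < 0])
    if not up and not down:
        raise ValueError("hub query has no signed genes")

    n_lib = len(lib_genes)
    col_of = {g: i for i, g in enumerate(lib_genes)}
    up_idx = np.array([col_of[g] for g in sorted(up)], dtype=int)
    down_idx = np.array([col_of[g] for g in sorted(down)], dtype=int)

    rows = []
    for drug in lib.index:
        vals = scores_mat.loc[drug].to_numpy(dtype=float)
        order = np.argsort(-vals, kind="stable")
        pos_of = np.empty(n_lib, dtype=int)
        pos_of[order] = np.arange(n_lib)
        sorted_abs = np.abs(vals[order]) ** weight_power

        def es(idx: np.ndarray) -> float:
            pos = np.sort(pos_of[idx])
            if weighted:
                w = sorted_abs[pos]
                total = w.sum()
                w = w / total if total > 0 else np.full(pos.size, 1.0 / pos.size)
            else:
                w = np.full(pos.size, 1.0 / pos.size)
            return _es_from_positions(pos.astype(float), w, n_lib)

        def conn(u_idx: np.ndarray, d_idx: np.ndarray) -> float:
            if u_idx.size == 0:
                return -es(d_idx)
            if d_idx.size == 0:
                return es(u_idx)
            es_up, es_down = es(u_idx), es(d_idx)
            if np.sign(es_up) == np.sign(es_down):
                return 0.0
            return (es_up - es_down) / 2.0

        obs = conn(up_idx, down_idx)
        perm_ge = 0
        for _ in range(n_perm):
            chosen = rng.choice(n_lib, size=len(up) + len(down), replace=False)
            if conn(chosen[: len(up)], chosen[len(up):]) >= obs:
                perm_ge += 1
        p = (1 + perm_ge) / (1 + n_perm)
        rows.append((drug, obs, p, lib.loc[drug, "cell_line"]))
    table = pd.DataFrame(rows, columns=["drug", "score", "p", "cell_line"]).set_index("drug")
    table["padj"] = adjust_fdr(table["p"].to_numpy())
    table["effective"] = (table["padj"] < padj_cutoff) & (table["score"] > score_cutoff)
    table = table.sort_values("score", ascending=False)
    return ConnectivityReport(table, score_cutoff, padj_cutoff, notes)
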