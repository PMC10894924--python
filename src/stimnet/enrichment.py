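"""Gene-set over-representation by the hypergeometric (Fisher) upper tail.

Module genes are split by response direction (sign of the mean log2FC) and
each direction is tested separately against every gene set, one-sided for
enrichment, with BH adjustment across sets per (module, direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DeResult, adjust_fdr
from .io_formats import GeneSetCollection

__all__ = ["EnrichmentResult", "overrepresentation", "cross_module_regulation_test"]


@dataclass
class EnrichmentResult:
    """Long table: per (direction, set) overlap, odds ratio, p, padj."""

    table: pd.DataFrame
    background_size: int
    notes: list[str]


def _hypergeom_tail(overlap: int, background: int, set_size: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, query))


def overrepresentation(
    module_genes: set[str],
    de: DeResult,
    collection: GeneSetCollection,
    background: set[str],
    min_set_size: int = 5,
    max_set_fraction: float = 0.5,
) -> EnrichmentResult:
    """Direction-split over-representation of module genes in each set.

    The query is the module split by the sign of the mean log2FC; sets are
    intersected with the background first, and sets smaller than
    ``min_set_size`` or larger than ``max_set_fraction`` of the background
    are skipped.
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not module_genes <= background:
        raise ValueError("module genes must be a subset of the background")
    mean_fc = de.table["mean_log2fc"]
    up = {g for g in module_genes if g in mean_fc.index and mean_fc[g] > 0}
    down = {g for g in module_genes if g in mean_fc.index and mean_fc[g] < 0}
    notes: list[str] = []
    rows = []
    N = len(background)
    for direction, query in (("up", up), ("down", down)):
        if not query:
            notes.append(f"no {direction}-regulated module genes; direction skipped")
            continue
        pvals, meta = [], []
        for name in sorted(collection.sets):
            members = collection.sets[name] & background
            if len(members) < min_set_size or len(members) > max_set_fraction * N:
                continue
            k = len(members & query)
            p = _hypergeom_tail(k, N, len(members), len(query))
            a, b = k, len(query) - k
            c, d = len(members) - k, N - len(members) - len(query) + k
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            pvals.append(p)
            meta.append((direction, name, k, len(members), len(query), odds, p))
        if pvals:
            padj = adjust_fdr(pvals)
            for (direction_, name, k, m, q, odds, p), pa in zip(meta, padj):
                rows.append((direction_, name, k, m, q, N, odds, p, pa))
    table = pd.DataFrame(
        rows,
        columns=["direction", "set", "overlap", "set_size", "query_size",
                 "background_size", "odds_ratio", "p", "padj"],
    )
    return EnrichmentResult(table, background_size=N, notes=notes)


def cross_module_regulation_test(
    regulons: dict[str, dict[str, float]],
    labels: dict[str, str],
    source_module: str,
    target_module: str,
    background: set[str],
) -> dict:
    """Are targets of the source module's TFs over-represented in the target
    module? One-sided hypergeometric on the exact intersection counts."""
    if not regulons:
        raise ValueError("empty regulon set")
    source_tfs = [tf for tf in regulons if labels.get(tf) == source_module]
    if not source_tfs:
        raise ValueError(
            f"no transcription factor of module {source_module!r} appears in "
            "the regulatory network"
        )
    query = set().union(*(regulons[tf].keys() for tf in source_tfs)) & background
    target_genes = {g for g, m in labels.items() if m == target_module} & background
    overlap = query & target_genes
    p = _hypergeom_tail(len(overlap), len(background), len(target_genes), len(query))
    return {
        "source_module": source_module,
        "target_module": target_module,
        "source_tfs": sorted(source_tfs),
        "query_size": len(query),
        "target_module_size": len(target_genes),
        "overlap": len(overlap),
        "overlap_genes": sorted(overlap),
        "background_size": len(background),
        "p": p,
    }
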