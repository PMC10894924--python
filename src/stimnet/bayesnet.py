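"""Bootstrapped hill-climbing Bayesian networks over module summaries.

Each bootstrap iteration averages a random subset of genes per module into a
module × patient summary, appends the clinical trait, and learns a DAG by
greedy hill climbing under the linear-Gaussian BIC. Edge strength is the
fraction of iterations containing the edge (either direction); direction
confidence is the conditional frequency of the majority orientation. The
consensus keeps edges above an elbow threshold on the strength CDF and
orients them by majority, breaking any residual cycle at its weakest edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import ModulePartition
from .io_formats import ClinicalTable
from .preprocess import ResponseMatrix

__all__ = ["ConsensusBN", "hill_climb", "bootstrap_consensus", "elbow_threshold"]


@dataclass
class ConsensusBN:
    """Consensus DAG with per-edge strength and direction confidence."""

    nodes: list[str]
    edges: list[dict]  # {from, to, strength, direction_confidence}
    strength_threshold: float
    n_bootstrap: int
    all_strengths: dict[tuple[str, str], float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e["from"], e["to"], weight=e["strength"],
                       direction_confidence=e["direction_confidence"])
        return g

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": self.edges,
            "strength_threshold": self.strength_threshold,
            "n_bootstrap": self.n_bootstrap,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# scoring


def _node_score(X: np.ndarray, v: int, parents: tuple[int, ...]) -> float:
    """Linear-Gaussian BIC contribution of one node given its parents.

    score = loglik − (k/2)·log n with k = |parents| + 2 (coefficients,
    intercept, residual variance); higher is better.
    """
    n = X.shape[0]
    y = X[:, v]
    if parents:
        A = np.column_stack([np.ones(n), X[:, list(parents)]])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
    else:
        resid = y - y.mean()
    sigma2 = float(resid @ resid) / n
    sigma2 = max(sigma2, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = len(parents) + 2
    return loglik - 0.5 * k * np.log(n)


def network_score(data: pd.DataFrame, graph: nx.DiGraph) -> float:
    """Total linear-Gaussian BIC of a DAG on the given observations."""
    X = data.to_numpy(dtype=float)
    cols = {c: i for i, c in enumerate(data.columns)}
    total = 0.0
    for v in data.columns:
        parents = tuple(sorted(cols[p] for p in graph.predecessors(v)))
        total += _node_score(X, cols[v], parents)
    return total


def _creates_cycle(parents: dict[int, set[int]], u: int, v: int) -> bool:
    """Would adding u -> v create a cycle? (v must not reach u)."""
    # children map derived on the fly; graphs here are tiny
    stack, seen = [u], set()
    while stack:
        node = stack.pop()
        if node == v:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(parents[node])
    return False


def hill_climb(
    data: pd.DataFrame,
    score: str = "bic_gaussian",
    n_restarts: int = 6,
    seed: int = 0,
) -> nx.DiGraph:
    """Greedy DAG search over add/delete/reverse single-edge moves.

    Deterministic: moves are enumerated in lexicographic order, the first
    best-scoring admissible move is taken, and each search stops at a local
    optimum. In addition to the climb from the empty graph, ``n_restarts``
    climbs start from random DAGs (seeded) and the best-scoring result wins.
    Continuous data only; constant columns are rejected.
    """
    if score != "bic_gaussian":
        raise ValueError(f"unknown score {score!r}")
    if len(data) < 10:
        raise ValueError("structure learning needs >= 10 observations")
    X = data.to_numpy(dtype=float)
    names = list(data.columns)
    p = len(names)
    const = [names[i] for i in range(p) if X[:, i].std() == 0]
    if const:
        raise ValueError(f"constant columns cannot be scored: {const}")

    cache: dict[tuple[int, tuple[int, ...]], float] = {}
    rng = np.random.default_rng(seed)
    starts: list[dict[int, set[int]]] = [{i: set() for i in range(p)}]
    for _ in range(n_restarts):
        order = rng.permutation(p)
        parents_r: dict[int, set[int]] = {i: set() for i in range(p)}
        for pos in range(1, p):
            for prev in range(pos):
                if rng.random() < 0.3:
                    parents_r[int(order[pos])].add(int(order[prev]))
        starts.append(parents_r)

    def node_score(v: int, ps: set[int]) -> float:
        key = (v, tuple(sorted(ps)))
        if key not in cache:
            cache[key] = _node_score(X, v, key[1])
        return cache[key]

    best_parents: dict[int, set[int]] = starts[0]
    best_total = -np.inf
    for start in starts:
        parents = {v: set(ps) for v, ps in start.items()}
        current = {v: node_score(v, parents[v]) for v in range(p)}

        while True:
            best: tuple[float, tuple] | None = None
            for u in range(p):
                for v in range(p):
                    if u == v:
                        continue
                    if u in parents[v]:
                        # delete u -> v
                        delta = node_score(v, parents[v] - {u}) - current[v]
                        move = ("delete", u, v)
                        if best is None or delta > best[0] + 1e-12:
                            best = (delta, move)
                        # reverse u -> v  (becomes v -> u)
                        if not _creates_cycle(
                            {k: (s - {u} if k == v else s)
                             for k, s in parents.items()},
                            v, u,
                        ):
                            delta_rev = (
                                node_score(v, parents[v] - {u}) - current[v]
                                + node_score(u, parents[u] | {v}) - current[u]
                            )
                            move = ("reverse", u, v)
                            if delta_rev > (best[0] if best else -np.inf) + 1e-12:
                                best = (delta_rev, move)
                    else:
                        if _creates_cycle(parents, u, v):
                            continue
                        delta = node_score(v, parents[v] | {u}) - current[v]
                        move = ("add", u, v)
                        if best is None or delta > best[0] + 1e-12:
                            best = (delta, move)
            if best is None or best[0] <= 1e-9:
                break
            _, (op, u, v) = best
            if op == "add":
                parents[v].add(u)
            elif op == "delete":
                parents[v].discard(u)
            else:  # reverse
                parents[v].discard(u)
                parents[u].add(v)
            current[v] = node_score(v, parents[v])
            current[u] = node_score(u, parents[u])

        total = sum(current.values())
        if total > best_total + 1e-12:
            best_total = total
            best_parents = parents

    g = nx.DiGraph()
    g.add_nodes_from(names)
    for v, ps in best_parents.items():
        for u in ps:
            g.add_edge(names[u], names[v])
    assert nx.is_directed_acyclic_graph(g)
    return g


# ---------------------------------------------------------------------------
# bootstrap consensus


def elbow_threshold(strengths: np.ndarray) -> float:
    """Elbow of the empirical CDF: the strength where the CDF deviates most
    from the chord joining its endpoints.

    When the maximal deviation lies below the chord — the CDF is flat across
    a gap and jumps late, i.e. a separated cluster of strong edges — the
    threshold is placed inside the gap (midpoint to the previous distinct
    strength) so the strong cluster itself is retained by a strict ``>``.
    """
    s = np.sort(np.asarray(strengths, dtype=float))
    m = s.size
    if m == 0:
        return 0.0
    if s[-1] == s[0]:
        return s[0] / 2.0
    y = np.arange(1, m + 1) / m
    chord = y[0] + (s - s[0]) * (y[-1] - y[0]) / (s[-1] - s[0])
    dev = y - chord
    i = int(np.argmax(np.abs(dev)))
    if dev[i] >= 0:
        return float(s[i])
    below = s[s < s[i]]
    prev = float(below[-1]) if below.size else 0.0
    return (prev + float(s[i])) / 2.0


def bootstrap_consensus(
    resp: ResponseMatrix,
    labels: ModulePartition,
    clin: ClinicalTable,
    trait: str = "dbp",
    n_iter: int = 1000,
    genes_per_module: int = 20,
    direction_rule: float = 0.5,
    strength_threshold: float | None = None,
    majority_floor: float = 0.5,
    resample_patients: bool = False,
    seed: int = 0,
) -> ConsensusBN:
    """Bootstrap hill-climbing consensus over modules plus a clinical trait.

    Per iteration, ``genes_per_module`` genes are sampled per module (without
    replacement where possible) and averaged per patient; the trait column is
    appended; a DAG is learned by :func:`hill_climb`. Optionally the patients
    are also resampled with replacement. The consensus keeps edges with
    strength above ``strength_threshold`` (default: the elbow of the
    strength CDF, never below ``majority_floor`` — an edge absent from most
    bootstrap networks stays out of the consensus, mirroring the majority
    rule used for directions), oriented
    by majority direction; residual cycles are broken at their weakest edge.
    """
    rng = np.random.default_rng(seed)
    modules = labels.modules
    if not modules:
        raise ValueError("no modules to summarize")
    trait_vals = clin.covariate(trait).reindex(resp.patient_ids)
    if trait_vals.isna().mean() > 0.2:
        raise ValueError(f"trait {trait!r} missing for more than 20% of patients")
    keep = list(trait_vals.dropna().index)
    fc = resp.log2fc[keep]
    trait_arr = trait_vals.loc[keep].to_numpy(dtype=float)

    notes: list[str] = []
    gene_idx: dict[str, np.ndarray] = {}
    positions = {g: i for i, g in enumerate(fc.index)}
    for m in modules:
        genes = labels.genes_in(m)
        gene_idx[m] = np.array([positions[g] for g in genes if g in positions])
        if gene_idx[m].size < genes_per_module:
            notes.append(
                f"module {m} has {gene_idx[m].size} genes < {genes_per_module}; "
                "sampling with replacement"
            )
    X_full = fc.to_numpy(dtype=float)
    n_pat = len(keep)

    edge_counts: dict[tuple[str, str], int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    node_names = modules + [trait]
    for _ in range(n_iter):
        cols = {}
        for m in modules:
            pool = gene_idx[m]
            replace = pool.size < genes_per_module
            chosen = rng.choice(pool, size=genes_per_module, replace=replace)
            cols[m] = X_full[chosen].mean(axis=0)
        cols[trait] = trait_arr
        tab = pd.DataFrame(cols, index=keep)[node_names]
        if resample_patients:
            rows = rng.integers(0, n_pat, n_pat)
            tab = tab.iloc[rows].reset_index(drop=True)
        dag = hill_climb(tab)
        for u, v in dag.edges:
            edge_counts[(u, v)] = edge_counts.get((u, v), 0) + 1
            pair = tuple(sorted((u, v)))
            pair_counts[pair] = pair_counts.get(pair, 0) + 1

    strengths = {pair: c / n_iter for pair, c in pair_counts.items()}
    threshold = (
        strength_threshold
        if strength_threshold is not None
        else max(elbow_threshold(np.array(list(strengths.values()))), majority_floor)
    )

    edges = []
    for pair, strength in sorted(strengths.items()):
        if strength <= threshold:
            continue
        a, b = pair
        ab = edge_counts.get((a, b), 0)
        ba = edge_counts.get((b, a), 0)
        if ab >= ba:
            frm, to, conf = a, b, ab / (ab + ba)
        else:
            frm, to, conf = b, a, ba / (ab + ba)
        if conf < direction_rule:
            conf = direction_rule  # exact ties orient lexicographically
        edges.append({"from": frm, "to": to, "strength": strength,
                      "direction_confidence": conf})

    # break residual cycles at the weakest edge
    g = nx.DiGraph()
    g.add_nodes_from(node_names)
    for e in edges:
        g.add_edge(e["from"], e["to"], strength=e["strength"])
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        weakest = min(cycle, key=lambda uv: g.edges[uv]["strength"])
        g.remove_edge(*weakest)
        edges = [e for e in edges if (e["from"], e["to"]) != weakest]
        notes.append(f"cycle broken by removing edge {weakest[0]}->{weakest[1]}")

    for a, b in combinations(node_names, 2):
        strengths.setdefault((a, b), 0.0)
    return ConsensusBN(
        nodes=node_names,
        edges=edges,
        strength_threshold=float(threshold),
        n_bootstrap=n_iter,
        all_strengths={tuple(sorted(k)): v for k, v in strengths.items()},
        notes=notes,
    )
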