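from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stimnet import grn, preprocess, synthetic
from stimnet.grn import apply_dpi, aracne_network, estimate_mi, mode_of_regulation

from conftest import make_response


def dpi_oracle(g: nx.Graph, tolerance: float) -> set:
    """All-triangles brute force: weakest edge of each complete triangle."""
    removals = set()
    for a, b, c in combinations(sorted(g.nodes), 3):
        if g.has_edge(a, b) and g.has_edge(a, c) and g.has_edge(b, c):
            edges = [(g.edges[a, b]["weight"], (a, b)),
                     (g.edges[a, c]["weight"], (a, c)),
                     (g.edges[b, c]["weight"], (b, c))]
            edges.sort()
            if edges[0][0] < (1 - tolerance) * edges[1][0]:
                removals.add(tuple(sorted(edges[0][1])))
    return removals


class TestEstimateMi:
    def test_symmetric_and_monotone_invariant(self, rng):
        x = rng.standard_normal(200)
        y = 0.7 * x + rng.standard_normal(200)
        assert estimate_mi(x, y) == pytest.approx(estimate_mi(y, x), abs=1e-12)
        assert estimate_mi(np.exp(x), y ** 3 + 5 * y) == pytest.approx(
            estimate_mi(x, y), abs=1e-12)

    def test_independent_samples_near_zero(self):
        high = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mi = estimate_mi(rng.standard_normal(1000), rng.standard_normal(1000))
            high += mi > 0.05
        assert high <= 1  # <= 5% of null seeds

    def test_deterministic_dependence_saturates(self, rng):
        x = rng.standard_normal(1000)
        B = max(2, int(np.sqrt(1000 / 5)))
        assert estimate_mi(x, x) >= 0.9 * np.log(B)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(12)
        rho = 0.9
        x = rng.standard_normal(5000)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(5000)
        assert estimate_mi(x, y) == pytest.approx(-0.5 * np.log(1 - rho ** 2),
                                                  abs=0.15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            estimate_mi(np.ones(30), np.ones(31))


class TestApplyDpi:
    def _triangle(self, w):
        g = nx.Graph()
        g.add_edge("a", "b", weight=w[0])
        g.add_edge("a", "c", weight=w[1])
        g.add_edge("b", "c", weight=w[2])
        return g

    def test_weakest_edge_of_triangle_removed(self):
        pruned = apply_dpi(self._triangle([0.9, 0.8, 0.3]), tolerance=0.0)
        assert not pruned.has_edge("b", "c")
        assert pruned.has_edge("a", "b") and pruned.has_edge("a", "c")

    def test_tolerance_one_disables_filter(self):
        pruned = apply_dpi(self._triangle([0.9, 0.8, 0.3]), tolerance=1.0)
        assert pruned.number_of_edges() == 3

    def test_open_chain_untouched(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("b", "c", weight=0.2)
        assert apply_dpi(g, 0.0).number_of_edges() == 2

    def test_matches_all_triangles_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
            tol = float(rng.choice([0.0, 0.1, 0.3]))
            pruned = apply_dpi(g, tol)
            kept = {tuple(sorted(e)) for e in pruned.edges}
            expect = ({tuple(sorted(e)) for e in g.edges}
                      - dpi_oracle(g, tol))
            assert kept == expect

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            apply_dpi(nx.Graph(), -0.1)


def _grn_cohort(seed=0, n_tfs=10):
    cfg = synthetic.SimulationConfig(
        seed=seed, n_genes=600, n_modules=2, module_sizes=(60, 50),
        n_tfs=n_tfs, targets_per_tf=20)
    base, stim, clin, truth = synthetic.simulate_cohort(cfg)
    resp, _ = preprocess.build_response_matrix(base, stim)
    return resp, truth


class TestAracneNetwork:
    def test_planted_regulons_recovered(self, quiet):
        resp, truth = _grn_cohort(seed=8)
        regs = aracne_network(resp, list(truth.regulons), n_boot=60, seed=8)
        pred = set(zip(regs.table.tf, regs.table.target))
        true = {(tf, t) for tf, ts in truth.regulons.items() for t in ts}
        tp = len(pred & true)
        assert tp / len(pred) >= 0.8   # precision
        assert tp / len(true) >= 0.8   # recall

    def test_regulator_restriction_and_no_self_loops(self, quiet):
        resp, truth = _grn_cohort(seed=9)
        regs = aracne_network(resp, list(truth.regulons), n_boot=30, seed=9)
        tfs = set(truth.regulons)
        assert set(regs.table["tf"]) <= tfs
        assert (regs.table["tf"] != regs.table["target"]).all()

    def test_ubiquitous_edge_kept_with_weight_one(self, quiet):
        """A deterministic TF-target pair clears the MI floor in every
        bootstrap and is retained with confidence weight exactly 1."""
        rng = np.random.default_rng(10)
        X = rng.standard_normal((100, 38))
        X[1] = X[0]  # exact copy of the TF row
        resp = make_response(X)
        regs = aracne_network(resp, [resp.gene_ids[0]], n_boot=40, seed=10)
        pair = regs.table.set_index("target")
        assert pair.loc[resp.gene_ids[1], "weight"] == 1.0
        assert regs.table["weight"].max() <= 1.0

    def test_shuffled_null_nearly_empty(self, quiet):
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((400, 38))
            resp = make_response(X)
            regs = aracne_network(resp, resp.gene_ids[:20], n_boot=60, seed=seed)
            counts.append(len(regs.table))
        # 7,600 testable pairs; spurious consensus edges are at most a couple
        # of near-ties of the small-sample MI floor
        assert max(counts) <= 3
        assert np.mean(counts) <= 1.5

    def test_no_tf_overlap_rejected(self, quiet):
        resp, _ = _grn_cohort(seed=11)
        with pytest.raises(ValueError):
            aracne_network(resp, ["not_a_gene"], n_boot=5)


class TestModeOfRegulation:
    def test_planted_signs_recovered(self, quiet):
        resp, truth = _grn_cohort(seed=12)
        regs = aracne_network(resp, list(truth.regulons), n_boot=40, seed=12)
        regs = mode_of_regulation(regs, resp)
        tmap = {(tf, t): m for tf, ts in truth.regulons.items()
                for t, m in ts.items()}
        checked = wrong = 0
        for row in regs.table.itertuples():
            if (row.tf, row.target) in tmap and np.isfinite(row.mor):
                checked += 1
                wrong += np.sign(row.mor) != np.sign(tmap[(row.tf, row.target)])
        assert checked > 50
        assert wrong / checked <= 0.1
        assert regs.table["mor"].abs().max() <= 1 + 1e-9

    def test_constant_profile_gives_missing_mor(self, quiet):
        X = np.vstack([np.linspace(-1, 1, 38),
                       np.linspace(-1, 1, 38) + 0.001,
                       np.ones(38)])
        resp = make_response(X)
        table = pd.DataFrame(
            {"tf": [resp.gene_ids[0]] * 2,
             "target": [resp.gene_ids[1], resp.gene_ids[2]],
             "weight": [1.0, 1.0], "mor": [np.nan, np.nan]})
        regs = grn.RegulonSet(table, [resp.gene_ids[0]], 1)
        out = mode_of_regulation(regs, resp)
        assert np.isfinite(out.table["mor"].iloc[0])
        assert np.isnan(out.table["mor"].iloc[1])
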