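import warnings

import numpy as np
import pandas as pd
import pytest

from stimnet import coexpression as cx
from stimnet.coexpression import AdjacencyMatrix, ModulePartition

from conftest import make_response


def tom_oracle(A):
    """O(n^3) double-loop topological overlap, straight from the formula."""
    A = A.copy().astype(float)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=0)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    np.fill_diagonal(out, 1.0)
    return 1.0 - out  # dissimilarity


def _adjacency(A, power=5):
    genes = [f"g{i}" for i in range(A.shape[0])]
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(pd.DataFrame(A, index=genes, columns=genes), power)


class TestSoftAdjacency:
    @pytest.mark.parametrize("r,expected", [(0.5, 0.03125), (-0.5, 0.03125),
                                            (1.0, 1.0)])
    def test_powers_of_correlation(self, r, expected):
        # two genes with exact correlation r across 8 patients, built by
        # Gram-Schmidt so the sample correlation is r to machine precision
        x = np.linspace(-1, 1, 8)
        z = np.cos(np.linspace(0.3, 5.9, 8))
        z = z - z.mean()
        z -= (z @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        zc = z / np.linalg.norm(z)
        y = r * xc + np.sqrt(1 - r ** 2) * zc
        resp = make_response(np.vstack([xc, y]))
        adj = cx.soft_adjacency(resp, power=5)
        assert adj.values.iloc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_signed_option(self):
        x = np.linspace(-1, 1, 10)
        resp = make_response(np.vstack([x, -x]))
        adj = cx.soft_adjacency(resp, power=5, signed=True)
        assert adj.values.iloc[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_constant_gene_rejected(self):
        resp = make_response(np.vstack([np.ones(6), np.arange(6.0)]))
        with pytest.raises(ValueError, match="constant"):
            cx.soft_adjacency(resp)


class TestTopologicalOverlap:
    def test_complete_unit_triangle_has_zero_dissimilarity(self):
        A = np.ones((3, 3))
        diss = cx.topological_overlap(_adjacency(A))
        off = diss.to_numpy()[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_isolated_pair_dissimilarity_one(self):
        A = np.zeros((4, 4))
        diss = cx.topological_overlap(_adjacency(A))
        assert diss.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for n in (6, 12, 20):
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            diss = cx.topological_overlap(_adjacency(A.copy()))
            ref = tom_oracle(A)
            np.testing.assert_allclose(diss.to_numpy(), ref, atol=1e-12)

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        genes = ["a", "b", "c"]
        adj = AdjacencyMatrix(pd.DataFrame(np.eye(3), index=genes, columns=genes), 5)
        adj.values.iloc[0, 1] = 0.5  # break symmetry after validation
        with pytest.raises(ValueError):
            cx.topological_overlap(adj)


class TestModuleEigengenes:
    def test_identical_profiles_give_unit_correlation(self, rng):
        prof = rng.standard_normal(15)
        X = np.tile(prof, (8, 1))
        resp = make_response(X)
        part = ModulePartition({g: "M1" for g in resp.gene_ids})
        eig = cx.module_eigengenes(resp, part)
        r = np.corrcoef(eig.values.loc["M1"], prof)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert eig.values.loc["M1"] @ (prof - prof.mean()) > 0  # sign convention

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.standard_normal((30, 12))
        resp = make_response(X)
        part = ModulePartition({g: "M1" for g in resp.gene_ids})
        eig = cx.module_eigengenes(resp, part)
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        vals, vecs = np.linalg.eigh(Z.T @ Z)
        lead = vecs[:, -1]
        got = eig.values.loc["M1"].to_numpy()
        got /= np.linalg.norm(got)
        assert min(np.linalg.norm(got - lead), np.linalg.norm(got + lead)) < 1e-8
        assert eig.variance_explained["M1"] == pytest.approx(
            vals[-1] / vals.sum(), abs=1e-9)

    def test_variance_explained_bounded(self, small_response):
        part = ModulePartition(
            {g: ("M1" if i % 2 else "M2")
             for i, g in enumerate(small_response.gene_ids[:100])}
            | {g: "unassigned" for g in small_response.gene_ids[100:]})
        eig = cx.module_eigengenes(small_response, part)
        for v in eig.variance_explained.values():
            assert 0 < v <= 1


def _planted_blocks(rng, sizes=(60, 60), n_noise=80, n_pat=40, cor=0.8):
    rows, labels = [], {}
    i = 0
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n_pat)
        for _ in range(size):
            g = np.sqrt(cor) * f + np.sqrt(1 - cor) * rng.standard_normal(n_pat)
            rows.append(g)
            labels[f"G{i:04d}"] = f"B{b}"
            i += 1
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_pat))
        labels[f"G{i:04d}"] = "unassigned"
        i += 1
    return make_response(np.array(rows)), labels


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self, rng, quiet):
        from sklearn.metrics import adjusted_rand_score

        resp, labels = _planted_blocks(rng)
        adj = cx.soft_adjacency(resp)
        diss = cx.topological_overlap(adj)
        part, eig = cx.detect_modules(diss, resp)
        truth = pd.Series(labels)
        pred = pd.Series(part.labels).reindex(truth.index)
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0, abs=1e-9)
        assert len(part.modules) == 2

    def test_block_below_min_size_unassigned(self, rng, quiet):
        resp, labels = _planted_blocks(rng, sizes=(20,), n_noise=120)
        adj = cx.soft_adjacency(resp)
        part, _ = cx.detect_modules(cx.topological_overlap(adj), resp, min_size=50)
        block = [g for g, m in labels.items() if m == "B0"]
        assert all(part.labels[g] == cx.UNASSIGNED for g in block)

    def test_pure_noise_mostly_unassigned(self, quiet):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            resp, _ = _planted_blocks(rng, sizes=(), n_noise=300)
            adj = cx.soft_adjacency(resp)
            part, _ = cx.detect_modules(cx.topological_overlap(adj), resp)
            frac_unassigned = np.mean(
                [m == cx.UNASSIGNED for m in part.labels.values()])
            assert frac_unassigned >= 0.9

    def test_merge_pass_idempotent(self, rng, quiet):
        resp, _ = _planted_blocks(rng)
        adj = cx.soft_adjacency(resp)
        part, _ = cx.detect_modules(cx.topological_overlap(adj), resp)
        again, changed = cx._merge_pass(resp, part, merge_height=0.2)
        assert not changed

    def test_deep_split_accepted_with_warning(self, rng):
        resp, _ = _planted_blocks(rng, sizes=(60,), n_noise=20)
        adj = cx.soft_adjacency(resp)
        with pytest.warns(UserWarning, match="ignored"):
            cx.detect_modules(cx.topological_overlap(adj), resp, deep_split=3)


class TestModuleTraitMatrix:
    def _clin(self, dbp):
        from stimnet.io_formats import (BINARY_COVARIATES,
                                        CONTINUOUS_COVARIATES, ClinicalTable)

        n = len(dbp)
        rng = np.random.default_rng(1)
        data = {c: rng.integers(0, 2, n).astype(float) for c in BINARY_COVARIATES}
        data.update({c: rng.uniform(40, 120, n) for c in CONTINUOUS_COVARIATES})
        data["dbp"] = dbp
        return ClinicalTable(pd.DataFrame(data, index=[f"P{j:03d}" for j in range(n)]))

    def test_planted_eigengene_trait_link_significant(self, quiet):
        rng = np.random.default_rng(0)
        n = 200
        dbp = rng.uniform(50, 110, n)
        z = (dbp - dbp.mean()) / dbp.std()
        rows = [0.6 * z + 0.8 * rng.standard_normal(n) for _ in range(60)]
        rows += [rng.standard_normal(n) for _ in range(60)]
        resp = make_response(np.array(rows))
        labels = {g: ("M1" if i < 60 else "M2")
                  for i, g in enumerate(resp.gene_ids)}
        eig = cx.module_eigengenes(resp, ModulePartition(labels))
        out = cx.module_trait_matrix(eig, self._clin(dbp), covariates=["dbp"])
        m1 = out[(out["feature"] == "M1")].iloc[0]
        assert m1["padj"] < 0.05 and abs(m1["r"]) > 0.4
        assert (out["r"].dropna().abs() <= 1).all()
        assert m1["stars"] != ""

    def test_permuted_trait_not_significant(self, quiet):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            rows = [rng.standard_normal(n) for _ in range(40)]
            resp = make_response(np.array(rows))
            labels = {g: ("M1" if i < 20 else "M2")
                      for i, g in enumerate(resp.gene_ids)}
            eig = cx.module_eigengenes(resp, ModulePartition(labels))
            out = cx.module_trait_matrix(eig, self._clin(rng.uniform(50, 110, n)),
                                         covariates=["dbp"])
            hits += (out["padj"].dropna() < 0.05).any()
        assert hits <= 1
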