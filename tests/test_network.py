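"""Signed network construction: adjacency, TOM, module detection, merging,
eigenproteins, kME."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import csfnet as cn
from csfnet.network import (
    EigenproteinSet,
    ModulePartition,
    NetworkParams,
    build_network,
    detect_modules,
    kme_table,
    merge_modules,
    module_eigenproteins,
    signed_adjacency,
    tom_similarity,
)

from conftest import make_blocks


class TestAdjacency:
    def test_endpoints_and_midpoint(self):
        params = NetworkParams(beta=4)
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(C, params)[0, 1] == pytest.approx(1.0)
        C[0, 1] = C[1, 0] = -1.0
        assert signed_adjacency(C, params)[0, 1] == pytest.approx(0.0)
        C[0, 1] = C[1, 0] = 0.0
        assert signed_adjacency(C, params)[0, 1] == pytest.approx(0.0625)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.array([[1.0, 1.5], [1.5, 1.0]]), NetworkParams())


class TestTom:
    def test_clique_gives_unit_overlap(self):
        A = np.ones((3, 3))
        assert tom_similarity(A)[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_is_zero(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 0.0
        assert tom_similarity(A)[0, 1] == pytest.approx(0.0)

    def test_three_node_hand_computation(self):
        A = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.2], [0.4, 0.2, 1.0]])
        # (0.4*0.2 + 0.5) / (min(0.9, 0.7) + 1 - 0.5) = 0.58 / 1.2
        assert tom_similarity(A)[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        C = np.clip(rng.uniform(-1, 1, (8, 8)), -1, 1)
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        A = signed_adjacency(C, NetworkParams())
        tom = tom_similarity(A)
        n = len(A)
        for i in range(n):
            for j in range(i):
                shared = sum(A[i, k] * A[k, j] for k in range(n) if k not in (i, j))
                k_i = A[i].sum() - 1
                k_j = A[j].sum() - 1
                expect = (shared + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expect, abs=1e-10)

    def test_entries_in_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 20))
        A = signed_adjacency(cn.bicor_matrix(X), NetworkParams())
        tom = tom_similarity(A)
        assert np.all(A >= 0) and np.all(A <= 1)
        assert np.all(tom >= 0) and np.all(tom <= 1)

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_similarity(A)


class TestDetectModules:
    def test_three_planted_blocks_recovered_exactly(self):
        X, labels = make_blocks([60, 40, 20], 50, rho=0.8, seed=0)
        net = build_network(X, NetworkParams())
        pred = np.array([0 if v == "unassigned" else int(v[1:])
                         for v in net.partition.labels])
        assert adjusted_rand_score(labels, pred) == 1.0
        assert list(net.partition.sizes) == [60, 40, 20]

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((500, 50)),
                         index=[f"X{i:05d}|G{i}" for i in range(500)],
                         columns=[f"s{j}" for j in range(50)])
        net = build_network(X, NetworkParams())
        assert net.partition.frac_assigned <= 0.2

    def test_block_below_min_size_stays_unassigned(self):
        X, labels = make_blocks([10], 50, rho=0.8, seed=1, n_noise=100)
        net = build_network(X, NetworkParams(min_module_size=15))
        block = net.partition.labels.iloc[:10]
        assert (block == "unassigned").all()

    def test_fewer_proteins_than_min_size_all_unassigned(self):
        X, _ = make_blocks([5], 30, rho=0.9, seed=2)
        part = detect_modules(np.zeros((5, 5)), NetworkParams(min_module_size=15),
                              protein_ids=X.index)
        assert (part.labels == "unassigned").all()

    def test_deterministic(self):
        X, _ = make_blocks([40, 30], 40, rho=0.7, seed=3, n_noise=50)
        a = build_network(X, NetworkParams())
        b = build_network(X, NetworkParams())
        assert a.partition.labels.equals(b.partition.labels)

    def test_labels_ordered_by_decreasing_size(self, small_network):
        net, _ = small_network
        sizes = list(net.partition.sizes)
        assert sizes == sorted(sizes, reverse=True)
        assert all(s >= 15 for s in sizes)


class TestMergeModules:
    def test_shared_factor_modules_merge(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal(60)
        a = 0.9 * f[None, :] + 0.25 * rng.standard_normal((30, 60))
        b = 0.9 * f[None, :] + 0.25 * rng.standard_normal((25, 60))
        X = pd.DataFrame(np.vstack([a, b]),
                         index=[f"X{i:05d}|G{i}" for i in range(55)],
                         columns=[f"s{j}" for j in range(60)])
        labels = pd.Series(["M1"] * 30 + ["M2"] * 25, index=X.index)
        merged, _ = merge_modules(X, ModulePartition(labels=labels), NetworkParams())
        assert len(merged.modules) == 1

    def test_distinct_factors_not_merged(self):
        X, _ = make_blocks([30, 25], 60, rho=0.8, seed=5)
        labels = pd.Series(["M1"] * 30 + ["M2"] * 25, index=X.index)
        merged, es = merge_modules(X, ModulePartition(labels=labels), NetworkParams())
        assert len(merged.modules) == 2
        r = np.corrcoef(es.eigenproteins.to_numpy())[0, 1]
        assert 1 - abs(r) > 0.07

    def test_each_merge_reduces_count_by_one(self):
        rng = np.random.default_rng(6)
        f = rng.standard_normal(50)
        parts = [0.9 * f[None, :] + 0.2 * rng.standard_normal((20, 50))
                 for _ in range(3)]
        X = pd.DataFrame(np.vstack(parts),
                         index=[f"X{i:05d}|G{i}" for i in range(60)],
                         columns=[f"s{j}" for j in range(50)])
        labels = pd.Series(["M1"] * 20 + ["M2"] * 20 + ["M3"] * 20, index=X.index)
        merged, _ = merge_modules(X, ModulePartition(labels=labels), NetworkParams())
        assert len(merged.modules) == 1  # 3 -> 2 -> 1 pairwise


class TestEigenproteins:
    def test_identical_profiles_reproduce_profile(self):
        rng = np.random.default_rng(7)
        profile = rng.standard_normal(20)
        X = pd.DataFrame(np.tile(profile, (5, 1)),
                         index=[f"X{i:05d}|G{i}" for i in range(5)],
                         columns=[f"s{j}" for j in range(20)])
        part = ModulePartition(labels=pd.Series(["M1"] * 5, index=X.index))
        es = module_eigenproteins(X, part)
        assert es.var_explained["M1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert es.eigenproteins.loc["M1"].to_numpy() == pytest.approx(z, abs=1e-8)

    def test_standardized_and_sign_aligned(self, small_network):
        net, _ = small_network
        E = net.eigenproteins.eigenproteins
        assert np.allclose(E.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(E.std(axis=1, ddof=1), 1, atol=1e-8)

    def test_var_explained_matches_full_decomposition(self):
        from csfnet._util import zscore_rows

        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((5, 6)),
                         index=[f"X{i:05d}|G{i}" for i in range(5)],
                         columns=[f"s{j}" for j in range(6)])
        part = ModulePartition(labels=pd.Series(["M1"] * 5, index=X.index))
        es = module_eigenproteins(X, part)
        Z = zscore_rows(X.to_numpy())
        eigvals = np.linalg.eigvalsh(Z @ Z.T)
        assert es.var_explained["M1"] == pytest.approx(
            eigvals.max() / eigvals.sum(), abs=1e-8)


class TestKme:
    def test_single_protein_module_kme_is_one(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((1, 30)), index=["X00000|G0"],
                         columns=[f"s{j}" for j in range(30)])
        part = ModulePartition(labels=pd.Series(["M1"], index=X.index))
        es = module_eigenproteins(X, part)
        kme = kme_table(X, es)
        assert kme.loc["X00000|G0", "M1"] == pytest.approx(1.0, abs=1e-8)

    def test_bounded(self, small_network):
        net, _ = small_network
        assert (net.kme.abs() <= 1 + 1e-12).all().all()

    def test_higher_loading_gives_higher_kme(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            f = rng.standard_normal(80)
            lam = np.concatenate([[0.9, 0.5], rng.uniform(0.4, 0.95, 18)])
            X = lam[:, None] * f[None, :] + 0.5 * rng.standard_normal((20, 80))
            Xf = pd.DataFrame(X, index=[f"X{i:05d}|G{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(80)])
            part = ModulePartition(labels=pd.Series(["M1"] * 20, index=Xf.index))
            es = module_eigenproteins(Xf, part)
            kme = kme_table(Xf, es)["M1"]
            hits += kme.iloc[0] > kme.iloc[1]
        assert hits >= 19  # lambda = 0.9 protein outranks lambda = 0.5


def test_full_stage_recovers_planted_modules(small_network):
    net, truth = small_network
    tl = truth.module_labels()
    pl = net.partition.labels.reindex(truth.protein_ids)
    pred = np.array([0 if v == "unassigned" else int(v[1:]) for v in pl])
    mask = tl > 0
    assert adjusted_rand_score(tl[mask], pred[mask]) >= 0.8
    assert net.partition.frac_assigned >= 0.4  # planted fraction is ~49%
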