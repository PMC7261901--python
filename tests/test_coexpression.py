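import numpy as np
import pandas as pd
import pytest

from cernet import coexpression as cx

from conftest import random_adjacency


def tom_loop_oracle(A):
    """Triple-nested-loop TOM, independent of the matrix implementation."""
    n = len(A)
    k = [sum(A[i][u] for u in range(n)) for i in range(n)]
    T = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(A[i][u] * A[u][j] for u in range(n) if u != i and u != j)
            T[i][j] = (L + A[i][j]) / (min(k[i], k[j]) + 1.0 - A[i][j])
    return np.array(T)


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 10)))
        S = cx.similarity(expr)
        assert np.allclose(np.diag(S), 1.0)

    def test_sign_invariance(self, rng):
        x = rng.normal(size=12)
        expr = pd.DataFrame([x, -x], index=["x", "negx"])
        S = cx.similarity(expr)
        assert S.loc["x", "negx"] == pytest.approx(1.0)

    def test_matches_pearson_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.1])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        S = cx.similarity(pd.DataFrame([x, y], index=["x", "y"]))
        assert S.loc["x", "y"] == pytest.approx(abs(num / den), abs=1e-12)

    def test_zero_variance_dropped_with_warning(self, rng):
        expr = pd.DataFrame(np.vstack([rng.normal(size=(3, 8)),
                                       np.full(8, 4.0)]),
                            index=["a", "b", "c", "flat"])
        with pytest.warns(UserWarning, match="zero-variance"):
            S = cx.similarity(expr)
        assert "flat" not in S.index

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            cx.similarity(pd.DataFrame(rng.normal(size=(4, 2))))


class TestSoftAdjacency:
    def test_square_of_half(self):
        S = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        A = cx.soft_adjacency(S, 2)
        assert A.iloc[0, 1] == pytest.approx(0.25)
        assert A.iloc[0, 0] == 0.0

    def test_beta_one_is_identity_off_diagonal(self, rng):
        S = random_adjacency(rng, 6)
        np.fill_diagonal(S.values, 1.0)
        A = cx.soft_adjacency(S, 1)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(A.to_numpy()[off], S.to_numpy()[off])

    def test_published_power(self):
        S = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]])
        A = cx.soft_adjacency(S, 22)
        assert A.iloc[0, 1] == pytest.approx(0.9 ** 22)
        assert A.iloc[0, 1] == pytest.approx(0.0985, abs=5e-4)

    @pytest.mark.parametrize("beta", [0, -1, 2.5])
    def test_invalid_beta_rejected(self, beta):
        S = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError):
            cx.soft_adjacency(S, beta)

    def test_monotone_decreasing_in_beta(self, rng):
        S = random_adjacency(rng, 8) * 0.99  # strictly below 1 off-diagonal
        np.fill_diagonal(S.values, 1.0)
        off = ~np.eye(8, dtype=bool)
        prev = None
        for beta in range(1, 31):
            A = cx.soft_adjacency(S, beta).to_numpy()[off]
            if prev is not None:
                assert (A < prev).all()
            prev = A


class TestConnectivity:
    def test_zero_adjacency(self):
        A = pd.DataFrame(np.zeros((4, 4)))
        assert (cx.connectivity(A) == 0).all()

    def test_uniform_weights(self):
        A = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(A.values, 0.0)
        assert np.allclose(cx.connectivity(A), 1.0)

    def test_matches_double_loop(self, rng):
        A = random_adjacency(rng, 5)
        arr = A.to_numpy()
        expected = [sum(arr[i, j] for j in range(5) if j != i)
                    for i in range(5)]
        assert np.allclose(cx.connectivity(A), expected, atol=1e-12)


class TestScaleFreeFit:
    def test_power_law_recovered(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(size=5000)
        k = 1.0 / (1.0 - u * (1.0 - 1.0 / 100.0))  # p(k) ~ k^-2 on [1, 100]
        fit = cx.scale_free_fit(k)
        assert fit.slope == pytest.approx(-2.0, abs=0.3)
        assert fit.signed_r2 > 0.9

    def test_constant_k_rejected(self):
        with pytest.raises(ValueError):
            cx.scale_free_fit(np.full(100, 3.0))

    def test_anti_scale_free_has_negative_signed_r2(self):
        # frequency increasing with k => positive slope => negative signed R^2
        k = np.concatenate([np.full(10, 1.0), np.full(100, 5.0),
                            np.full(1000, 10.0)])
        fit = cx.scale_free_fit(k, n_bins=10)
        assert fit.signed_r2 < 0


def latent_factor_expression(seed=0, n_feat=80, n_samp=30):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_samp)
    w = rng.uniform(0.2, 0.95, size=n_feat)
    noise = rng.normal(scale=np.sqrt(1 - w ** 2)[:, None],
                       size=(n_feat, n_samp))
    return pd.DataFrame(w[:, None] * z[None, :] + noise,
                        index=[f"g{i}" for i in range(n_feat)])


class TestPickBeta:
    def test_deterministic(self):
        expr = latent_factor_expression()
        a = cx.pick_beta(expr)
        b = cx.pick_beta(expr)
        assert a.chosen_beta == b.chosen_beta
        pd.testing.assert_frame_equal(a.fits, b.fits)

    def test_zero_target_chooses_beta_one(self):
        expr = latent_factor_expression(seed=1)
        sweep = cx.pick_beta(expr, r2_target=-1.0, min_mean_k=0.0)
        assert sweep.chosen_beta == 1
        assert sweep.scale_free

    def test_agrees_with_independent_sweep(self):
        expr = latent_factor_expression(seed=0)
        sweep = cx.pick_beta(expr, r2_target=0.8, min_mean_k=1.0)
        # independent scripted sweep: raw numpy, histogram + polyfit
        arr = expr.to_numpy()
        S = np.abs(np.corrcoef(arr))
        chosen = None
        for beta in range(1, 31):
            A = S ** beta
            np.fill_diagonal(A, 0.0)
            k = A.sum(axis=1)
            counts, edges = np.histogram(k, bins=10)
            sums, _ = np.histogram(k, bins=edges, weights=k)
            good = counts > 0
            km = sums[good] / counts[good]
            good2 = km > 0
            slope, _ = np.polyfit(np.log10(km[good2]),
                                  np.log10(counts[good][good2] / k.size), 1)
            fitted = np.polyval(
                np.polyfit(np.log10(km[good2]),
                           np.log10(counts[good][good2] / k.size), 1),
                np.log10(km[good2]))
            y = np.log10(counts[good][good2] / k.size)
            r2 = 1 - ((y - fitted) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            if -np.sign(slope) * r2 >= 0.8 and k.mean() >= 1.0:
                chosen = beta
                break
        assert chosen is not None
        assert abs(sweep.chosen_beta - chosen) <= 2

    def test_fallback_flag_when_nothing_qualifies(self):
        expr = latent_factor_expression(seed=3)
        with pytest.warns(UserWarning, match="falling back"):
            sweep = cx.pick_beta(expr, r2_target=0.9999, min_mean_k=0.0)
        assert not sweep.scale_free


class TestTom:
    def test_all_zero_adjacency(self):
        A = pd.DataFrame(np.zeros((4, 4)))
        T = cx.tom(A)
        off = ~np.eye(4, dtype=bool)
        assert (T.to_numpy()[off] == 0).all()
        assert np.allclose(np.diag(T), 1.0)
        assert (cx.tom_dissimilarity(A).to_numpy()[off] == 1).all()

    def test_two_node_hand_case(self):
        A = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]])
        T = cx.tom(A)
        assert T.iloc[0, 1] == pytest.approx(1.0)  # (0+1)/(1+1-1)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 21))
            A = random_adjacency(rng, n)
            expected = tom_loop_oracle(A.to_numpy().tolist())
            assert np.abs(cx.tom(A).to_numpy() - expected).max() < 1e-12

    def test_entries_in_unit_interval(self, rng):
        for _ in range(1000):
            A = random_adjacency(rng, int(rng.integers(5, 15)))
            T = cx.tom(A).to_numpy()
            assert T.min() >= 0.0 and T.max() <= 1.0 + 1e-12

    def test_invalid_adjacency_rejected(self, rng):
        A = random_adjacency(rng, 5)
        A.iloc[0, 0] = 0.5
        with pytest.raises(ValueError, match="diagonal"):
            cx.tom(A)
        B = random_adjacency(rng, 5)
        B.iloc[0, 1] = 2.0
        with pytest.raises(ValueError):
            cx.tom(B)


def two_block_adjacency(rng, block=20, lo=0.7, hi=0.9, noise=0.1):
    n = 2 * block
    A = rng.uniform(0.0, noise, size=(n, n))
    for b in range(2):
        ix = np.arange(b * block, (b + 1) * block)
        A[np.ix_(ix, ix)] = rng.uniform(lo, hi, size=(block, block))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    labels = [f"g{i}" for i in range(n)]
    return pd.DataFrame(A, index=labels, columns=labels), \
        np.repeat([0, 1], block)


class TestClusterModules:
    def test_two_planted_blocks_recovered(self, rng):
        A, truth = two_block_adjacency(rng)
        labels = cx.cluster_modules(cx.tom_dissimilarity(A), cut_height=0.8)
        assert labels.max() == 2
        # each true block maps to exactly one module label
        for b in (0, 1):
            assert len(set(labels[truth == b])) == 1

    def test_full_cut_single_module(self, rng):
        A = random_adjacency(rng, 10)
        labels = cx.cluster_modules(cx.tom_dissimilarity(A), cut_height=1.0,
                                    min_module_size=1)
        assert set(labels) == {1}

    def test_deterministic(self, rng):
        A, _ = two_block_adjacency(rng)
        D = cx.tom_dissimilarity(A)
        pd.testing.assert_series_equal(cx.cluster_modules(D),
                                       cx.cluster_modules(D))

    def test_small_clusters_unassigned(self, rng):
        A, _ = two_block_adjacency(rng, block=4)
        labels = cx.cluster_modules(cx.tom_dissimilarity(A), cut_height=0.8,
                                    min_module_size=10)
        assert set(labels) == {0}

    def test_bad_cut_height_rejected(self, rng):
        A = random_adjacency(rng, 6)
        with pytest.raises(ValueError):
            cx.cluster_modules(cx.tom_dissimilarity(A), cut_height=1.5)


class TestLncMrnaNetwork:
    def test_perfect_pair_has_edge(self):
        x = np.arange(10, dtype=float)
        lnc = pd.DataFrame([x], index=["L1"])
        mrna = pd.DataFrame([2 * x + 1], index=["M1"])
        g = cx.build_lnc_mrna_network(lnc, mrna)
        assert g.has_edge("L1", "M1")
        assert g.edges["L1", "M1"]["weight"] == pytest.approx(1.0)

    def test_independent_noise_rarely_connected(self, rng):
        lnc = pd.DataFrame(rng.normal(size=(20, 10)),
                           index=[f"L{i}" for i in range(20)])
        mrna = pd.DataFrame(rng.normal(size=(20, 10)),
                            index=[f"M{i}" for i in range(20)])
        g = cx.build_lnc_mrna_network(lnc, mrna, pcc_min=0.8)
        assert g.number_of_edges() <= 4  # 400 pairs, each < 1% chance

    def test_too_few_samples_rejected(self, rng):
        lnc = pd.DataFrame(rng.normal(size=(2, 3)))
        mrna = pd.DataFrame(rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            cx.build_lnc_mrna_network(lnc, mrna)

    def test_degree_matches_edge_incidence(self, rng):
        lnc = pd.DataFrame(rng.normal(size=(10, 8)),
                           index=[f"L{i}" for i in range(10)])
        mrna = pd.DataFrame(rng.normal(size=(15, 8)),
                            index=[f"M{i}" for i in range(15)])
        g = cx.build_lnc_mrna_network(lnc, mrna, pcc_min=0.3, alpha=0.5)
        for node in g.nodes:
            incident = sum(1 for e in g.edges if node in e)
            assert g.degree(node) == incident


class TestHubSubnetwork:
    @staticmethod
    def star_network():
        import networkx as nx
        g = nx.Graph()
        for lnc, n_neighbors in (("L1", 5), ("L2", 2), ("L3", 1)):
            g.add_node(lnc, node_class="lncRNA")
        neighbors = {"L1": [f"M{i}" for i in range(5)],
                     "L2": ["M0", "M5"], "L3": ["M6"]}
        for lnc, ms in neighbors.items():
            for m in ms:
                g.add_node(m, node_class="mRNA")
                g.add_edge(lnc, m, etype="pp")
        return g

    def test_zero_min_degree_keeps_whole_network(self):
        g = self.star_network()
        sub = cx.extract_hub_subnetwork(g, 0)
        assert set(sub.nodes) == set(g.nodes)
        assert set(sub.edges) == set(g.edges)

    def test_unreachable_degree_gives_empty(self):
        sub = cx.extract_hub_subnetwork(self.star_network(), 6)
        assert sub.number_of_nodes() == 0

    def test_hand_enumerated_hub(self):
        sub = cx.extract_hub_subnetwork(self.star_network(), 3)
        assert set(sub.nodes) == {"L1", "M0", "M1", "M2", "M3", "M4"}
        assert sub.number_of_edges() == 5

    def test_negative_min_degree_rejected(self):
        with pytest.raises(ValueError):
            cx.extract_hub_subnetwork(self.star_network(), -1)
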