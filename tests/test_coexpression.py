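"""Network construction: TOM oracle, module detection, traits, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haplodyn.coexpression import (
    GREY,
    adjacency_matrix,
    build_network,
    detect_modules,
    hub_screen,
    module_eigengene,
    module_trait,
    pick_soft_threshold,
    topological_overlap,
)
from haplodyn.io_formats import SampleMeta, ValidationError
from haplodyn.quantify import fpkm
from haplodyn.synthetic_data import SimConfig, simulate


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the unsigned topological overlap."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, (n, n))
    a = (m + m.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


class TestTom:
    def test_empty_neighborhood_gives_zero(self):
        a = np.eye(5)
        tom = topological_overlap(a)
        off = tom[~np.eye(5, dtype=bool)]
        assert np.all(off == 0.0)

    def test_complete_graph_gives_one(self):
        a = np.ones((6, 6))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, 1.0)

    def test_matches_brute_force_on_random_matrices(self):
        """100 random 6-12 node adjacencies, elementwise within 1e-12."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(6, 13))
            a = random_adjacency(rng, n)
            tom = topological_overlap(a)
            np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)
            assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_bounds_on_many_draws(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            tom = topological_overlap(random_adjacency(rng, 8))
            assert (tom >= -1e-12).all() and (tom <= 1.0 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValidationError):
            topological_overlap(a)


class TestSoftThreshold:
    def test_adjacency_power_arithmetic(self):
        expr = pd.DataFrame(
            np.random.default_rng(7).normal(size=(3, 8)), index=["a", "b", "c"]
        )
        adj = adjacency_matrix(expr, beta=6)
        c = np.corrcoef(expr.to_numpy())
        assert adj.iloc[0, 1] == pytest.approx(abs(c[0, 1]) ** 6)
        # reference point: |cor| = 0.5 at beta 6 -> 0.015625
        assert 0.5**6 == pytest.approx(0.015625)

    def test_too_few_genes_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)))
        with pytest.raises(ValidationError):
            pick_soft_threshold(expr)

    def test_structured_expression_selects_moderate_power(self):
        sim = simulate(
            SimConfig(n_genes=600, seed=15, n_modules=4, module_size=80,
                      module_cor=0.8, pi_bias=0.0, pi_de=0.0, n_reps=3)
        )
        expr = fpkm(sim.gene_counts, sim.models)
        beta, diag = pick_soft_threshold(expr)
        assert 1 <= beta <= 20
        assert set(diag.columns) == {"fit_r2", "mean_k", "max_k"}


def _planted_network(seed, n_reps=4):
    cfg = SimConfig(
        n_genes=3000, seed=seed, n_modules=3, module_size=100, module_cor=0.8,
        pi_bias=0.0, pi_de=0.0, n_reps=n_reps,
    )
    sim = simulate(cfg)
    expr = fpkm(sim.gene_counts, sim.models)
    mod = sim.truth.genes["module"]
    bg = np.random.default_rng(seed).choice(mod[mod == ""].index, 300, replace=False)
    genes = list(mod[mod != ""].index) + list(bg)
    return expr.loc[genes], sim, mod


class TestModuleDetection:
    def test_planted_modules_recovered(self):
        """3 planted modules among 600 genes recovered with ARI >= 0.8."""
        from sklearn.metrics import adjusted_rand_score

        expr, sim, mod = _planted_network(seed=5)
        net = build_network(expr, sim.samples, min_module_size=80)
        true = mod.reindex(net.modules.index).replace("", GREY)
        assert net.eigengenes.shape[1] >= 3
        assert adjusted_rand_score(true, net.modules) >= 0.8

    def test_structureless_noise_stays_grey(self):
        """On independent noise, at most 10% of genes leave grey."""
        sim = simulate(SimConfig(n_genes=500, seed=6, n_modules=0, pi_bias=0.0, pi_de=0.0))
        net = build_network(fpkm(sim.gene_counts, sim.models), sim.samples)
        assert (net.modules != GREY).mean() <= 0.10

    def test_min_size_above_n_genes_gives_all_grey(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(60, 10)),
                            index=[f"g{i}" for i in range(60)])
        adj = adjacency_matrix(expr, 6)
        tom = topological_overlap(adj)
        labels, eig = detect_modules(tom, expr, min_module_size=100)
        assert (labels == GREY).all()
        assert eig.shape[1] == 0

    def test_correlated_eigengenes_merge(self):
        """Two planted groups driven by the same latent factor merge under
        the 0.3 eigengene cut (1 - cor < 0.3)."""
        rng = np.random.default_rng(9)
        z = rng.normal(size=20)
        block = lambda: z + rng.normal(scale=0.25, size=(40, 20))  # noqa: E731
        expr = pd.DataFrame(
            np.vstack([block(), block()]), index=[f"g{i}" for i in range(80)]
        )
        adj = adjacency_matrix(expr, 6)
        tom = topological_overlap(adj)
        labels, eig = detect_modules(tom, expr, min_module_size=20, branch_cut=0.5)
        assert eig.shape[1] == 1  # merged into a single module

    def test_eigengene_is_dominant_component(self):
        """The eigengene explains at least as much standardized variance as
        any single member gene profile."""
        rng = np.random.default_rng(10)
        z = rng.normal(size=12)
        x = 2.0 * z + rng.normal(scale=0.7, size=(30, 12))
        e = module_eigengene(x)
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        var_e = np.mean((xs @ e / np.linalg.norm(e)) ** 2)
        for row in xs:
            var_g = np.mean((xs @ row / np.linalg.norm(row)) ** 2)
            assert var_e >= var_g - 1e-9
        # sign convention: positively correlated with the mean profile
        assert np.corrcoef(e, xs.mean(axis=0))[0, 1] > 0

    def test_gene_permutation_permutes_labels(self):
        expr, sim, _ = _planted_network(seed=23)
        net1 = build_network(expr, sim.samples, min_module_size=80, beta=6)
        perm = np.random.default_rng(0).permutation(len(expr))
        net2 = build_network(expr.iloc[perm], sim.samples, min_module_size=80, beta=6)
        # same partition regardless of input order
        from sklearn.metrics import adjusted_rand_score

        common = net1.modules.index
        assert adjusted_rand_score(net1.modules[common], net2.modules[common]) == pytest.approx(1.0)


class TestModuleTrait:
    def _samples(self):
        return [
            SampleMeta(f"s{i}", tr, t)
            for i, (tr, t) in enumerate(
                [("control", 0), ("control", 24), ("NaCl", 24), ("NaCl", 48), ("PEG", 24)]
            )
        ]

    def test_indicator_eigengene_correlates_perfectly(self):
        samples = self._samples()
        eig = pd.DataFrame(
            {"M1": [0.0, 0.0, 1.0, 0.0, 0.0]}, index=[s.sample_id for s in samples]
        )
        cor, p = module_trait(eig, samples)
        assert cor.loc["M1", "NaCl_24h"] == pytest.approx(1.0)
        assert p.loc["M1", "NaCl_24h"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_trait_gives_zero(self):
        samples = self._samples()
        eig = pd.DataFrame(
            {"M1": [1.0, -1.0, 0.0, 0.0, 0.0]}, index=[s.sample_id for s in samples]
        )
        cor, _ = module_trait(eig, samples)
        assert cor.loc["M1", "PEG_24h"] == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_closed_form(self):
        rng = np.random.default_rng(11)
        samples = [
            SampleMeta(f"s{i}", tr, t)
            for i, (tr, t) in enumerate(
                [("control", 0), ("control", 24), ("control", 48), ("control", 72),
                 ("NaCl", 24), ("NaCl", 48), ("NaCl", 72),
                 ("PEG", 24), ("PEG", 48), ("PEG", 72)]
            )
        ]
        eig = pd.DataFrame({"M1": rng.normal(size=10)}, index=[s.sample_id for s in samples])
        cor, p = module_trait(eig, samples)
        n = 10
        for trait in cor.columns:
            r = cor.loc["M1", trait]
            tstat = r * np.sqrt((n - 2) / (1 - r * r))
            assert p.loc["M1", trait] == pytest.approx(2 * stats.t.sf(abs(tstat), n - 2), rel=1e-10)


@pytest.fixture(scope="module")
def network():
    expr, sim, _ = _planted_network(seed=11)
    return build_network(expr, sim.samples, min_module_size=80)


class TestHubScreen:
    def test_gs_mm_thresholds_strict(self, network):
        hub = hub_screen(network, gs_min=0.2, mm_min=0.8)
        for _, row in hub["hubs"].iterrows():
            g = row["gene_id"]
            assert network.gs.loc[g].abs().max() > 0.2
            assert abs(network.mm.loc[g, row["module"]]) > 0.8
            assert network.modules[g] == row["module"]  # hubs belong to their module

    def test_edge_counts_match_brute_force(self, network):
        hub = hub_screen(network, edge_weight_min=0.3)
        a = network.adjacency
        labels = network.modules
        for g in a.index[:50]:
            if labels[g] == GREY:
                assert hub["edge_count"][g] == 0
                continue
            members = [m for m in a.index if labels[m] == labels[g] and m != g]
            expected = sum(a.loc[g, m] >= 0.3 for m in members)
            assert hub["edge_count"][g] == expected

    def test_high_threshold_empties_edges(self, network):
        hub = hub_screen(network, edge_weight_min=1.01)
        assert len(hub["edges"]) == 0
        assert (hub["edge_count"] == 0).all()
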