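"""Neighbor graphs, Moran's I, diversity and fitness proxies."""

import numpy as np
import pandas as pd
import pytest

from editrace.matrix import CharacterMatrix
from editrace.reconstruct import weighted_hamming_matrix
from editrace.simulate import SimulationConfig, simulate_experiment
from editrace.spatial import (
    NeighborGraph,
    build_neighbor_graph,
    fitness_feature_correlation,
    local_lm_diversity,
    mean_neighbor_lm_distance,
    morans_i,
    morans_i_batch,
    pairwise_distance_table,
)
from editrace.tree import LineageTree


def positions_frame(coords, sections=None):
    cells = [f"c{i}" for i in range(len(coords))]
    df = pd.DataFrame(coords, columns=["x_um", "y_um"])
    df.insert(0, "cell", cells)
    if sections is not None:
        df["section"] = sections
    return df


class TestNeighborGraph:
    def test_spatial_radius(self):
        g = build_neighbor_graph(
            "spatial", positions=positions_frame([(0, 0), (50, 0), (200, 0)]),
            parameter=100,
        )
        assert g.n_edges == 1 and g.adjacency[0, 1] == 1

    def test_sections_never_connect(self):
        g = build_neighbor_graph(
            "spatial",
            positions=positions_frame([(0, 0), (10, 0)], sections=["s1", "s2"]),
            parameter=100,
        )
        assert g.n_edges == 0

    def test_phylo_window(self):
        tree = LineageTree.from_newick("((a:2,b:2):18,(c:20,d:20):0);")
        g = build_neighbor_graph("phylo", tree=tree, parameter=10)
        idx = {c: i for i, c in enumerate(g.cells)}
        assert g.adjacency[idx["a"], idx["b"]] == 1  # split 2 days ago
        assert g.adjacency[idx["a"], idx["c"]] == 0  # split 20 days ago

    def test_symmetry_and_no_self_edges(self):
        rng = np.random.default_rng(0)
        g = build_neighbor_graph(
            "spatial", positions=positions_frame(rng.uniform(0, 300, (40, 2))),
            parameter=80,
        )
        assert (g.adjacency == g.adjacency.T).all()
        assert np.diag(g.adjacency).sum() == 0


def naive_morans_i(values, W):
    x = np.asarray(values, dtype=float)
    z = (x - x.mean()) / x.std()
    n = z.size
    num = sum(
        W[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return n / W.sum() * num / (z**2).sum()


class TestMoransI:
    def test_two_clique_fixture_is_one(self):
        adj = np.zeros((8, 8))
        adj[:4, :4] = 1
        adj[4:, 4:] = 1
        np.fill_diagonal(adj, 0)
        g = NeighborGraph(adj, [f"c{i}" for i in range(8)], "spatial", 0)
        i_obs, p = morans_i(np.repeat([1.0, -1.0], 4), g, n_perm=500, seed=0)
        assert i_obs == pytest.approx(1.0)
        assert p < 0.05

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        pos = positions_frame(rng.uniform(0, 200, (n, 2)))
        g = build_neighbor_graph("spatial", positions=pos, parameter=80)
        vals = rng.normal(size=n)
        i_obs, _ = morans_i(vals, g, n_perm=0)
        assert i_obs == pytest.approx(naive_morans_i(vals, g.adjacency))

    def test_null_mean_matches_theory(self):
        """Random labels give E[I] = -1/(N-1)."""
        rng = np.random.default_rng(1)
        adj = np.zeros((10, 10))
        adj[:5, :5] = 1
        adj[5:, 5:] = 1
        np.fill_diagonal(adj, 0)
        g = NeighborGraph(adj, [f"c{i}" for i in range(10)], "spatial", 0)
        draws = [morans_i(rng.normal(size=10), g, n_perm=0)[0] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(-1 / 9, abs=0.01)

    def test_constant_values_are_nan(self):
        adj = 1 - np.eye(5)
        g = NeighborGraph(adj, list("abcde"), "spatial", 0)
        i_obs, p = morans_i(np.ones(5), g, n_perm=10)
        assert np.isnan(i_obs) and np.isnan(p)

    def test_batch_applies_bh(self):
        rng = np.random.default_rng(3)
        adj = np.zeros((30, 30))
        adj[:15, :15] = 1
        adj[15:, 15:] = 1
        np.fill_diagonal(adj, 0)
        g = NeighborGraph(adj, [f"c{i}" for i in range(30)], "spatial", 0)
        feats = pd.DataFrame(
            {
                "clustered": np.repeat([1.0, -1.0], 15) + rng.normal(0, 0.1, 30),
                "noise": rng.normal(size=30),
            }
        )
        out = morans_i_batch(feats, g, n_perm=200, seed=0)
        assert set(out["feature"]) == {"clustered", "noise"}
        clustered_q = out.loc[out["feature"] == "clustered", "q"].iloc[0]
        assert clustered_q < 0.05

    def test_heritable_trait_detected_on_phylo_graph(self):
        """A clade-indicator trait autocorrelates on the lineage graph."""
        cfg = SimulationConfig(n_cells=60, n_sites=30, detection_efficiency=1.0)
        tree, _, _, _ = simulate_experiment(cfg, 21)
        # a 60-cell tree spans ~7 days; a 2-day window keeps the graph sparse
        g = build_neighbor_graph("phylo", tree=tree, parameter=2)
        clade = tree.children(tree.root)[0]
        members = {str(x) for x in tree.leaf_sets()[clade]}
        trait = np.array([1.0 if c in members else -1.0 for c in g.cells])
        i_obs, p = morans_i(trait, g, n_perm=300, seed=0)
        assert i_obs > 0 and p < 0.05


class TestLocalDiversity:
    def test_clonal_neighborhood_zero(self):
        cm = CharacterMatrix.from_array(
            np.ones((5, 4), dtype=int), 8, cells=[f"c{i}" for i in range(5)]
        )
        pos = positions_frame([(0, 0), (10, 0), (0, 10), (10, 10), (5, 5)])
        div = local_lm_diversity(cm, pos, radius=100)
        assert (div == 0).all()

    def test_isolated_cell_is_nan(self):
        cm = CharacterMatrix.from_array(
            np.array([[1], [2], [3]]), 8, cells=["c0", "c1", "c2"]
        )
        pos = positions_frame([(0, 0), (10, 0), (1000, 1000)])
        div = local_lm_diversity(cm, pos, radius=100)
        assert np.isnan(div["c2"]) and div["c0"] > 0

    def test_matches_submatrix_oracle(self):
        rng = np.random.default_rng(5)
        n = 25
        arr = rng.integers(0, 4, size=(n, 8))
        cells = [f"c{i}" for i in range(n)]
        cm = CharacterMatrix.from_array(arr, 8, cells=cells)
        coords = rng.uniform(0, 150, (n, 2))
        pos = positions_frame(coords)
        div = local_lm_diversity(cm, pos, radius=60)
        dm = weighted_hamming_matrix(cm).values
        for i, cell in enumerate(cells):
            members = [
                j for j in range(n)
                if np.hypot(*(coords[i] - coords[j])) <= 60
            ]
            if len(members) < 2:
                assert np.isnan(div[cell])
                continue
            sub = dm[np.ix_(members, members)]
            expected = sub[np.triu_indices(len(members), k=1)].mean()
            assert div[cell] == pytest.approx(expected)


class TestFitnessProxy:
    def test_identical_cells_zero(self):
        cm = CharacterMatrix.from_array(np.ones((21, 3), dtype=int), 8)
        assert (mean_neighbor_lm_distance(cm, k=20) == 0).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        arr = rng.integers(0, 5, size=(30, 6))
        cm = CharacterMatrix.from_array(arr, 8)
        proxy = mean_neighbor_lm_distance(cm, k=5)
        dm = weighted_hamming_matrix(cm).values
        for i, cell in enumerate(cm.cells):
            d = np.delete(dm[i], i)
            idx = np.delete(np.arange(30), i)
            order = np.lexsort((idx, d))
            expected = d[order[:5]].mean()
            assert proxy[cell] == pytest.approx(expected)

    def test_recent_expansion_scores_fitter(self):
        """A fast-dividing clade accrues fewer marks per generation, so its
        cells sit closer to their nearest LM neighbors."""
        import networkx as nx

        from editrace.simulate import (
            overlay_lineage_marks,
            simulate_birth_death_with_retries,
        )

        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(n_cells=30, n_sites=40, edit_fraction=0.7)
            fast = simulate_birth_death_with_retries(cfg, 300 + seed)
            slow = simulate_birth_death_with_retries(cfg, 600 + seed)
            # same topology depth, but the fast clade's lifetimes are compressed
            graph = nx.DiGraph()
            for label, sub, scale in (("f", fast, 0.3), ("s", slow, 1.0)):
                for u, v, data in sub.graph.edges(data=True):
                    graph.add_edge(
                        f"{label}{u}", f"{label}{v}", length=data["length"] * scale
                    )
                graph.add_edge("root", f"{label}{sub.root}", length=1.0)
            from editrace.tree import LineageTree

            joint = LineageTree(graph, "root")
            times = joint.node_times()
            total = float(np.mean([times[l] for l in joint.leaves]))
            _, cm = overlay_lineage_marks(joint, cfg, 900 + seed, total_time=total)
            proxy = mean_neighbor_lm_distance(cm, k=10)
            fast_mean = proxy[[c for c in proxy.index if c.startswith("f")]].mean()
            slow_mean = proxy[[c for c in proxy.index if c.startswith("s")]].mean()
            wins += fast_mean < slow_mean
        assert wins >= 8

    def test_needs_more_cells_than_k(self):
        cm = CharacterMatrix.from_array(np.ones((5, 3), dtype=int), 8)
        with pytest.raises(ValueError):
            mean_neighbor_lm_distance(cm, k=10)


class TestPairwiseDistances:
    def _setup(self, seed=0, n=30):
        cfg = SimulationConfig(n_cells=n, n_sites=30, detection_efficiency=1.0)
        tree, _, cm, _ = simulate_experiment(cfg, seed)
        rng = np.random.default_rng(seed)
        cells = [str(l) for l in tree.leaves]
        pos = pd.DataFrame(
            {
                "cell": cells,
                "x_um": rng.uniform(0, 200, len(cells)),
                "y_um": rng.uniform(0, 200, len(cells)),
            }
        )
        return tree, cm, pos

    def test_all_pairs_when_few(self):
        tree, cm, pos = self._setup()
        table = pairwise_distance_table(tree, cm, pos, n_pairs=20000, seed=0)
        n = len(pos)
        assert len(table) == n * (n - 1) // 2
        assert not table.duplicated(["cell_a", "cell_b"]).any()

    def test_cherry_distance_is_terminal_branch_sum(self):
        tree = LineageTree.from_newick("((a:1.5,b:2.5):1,c:4);")
        cm = CharacterMatrix.from_array(
            np.array([[1], [1], [2]]), 8, cells=["a", "b", "c"]
        )
        pos = pd.DataFrame(
            {"cell": ["a", "b", "c"], "x_um": [0, 1, 2], "y_um": [0, 0, 0]}
        )
        table = pairwise_distance_table(tree, cm, pos, seed=0)
        row = table[(table["cell_a"] == "a") & (table["cell_b"] == "b")]
        assert row["phylo_distance"].iloc[0] == pytest.approx(4.0)

    def test_cross_section_pairs_excluded(self):
        tree, cm, pos = self._setup()
        pos["section"] = ["s1" if i % 2 else "s2" for i in range(len(pos))]
        table = pairwise_distance_table(tree, cm, pos, seed=0)
        sec = pos.set_index("cell")["section"]
        assert (sec[table["cell_a"]].values == sec[table["cell_b"]].values).all()


class TestFitnessCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        fitness = pd.Series(rng.normal(size=200))
        out = fitness_feature_correlation(fitness, pd.DataFrame({"self": fitness}))
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_planted_anticorrelation_significant(self):
        rng = np.random.default_rng(1)
        fitness = pd.Series(rng.normal(size=500))
        feats = pd.DataFrame(
            {
                "anti": -fitness + rng.normal(0, 0.5, 500),
                "noise": rng.normal(size=500),
            }
        )
        out = fitness_feature_correlation(fitness, feats).set_index("feature")
        assert out.loc["anti", "pearson_r"] < 0
        assert out.loc["anti", "q"] < 0.05
        assert abs(out.loc["noise", "pearson_r"]) < 0.15
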