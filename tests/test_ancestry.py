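"""Ancestral-state inference, branch collapse, timing, growth counts."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import random_tree
from editrace.ancestry import (
    TransitionCosts,
    collapse_unsupported_branches,
    estimate_branch_lengths,
    extant_counts,
    lca_timing,
    lm_installation_efficiency,
    sankoff_ancestral_states,
    sankoff_total_cost,
)
from editrace.matrix import MISSING, UNEDITED, CharacterMatrix
from editrace.simulate import (
    SimulationConfig,
    edit_rate_for_target_fraction,
    simulate_experiment,
)
from editrace.tree import LineageTree


def exhaustive_min_cost(tree, cm, costs=TransitionCosts()):
    """Brute-force minimum total cost over all internal assignments with an
    all-unedited root."""
    n_states = cm.n_marks + 1
    cost = costs.matrix(n_states)
    internals = [n for n in tree.nodes if not tree.is_leaf(n) and n != tree.root]
    total = 0.0
    for site in range(cm.n_sites):
        obs = {c: cm.data.loc[c].iloc[site] for c in cm.cells}
        best = math.inf
        for combo in itertools.product(range(n_states), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            assign[tree.root] = UNEDITED
            c_tot = 0.0
            feasible = True
            for node in tree.nodes:
                if node == tree.root:
                    continue
                parent_state = assign[tree.parent(node)]
                if tree.is_leaf(node):
                    leaf_state = obs[str(node)]
                    if leaf_state == MISSING:
                        c_tot += min(cost[parent_state, s] for s in range(n_states))
                    else:
                        c_tot += cost[parent_state, leaf_state]
                else:
                    c_tot += cost[parent_state, assign[node]]
            best = min(best, c_tot)
        total += best
    return total


class TestSankoff:
    def test_shared_mark_installed_once_below_root(self):
        cm = CharacterMatrix.from_array(np.array([[3], [3], [3]]), 4, cells=list("abc"))
        tree = LineageTree.from_newick("((a,b),c);")
        states = sankoff_ancestral_states(tree, cm)
        inner = tree.lca(["a", "b"])
        assert states[inner][0] == 3
        assert states[tree.root][0] == UNEDITED
        assert sankoff_total_cost(tree, states, n_marks=4) == pytest.approx(1.2)

    def test_cherry_prefers_unedited_parent(self):
        """Installing (0.6) beats erasing (1.0), so the parent stays unedited."""
        cm = CharacterMatrix.from_array(np.array([[UNEDITED], [1]]), 4, cells=["a", "b"])
        tree = LineageTree.from_newick("(a,b);")
        states = sankoff_ancestral_states(tree, cm)
        assert states[tree.root][0] == UNEDITED
        assert sankoff_total_cost(tree, states, n_marks=4) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(6))
    def test_total_cost_equals_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        tree = random_tree(rng, n, multifurcate=bool(seed % 2))
        arr = rng.integers(-1, 4, size=(n, 3))
        cm = CharacterMatrix.from_array(
            arr, 3, cells=[str(l) for l in sorted(tree.leaves, key=str)]
        )
        states = sankoff_ancestral_states(tree, cm)
        got = sankoff_total_cost(tree, states, n_marks=3)
        assert got == pytest.approx(exhaustive_min_cost(tree, cm), abs=1e-9)

    def test_leaf_matrix_mismatch_raises(self):
        tree = LineageTree.from_newick("((a,b),c);")
        cm = CharacterMatrix.from_array(np.zeros((2, 1), dtype=int), 4, cells=["a", "b"])
        with pytest.raises(ValueError):
            sankoff_ancestral_states(tree, cm)


class TestCollapse:
    def _states(self, tree, mapping):
        return {n: np.array(mapping[str(n)]) for n in tree.nodes}

    def test_saturated_clades_untouched(self):
        tree = LineageTree.from_newick("((a,b)x,(c,d)y)r;")
        states = self._states(
            tree,
            {"r": [0], "x": [1], "y": [2], "a": [1], "b": [1], "c": [2], "d": [2]},
        )
        collapsed, _ = collapse_unsupported_branches(tree, states)
        assert len(collapsed.nodes) == len(tree.nodes)

    def test_markless_interior_becomes_multifurcation(self):
        tree = LineageTree.from_newick("((a,b)x,c)r;")
        states = self._states(tree, {"r": [0], "x": [0], "a": [0], "b": [0], "c": [0]})
        collapsed, _ = collapse_unsupported_branches(tree, states)
        assert collapsed.children(collapsed.root) and len(
            collapsed.children(collapsed.root)
        ) == 3

    def test_mixed_case_matches_manual_rule(self):
        tree = LineageTree.from_newick("(((a,b)x,(c,d)y)z,(e,f)w)r;")
        states = self._states(
            tree,
            {
                "r": [0], "z": [1], "w": [2],
                "x": [1],  # same as z -> contract
                "y": [3],
                "a": [1], "b": [1], "c": [3], "d": [3], "e": [2], "f": [2],
            },
        )
        collapsed, _ = collapse_unsupported_branches(tree, states)
        z_kids = {str(k) for k in collapsed.children("z")}
        assert z_kids == {"a", "b", "y"}

    def test_collapse_idempotent_and_supported(self, small_experiment):
        _, tree, _, truth_cm, _ = small_experiment
        from editrace.reconstruct import reconstruct_nj, weighted_hamming_matrix

        rec = reconstruct_nj(weighted_hamming_matrix(truth_cm), truth_cm)
        states = sankoff_ancestral_states(rec, truth_cm)
        once, st1 = collapse_unsupported_branches(rec, states)
        twice, _ = collapse_unsupported_branches(once, st1)
        assert set(once.nodes) == set(twice.nodes)
        for node in once.nodes:
            if node == once.root or once.is_leaf(node):
                continue
            assert not np.array_equal(st1[once.parent(node)], st1[node])
        assert set(once.leaves) == set(rec.leaves)


class TestBranchLengths:
    def test_closed_form_edge_duration(self):
        # u=10 unedited sites, k=5 edited on the edge, rate 0.1:
        # raw duration = -ln(0.5)/0.1 ~ 6.93 before rescaling
        tree = LineageTree.from_newick("(a,b)r;")
        states = {
            "r": np.zeros(10, dtype=int),
            "a": np.concatenate([np.ones(5, dtype=int), np.zeros(5, dtype=int)]),
            "b": np.zeros(10, dtype=int),
        }
        raw = -math.log(0.5) / 0.1
        out = estimate_branch_lengths(tree, states, rate=0.1, total_time=raw)
        times = out.node_times(include_root_length=False)
        mean_path = np.mean([times[l] for l in out.leaves])
        assert mean_path == pytest.approx(raw, abs=1e-9)

    def test_editless_tree_all_floor_rescaled(self):
        tree = LineageTree.from_newick("((a,b)x,c)r;")
        states = {n: np.zeros(4, dtype=int) for n in tree.nodes}
        out = estimate_branch_lengths(tree, states, rate=0.05, total_time=12.0)
        times = out.node_times(include_root_length=False)
        lengths = {out.branch_length(n) for n in out.nodes if n != out.root}
        assert len(lengths) == 1  # every edge at the shared floor
        assert np.mean([times[l] for l in out.leaves]) == pytest.approx(12.0)

    def test_mean_path_equals_duration(self, small_experiment):
        cfg, tree, states, truth_cm, _ = small_experiment
        rate = edit_rate_for_target_fraction(cfg.edit_fraction, 16.0)
        out = estimate_branch_lengths(tree, states, rate, total_time=16.0)
        times = out.node_times(include_root_length=False)
        assert np.mean([times[l] for l in out.leaves]) == pytest.approx(16.0, abs=1e-9)

    def test_duration_recovery_correlates(self):
        """Estimated edge durations track the simulated truth."""
        rhos = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_cells=80, n_sites=40, edit_fraction=0.7, detection_efficiency=1.0
            )
            tree, states, _, _ = simulate_experiment(cfg, seed)
            times = tree.node_times()
            total = float(np.mean([times[l] for l in tree.leaves]))
            rate = edit_rate_for_target_fraction(0.7, total)
            est = estimate_branch_lengths(tree, states, rate, total)
            true_d, est_d = [], []
            for u, v in tree.graph.edges:
                true_d.append(tree.graph.edges[u, v]["length"])
                est_d.append(est.graph.edges[u, v]["length"])
            rhos.append(spearmanr(true_d, est_d).statistic)
        assert np.median(rhos) > 0.5


class TestTiming:
    def test_whole_population_lca_is_root(self, balanced8):
        for node in balanced8.nodes:
            if node != balanced8.root:
                balanced8.set_branch_length(node, 1.0)
        assert lca_timing(balanced8, {str(l) for l in balanced8.leaves}) == 0.0

    def test_cherry_timing_in_rescaled_tree(self):
        tree = LineageTree.from_newick("(((a:1,b:1)p:15,c:16)q:0,d:16)r;")
        assert lca_timing(tree, {"a", "b"}) == pytest.approx(15.0)

    def test_barcode_rounds_ordered(self):
        """Earlier barcoding rounds map to earlier inferred LCA times."""
        from editrace.evaluate import best_lca_clade
        from editrace.reconstruct import reconstruct_nj, weighted_hamming_matrix
        from editrace.simulate import plant_barcode_groups

        ordered = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_cells=100, n_sites=40, edit_fraction=0.7, detection_efficiency=1.0
            )
            tree, _, truth_cm, obs = simulate_experiment(cfg, seed)
            times = tree.node_times()
            total = float(np.mean([times[l] for l in tree.leaves]))
            early = plant_barcode_groups(tree, 5 / 16 * total, "e")
            late = plant_barcode_groups(tree, 7 / 16 * total, "l")
            rec = reconstruct_nj(weighted_hamming_matrix(obs), obs)
            st = sankoff_ancestral_states(rec, obs)
            coll, st = collapse_unsupported_branches(rec, st)
            timed = estimate_branch_lengths(
                coll, st, edit_rate_for_target_fraction(0.7, total), total
            )
            t_early = np.mean(
                [lca_timing(timed, {c for c, g in early.items() if g == lab})
                 for lab in set(early.values())]
            )
            t_late = np.mean(
                [lca_timing(timed, {c for c, g in late.items() if g == lab})
                 for lab in set(late.values())]
            )
            ordered += t_early < t_late
        assert ordered >= 8


class TestExtantCounts:
    def test_boundary_counts(self):
        cfg = SimulationConfig(n_cells=30, death_rate=0.0)
        from editrace.simulate import simulate_birth_death

        tree = simulate_birth_death(cfg, 5)
        tmax = max(tree.node_times().values())
        table = extant_counts(tree, [0.0, tmax])
        assert table["extant"].tolist() == [1, 30]

    def test_pure_birth_log_linear_growth(self):
        from editrace.simulate import simulate_birth_death

        tree = simulate_birth_death(SimulationConfig(n_cells=60, death_rate=0.0), 5)
        tmax = max(tree.node_times().values())
        ts = np.linspace(0, tmax, 12)
        counts = extant_counts(tree, ts)["extant"].to_numpy()
        assert (np.diff(counts) >= 0).all()
        logc = np.log(counts)
        fit = np.polyfit(ts, logc, 1)
        resid = logc - np.polyval(fit, ts)
        r2 = 1 - resid.var() / logc.var()
        assert r2 > 0.9

    def test_out_of_range_raises(self, balanced8):
        for node in balanced8.nodes:
            if node != balanced8.root:
                balanced8.set_branch_length(node, 1.0)
        with pytest.raises(ValueError):
            extant_counts(balanced8, [99.0])


class TestInstallationEfficiency:
    def test_single_mark_site(self):
        tree = LineageTree.from_newick("((a,b)x,c)r;")
        states = {
            "r": np.array([0]), "x": np.array([2]),
            "a": np.array([2]), "b": np.array([2]), "c": np.array([0]),
        }
        eff = lm_installation_efficiency(tree, states, 4)
        assert eff.iloc[0].to_numpy() == pytest.approx([0, 1, 0, 0])

    def test_rows_sum_to_one_and_recover_distribution(self):
        from editrace.simulate import lm_distribution_for_entropy

        dist = lm_distribution_for_entropy(8, 0.95)
        cfg = SimulationConfig(
            n_cells=800, n_sites=25, n_marks=8, lm_distribution=dist, edit_fraction=0.7
        )
        tree, states, _, _ = simulate_experiment(cfg, 7)
        eff = lm_installation_efficiency(tree, states, 8)
        sums = eff.sum(axis=1, skipna=False).dropna()
        assert np.allclose(sums, 1.0)
        pooled = eff.mean(axis=0).to_numpy()
        assert np.nanmax(np.abs(pooled - dist.probs)) < 0.05
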