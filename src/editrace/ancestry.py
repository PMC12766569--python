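"""Ancestral lineage-mark inference and tree timing.

Sankoff dynamic programming with asymmetric transition costs infers per-node
LM states (the root is constrained to the all-unedited day-0 state); edges
gaining no mark are collapsed; branch durations are then estimated from the
number of sites edited per edge under a constant-rate irreversible-editing
model and rescaled so the mean root-to-leaf path equals the tracing
duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import MISSING, UNEDITED, CharacterMatrix
from .tree import LineageTree

__all__ = [
    "TransitionCosts",
    "sankoff_ancestral_states",
    "sankoff_total_cost",
    "collapse_unsupported_branches",
    "estimate_branch_lengths",
    "lca_timing",
    "extant_counts",
    "lm_installation_efficiency",
]


@dataclass(frozen=True)
class TransitionCosts:
    """Asymmetric per-site transition costs for ancestral inference.

    Installing a mark at an unedited site is cheap (0.6); losing a mark or
    switching between marks is expensive (1), reflecting irreversible editing
    with some tolerance for readout error.
    """

    install: float = 0.6
    erase_or_switch: float = 1.0

    def matrix(self, n_states: int) -> np.ndarray:
        """Dense cost matrix over states {0=unedited, 1..S=marks}."""
        c = np.full((n_states, n_states), self.erase_or_switch)
        np.fill_diagonal(c, 0.0)
        c[0, 1:] = self.install
        return c


def sankoff_ancestral_states(
    tree: LineageTree,
    cm: CharacterMatrix,
    costs: TransitionCosts = TransitionCosts(),
) -> Dict[object, np.ndarray]:
    """Minimum-cost ancestral states per node, per edit site.

    Leaves take their observed states (missing entries contribute zero cost
    for every state).  The root is fixed to all-unedited; the top-down
    backtrace picks, for each child, the state minimizing transition plus
    subtree cost (ties resolve to unedited, then the lowest mark index).
    """
    leaf_names = {str(l) for l in tree.leaves}
    if not leaf_names <= set(cm.cells):
        raise ValueError("character matrix does not cover all leaves")
    n_states = cm.n_marks + 1
    cost = costs.matrix(n_states)
    nodes = list(tree.postorder())
    obs = {c: cm.data.loc[c].to_numpy() for c in cm.cells}
    M = cm.n_sites
    inf = np.inf

    # bottom-up: S[node] has shape (M, n_states) = min subtree cost per state
    S: Dict[object, np.ndarray] = {}
    for node in nodes:
        kids = tree.children(node)
        if not kids:
            row = obs[str(node)]
            s = np.full((M, n_states), inf)
            missing = row == MISSING
            s[missing, :] = 0.0
            present = ~missing
            s[present, row[present]] = 0.0
            S[node] = s
        else:
            acc = np.zeros((M, n_states))
            for k in kids:
                # min over child state of cost(parent_state -> child_state) + S[k]
                acc += (S[k][:, None, :] + cost[None, :, :]).min(axis=2)
            S[node] = acc

    # top-down backtrace from the fixed all-unedited root
    states: Dict[object, np.ndarray] = {tree.root: np.zeros(M, dtype=int)}
    order = [n for n in tree.preorder()]
    for node in order:
        if node == tree.root:
            continue
        parent_state = states[tree.parent(node)]
        if not tree.children(node):
            row = obs[str(node)].copy()
            # a missing leaf inherits the cheapest state given its parent
            missing = row == MISSING
            if missing.any():
                total = cost[parent_state[missing], :]  # (m, n_states)
                row[missing] = np.argmin(total, axis=1)
            states[node] = row
            continue
        total = cost[parent_state, :] + S[node][np.arange(M), :]
        states[node] = np.argmin(total, axis=1)
    return states


def sankoff_total_cost(
    tree: LineageTree,
    states: Dict[object, np.ndarray],
    costs: TransitionCosts = TransitionCosts(),
    n_marks: Optional[int] = None,
) -> float:
    """Total transition cost of an assignment (missing leaves cost 0)."""
    n_states = (n_marks or int(max(v.max() for v in states.values()))) + 1
    cost = costs.matrix(n_states)
    total = 0.0
    for node in tree.preorder():
        if node == tree.root:
            continue
        p = states[tree.parent(node)]
        c = states[node]
        total += cost[p, c].sum()
    return float(total)


def collapse_unsupported_branches(
    tree: LineageTree, states: Dict[object, np.ndarray]
) -> Tuple[LineageTree, Dict[object, np.ndarray]]:
    """Contract internal edges whose endpoints share identical state vectors.

    The result may be multifurcating; leaves are never removed.  Collapsing
    is idempotent: a second pass finds nothing to contract.
    """
    graph = tree.graph.copy()
    root = tree.root
    for node in list(tree.postorder()):
        if node == root or node not in graph:
            continue
        if graph.out_degree(node) == 0:
            continue  # leaves stay
        parent = next(graph.predecessors(node))
        if np.array_equal(states[parent], states[node]):
            for child in list(graph.successors(node)):
                attrs = graph.edges[node, child]
                graph.add_edge(parent, child, **attrs)
            graph.remove_node(node)
    new_tree = LineageTree(graph, root, tree.root_length)
    new_states = {n: states[n] for n in graph.nodes}
    new_tree.states = new_states
    return new_tree, new_states


def estimate_branch_lengths(
    tree: LineageTree,
    states: Dict[object, np.ndarray],
    rate: float,
    total_time: float,
) -> LineageTree:
    """Per-edge durations from edit counts under a constant editing rate.

    For an edge whose parent carries ``u`` unedited sites of which ``k``
    gain a mark on the edge, the duration is ``-ln(max(1 - k/u, eps))/rate``
    with ``eps = 1/(2u)`` guarding fully saturating edges; edges with no
    unedited exposure get the smallest positive estimated duration.  The
    whole tree is rescaled so the mean root-to-leaf path equals
    ``total_time`` days.
    """
    if total_time <= 0:
        raise ValueError("total_time must be > 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    graph = tree.graph.copy()
    raw: Dict[Tuple[object, object], Optional[float]] = {}
    for u_node, v_node in graph.edges:
        p = states[u_node]
        c = states[v_node]
        exposure = int((p == UNEDITED).sum())
        if exposure == 0:
            raw[(u_node, v_node)] = None
            continue
        k = int(((p == UNEDITED) & (c != UNEDITED)).sum())
        eps = 1.0 / (2.0 * exposure)
        frac = max(1.0 - k / exposure, eps)
        raw[(u_node, v_node)] = -math.log(frac) / rate

    # zero-edit and zero-exposure edges share the smallest positive duration
    positive = [d for d in raw.values() if d is not None and d > 0]
    floor = min(positive) if positive else 1.0
    for edge, d in raw.items():
        graph.edges[edge]["length"] = d if (d is not None and d > 0) else floor

    new_tree = LineageTree(graph, tree.root)
    times = new_tree.node_times(include_root_length=False)
    leaves = new_tree.leaves
    mean_path = float(np.mean([times[l] for l in leaves]))
    scale = total_time / mean_path
    for u_node, v_node in graph.edges:
        graph.edges[u_node, v_node]["length"] *= scale
    out = LineageTree(graph, tree.root)
    out.states = {n: states[n] for n in graph.nodes}
    return out


def lca_timing(tree: LineageTree, group: Iterable[str]) -> float:
    """Days from the root to the best-FMI clade ancestor of a cell group."""
    from .evaluate import best_lca_clade

    node, _ = best_lca_clade(tree, group)
    times = tree.node_times(include_root_length=False)
    return float(times[node])


def extant_counts(
    tree: LineageTree,
    timepoints: Sequence[float],
    clades: Optional[Dict[str, Iterable[str]]] = None,
) -> pd.DataFrame:
    """Number of lineages alive at each timepoint, per clade.

    A lineage is alive at time t when its edge spans t (parent time <= t <
    own time); leaves are extant cells, so they stay counted from their
    birth onward.  The founder stem (``root_length``) contributes a single
    lineage before the first division.
    """
    times = tree.node_times()
    t_max = max(times.values())
    clades = clades or {"all": [str(l) for l in tree.leaves]}
    leaf_sets = tree.leaf_sets()
    rows = []
    for name, members in clades.items():
        members = {str(m) for m in members}
        anc = tree.lca([l for l in tree.leaves if str(l) in members])
        sub_nodes = [n for n, ls in leaf_sets.items() if ls <= leaf_sets[anc]]
        sub_nodes = set(sub_nodes)
        for t in timepoints:
            if t < 0 or t > t_max:
                raise ValueError(f"timepoint {t} outside [0, {t_max}]")
            count = 0
            for node in sub_nodes:
                start = (
                    times[node] - (tree.root_length or 0.0)
                    if node == tree.root
                    else times[tree.parent(node)]
                )
                end = times[node]
                alive = start <= t if tree.is_leaf(node) else start <= t < end
                # zero-length stems: the root division at t=0 counts once
                if node == tree.root and start == end:
                    alive = False
                if alive:
                    count += 1
            rows.append({"clade": name, "time": float(t), "extant": count})
    return pd.DataFrame(rows)


def lm_installation_efficiency(
    tree: LineageTree, states: Dict[object, np.ndarray], n_marks: int
) -> pd.DataFrame:
    """Per-site LM usage from unedited->LM transitions along branches.

    For each edit site, counts transitions out of the unedited state into
    each mark over all edges, divides by the unedited-parent exposures, and
    normalizes across marks to sum to 1.  Sites with zero exposure are
    reported as NaN.
    """
    M = next(iter(states.values())).size
    counts = np.zeros((M, n_marks))
    exposures = np.zeros(M)
    for node in tree.preorder():
        if node == tree.root:
            continue
        p = states[tree.parent(node)]
        c = states[node]
        was_unedited = p == UNEDITED
        exposures += was_unedited
        gained = was_unedited & (c > 0)
        for site in np.flatnonzero(gained):
            counts[site, c[site] - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / counts.sum(axis=1, keepdims=True)
    probs[exposures == 0] = np.nan
    return pd.DataFrame(
        probs,
        index=[f"site{j}" for j in range(M)],
        columns=[f"LM_{i + 1}" for i in range(n_marks)],
    )
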