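"""Joint spatial-lineage statistics.

Neighbor graphs are binary and symmetric: phylogenetic neighbors share a
lowest common ancestor within a recent time window (default 10 days);
spatial neighbors lie within a radius (default 100 um) in the same section.
Moran's I over such a graph measures heritability (phylo graph) or spatial
coherence (spatial graph) of a per-cell value; significance comes from a
one-sided permutation test with Benjamini-Hochberg correction across a
feature batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .reconstruct import weighted_hamming_matrix
from .tree import LineageTree

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "morans_i",
    "morans_i_batch",
    "local_lm_diversity",
    "mean_neighbor_lm_distance",
    "pairwise_distance_table",
    "fitness_feature_correlation",
]


@dataclass
class NeighborGraph:
    """Symmetric 0/1 connectivity over cells, no self-edges."""

    adjacency: np.ndarray
    cells: list
    kind: str
    parameter: float

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if (a != a.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("no self-edges allowed")
        self.adjacency = a.astype(float)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def build_neighbor_graph(
    kind: str,
    tree: Optional[LineageTree] = None,
    positions: Optional[pd.DataFrame] = None,
    parameter: float = None,
) -> NeighborGraph:
    """Binary neighbor graph, phylogenetic-window or spatial-radius.

    ``kind='phylo'``: cells are neighbors when both lie within ``parameter``
    days of their LCA (default 10).  ``kind='spatial'``: cells are neighbors
    within ``parameter`` um (default 100) in the x-y plane; pairs from
    different sections are never connected.  ``positions`` columns: cell,
    x_um, y_um, optional section.
    """
    if kind == "phylo":
        if tree is None:
            raise ValueError("phylo graph needs a tree")
        window = 10.0 if parameter is None else float(parameter)
        times = tree.node_times()
        leaves = sorted(tree.leaves, key=str)
        n = len(leaves)
        adj = np.zeros((n, n))
        # pairwise LCA times via per-node leaf sets
        leaf_idx = {l: i for i, l in enumerate(leaves)}
        t_leaf = np.array([times[l] for l in leaves])
        for node, ls in tree.leaf_sets().items():
            if tree.is_leaf(node):
                continue
            kids = tree.children(node)
            kid_sets = [tree.leaf_sets()[k] for k in kids]
            for a in range(len(kid_sets)):
                for b in range(a + 1, len(kid_sets)):
                    ia = [leaf_idx[x] for x in kid_sets[a]]
                    ib = [leaf_idx[x] for x in kid_sets[b]]
                    for i in ia:
                        for j in ib:
                            ok = (t_leaf[i] - times[node] <= window) and (
                                t_leaf[j] - times[node] <= window
                            )
                            if ok:
                                adj[i, j] = adj[j, i] = 1.0
        return NeighborGraph(adj, [str(l) for l in leaves], "phylo", window)
    if kind == "spatial":
        if positions is None:
            raise ValueError("spatial graph needs positions")
        radius = 100.0 if parameter is None else float(parameter)
        cells = list(positions["cell"])
        xy = positions[["x_um", "y_um"]].to_numpy(dtype=float)
        section = (
            positions["section"].to_numpy()
            if "section" in positions.columns
            else np.zeros(len(cells))
        )
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        adj = (dist <= radius) & (section[:, None] == section[None, :])
        np.fill_diagonal(adj, False)
        return NeighborGraph(adj.astype(float), cells, "spatial", radius)
    raise ValueError(f"unknown graph kind {kind!r}")


def morans_i(
    values: Sequence[float],
    graph: NeighborGraph,
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Moran's I with a one-sided permutation p-value.

    ``I = N / sum(w) * sum_ij w_ij x_i x_j / sum_i x_i^2`` over z-scored
    values.  p = (1 + #{I_perm >= I_obs}) / (1 + n_perm).  Constant values
    yield (nan, nan).
    """
    x = np.asarray(values, dtype=float)
    W = graph.adjacency
    if x.size != W.shape[0]:
        raise ValueError("values do not match graph size")
    if x.size < 3 or W.sum() == 0:
        raise ValueError("need >= 3 cells and a nonempty graph")
    if np.isclose(x.std(), 0.0):
        return float("nan"), float("nan")
    z = (x - x.mean()) / x.std()

    def stat(v: np.ndarray) -> float:
        return float(v.size / W.sum() * (v @ W @ v) / (v @ v))

    i_obs = stat(z)
    if n_perm <= 0:
        return i_obs, float("nan")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    num = ((perms @ W) * perms).sum(axis=1)
    stats = z.size / W.sum() * num / (perms**2).sum(axis=1)
    p = (1 + int((stats >= i_obs).sum())) / (1 + n_perm)
    return i_obs, float(p)


def morans_i_batch(
    features: pd.DataFrame,
    graph: NeighborGraph,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I per feature column with BH-adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    rows = []
    for col in features.columns:
        i_val, p = morans_i(
            features[col].to_numpy(), graph, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append({"feature": col, "morans_i": i_val, "p": p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def local_lm_diversity(
    cm: CharacterMatrix,
    positions: pd.DataFrame,
    radius: float = 100.0,
    include_focal: bool = True,
) -> pd.Series:
    """Mean pairwise LM distance among each cell's spatial neighborhood.

    Neighborhood = cells within ``radius`` um (same section), including the
    focal cell by default; neighborhoods with fewer than two members give
    NaN.
    """
    graph = build_neighbor_graph("spatial", positions=positions, parameter=radius)
    order = [c for c in graph.cells]
    dm = weighted_hamming_matrix(cm.subset_cells(order)).values
    out = {}
    A = graph.adjacency.astype(bool)
    for i, cell in enumerate(order):
        members = list(np.flatnonzero(A[i]))
        if include_focal:
            members.append(i)
        if len(members) < 2:
            out[cell] = np.nan
            continue
        sub = dm[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        out[cell] = float(sub[iu].mean())
    return pd.Series(out, name="local_lm_diversity")


def mean_neighbor_lm_distance(cm: CharacterMatrix, k: int = 20) -> pd.Series:
    """Tree-independent fitness proxy: mean LM distance to the k most
    similar cells (ties at the k-th rank break on cell order).  Lower values
    indicate recent clonal expansion, hence higher fitness.
    """
    if cm.n_cells <= k:
        raise ValueError("need more cells than k")
    dm = weighted_hamming_matrix(cm).values
    out = {}
    n = cm.n_cells
    for i in range(n):
        d = dm[i].copy()
        order = np.lexsort((np.arange(n), d))  # distance, then cell order
        neighbors = [j for j in order if j != i][:k]
        out[cm.cells[i]] = float(d[neighbors].mean())
    return pd.Series(out, name="mean_neighbor_lm_distance")


def pairwise_distance_table(
    tree: LineageTree,
    cm: CharacterMatrix,
    positions: pd.DataFrame,
    n_pairs: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetic, LM and spatial distance for sampled cell pairs.

    Pairs are sampled without replacement (all pairs when fewer than
    ``n_pairs`` exist); cross-section pairs are excluded.  Phylogenetic
    distance is the total path time from the pair's LCA to both cells.  A
    shuffled-position control distance accompanies every pair.
    """
    rng = np.random.default_rng(seed)
    pos = positions.set_index("cell")
    cells = [str(l) for l in tree.leaves if str(l) in pos.index and str(l) in cm.cells]
    section = (
        pos["section"] if "section" in pos.columns else pd.Series(0, index=pos.index)
    )
    pairs = [
        (a, b)
        for i, a in enumerate(cells)
        for b in cells[i + 1 :]
        if section[a] == section[b]
    ]
    if len(pairs) > n_pairs:
        chosen = rng.choice(len(pairs), size=n_pairs, replace=False)
        pairs = [pairs[i] for i in chosen]
    dm = weighted_hamming_matrix(cm.subset_cells(cells))
    dmap = {c: i for i, c in enumerate(cells)}
    times = tree.node_times()
    shuffled = dict(zip(cells, [cells[i] for i in rng.permutation(len(cells))]))
    xy = pos[["x_um", "y_um"]]

    rows = []
    for a, b in pairs:
        anc = tree.lca([a, b])
        phylo = (times[a] - times[anc]) + (times[b] - times[anc])
        spatial = float(np.hypot(*(xy.loc[a] - xy.loc[b])))
        sa, sb = shuffled[a], shuffled[b]
        spatial_shuffled = float(np.hypot(*(xy.loc[sa] - xy.loc[sb])))
        rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "phylo_distance": float(phylo),
                "lm_distance": float(dm.values[dmap[a], dmap[b]]),
                "spatial_distance": spatial,
                "spatial_distance_shuffled": spatial_shuffled,
            }
        )
    return pd.DataFrame(rows)


def fitness_feature_correlation(
    fitness: pd.Series, features: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of a fitness score against each feature.

    Two-sided t-test p-values, BH-adjusted across the feature battery;
    features with fewer than 3 complete pairs are skipped.
    """
    from scipy.stats import pearsonr
    from statsmodels.stats.multitest import multipletests

    rows = []
    for col in features.columns:
        joined = pd.concat([fitness, features[col]], axis=1).dropna()
        if len(joined) < 3:
            continue
        r, p = pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append({"feature": col, "pearson_r": float(r), "p": float(p), "n": len(joined)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
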