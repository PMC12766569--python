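"""Distance computation and tree reconstruction from character matrices.

The pairwise dissimilarity is a weighted Hamming distance over edit sites:
per site the cost is 0 when the states match or either is missing, 1 when
exactly one cell is unedited, and 2 when both carry different lineage marks
(shared edits thus count double relative to presence/absence, the usual
convention for irreversible recorders).  The sum is divided by the number of
sites detected in both cells.

Neighbor joining (scikit-bio) and UPGMA (scipy average linkage) operate on
this matrix; NJ trees are rooted with a synthetic all-unedited outgroup that
is removed afterwards.  The greedy splitter recursively partitions cells on
the most frequent (site, mark) pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import MISSING, UNEDITED, CharacterMatrix
from .tree import LineageTree

__all__ = [
    "DistanceMatrix",
    "weighted_hamming_matrix",
    "reconstruct_nj",
    "reconstruct_upgma",
    "reconstruct_greedy",
]

_ROOT_SENTINEL = "__unedited_outgroup__"


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative cell-by-cell distances with a zero diagonal."""

    values: np.ndarray
    ids: List[str]
    #: (i, j) id pairs that shared no detected site and received the
    #: max-finite+1 sentinel distance
    undetected_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(v).any():
            raise ValueError("diagonal must be zero")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("entries must be finite and nonnegative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.ids)


def weighted_hamming_matrix(
    cm: CharacterMatrix, site_weights: Optional[Sequence[float]] = None
) -> DistanceMatrix:
    """Weighted Hamming distance matrix between all cell pairs.

    ``site_weights`` multiply the per-site cost and contribute their weight
    (rather than 1) to the normalizing count of co-detected sites.  Pairs
    with no co-detected site are assigned the maximum finite distance plus 1
    and recorded in ``undetected_pairs``.
    """
    if cm.n_cells < 2:
        raise ValueError("need at least 2 cells")
    arr = cm.values
    if site_weights is None:
        w = np.ones(cm.n_sites)
    else:
        w = np.asarray(site_weights, dtype=float)
        if w.shape != (cm.n_sites,) or (w <= 0).any():
            raise ValueError("site weights must be positive, one per site")

    detected = arr != MISSING
    unedited = arr == UNEDITED
    n = cm.n_cells
    dist = np.zeros((n, n))
    lmat = np.zeros((n, n))
    for i in range(n):
        both = detected[i] & detected  # (n, M)
        mismatch = (arr[i] != arr) & both
        one_unedited = (unedited[i] | unedited) & mismatch
        delta = np.where(mismatch, np.where(one_unedited, 1.0, 2.0), 0.0)
        dist[i] = (delta * w).sum(axis=1)
        lmat[i] = (both * w).sum(axis=1)

    undetected = []
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(lmat > 0, dist / np.where(lmat > 0, lmat, 1.0), np.nan)
    np.fill_diagonal(out, 0.0)
    if np.isnan(out).any():
        finite_max = np.nanmax(out)
        ii, jj = np.where(np.isnan(out))
        for a, b in zip(ii, jj):
            if a < b:
                undetected.append((cm.cells[a], cm.cells[b]))
        out = np.where(np.isnan(out), finite_max + 1.0, out)
        warnings.warn(
            f"{len(undetected)} cell pair(s) share no detected site; assigned "
            "max-finite+1 distance"
        )
    return DistanceMatrix(out, list(cm.cells), undetected)


# ----------------------------------------------------------------------
# skbio/scipy tree conversions
# ----------------------------------------------------------------------

def _skbio_to_lineage_tree(sk_tree) -> LineageTree:
    graph = nx.DiGraph()
    counter = itertools.count()
    names = {}

    def name_of(node):
        if node.name is not None:
            return node.name
        return f"_i{next(counter)}"

    for node in sk_tree.preorder():
        names[id(node)] = name_of(node)
    root = names[id(sk_tree)]
    graph.add_node(root)
    for node in sk_tree.preorder():
        for child in node.children:
            length = max(0.0, float(child.length)) if child.length is not None else None
            attrs = {"length": length} if length is not None else {}
            graph.add_edge(names[id(node)], names[id(child)], **attrs)
    return LineageTree(graph, root)


def reconstruct_nj(dm: DistanceMatrix, cm: CharacterMatrix) -> LineageTree:
    """Neighbor joining rooted by a synthetic all-unedited outgroup.

    The outgroup cell is appended to the character matrix, distances are
    recomputed, the NJ tree is rooted on the outgroup, and the outgroup is
    removed.  Negative NJ edge lengths are clipped at 0.
    """
    from skbio.tree import nj as skbio_nj

    if set(dm.ids) != set(cm.cells):
        raise ValueError("distance matrix and character matrix disagree on cells")
    if cm.n_cells < 3:
        raise ValueError("need at least 3 cells for neighbor joining")

    aug = pd.concat(
        [
            cm.data,
            pd.DataFrame(
                [[UNEDITED] * cm.n_sites], index=[_ROOT_SENTINEL], columns=cm.sites
            ),
        ]
    )
    aug_dm = weighted_hamming_matrix(CharacterMatrix(aug, cm.n_marks))
    tree = skbio_nj(aug_dm.to_skbio())
    rooted = tree.root_by_outgroup([_ROOT_SENTINEL])
    # drop the outgroup tip and promote its sibling subtree to the root
    outgroup = next(t for t in rooted.tips() if t.name == _ROOT_SENTINEL)
    parent = outgroup.parent
    parent.remove(outgroup)
    rooted.prune()  # suppress the resulting unifurcation
    lt = _skbio_to_lineage_tree(rooted)
    assert set(map(str, lt.leaves)) == set(cm.cells)
    return lt


def reconstruct_upgma(dm: DistanceMatrix) -> LineageTree:
    """Average-linkage agglomeration; rooted by construction.

    Branch lengths are differences of merge heights (each merge height is
    half the average inter-cluster distance, so ultrametric matrices are
    recovered exactly).
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 cells")
    Z = linkage(squareform(dm.values, checks=False), method="average")
    graph = nx.DiGraph()
    heights = {i: 0.0 for i in range(n)}
    labels = {i: dm.ids[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        node = f"_u{k}"
        idx = n + k
        heights[idx] = h / 2.0  # ultrametric height of the merge point
        labels[idx] = node
        for child in (int(a), int(b)):
            graph.add_edge(node, labels[child], length=max(0.0, heights[idx] - heights[child]))
    return LineageTree(graph, labels[n + len(Z) - 1])


def reconstruct_greedy(cm: CharacterMatrix, prefer_low_frequency: bool = False) -> LineageTree:
    """Top-down recursive partitioning on informative (site, mark) pairs.

    At each group the (site, LM) pair carried by the largest number of cells
    (smallest when ``prefer_low_frequency``) that still splits the group is
    selected; cells missing at that site follow the larger side.  Groups
    with no informative pair become a multifurcation.  Ties break on
    lexicographic (site id, LM index) order.
    """
    if cm.n_cells < 2:
        raise ValueError("need at least 2 cells")
    arr = cm.values
    cells = np.array(cm.cells)
    sites = list(cm.sites)
    graph = nx.DiGraph()
    counter = itertools.count()

    def split(rows: np.ndarray) -> object:
        if rows.size == 1:
            node = str(cells[rows[0]])
            graph.add_node(node)
            return node
        sub = arr[rows]
        best = None  # (key, site, lm)
        for j in range(sub.shape[1]):
            col = sub[:, j]
            marks, counts = np.unique(col[col > 0], return_counts=True)
            detected = int((col != MISSING).sum())
            for lm, cnt in zip(marks, counts):
                if cnt == detected:  # uninformative: every detected cell has it
                    continue
                key = -cnt if not prefer_low_frequency else cnt
                cand = (key, sites[j], int(lm))
                if best is None or cand < best:
                    best = cand
        node = f"_g{next(counter)}"
        if best is None:
            # no informative pair: multifurcation over all member cells
            for r in rows:
                leaf = str(cells[r])
                graph.add_node(leaf)
                graph.add_edge(node, leaf)
            return node
        _, site, lm = best
        j = sites.index(site)
        col = arr[rows, j]
        has = col == lm
        lacks = (col != lm) & (col != MISSING)
        miss = col == MISSING
        if miss.any():
            # missing cells follow the larger side
            if has.sum() >= lacks.sum():
                has = has | miss
            else:
                lacks = lacks | miss
        left, right = rows[has], rows[lacks]
        graph.add_edge(node, split(left))
        graph.add_edge(node, split(right))
        return node

    root = split(np.arange(cm.n_cells))
    return LineageTree(graph, root)
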