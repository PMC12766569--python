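"""Tree-quality metrics and phylogeny/barcode-group agreement.

* normalized Robinson-Foulds distance over nontrivial bipartitions,
* depth-normalized triplets correct (triplets sampled evenly across the
  depth of their lowest common ancestor in the ground-truth tree),
* Fowlkes-Mallows index between a barcode group and tree clades, and
* downsampling sweeps over detection rate / edit-site count.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .tree import LineageTree

__all__ = [
    "normalized_rf",
    "depth_normalized_triplets_correct",
    "fmi",
    "best_lca_clade",
    "permuted_fmi_baseline",
    "downsampling_sweep",
    "triplet_outgroup",
]


def _nontrivial_bipartitions(tree: LineageTree) -> Set[FrozenSet[str]]:
    """Unrooted nontrivial bipartitions, canonicalized as the smaller side."""
    all_leaves = frozenset(str(l) for l in tree.leaves)
    sets = tree.leaf_sets()
    out: Set[FrozenSet[str]] = set()
    for node, leaves in sets.items():
        side = frozenset(str(l) for l in leaves)
        if len(side) < 2 or len(all_leaves) - len(side) < 2:
            continue
        other = all_leaves - side
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def normalized_rf(t1: LineageTree, t2: LineageTree) -> float:
    """Symmetric-difference bipartition count over the total in both trees.

    0 iff the unrooted topologies agree; 1 when no nontrivial bipartition is
    shared.  Trees with no nontrivial bipartition (stars) are at distance 0
    from each other.
    """
    l1 = {str(l) for l in t1.leaves}
    l2 = {str(l) for l in t2.leaves}
    if l1 != l2:
        raise ValueError("leaf sets differ")
    b1 = _nontrivial_bipartitions(t1)
    b2 = _nontrivial_bipartitions(t2)
    total = len(b1) + len(b2)
    if total == 0:
        return 0.0
    return len(b1 ^ b2) / total


# ----------------------------------------------------------------------
# triplets
# ----------------------------------------------------------------------

def triplet_outgroup(tree: LineageTree, a: str, b: str, c: str) -> Optional[str]:
    """The out-taxon of a leaf triplet, or None when unresolved.

    The pair with the strictly deepest LCA is the in-pair; if the three
    pairwise LCAs all coincide the triplet is unresolved (multifurcation).
    """
    depths = tree.depths()
    lca_ab = tree.lca([a, b])
    lca_ac = tree.lca([a, c])
    lca_bc = tree.lca([b, c])
    d = {c: depths[lca_ab], b: depths[lca_ac], a: depths[lca_bc]}
    best = max(d.values())
    winners = [k for k, v in d.items() if v == best]
    return winners[0] if len(winners) == 1 else None


def _triplet_lca_depth(tree: LineageTree, triplet: Tuple[str, str, str]) -> int:
    return tree.depths()[tree.lca(triplet)]


def depth_normalized_triplets_correct(
    truth: LineageTree,
    recon: LineageTree,
    n_triplets: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of leaf triplets whose out-taxon agrees between the trees.

    Triplets are sampled from the truth tree evenly across the occupied
    depths of their LCA (remainder allocated to the shallowest strata).  A
    triplet unresolved by a multifurcation counts as correct only when it is
    unresolved in both trees.
    """
    leaves_t = {str(l) for l in truth.leaves}
    leaves_r = {str(l) for l in recon.leaves}
    shared = leaves_t & leaves_r
    if len(shared) < 3:
        raise ValueError("need at least 3 shared leaves")
    rng = np.random.default_rng(seed)

    depths = truth.depths()
    leaf_sets = truth.leaf_sets()
    # per internal node: leaves below each child, restricted to shared leaves
    node_info = []
    for node in truth.nodes:
        kids = truth.children(node)
        if not kids:
            continue
        groups = [sorted(str(x) for x in leaf_sets[k] if str(x) in shared) for k in kids]
        groups = [g for g in groups if g]
        total = sum(len(g) for g in groups)
        if total < 3 or len(groups) < 2:
            continue
        # triplets with LCA exactly here: all 3 from below, not all in one child
        n_all = math.comb(total, 3)
        n_within = sum(math.comb(len(g), 3) for g in groups)
        count = n_all - n_within
        if count > 0:
            node_info.append((node, depths[node], groups, count))
    if not node_info:
        raise ValueError("truth tree has no triplet-defining internal node")

    strata: Dict[int, List[Tuple]] = {}
    for info in node_info:
        strata.setdefault(info[1], []).append(info)
    occupied = sorted(strata)
    base, rem = divmod(n_triplets, len(occupied))
    alloc = {d: base + (1 if i < rem else 0) for i, d in enumerate(occupied)}

    def sample_triplet_at(node_infos) -> Tuple[str, str, str]:
        counts = np.array([ni[3] for ni in node_infos], dtype=float)
        node, _, groups, _ = node_infos[rng.choice(len(node_infos), p=counts / counts.sum())]
        pool = [leaf for g in groups for leaf in g]
        group_of = {leaf: gi for gi, g in enumerate(groups) for leaf in g}
        while True:
            picks = rng.choice(len(pool), size=3, replace=False)
            trip = tuple(sorted(pool[i] for i in picks))
            if len({group_of[t] for t in trip}) >= 2:
                return trip

    def agree(trip: Tuple[str, str, str]) -> bool:
        return triplet_outgroup(truth, *trip) == triplet_outgroup(recon, *trip)

    weighted_sum = 0.0
    weight_total = 0
    for depth in occupied:
        want = alloc[depth]
        if want == 0:
            continue
        infos = strata[depth]
        available = sum(ni[3] for ni in infos)
        if available <= want:
            # stratum exhausted: its exact mean (the without-replacement limit)
            vals = []
            for node, _, groups, _ in infos:
                pool = [leaf for g in groups for leaf in g]
                group_of = {leaf: gi for gi, g in enumerate(groups) for leaf in g}
                for trip in itertools.combinations(sorted(pool), 3):
                    if len({group_of[t] for t in trip}) >= 2:
                        vals.append(agree(trip))
            stratum_mean = float(np.mean(vals))
        else:
            seen: set = set()
            while len(seen) < want:
                seen.add(sample_triplet_at(infos))
            stratum_mean = float(np.mean([agree(t) for t in seen]))
        weighted_sum += want * stratum_mean
        weight_total += want
    return weighted_sum / weight_total


# ----------------------------------------------------------------------
# Fowlkes-Mallows agreement
# ----------------------------------------------------------------------

def fmi(group: Iterable[str], clade: Iterable[str]) -> float:
    """sqrt(precision x recall) of a clade against a barcode group.

    TP = |group ∩ clade|, FP = |clade \\ group|, FN = |group \\ clade|.
    """
    g = set(group)
    c = set(clade)
    if not g:
        raise ValueError("empty group")
    tp = len(g & c)
    if tp == 0:
        return 0.0
    fp = len(c - g)
    fn = len(g - c)
    return math.sqrt(tp / (tp + fp) * tp / (tp + fn))


def best_lca_clade(
    tree: LineageTree, group: Iterable[str], labeled: Optional[Iterable[str]] = None
) -> Tuple[object, float]:
    """Internal node whose leaf set maximizes the FMI for a barcode group.

    ``labeled`` restricts clade membership to barcoded cells (cells without a
    barcode are excluded from the score).  Ties prefer the deepest node, then
    the smallest clade.
    """
    group = set(group)
    if not group:
        raise ValueError("empty group")
    leaf_names = {str(l) for l in tree.leaves}
    if not group <= leaf_names:
        raise ValueError("group contains non-leaf cells")
    labeled = set(labeled) if labeled is not None else None
    depths = tree.depths()
    best = None
    for node, leaves in tree.leaf_sets().items():
        if tree.is_leaf(node):
            continue
        clade = {str(l) for l in leaves}
        if labeled is not None:
            clade &= labeled
        score = fmi(group, clade) if clade else 0.0
        key = (score, depths[node], -len(clade))
        if best is None or key > best[0]:
            best = (key, node)
    return best[1], best[0][0]


def permuted_fmi_baseline(
    tree: LineageTree, group: Iterable[str], n_perm: int = 100, seed: int = 0
) -> np.ndarray:
    """Best-LCA FMI scores after randomly permuting group labels over leaves."""
    rng = np.random.default_rng(seed)
    leaves = sorted(str(l) for l in tree.leaves)
    k = len(set(group))
    scores = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.choice(leaves, size=k, replace=False)
        scores[i] = best_lca_clade(tree, set(perm))[1]
    return scores


# ----------------------------------------------------------------------
# downsampling sweeps
# ----------------------------------------------------------------------

def downsampling_sweep(
    cm: CharacterMatrix,
    truth: Optional[LineageTree] = None,
    groups: Optional[Dict[str, str]] = None,
    detection_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    site_grid: Sequence[int] = tuple(range(5, 50, 5)),
    reps: int = 10,
    seed: int = 0,
    n_triplets: int = 200,
) -> pd.DataFrame:
    """Reconstruction accuracy as detection rate or edit-site count shrinks.

    For every grid point and repetition the matrix is downsampled, a tree is
    rebuilt with neighbor joining, and scored against the ground-truth tree
    (normalized RF, triplets correct) and/or the barcode groups (mean
    best-LCA FMI).  When a target exceeds what the data supports, no
    downsampling is performed and the realized value is reported.
    """
    from .reconstruct import reconstruct_nj, weighted_hamming_matrix
    from .simulate import apply_detection_dropout

    if truth is None and groups is None:
        raise ValueError("provide a truth tree and/or barcode groups")
    rng = np.random.default_rng(seed)
    base_detection = 1.0 - cm.missing_fraction()
    rows = []

    def score(sub: CharacterMatrix, record: dict) -> None:
        tree = reconstruct_nj(weighted_hamming_matrix(sub), sub)
        if truth is not None:
            record["normalized_rf"] = normalized_rf(truth, tree)
            record["triplets_correct"] = depth_normalized_triplets_correct(
                truth, tree, n_triplets=n_triplets, seed=int(rng.integers(2**31))
            )
        if groups is not None:
            labeled = set(groups)
            labels = sorted(set(groups.values()))
            scores = [
                best_lca_clade(tree, {c for c, g in groups.items() if g == lab}, labeled)[1]
                for lab in labels
            ]
            record["mean_fmi"] = float(np.mean(scores))
        rows.append(record)

    for target in detection_grid:
        for rep in range(reps):
            if target >= base_detection:
                sub, realized = cm, base_detection
            else:
                # thin detected entries down to the target rate
                keep = target / base_detection
                sub = apply_detection_dropout(cm, keep, int(rng.integers(2**31)))
                realized = 1.0 - sub.missing_fraction()
            score(
                sub,
                {
                    "sweep": "detection",
                    "target": float(target),
                    "realized": float(realized),
                    "rep": rep,
                },
            )
    for n_sites in site_grid:
        for rep in range(reps):
            if n_sites >= cm.n_sites:
                sub, realized = cm, cm.n_sites
            else:
                picked = rng.choice(cm.n_sites, size=n_sites, replace=False)
                sub = cm.subset_sites([cm.sites[i] for i in sorted(picked)])
                realized = n_sites
            score(
                sub,
                {
                    "sweep": "sites",
                    "target": int(n_sites),
                    "realized": int(realized),
                    "rep": rep,
                },
            )
    return pd.DataFrame(rows)
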