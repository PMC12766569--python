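"""Sequencing-readout quality control and clone calling.

Operates on long-form UMI tables with columns
``cell, intbc, site1..siteK (integer state codes), umis, reads`` plus
separate static-barcode tables ``cell, round, barcode, umis``.

The pipeline follows the readout error model of expressed recorders:
low-count PCR/ambient alleles are removed with an adaptive two-component
mixture threshold, conflicting alleles within a (cell, intBC) are resolved
with a bias toward later (edited) states, duplicate cassette integrations
are dropped clone-wide, conflict-heavy cells are flagged as doublets, and
clones are called by non-negative matrix factorization over the
cell-by-intBC count matrix with Jaccard-based doublet detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CloneAssignment",
    "DOUBLET",
    "UNASSIGNED",
    "gmm_threshold",
    "resolve_conflicting_alleles",
    "filter_duplicate_intbcs",
    "filter_conflict_doublets",
    "call_clones",
    "call_barcode_groups",
    "run_qc_pipeline",
    "synth_umi_table",
    "allele_columns",
]

DOUBLET = "DOUBLET"
UNASSIGNED = "UNASSIGNED"


def allele_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c.startswith("site")]


def _allele_key(table: pd.DataFrame) -> pd.Series:
    cols = allele_columns(table)
    return table[cols].astype(str).agg(",".join, axis=1)


@dataclass
class CloneAssignment:
    """Cell-to-clone labels plus the intBC set that defines each clone."""

    labels: Dict[str, str]
    clone_intbcs: Dict[str, Set[str]]

    def cells_of(self, clone: str) -> List[str]:
        return [c for c, l in self.labels.items() if l == clone]


def gmm_threshold(values: Sequence[float]) -> Tuple[float, np.ndarray]:
    """Adaptive low-count filter via a two-component mixture on log counts.

    Returns ``(threshold, keep_mask)`` where items assigned to the
    lower-mean component are dropped.  Falls back to keeping everything
    (with a warning) when the fit degenerates: fewer than 20 values, zero
    variance, or components closer than 1e-3 in mean.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("counts must be positive")
    logv = np.log(values)
    if values.size < 20 or np.isclose(logv.var(), 0.0):
        warnings.warn("mixture fit degenerate; no filtering applied")
        return float(values.min()), np.ones(values.size, dtype=bool)
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gm.fit(logv[:, None])
    means = gm.means_.ravel()
    gm1 = GaussianMixture(n_components=1, random_state=0).fit(logv[:, None])
    unimodal = gm1.bic(logv[:, None]) <= gm.bic(logv[:, None])
    if unimodal or abs(means[0] - means[1]) < 1e-3:
        warnings.warn("mixture components indistinguishable; no filtering applied")
        return float(values.min()), np.ones(values.size, dtype=bool)
    upper = int(np.argmax(means))
    post = gm.predict_proba(logv[:, None])[:, upper]
    keep = post >= 0.5
    if not keep.any():  # pragma: no cover - pathological
        warnings.warn("mixture filter would drop everything; no filtering applied")
        return float(values.min()), np.ones(values.size, dtype=bool)
    threshold = float(values[keep].min())
    return threshold, keep


def resolve_conflicting_alleles(table: pd.DataFrame, min_edited_share: float = 0.20) -> pd.DataFrame:
    """Pick one allele per (cell, intBC), favoring late edits.

    When exactly two alleles differ at a single site with one unedited
    there, the edited allele wins provided it carries more than
    ``min_edited_share`` of the pair's UMIs (expressed readouts lag the
    genome, so the newer edited allele may be the minor species).  Otherwise
    the max-UMI allele wins, ties broken lexicographically.
    """
    cols = allele_columns(table)
    out_rows = []
    for (cell, intbc), grp in table.groupby(["cell", "intbc"], sort=False):
        if len(grp) == 1:
            out_rows.append(grp)
            continue
        agg = grp.groupby(cols, as_index=False).agg(
            umis=("umis", "sum"), reads=("reads", "sum")
        )
        chosen = None
        if len(agg) == 2:
            a = agg.iloc[0][cols].to_numpy(dtype=int)
            b = agg.iloc[1][cols].to_numpy(dtype=int)
            diff = np.flatnonzero(a != b)
            if diff.size == 1 and (a[diff[0]] == 0) != (b[diff[0]] == 0):
                edited_idx = 0 if a[diff[0]] != 0 else 1
                share = agg.iloc[edited_idx]["umis"] / agg["umis"].sum()
                if share > min_edited_share:
                    chosen = agg.iloc[[edited_idx]]
        if chosen is None:
            agg = agg.sort_values(["umis"] + cols, ascending=[False] + [True] * len(cols))
            chosen = agg.iloc[[0]]
        chosen = chosen.assign(cell=cell, intbc=intbc)
        out_rows.append(chosen[["cell", "intbc"] + cols + ["umis", "reads"]])
    return pd.concat(out_rows, ignore_index=True)


def filter_duplicate_intbcs(
    table: pd.DataFrame, clones: CloneAssignment, max_multi_allele_umi_fraction: float = 0.25
) -> pd.DataFrame:
    """Drop intBCs with duplicate integrations, clone-wide.

    Per (clone, intBC): the fraction of UMIs found in cells carrying more
    than one allele of that intBC; strictly above the threshold removes the
    intBC from every cell of the clone.
    """
    t = table.copy()
    t["clone"] = t["cell"].map(clones.labels)
    t["allele"] = _allele_key(t)
    drop_pairs = set()
    for (clone, intbc), grp in t.groupby(["clone", "intbc"], sort=False):
        if pd.isna(clone):
            continue
        n_alleles = grp.groupby("cell")["allele"].nunique()
        multi_cells = set(n_alleles[n_alleles > 1].index)
        frac = grp.loc[grp["cell"].isin(multi_cells), "umis"].sum() / grp["umis"].sum()
        if frac > max_multi_allele_umi_fraction:
            drop_pairs.add((clone, intbc))
    mask = [
        (cl, ib) not in drop_pairs for cl, ib in zip(t["clone"], t["intbc"])
    ]
    return table.loc[mask].reset_index(drop=True)


def filter_conflict_doublets(
    table: pd.DataFrame, max_conflict_fraction: float = 0.25
) -> Set[str]:
    """Cells whose UMI mass is dominated by conflicted intBCs.

    An intBC is conflicted within a cell when it shows more than one allele.
    Cells whose conflicted-intBC UMI fraction strictly exceeds the threshold
    (0.25 for sequencing, 0.50 for imaging) are returned for removal.
    """
    t = table.copy()
    t["allele"] = _allele_key(t)
    flagged = set()
    for cell, grp in t.groupby("cell", sort=False):
        n_alleles = grp.groupby("intbc")["allele"].nunique()
        conflicted = set(n_alleles[n_alleles > 1].index)
        frac = grp.loc[grp["intbc"].isin(conflicted), "umis"].sum() / grp["umis"].sum()
        if frac > max_conflict_fraction:
            flagged.add(cell)
    return flagged


def call_clones(
    table: pd.DataFrame,
    n_clones: int,
    method: str = "nmf",
    seed: int = 0,
    min_jaccard: float = 0.5,
    intbc_detection_fraction: float = 0.5,
) -> CloneAssignment:
    """NMF (or spectral) clone calling with Jaccard doublet detection.

    The cell-by-intBC UMI matrix is factorized; initial labels come from the
    argmax of the cell factor (or spectral clusters on binarized detections).
    Each clone's intBC set holds the intBCs detected in more than half of
    its cells.  Cells are then re-assigned to the single clone or clone-pair
    union with maximal Jaccard similarity to their detected intBC set:
    pair-union winners are doublets, best similarity below ``min_jaccard``
    is unassigned.
    """
    from sklearn.decomposition import NMF
    from sklearn.cluster import SpectralClustering

    pivot = table.pivot_table(
        index="cell", columns="intbc", values="umis", aggfunc="sum", fill_value=0
    ).sort_index()
    cells = list(pivot.index)
    intbcs = list(pivot.columns)
    if n_clones < 1 or n_clones > len(cells):
        raise ValueError("n_clones must be in [1, n_cells]")
    X = pivot.to_numpy(dtype=float)
    # scale-invariance: clone structure lives in detection patterns
    X_norm = X / max(X.max(), 1.0)

    if method == "nmf":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = NMF(
                n_components=n_clones,
                init="nndsvd",
                random_state=seed,
                max_iter=500,
            ).fit_transform(X_norm)
        initial = W.argmax(axis=1)
    elif method == "spectral":
        B = (X > 0).astype(float)
        initial = SpectralClustering(
            n_clusters=n_clones, random_state=seed, affinity="nearest_neighbors",
            n_neighbors=min(10, len(cells) - 1),
        ).fit_predict(B)
    else:
        raise ValueError(f"unknown method {method!r}")

    detected = X > 0
    clone_sets: Dict[str, Set[str]] = {}
    for k in range(n_clones):
        members = np.flatnonzero(initial == k)
        if members.size == 0:
            continue
        frac = detected[members].mean(axis=0)
        clone_sets[f"clone{k}"] = {
            intbcs[j] for j in np.flatnonzero(frac > intbc_detection_fraction)
        }
    clone_sets = {k: v for k, v in clone_sets.items() if v}

    labels: Dict[str, str] = {}
    names = sorted(clone_sets)
    pair_names = [
        (a, b) for i, a in enumerate(names) for b in names[i + 1 :]
    ]
    for i, cell in enumerate(cells):
        cell_set = {intbcs[j] for j in np.flatnonzero(detected[i])}
        if not cell_set:
            labels[cell] = UNASSIGNED
            continue
        best_label, best_sim = UNASSIGNED, -1.0
        for name in names:
            s = clone_sets[name]
            sim = len(cell_set & s) / len(cell_set | s)
            if sim > best_sim:
                best_label, best_sim = name, sim
        for a, b in pair_names:
            s = clone_sets[a] | clone_sets[b]
            sim = len(cell_set & s) / len(cell_set | s)
            if sim > best_sim:
                best_label, best_sim = DOUBLET, sim
        labels[cell] = best_label if best_sim >= min_jaccard else UNASSIGNED
    return CloneAssignment(labels, clone_sets)


def call_barcode_groups(
    barcodes: pd.DataFrame,
    min_cells: int = 5,
    cooccurrence: float = 0.8,
    umi_dominance: float = 0.8,
) -> Dict[str, str]:
    """Greedy static-barcode grouping.

    Repeats until no viable seed: (1) seed with the barcode detected in the
    highest fraction of unassigned cells (lexicographic tie-break), (2)
    cluster all barcodes present in more than 80% of the seed's cells, (3)
    assign unassigned cells whose cluster barcodes account for more than
    80% of their barcode UMIs, (4) keep the group only if at least 5 cells
    joined.  Returns cell -> group label (seed barcode id).
    """
    t = barcodes.copy()
    assigned: Dict[str, str] = {}
    used_seeds: Set[str] = set()
    all_cells = sorted(t["cell"].unique())
    cell_bcs = {c: set(g["barcode"]) for c, g in t.groupby("cell", sort=False)}
    cell_umis = {
        c: g.groupby("barcode")["umis"].sum() for c, g in t.groupby("cell", sort=False)
    }
    for _ in range(t["barcode"].nunique()):
        unassigned = [c for c in all_cells if c not in assigned]
        if not unassigned:
            break
        counts: Dict[str, int] = {}
        for c in unassigned:
            for b in cell_bcs[c]:
                counts[b] = counts.get(b, 0) + 1
        candidates = sorted(
            (b for b in counts if b not in used_seeds),
            key=lambda b: (-counts[b], b),
        )
        if not candidates:
            break
        seed_bc = candidates[0]
        used_seeds.add(seed_bc)
        seed_cells = [c for c in all_cells if seed_bc in cell_bcs[c]]
        cluster = {seed_bc}
        other_counts: Dict[str, int] = {}
        for c in seed_cells:
            for b in cell_bcs[c]:
                other_counts[b] = other_counts.get(b, 0) + 1
        for b, n in other_counts.items():
            if b != seed_bc and n / len(seed_cells) > cooccurrence:
                cluster.add(b)
        members = []
        for c in unassigned:
            umis = cell_umis[c]
            share = umis[umis.index.isin(cluster)].sum() / umis.sum()
            if share > umi_dominance:
                members.append(c)
        if len(members) >= min_cells:
            for c in members:
                assigned[c] = seed_bc
    return assigned


def run_qc_pipeline(
    table: pd.DataFrame,
    n_clones: int,
    method: str = "nmf",
    seed: int = 0,
    doublet_conflict_threshold: float = 0.25,
) -> Tuple[pd.DataFrame, CloneAssignment, Set[str]]:
    """Canonical QC + clone-calling order.

    1. adaptive mixture filter on reads per allele (PCR/sequencing errors),
    2. per-intBC mixture filter on UMIs per allele (ambient RNA),
    3. clone calling (NMF + Jaccard doublets),
    4. duplicate-integration intBC removal (clone-wide, pre-resolution),
    5. conflict-doublet cell removal,
    6. conflicting-allele resolution to one allele per (cell, intBC).

    Returns (clean table, clone assignment, flagged doublet cells); flagged
    cells combine the conflict rule and the Jaccard pair-match rule.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, keep = gmm_threshold(table["reads"].to_numpy())
        t = table.loc[keep]
        kept_parts = []
        for _, grp in t.groupby("intbc", sort=False):
            if len(grp) < 20:
                kept_parts.append(grp)
                continue
            _, k2 = gmm_threshold(grp["umis"].to_numpy())
            kept_parts.append(grp.loc[k2])
        t = pd.concat(kept_parts)
    clones = call_clones(t, n_clones, method=method, seed=seed)
    t = filter_duplicate_intbcs(t, clones)
    conflict_cells = filter_conflict_doublets(t, doublet_conflict_threshold)
    jaccard_doublets = {c for c, l in clones.labels.items() if l == DOUBLET}
    flagged = conflict_cells | jaccard_doublets
    t = t[~t["cell"].isin(flagged)]
    t = resolve_conflicting_alleles(t)
    return t.reset_index(drop=True), clones, flagged


# ----------------------------------------------------------------------
# synthetic UMI-table generator
# ----------------------------------------------------------------------

def synth_umi_table(
    n_clones: int = 6,
    cells_per_clone: int = 100,
    intbcs_per_clone: int = 10,
    umi_depth: float = 30.0,
    ambient_rate: float = 0.05,
    doublet_rate: float = 0.05,
    duplicate_intbc_rate: float = 0.1,
    duplicate_cell_fraction: float = 0.6,
    barcode_rounds: int = 2,
    n_marks: int = 8,
    intbc_pool_size: Optional[int] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, object]]:
    """Synthetic (LM table, static-barcode table, ground truth).

    Emulates the dominant noise sources of expressed-recorder readouts:
    bimodal UMI support (true alleles high, PCR-error/ambient alleles low),
    ambient cross-cell allele leakage, cell doublets as merged records of
    two clones, occasional duplicate integrations of the same intBC within
    a clone, and per-round static barcodes shared clone-wide.

    Clones draw their cassettes from a finite intBC pool (default half the
    would-be-disjoint size), so distinct clones share some intBCs with
    different alleles -- the overlap that makes doublets show conflicting
    alleles, as with a real bounded barcode whitelist.  Pass
    ``intbc_pool_size`` large (or 0 for exactly disjoint sets) to remove the
    overlap.
    """
    rng = np.random.default_rng(seed)
    if intbc_pool_size == 0:
        pool_size = n_clones * intbcs_per_clone
        disjoint = True
    else:
        pool_size = intbc_pool_size or max(
            intbcs_per_clone + 1, n_clones * intbcs_per_clone // 2
        )
        disjoint = False
    intbc_ids = [f"iBC{k:03d}" for k in range(pool_size)]
    clone_intbcs = {}
    for k in range(n_clones):
        if disjoint:
            picked = intbc_ids[k * intbcs_per_clone : (k + 1) * intbcs_per_clone]
        else:
            picked = sorted(
                rng.choice(pool_size, size=intbcs_per_clone, replace=False)
            )
            picked = [intbc_ids[i] for i in picked]
        clone_intbcs[f"clone{k}"] = picked
    # one true allele (3 edit sites) per (clone, intbc)
    true_allele = {
        (cl, ib): tuple(rng.integers(0, n_marks + 1, size=3))
        for cl, ibs in clone_intbcs.items()
        for ib in ibs
    }
    dup_intbcs = {
        cl: set(
            np.array(ibs)[rng.random(len(ibs)) < duplicate_intbc_rate]
        )
        for cl, ibs in clone_intbcs.items()
    }
    dup_allele = {
        (cl, ib): tuple(rng.integers(0, n_marks + 1, size=3))
        for cl, ibs in dup_intbcs.items()
        for ib in ibs
    }

    def high_umis() -> int:
        return int(rng.poisson(umi_depth)) + 10

    def low_umis() -> int:
        return int(rng.integers(1, 3))

    rows = []
    truth_rows = []
    cell_counter = 0

    def emit_cell(clone: str, kind: str, other_clone: Optional[str] = None) -> str:
        nonlocal cell_counter
        cell = f"cell{cell_counter:05d}"
        cell_counter += 1
        sources = [clone] if other_clone is None else [clone, other_clone]
        for src in sources:
            for ib in clone_intbcs[src]:
                a = true_allele[(src, ib)]
                rows.append((cell, ib, *a, high_umis(), 0))
                if ib in dup_intbcs[src] and rng.random() < duplicate_cell_fraction:
                    rows.append((cell, ib, *dup_allele[(src, ib)], high_umis(), 0))
        # ambient leakage: low-UMI allele copied from another clone
        if rng.random() < ambient_rate:
            src = f"clone{rng.integers(n_clones)}"
            ib = clone_intbcs[src][rng.integers(intbcs_per_clone)]
            rows.append((cell, ib, *true_allele[(src, ib)], low_umis(), 0))
        # PCR-error allele: corrupt one site of one intBC at low support
        if rng.random() < ambient_rate:
            ib = clone_intbcs[clone][rng.integers(intbcs_per_clone)]
            a = list(true_allele[(clone, ib)])
            a[rng.integers(3)] = int(rng.integers(0, n_marks + 1))
            rows.append((cell, ib, *a, low_umis(), 0))
        truth_rows.append(
            {"cell": cell, "clone": clone, "kind": kind, "other": other_clone}
        )
        return cell

    for k in range(n_clones):
        clone = f"clone{k}"
        for _ in range(cells_per_clone):
            if rng.random() < doublet_rate:
                other = f"clone{(k + 1 + rng.integers(n_clones - 1)) % n_clones}"
                emit_cell(clone, "doublet", other)
            else:
                emit_cell(clone, "singlet")

    table = pd.DataFrame(
        rows, columns=["cell", "intbc", "site1", "site2", "site3", "umis", "reads"]
    )
    table = (
        table.groupby(["cell", "intbc", "site1", "site2", "site3"], as_index=False)
        .agg(umis=("umis", "sum"), reads=("reads", "sum"))
    )
    # reads scale with UMIs (true alleles well-supported, errors shallow)
    table["reads"] = (table["umis"] * 3 + rng.integers(0, 3, size=len(table))).astype(int)
    truth = pd.DataFrame(truth_rows)

    bc_rows = []
    for rnd in range(barcode_rounds):
        for k in range(n_clones):
            bc = f"bc_r{rnd}_{k:02d}"
            for cell, clone in zip(truth["cell"], truth["clone"]):
                if clone == f"clone{k}":
                    bc_rows.append((cell, f"round{rnd}", bc, int(rng.integers(5, 30))))
    barcode_table = pd.DataFrame(bc_rows, columns=["cell", "round", "barcode", "umis"])

    ground_truth = {
        "clone_intbcs": clone_intbcs,
        "true_alleles": true_allele,
        "duplicate_intbcs": dup_intbcs,
        "doublets": set(truth.loc[truth["kind"] == "doublet", "cell"]),
        "cell_clone": dict(zip(truth["cell"], truth["clone"])),
    }
    return table, barcode_table, ground_truth
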