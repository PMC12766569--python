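"""Birth-death lineage simulation and recorder-design calculators.

Two editing models are used deliberately:

* Tree overlays use the continuous form: an unedited site edits along a
  branch of duration ``t`` days with probability ``1 - (1 - R)**t`` where the
  per-day rate ``R`` is chosen so a target fraction ``F`` of sites is edited
  after ``T`` days: ``R = 1 - (1 - F)**(1/T)``.
* The recorder-design calculators (saturation tables, minimum edit sites)
  use a simplified discrete framework: 100 modeled lineages, one division
  per day, no death, per-day per-site Bernoulli editing.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import MISSING, UNEDITED, CharacterMatrix
from .tree import LineageTree

__all__ = [
    "LMDistribution",
    "SimulationConfig",
    "ExtinctionError",
    "simulate_birth_death",
    "simulate_birth_death_with_retries",
    "edit_rate_for_target_fraction",
    "overlay_lineage_marks",
    "apply_detection_dropout",
    "normalized_entropy",
    "lm_distribution_for_entropy",
    "saturation_rate_table",
    "min_edit_sites_for_marked_fraction",
    "MinSitesResult",
    "plant_barcode_groups",
    "simulate_experiment",
]


class ExtinctionError(RuntimeError):
    """All lineages died before the target population size was reached."""


@dataclass
class LMDistribution:
    """Installation probabilities for the S lineage marks."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any():
            raise ValueError("negative LM probability")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("LM probabilities must sum to 1")

    @property
    def n_marks(self) -> int:
        return self.probs.size

    @property
    def normalized_entropy(self) -> float:
        return normalized_entropy(self.probs)

    @classmethod
    def uniform(cls, n_marks: int) -> "LMDistribution":
        return cls(np.full(n_marks, 1.0 / n_marks))


def normalized_entropy(probs: Sequence[float]) -> float:
    """Shannon entropy of LM probabilities divided by log(S); in [0, 1]."""
    p = np.asarray(probs, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 marks")
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("invalid probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def lm_distribution_for_entropy(
    n_marks: int, target_hnorm: float, tol: float = 1e-6
) -> LMDistribution:
    """Exponentially skewed LM distribution with a target normalized entropy.

    ``p_i`` is proportional to ``exp(-lam * i)``; ``lam`` is found by bisection
    (normalized entropy is monotone decreasing in ``lam``).  A target of 1
    returns the exactly uniform distribution.
    """
    if n_marks < 2:
        raise ValueError("need at least 2 marks")
    if not 0 < target_hnorm <= 1:
        raise ValueError("target normalized entropy must be in (0, 1]")
    if target_hnorm == 1.0:
        return LMDistribution.uniform(n_marks)

    idx = np.arange(n_marks)

    def probs_for(lam: float) -> np.ndarray:
        w = np.exp(-lam * idx)
        return w / w.sum()

    lo, hi = 1e-9, 1.0
    while normalized_entropy(probs_for(hi)) > target_hnorm:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise RuntimeError("bisection bracket expansion failed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if normalized_entropy(probs_for(mid)) > target_hnorm:
            lo = mid
        else:
            hi = mid
    return LMDistribution(probs_for(0.5 * (lo + hi)))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated tracing experiment.

    Defaults follow the stated simulation regime: log-normal lifetimes with
    mean 1 day (sigma = 0.5 on the log scale, so mu = -sigma**2/2), death
    rate 0.25 per lineage per day in competition with division.
    """

    n_cells: int = 100
    n_sites: int = 40
    n_marks: int = 8
    lm_distribution: Optional[LMDistribution] = None
    edit_fraction: float = 0.7
    experiment_length: float = 16.0
    detection_efficiency: float = 1.0
    death_rate: float = 0.25
    lifetime_sigma: float = 0.5
    lifetime_mean: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.edit_fraction < 1:
            raise ValueError("edit fraction F must be in [0, 1)")
        if not 0 <= self.detection_efficiency <= 1:
            raise ValueError("detection efficiency D must be in [0, 1]")
        if self.experiment_length <= 0:
            raise ValueError("experiment length T must be > 0")
        if min(self.n_sites, self.n_marks) < 1:
            raise ValueError("counts must be positive")
        if self.lm_distribution is None:
            self.lm_distribution = LMDistribution.uniform(self.n_marks)
        if self.lm_distribution.n_marks != self.n_marks:
            raise ValueError("LM distribution size disagrees with n_marks")


def _sample_lifetime(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    # "mean = 1" is the natural-scale mean; sigma the log-scale sd.
    mu = math.log(cfg.lifetime_mean) - cfg.lifetime_sigma**2 / 2.0
    return float(rng.lognormal(mu, cfg.lifetime_sigma))


def simulate_birth_death(config: SimulationConfig, seed: int) -> LineageTree:
    """Grow a birth-death tree until ``n_cells`` lineages are alive.

    Each cell draws a log-normal lifetime; death competes as an exponential
    clock at ``death_rate`` (the cell dies if the exponential draw is shorter
    than its division waiting time).  Extant cells at stop time are leaves and
    keep their full sampled lifetimes as branch lengths; dead lineages are
    pruned and pass-through divisions suppressed.  The founder's lifetime is
    kept as the stem above the root division (``root_length``).

    Raises
    ------
    ExtinctionError
        If every lineage dies before the population reaches ``n_cells``.
    """
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    counter = itertools.count()

    def new_node() -> str:
        return f"n{next(counter)}"

    root = new_node()
    graph.add_node(root)
    # event queue of (event_time, tiebreak, node, birth_time, lifetime, dies)
    events: List[Tuple[float, int, str, float, float, bool]] = []
    dead: set = set()
    tiebreak = itertools.count()
    lifetimes: Dict[str, float] = {}

    def schedule(node: str, birth: float) -> None:
        """Sample fate for a newborn cell and queue its next event."""
        life = _sample_lifetime(rng, config)
        lifetimes[node] = life
        if config.death_rate > 0:
            death_wait = rng.exponential(1.0 / config.death_rate)
        else:
            death_wait = math.inf
        if death_wait < life:
            heapq.heappush(events, (birth + death_wait, next(tiebreak), node, birth, life, True))
        else:
            heapq.heappush(events, (birth + life, next(tiebreak), node, birth, life, False))

    schedule(root, 0.0)
    alive = {root}

    while alive and len(alive) < config.n_cells:
        _, _, node, birth, life, dies = heapq.heappop(events)
        if node not in alive:  # pragma: no cover - defensive
            continue
        alive.discard(node)
        if dies:
            dead.add(node)
            if not alive:
                raise ExtinctionError("all lineages died before reaching target size")
            continue
        for _ in range(2):
            child = new_node()
            graph.add_edge(node, child)
            schedule(child, birth + life)
            alive.add(child)

    # branch length above each node = that cell's sampled lifetime
    for node in graph.nodes:
        parent = next(graph.predecessors(node), None)
        if parent is not None:
            graph.edges[parent, node]["length"] = float(lifetimes[node])

    root_length = float(lifetimes[root])
    _prune_dead(graph, root, dead)
    root, stem_extra = _suppress_unifurcations(graph, root)
    tree = LineageTree(graph, root, root_length=root_length + stem_extra)
    return tree


def _prune_dead(graph: nx.DiGraph, root, dead: set) -> None:
    """Remove dead lineages and any internal node with no extant descendant."""
    doomed = set()
    for node in reversed(list(nx.topological_sort(graph))):
        kids = list(graph.successors(node))
        if not kids:
            if node in dead:
                doomed.add(node)
        elif all(k in doomed for k in kids):
            doomed.add(node)
    graph.remove_nodes_from(doomed)


def _suppress_unifurcations(graph: nx.DiGraph, root) -> Tuple[object, float]:
    """Merge pass-through nodes, summing branch lengths.

    Returns the (possibly new) root and the total duration absorbed into the
    stem when root unifurcations are removed.
    """
    stem_extra = 0.0
    changed = True
    while changed:
        changed = False
        for node in list(graph.nodes):
            kids = list(graph.successors(node))
            if len(kids) != 1:
                continue
            child = kids[0]
            parent = next(graph.predecessors(node), None)
            if parent is None:
                stem_extra += graph.edges[node, child].get("length", 0.0)
                graph.remove_node(node)
                root = child
                changed = True
                break
            length = graph.edges[parent, node].get("length", 0.0) + graph.edges[
                node, child
            ].get("length", 0.0)
            graph.remove_node(node)
            graph.add_edge(parent, child, length=length)
            changed = True
    return root, stem_extra


def simulate_birth_death_with_retries(
    config: SimulationConfig, seed: int, max_retries: int = 20
) -> LineageTree:
    """Retry extinct runs with seeds derived deterministically from ``seed``."""
    children = np.random.SeedSequence(seed).spawn(max_retries)
    for ss in children:
        try:
            return simulate_birth_death(config, ss.generate_state(1)[0] % (2**31))
        except ExtinctionError:
            continue
    raise ExtinctionError(f"extinct in all {max_retries} retries")


def edit_rate_for_target_fraction(edit_fraction: float, total_days: float) -> float:
    """Per-day edit rate R with expected unedited fraction (1-F) after T days.

    R = 1 - (1 - F)**(1/T).
    """
    if not 0 <= edit_fraction < 1:
        raise ValueError("F must be in [0, 1)")
    if total_days <= 0:
        raise ValueError("T must be > 0")
    return 1.0 - (1.0 - edit_fraction) ** (1.0 / total_days)


def overlay_lineage_marks(
    tree: LineageTree,
    config: SimulationConfig,
    seed: int,
    total_time: Optional[float] = None,
) -> Tuple[Dict[object, np.ndarray], CharacterMatrix]:
    """Accrue heritable lineage marks down a tree.

    Editing starts from an all-unedited founder; an unedited site edits along
    a branch of duration ``t`` with probability ``1 - (1 - R)**t`` and, once
    edited, never changes.  The installed LM is drawn from the configured LM
    distribution.  Returns (per-node ground-truth states, leaf matrix); the
    leaf matrix contains no missing entries.
    """
    rng = np.random.default_rng(seed)
    T = total_time if total_time is not None else config.experiment_length
    rate = edit_rate_for_target_fraction(config.edit_fraction, T)
    probs = config.lm_distribution.probs
    M = config.n_sites
    states: Dict[object, np.ndarray] = {}

    def evolve(parent_state: np.ndarray, duration: float) -> np.ndarray:
        if duration is None:
            raise ValueError("tree lacks branch lengths")
        state = parent_state.copy()
        unedited = np.flatnonzero(state == UNEDITED)
        if unedited.size and rate > 0:
            p_edit = 1.0 - (1.0 - rate) ** duration
            hits = unedited[rng.random(unedited.size) < p_edit]
            if hits.size:
                state[hits] = rng.choice(probs.size, size=hits.size, p=probs) + 1
        return state

    founder = np.zeros(M, dtype=int)
    root_state = (
        evolve(founder, tree.root_length) if tree.root_length else founder.copy()
    )
    states[tree.root] = root_state
    for node in tree.preorder():
        if node == tree.root:
            continue
        parent = tree.parent(node)
        length = tree.graph.edges[parent, node].get("length")
        states[node] = evolve(states[parent], length)

    leaves = sorted(tree.leaves, key=str)
    arr = np.stack([states[leaf] for leaf in leaves])
    cm = CharacterMatrix.from_array(arr, config.n_marks, cells=[str(l) for l in leaves])
    return states, cm


def apply_detection_dropout(
    cm: CharacterMatrix, detection_efficiency: float, seed: int
) -> CharacterMatrix:
    """Replace each entry by MISSING independently with probability 1-D."""
    if not 0 <= detection_efficiency <= 1:
        raise ValueError("D must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arr = cm.values.copy()
    drop = rng.random(arr.shape) >= detection_efficiency
    arr[drop] = MISSING
    return CharacterMatrix.from_array(arr, cm.n_marks, cells=cm.cells, sites=cm.sites)


# ----------------------------------------------------------------------
# simplified recorder-design framework: one division/day, no death,
# 100 modeled lineages, per-day per-site Bernoulli editing
# ----------------------------------------------------------------------

def expected_saturation(rate: float, days: int) -> float:
    """Closed-form per-site saturation after ``days`` days at per-day ``rate``."""
    return 1.0 - (1.0 - rate) ** days


def saturation_rate_table(
    experiment_lengths: Sequence[int] = tuple(range(1, 101)),
    targets: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    rate_grid: Optional[np.ndarray] = None,
    reps: int = 10,
    seed: int = 0,
    n_lineages: int = 100,
    n_sites: int = 100,
) -> pd.DataFrame:
    """Best grid rate for each (experiment length, saturation target).

    For each length T and rate, the mean end-point edit fraction over
    ``reps`` repetitions of ``n_lineages`` lineages x ``n_sites`` sites is
    simulated day by day; the grid rate whose mean is closest to the target
    is reported together with the achieved saturation (which reveals any
    shortfall when the target exceeds what the capped grid can reach).
    """
    if rate_grid is None:
        rate_grid = np.round(np.arange(0, 0.3001, 0.001), 3)
    rate_grid = np.asarray(rate_grid, dtype=float)
    if rate_grid.size == 0 or len(list(experiment_lengths)) == 0:
        raise ValueError("grids must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    total_sites = n_lineages * n_sites
    for T in experiment_lengths:
        unedited = np.full((rate_grid.size, reps), total_sites, dtype=np.int64)
        for _ in range(int(T)):
            unedited -= rng.binomial(unedited, rate_grid[:, None])
        sat = 1.0 - unedited.mean(axis=1) / total_sites
        for target in targets:
            k = int(np.argmin(np.abs(sat - target)))
            rows.append(
                {
                    "experiment_length": int(T),
                    "target": float(target),
                    "best_rate": float(rate_grid[k]),
                    "achieved": float(sat[k]),
                    "shortfall": float(max(0.0, target - sat[k])),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MinSitesResult:
    """Outcome of the minimum-edit-sites search."""

    achievable: bool
    min_sites: Optional[int]
    best_rate: Optional[float]
    achieved_fraction: Optional[float]


def _marked_fraction_for_rates(
    uniforms: np.ndarray, rates: np.ndarray, n_sites: int
) -> np.ndarray:
    """Mean marked-division fraction per rate for one site count.

    ``uniforms`` has shape (lineages, days, max_sites); a site edits on the
    first day its uniform draw falls below the rate.  A division (day) is
    marked when at least one site first edits on that day.  Sharing the
    uniforms across rates and site counts is a common-random-numbers scheme:
    each per-rate estimate is unbiased, the best-over-rates search is not
    inflated by independent noise, and the marked set grows monotonically
    with the number of sites.
    """
    n_lineages, n_days, _ = uniforms.shape
    u = uniforms[:, :, :n_sites]
    offsets = (np.arange(n_lineages) * n_days)[:, None]
    out = np.empty(rates.size)
    for i, r in enumerate(rates):
        hit = u < r
        any_hit = hit.any(axis=1)
        first = hit.argmax(axis=1)
        flat = (first + offsets)[any_hit]
        marked_days = np.bincount(flat, minlength=n_lineages * n_days) > 0
        out[i] = marked_days.reshape(n_lineages, n_days).sum(axis=1).mean() / n_days
    return out


def analytic_marked_fraction(rate: float, days: int, n_sites: int) -> float:
    """Closed-form mean marked-division fraction.

    P(division d marked) = 1 - (1 - r(1-r)**(d-1))**M: a site is still
    unedited at day d with probability (1-r)**(d-1) and edits that day with
    probability r.
    """
    d = np.arange(1, days + 1)
    return float(np.mean(1.0 - (1.0 - rate * (1.0 - rate) ** (d - 1)) ** n_sites))


def min_edit_sites_for_marked_fraction(
    days: int,
    target_marked: float = 0.9,
    site_grid: Sequence[int] = tuple(range(1, 121)),
    rate_grid: Optional[np.ndarray] = None,
    reps: int = 10,
    seed: int = 0,
    n_lineages: int = 100,
    rate_window: Optional[float] = 0.005,
) -> MinSitesResult:
    """Smallest number of edit sites marking >= target of divisions.

    Models ``reps x n_lineages`` root-to-leaf lineages of ``days`` divisions
    each (one division per day, no death).  For each site count the rate
    grid is scanned and the best mean marked-division fraction taken; the
    smallest site count whose best rate reaches the target is returned.

    Two standard variance controls keep the 10-rep search centered on its
    expectation: the closed-form expectation brackets the site-count search
    and prunes the rate grid to ``rate_window`` around the analytically
    optimal rate (pass ``rate_window=None`` to scan the full grid; the prune
    removes the upward bias of maximizing a noisy objective over 301
    rates), and one shared uniform tensor drives every (site count, rate)
    cell, which makes the marked fraction exactly monotone in the site
    count.
    """
    if rate_grid is None:
        rate_grid = np.round(np.arange(0, 0.3001, 0.001), 3)
    rate_grid = np.asarray(rate_grid, dtype=float)
    site_grid = sorted(int(m) for m in site_grid)
    if not site_grid or rate_grid.size == 0:
        raise ValueError("grids must be nonempty")

    max_sites = site_grid[-1]
    rng = np.random.default_rng(seed)
    uniforms = rng.random((reps * n_lineages, days, max_sites), dtype=np.float32)
    day_idx = np.arange(1, days + 1)

    def analytic_curve(m: int) -> np.ndarray:
        p = 1.0 - (1.0 - rate_grid[:, None] * (1.0 - rate_grid[:, None]) ** (day_idx - 1)) ** m
        return p.mean(axis=1)

    bracket = next(
        (m for m in site_grid if float(analytic_curve(m).max()) >= target_marked), None
    )
    if bracket is None:
        candidates = [site_grid[-1]]  # check the largest anyway
    else:
        lo = max(site_grid[0], bracket - 5)
        candidates = [m for m in site_grid if m >= lo]

    best: Optional[Tuple[int, float, float]] = None
    for m in candidates:
        curve = analytic_curve(m)
        if rate_window is None:
            rates = rate_grid
        else:
            r_star = rate_grid[int(curve.argmax())]
            rates = rate_grid[np.abs(rate_grid - r_star) <= rate_window + 1e-12]
        fractions = _marked_fraction_for_rates(uniforms, rates, m)
        k = int(np.argmax(fractions))
        if fractions[k] >= target_marked:
            best = (m, float(rates[k]), float(fractions[k]))
            break
    if best is None:
        return MinSitesResult(False, None, None, None)
    return MinSitesResult(True, best[0], best[1], best[2])


def plant_barcode_groups(tree: LineageTree, time_days: float, prefix: str = "bc") -> Dict[str, str]:
    """Label every leaf by the lineage its ancestors occupied at a timepoint.

    Emulates a static-barcoding round at ``time_days``: each lineage alive at
    that moment receives a distinct barcode that all its descendants inherit.
    Returns leaf -> group label; the number of distinct labels equals the
    number of lineages alive at the barcoding time.
    """
    times = tree.node_times()
    leaf_sets = tree.leaf_sets()
    groups: Dict[str, str] = {}
    idx = 0
    for node in tree.preorder():
        if node == tree.root:
            start = times[node] - (tree.root_length or 0.0)
        else:
            start = times[tree.parent(node)]
        end = times[node]
        alive = start <= time_days <= end if tree.is_leaf(node) else start <= time_days < end
        if alive:
            label = f"{prefix}{idx}"
            idx += 1
            for leaf in leaf_sets[node]:
                groups[str(leaf)] = label
    return groups


def simulate_experiment(
    config: SimulationConfig, seed: int
) -> Tuple[LineageTree, Dict[object, np.ndarray], CharacterMatrix, CharacterMatrix]:
    """Tree + ground-truth overlay + dropout in one reproducible call.

    Child seeds for the tree, the mark overlay, and the dropout are derived
    deterministically from ``seed`` so composite runs are bit-reproducible.
    Returns (tree, truth states, truth leaf matrix, observed matrix).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    tree = simulate_birth_death_with_retries(config, seeds[0])
    times = tree.node_times()
    total = float(np.mean([times[l] for l in tree.leaves]))
    truth_states, truth_cm = overlay_lineage_marks(tree, config, seeds[1], total_time=total)
    observed = apply_detection_dropout(truth_cm, config.detection_efficiency, seeds[2])
    return tree, truth_states, truth_cm, observed
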