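"""Rooted lineage trees.

A :class:`LineageTree` is a rooted tree whose internal nodes are cell
divisions, whose branch lengths are durations in days, and whose leaves are
the cells observed at the end of an experiment.  The founder cell's own
lifetime (the stem above the root division) is stored as ``root_length``.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = ["LineageTree"]


class LineageTree:
    """Rooted tree over cells with optional branch lengths (days).

    Parameters
    ----------
    graph
        Directed graph with parent->child edges.  Edge attribute ``length``
        (nonnegative float) holds branch duration when known.
    root
        The unique node without a parent.
    root_length
        Optional duration of the stem edge above the root (the founder's
        lifetime in simulated trees).
    """

    def __init__(self, graph: nx.DiGraph, root, root_length: Optional[float] = None):
        if root not in graph:
            raise ValueError(f"root {root!r} not in graph")
        for n in graph.nodes:
            deg = graph.in_degree(n)
            if n == root:
                if deg != 0:
                    raise ValueError("root must have no parent")
            elif deg != 1:
                raise ValueError(f"node {n!r} has in-degree {deg}, expected 1")
        for u, v, data in graph.edges(data=True):
            length = data.get("length")
            if length is not None and length < 0:
                raise ValueError(f"negative branch length on edge {u!r}->{v!r}")
        if root_length is not None and root_length < 0:
            raise ValueError("negative root_length")
        self.graph = graph
        self.root = root
        self.root_length = root_length
        #: optional node -> np.ndarray of per-site states
        self.states: Dict[object, np.ndarray] = {}

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def nodes(self) -> List:
        return list(self.graph.nodes)

    def children(self, node) -> List:
        return list(self.graph.successors(node))

    def parent(self, node):
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def is_leaf(self, node) -> bool:
        return self.graph.out_degree(node) == 0

    @property
    def leaves(self) -> List:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves)

    def branch_length(self, node) -> Optional[float]:
        """Length of the edge above ``node`` (``root_length`` for the root)."""
        if node == self.root:
            return self.root_length
        return self.graph.edges[self.parent(node), node].get("length")

    def set_branch_length(self, node, length: float) -> None:
        if node == self.root:
            self.root_length = float(length)
        else:
            self.graph.edges[self.parent(node), node]["length"] = float(length)

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator:
        return reversed(list(self.preorder()))

    def preorder(self) -> Iterator:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(self.children(node))

    def leaf_set(self, node) -> frozenset:
        """Leaves descending from ``node`` (including ``node`` if a leaf)."""
        return self.leaf_sets()[node]

    def leaf_sets(self) -> Dict[object, frozenset]:
        cached = self.__dict__.get("_leaf_sets")
        if cached is not None:
            return cached
        sets: Dict[object, frozenset] = {}
        for node in self.postorder():
            kids = self.children(node)
            if not kids:
                sets[node] = frozenset([node])
            else:
                acc = set()
                for k in kids:
                    acc |= sets[k]
                sets[node] = frozenset(acc)
        self.__dict__["_leaf_sets"] = sets
        return sets

    def depths(self) -> Dict[object, int]:
        """Edge-count depth of every node from the root (cached)."""
        cached = self.__dict__.get("_depths")
        if cached is not None:
            return cached
        d = {self.root: 0}
        for node in self.preorder():
            if node == self.root:
                continue
            d[node] = d[self.parent(node)] + 1
        self.__dict__["_depths"] = d
        return d

    def invalidate_caches(self) -> None:
        """Drop memoized depths/leaf sets after a topology change."""
        self.__dict__.pop("_depths", None)
        self.__dict__.pop("_leaf_sets", None)

    def node_times(self, include_root_length: bool = True) -> Dict[object, float]:
        """Root-to-node path length in days.

        When ``root_length`` is set and ``include_root_length`` is true, times
        are measured from the founder's birth so the root division occurs at
        ``root_length``.
        """
        t0 = self.root_length if (include_root_length and self.root_length) else 0.0
        times = {self.root: float(t0)}
        for node in self.preorder():
            if node == self.root:
                continue
            length = self.graph.edges[self.parent(node), node].get("length")
            if length is None:
                raise ValueError("tree lacks branch lengths")
            times[node] = times[self.parent(node)] + length
        return times

    def lca(self, nodes: Iterable):
        """Lowest common ancestor of a set of nodes."""
        nodes = list(nodes)
        if not nodes:
            raise ValueError("empty node set")
        depths = self.depths()
        current = nodes[0]
        for other in nodes[1:]:
            a, b = current, other
            while depths[a] > depths[b]:
                a = self.parent(a)
            while depths[b] > depths[a]:
                b = self.parent(b)
            while a != b:
                a, b = self.parent(a), self.parent(b)
            current = a
        return current

    def copy(self) -> "LineageTree":
        t = LineageTree(self.graph.copy(), self.root, self.root_length)
        t.states = {k: v.copy() for k, v in self.states.items()}
        return t

    def __repr__(self) -> str:  # pragma: no cover
        return f"<LineageTree {len(self.graph)} nodes, {self.n_leaves} leaves>"

    # ------------------------------------------------------------------
    # newick interchange (parsing delegated to dendropy)
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node) -> str:
            kids = self.children(node)
            label = str(node) if not kids else ""
            inner = f"({','.join(fmt(k) for k in kids)})" if kids else ""
            length = (
                self.graph.edges[self.parent(node), node].get("length")
                if node != self.root
                else self.root_length
            )
            suffix = f":{length:.10g}" if length is not None else ""
            return f"{inner}{label}{suffix}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "LineageTree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
        graph = nx.DiGraph()
        counter = [0]

        def name_of(dnode):
            if dnode.taxon is not None:
                return dnode.taxon.label
            if dnode.label:
                return dnode.label
            counter[0] += 1
            return f"_n{counter[0]}"

        names = {}
        for dnode in dt.preorder_node_iter():
            names[id(dnode)] = name_of(dnode)
        root = names[id(dt.seed_node)]
        graph.add_node(root)
        for dnode in dt.preorder_node_iter():
            for child in dnode.child_nodes():
                attrs = {}
                if child.edge.length is not None:
                    attrs["length"] = float(child.edge.length)
                graph.add_edge(names[id(dnode)], names[id(child)], **attrs)
        root_length = (
            float(dt.seed_node.edge.length) if dt.seed_node.edge.length is not None else None
        )
        return cls(graph, root, root_length)
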