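"""Random binary genealogies carrying a single-origin mutation.

Trees are built by a coalescent-style process: starting from the leaves,
pairs of lineages merge uniformly at random with exponential waiting times
(rate k*(k-1)/2 for k open lineages), producing a rooted binary tree with
leaves at time 0 and node times in generations increasing root-ward.  One
uniformly chosen edge (the edge above a uniformly chosen non-root node)
carries the mutation; the leaves below that edge are the true carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream

__all__ = ["Genealogy", "simulate_genealogy"]


@dataclass
class Genealogy:
    """Rooted tree stored as parent pointers with node times.

    Nodes ``0..n_leaves-1`` are leaves (time 0); internal nodes follow.
    ``parent[root] == -1``.  ``mutated_node`` identifies the child end of
    the mutated edge (for a single-leaf tree it is the leaf itself).
    """

    parent: np.ndarray
    time: np.ndarray
    leaf_labels: list[str]
    mutated_node: int = -1
    region: list[str] | None = None
    _children: list[list[int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        for node, par in enumerate(self.parent):
            if par >= 0 and not self.time[node] < self.time[par]:
                raise ValueError("child time must be strictly below parent time")
        self._children = [[] for _ in range(self.parent.size)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                self._children[par].append(node)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def leaves_below(self, node: int) -> set[str]:
        """Labels of all leaves in the subtree rooted at ``node``."""
        out: set[str] = set()
        stack = [int(node)]
        while stack:
            cur = stack.pop()
            if self.is_leaf(cur):
                out.add(self.leaf_labels[cur])
            else:
                stack.extend(self._children[cur])
        return out

    def carriers(self) -> set[str]:
        """True carriers: leaves below the mutated edge."""
        if self.mutated_node < 0:
            raise ValueError("tree carries no mutation")
        return self.leaves_below(self.mutated_node)

    def tmrca_all(self) -> float:
        """Root time: TMRCA of the full leaf set."""
        return float(self.time[self.root])

    def to_newick(self) -> str:
        """Newick string with branch lengths in generations."""

        def render(node: int) -> str:
            length = 0.0 if self.parent[node] < 0 else self.time[self.parent[node]] - self.time[node]
            if self.is_leaf(node):
                return f"{self.leaf_labels[node]}:{length:.6g}"
            inner = ",".join(render(c) for c in self._children[node])
            return f"({inner}):{length:.6g}"

        node = self.root
        if self.is_leaf(node):  # degenerate single-leaf tree
            return f"{self.leaf_labels[node]};"
        inner = ",".join(render(c) for c in self._children[node])
        return f"({inner});"


def simulate_genealogy(n_leaves: int, seed: int) -> Genealogy:
    """Random binary coalescent-style genealogy with one mutated edge.

    Raises
    ------
    ValueError
        If ``n_leaves`` < 1.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = substream(seed, "genealogy")
    labels = [f"L{i}" for i in range(n_leaves)]
    if n_leaves == 1:
        return Genealogy(
            parent=np.array([-1]),
            time=np.array([0.0]),
            leaf_labels=labels,
            mutated_node=0,
        )

    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    open_lineages = list(range(n_leaves))
    t = 0.0
    nxt = n_leaves
    while len(open_lineages) > 1:
        k = len(open_lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = open_lineages[i], open_lineages[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        open_lineages = [x for x in open_lineages if x not in (a, b)]
        open_lineages.append(nxt)
        nxt += 1

    # mutation on the edge above a uniformly chosen non-root node
    root = n_nodes - 1
    candidates = [x for x in range(n_nodes) if x != root]
    mutated = int(rng.choice(candidates))
    return Genealogy(parent=parent, time=time, leaf_labels=labels, mutated_node=mutated)
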