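"""Minimal Newick reader producing :class:`~panelgwas.synth.genealogy.Genealogy`.

Branch lengths are read as generations; leaves sit at time 0 and internal
node times are reconstructed bottom-up (maximum over children when the
input is not perfectly ultrametric).
"""

from __future__ import annotations

import numpy as np

from .genealogy import Genealogy

__all__ = ["parse_newick"]


class _Node:
    __slots__ = ("label", "length", "children")

    def __init__(self) -> None:
        self.label = ""
        self.length = 0.0
        self.children: list["_Node"] = []


def _tokenize(text: str):
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "(),;:":
            yield ch
            i += 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < len(text) and text[j] not in "(),;:" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


def parse_newick(text: str) -> Genealogy:
    """Parse a single Newick tree string into a Genealogy (no mutation set)."""
    tokens = list(_tokenize(text.strip()))
    if not tokens or tokens[-1] != ";":
        raise ValueError("newick string must end with ';'")
    pos = 0

    def parse_clade() -> _Node:
        nonlocal pos
        node = _Node()
        if tokens[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise ValueError("malformed newick")
        if pos < len(tokens) and tokens[pos] not in "(),;:":
            node.label = tokens[pos]
            pos += 1
        if pos < len(tokens) and tokens[pos] == ":":
            node.length = float(tokens[pos + 1])
            pos += 2
        return node

    root = parse_clade()
    if tokens[pos] != ";":
        raise ValueError("trailing content after tree")

    # assign ids: leaves first (in traversal order), then internal nodes
    leaves: list[_Node] = []
    internals: list[_Node] = []

    def collect(node: _Node) -> None:
        if node.children:
            for child in node.children:
                collect(child)
            internals.append(node)
        else:
            leaves.append(node)

    collect(root)
    ids: dict[int, int] = {}
    for i, node in enumerate(leaves):
        ids[id(node)] = i
    for j, node in enumerate(internals):
        ids[id(node)] = len(leaves) + j

    n = len(leaves) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    time = np.zeros(n)

    def set_links(node: _Node) -> float:
        my = ids[id(node)]
        if not node.children:
            time[my] = 0.0
            return 0.0
        t = 0.0
        for child in node.children:
            ct = set_links(child)
            parent[ids[id(child)]] = my
            t = max(t, ct + child.length)
        time[my] = t
        return t

    set_links(root)
    labels = [node.label or f"L{i}" for i, node in enumerate(leaves)]
    return Genealogy(parent=parent, time=time, leaf_labels=labels)
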