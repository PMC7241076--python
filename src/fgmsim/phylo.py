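"""Genealogy recording, pruning and tree-shape statistics.

Every cell division in the simulation appends nodes to a lineage record
(one node per daughter cell, parent pointer to the mother's node).
Generations are discrete and non-overlapping, so branch lengths measured
in generations equal numbers of cell divisions.

A serially sampled tree is reconstructed by pruning the record to a set
of retained tips (extant cells captured at sampling points), suppressing
unifurcating nodes and summing branch lengths across them.  A retained
tip that is itself ancestral to later retained tips (a sampled ancestor)
is attached as a zero-length leaf at its division node.

Tree imbalance is summarized by the normalized Sackin index (mean
topological depth of the tips, in edges) and the number of cherries
(internal nodes whose two children are both tips).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genealogy",
    "LineageRecorder",
    "prune_genealogy",
    "sackin_normalized",
    "count_cherries",
    "terminal_branch_lengths",
    "write_newick",
]


@dataclass
class Genealogy:
    """Rooted tree with branch lengths in cell divisions.

    ``children[v]`` lists ``(child, branch_length)`` pairs; leaves carry
    labels.  After pruning, every internal node has >= 2 children.
    """

    children: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)
    root: int = 0

    @classmethod
    def from_nested(cls, spec) -> "Genealogy":
        """Build a tree from nested tuples, for tests and small examples.

        ``spec`` is either a leaf label (str) or a tuple of
        ``(subtree_spec, branch_length)`` pairs.
        """
        tree = cls()
        counter = [0]

        def build(node_spec):
            nid = counter[0]
            counter[0] += 1
            if isinstance(node_spec, str):
                tree.labels[nid] = node_spec
                tree.children[nid] = []
                return nid
            kids = []
            tree.children[nid] = kids
            for sub, bl in node_spec:
                kids.append((build(sub), float(bl)))
            return nid

        tree.root = build(spec)
        return tree

    def tips(self) -> list[int]:
        return [v for v, kids in self.children.items() if not kids]

    def n_tips(self) -> int:
        return len(self.tips())

    def tip_depths(self) -> dict[int, int]:
        """Topological depth (edge count) of every tip."""
        depths = {}
        stack = [(self.root, 0)]
        while stack:
            v, d = stack.pop()
            kids = self.children[v]
            if not kids:
                depths[v] = d
            for child, _bl in kids:
                stack.append((child, d + 1))
        return depths


class LineageRecorder:
    """Append-only record of cell-division nodes.

    Nodes are numbered consecutively; roots carry parent -1.  Chunked
    storage keeps per-generation appends cheap.
    """

    def __init__(self):
        self._parent_chunks: list[np.ndarray] = []
        self._gen_chunks: list[np.ndarray] = []
        self._size = 0
        self.sampled_nodes: list[np.ndarray] = []
        self.sampled_labels: list[list[str]] = []

    def __len__(self) -> int:
        return self._size

    def new_nodes(self, parent_nodes: np.ndarray, gen: int) -> np.ndarray:
        parent_nodes = np.asarray(parent_nodes, dtype=np.int64)
        k = parent_nodes.size
        self._parent_chunks.append(parent_nodes.copy())
        self._gen_chunks.append(np.full(k, gen, dtype=np.int64))
        ids = np.arange(self._size, self._size + k, dtype=np.int64)
        self._size += k
        return ids

    def record_sample(self, node_ids: np.ndarray, labels: list[str]) -> None:
        self.sampled_nodes.append(np.asarray(node_ids, dtype=np.int64).copy())
        self.sampled_labels.append(list(labels))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self._parent_chunks:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return (
            np.concatenate(self._parent_chunks),
            np.concatenate(self._gen_chunks),
        )

    def all_sampled(self) -> tuple[np.ndarray, list[str]]:
        if not self.sampled_nodes:
            return np.empty(0, dtype=np.int64), []
        nodes = np.concatenate(self.sampled_nodes)
        labels = [lb for chunk in self.sampled_labels for lb in chunk]
        return nodes, labels

    def tree(self) -> Genealogy:
        """Serially sampled tree over every recorded sampling point."""
        parent, gen = self.arrays()
        nodes, labels = self.all_sampled()
        return prune_genealogy(parent, gen, nodes, labels)


def prune_genealogy(
    parent: np.ndarray,
    gen: np.ndarray,
    tip_nodes: np.ndarray,
    tip_labels: list[str] | None = None,
) -> Genealogy:
    """Subtree induced by ``tip_nodes`` with unifurcations suppressed.

    Branch lengths are generation (division) differences summed across
    suppressed nodes.  If the retained tips span several founder
    lineages, the founder roots are joined under a synthetic root at
    generation 0 so that the result remains a single tree.
    """
    parent = np.asarray(parent, dtype=np.int64)
    gen = np.asarray(gen, dtype=np.int64)
    tip_nodes = np.asarray(tip_nodes, dtype=np.int64)
    if tip_nodes.size == 0:
        raise ValueError("cannot prune to an empty tip set")
    if tip_nodes.size != np.unique(tip_nodes).size:
        raise ValueError("retained tips must be distinct nodes")
    if tip_nodes.min() < 0 or tip_nodes.max() >= parent.size:
        raise ValueError("retained tips are not nodes of the lineage record")
    if tip_labels is None:
        tip_labels = [str(v) for v in tip_nodes]

    # Climb tip-to-root paths; nodes visited twice are merge points.
    counts: dict[int, int] = {}
    roots: set[int] = set()
    for tip in tip_nodes:
        v = int(tip)
        while True:
            c = counts.get(v, 0) + 1
            counts[v] = c
            if c >= 2:
                break
            p = int(parent[v])
            if p < 0:
                roots.add(v)
                break
            v = p

    tip_set = set(int(v) for v in tip_nodes)
    kept = set(v for v, c in counts.items() if c >= 2) | tip_set | roots

    children: dict[int, list[tuple[int, float]]] = {v: [] for v in kept}
    for v in kept:
        if v in roots:
            continue
        u = int(parent[v])
        while u not in kept:
            u = int(parent[u])
        children[u].append((v, float(gen[v] - gen[u])))

    if len(roots) == 1:
        root = next(iter(roots))
    else:
        root = -1  # synthetic root joining surviving founder lineages
        children[root] = [(r, float(gen[r])) for r in sorted(roots)]

    tree = Genealogy(children=children, labels={}, root=root)
    label_of = dict(zip((int(v) for v in tip_nodes), tip_labels))

    # Sampled ancestors become zero-length pendant leaves.
    next_id = int(parent.size)
    for v in sorted(tip_set):
        if children[v]:
            leaf = next_id
            next_id += 1
            children[v].append((leaf, 0.0))
            children[leaf] = []
            tree.labels[leaf] = label_of[v]
        else:
            tree.labels[v] = label_of[v]

    # Drop unlabeled unifurcating chains above the first real split.
    while len(children[tree.root]) == 1 and tree.root not in tree.labels:
        tree.root = children[tree.root][0][0]
    return tree


def sackin_normalized(tree: Genealogy) -> float:
    """Total topological tip depth divided by the number of tips."""
    depths = tree.tip_depths()
    if len(depths) < 2:
        raise ValueError("Sackin index requires at least 2 tips")
    return sum(depths.values()) / len(depths)


def count_cherries(tree: Genealogy) -> int:
    """Internal nodes whose two children are both tips."""
    if tree.n_tips() < 2:
        raise ValueError("cherry count requires at least 2 tips")
    cherries = 0
    for v, kids in tree.children.items():
        if len(kids) == 2 and all(not tree.children[c] for c, _ in kids):
            cherries += 1
    return cherries


def terminal_branch_lengths(tree: Genealogy) -> np.ndarray:
    """Branch lengths (divisions) of all pendant edges."""
    out = []
    for _v, kids in tree.children.items():
        for child, bl in kids:
            if not tree.children[child]:
                out.append(bl)
    return np.asarray(out, dtype=float)


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " ,():;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Genealogy) -> str:
    """Standard Newick string with branch lengths in cell divisions."""
    parts: dict[int, str] = {}
    # post-order without recursion (pruned trees can still be deep)
    stack = [(tree.root, False)]
    while stack:
        v, done = stack.pop()
        kids = tree.children[v]
        if not kids:
            parts[v] = _newick_label(tree.labels.get(v, str(v)))
            continue
        if not done:
            stack.append((v, True))
            stack.extend((c, False) for c, _ in kids)
        else:
            inner = ",".join(f"{parts[c]}:{bl:g}" for c, bl in kids)
            parts[v] = f"({inner})"
    return parts[tree.root] + ";"
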