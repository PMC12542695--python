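"""Rooted phylogenies with optional binary tip states.

Trees are held as :class:`dendropy.Tree` objects wrapped in
:class:`StatePhylogeny`, which adds the tip→{0,1} state map used by the
BiSSE machinery (state 0 = generalist, 1 = specialist by convention).
Only plain Newick is supported; branch lengths are mandatory on non-root
edges, must be non-negative, and zero-length branches are permitted but
logged.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "StatePhylogeny",
    "TreeError",
    "read_newick",
    "write_newick",
    "cophenetic",
    "tree_to_arrays",
]


class TreeError(ValueError):
    """Raised on malformed Newick input or invalid tree structure."""


@dataclass
class StatePhylogeny:
    """A rooted tree with branch lengths and optional binary tip states."""

    tree: dendropy.Tree
    tip_states: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels")
        n_zero = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise TreeError("branch without a length")
            if edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
            if edge.length == 0:
                n_zero += 1
        if n_zero:
            log.warning("tree contains %d zero-length branches", n_zero)
        if self.tip_states is not None:
            missing = [t for t in labels if t not in self.tip_states]
            if missing:
                raise TreeError(f"tips without a state: {missing[:5]}")
            bad = {t: s for t, s in self.tip_states.items() if s not in (0, 1)}
            if bad:
                raise TreeError(f"tip states must be 0/1, got {bad}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def is_binary(self) -> bool:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if len(node.child_nodes()) != 2:
                return False
        return True

    def root_height(self) -> float:
        """Maximum root-to-tip path length."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return max(leaf.root_distance for leaf in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick: {exc}") from exc
    return tree


def read_newick(path_or_string, tip_states: dict[str, int] | None = None) -> StatePhylogeny:
    """Read a single plain-Newick tree from a file path or literal string."""
    text = str(path_or_string)
    if "(" in text and ";" in text:
        tree = _tree_from_string(text)
    else:
        with open(text, encoding="utf-8") as fh:
            tree = _tree_from_string(fh.read())
    return StatePhylogeny(tree, tip_states)


def write_newick(phylo: StatePhylogeny, path, states_path=None) -> None:
    """Write the tree as Newick; optionally write tip states as a 2-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(phylo.as_newick() + "\n")
    if states_path is not None:
        if phylo.tip_states is None:
            raise TreeError("no tip states to write")
        pd.DataFrame(
            {"tip": list(phylo.tip_states), "state": list(phylo.tip_states.values())}
        ).to_csv(states_path, sep="\t", index=False, encoding="utf-8")


def read_tip_states(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    return {str(t): int(s) for t, s in zip(df.iloc[:, 0], df.iloc[:, 1])}


def cophenetic(phylo: StatePhylogeny) -> pd.DataFrame:
    """Tip × tip patristic distance matrix (sum of branch lengths on paths)."""
    pdm = phylo.tree.phylogenetic_distance_matrix()
    labels = phylo.tip_labels
    taxa = {t.label: t for t in phylo.tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class TreeArrays:
    """Flat postorder encoding of a rooted binary tree for the likelihood core.

    Nodes are numbered 0..n_nodes-1 with tips first (in ``tip_labels`` order).
    ``child_left``/``child_right`` are -1 for tips; ``blen[i]`` is the length
    of the branch above node i (0 for the root); ``postorder`` lists internal
    node visit order ending at the root.
    """

    tip_labels: list[str]
    child_left: np.ndarray
    child_right: np.ndarray
    blen: np.ndarray
    postorder: np.ndarray
    root: int


def tree_to_arrays(phylo: StatePhylogeny) -> TreeArrays:
    if not phylo.is_binary():
        raise TreeError("tree must be strictly bifurcating")
    tips = list(phylo.tree.leaf_node_iter())
    tip_labels = [t.taxon.label for t in tips]
    index: dict[int, int] = {id(node): i for i, node in enumerate(tips)}
    internals = [
        n for n in phylo.tree.postorder_node_iter() if not n.is_leaf()
    ]
    for k, node in enumerate(internals):
        index[id(node)] = len(tips) + k
    n_nodes = len(tips) + len(internals)
    child_left = np.full(n_nodes, -1, dtype=np.int64)
    child_right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    for node in phylo.tree.postorder_node_iter():
        i = index[id(node)]
        if node.edge.length is not None and node.parent_node is not None:
            blen[i] = node.edge.length
        if not node.is_leaf():
            left, right = node.child_nodes()
            child_left[i] = index[id(left)]
            child_right[i] = index[id(right)]
    postorder = np.array([index[id(n)] for n in internals], dtype=np.int64)
    root = index[id(phylo.tree.seed_node)]
    return TreeArrays(tip_labels, child_left, child_right, blen, postorder, root)


def tip_state_array(phylo: StatePhylogeny, arrays: TreeArrays) -> np.ndarray:
    if phylo.tip_states is None:
        raise TreeError("phylogeny carries no tip states")
    return np.array([phylo.tip_states[t] for t in arrays.tip_labels], dtype=np.int64)
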