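"""Phylogenetic trees as flat arrays, built from newick via dendropy.

The likelihood engine needs only a rooted topology in postorder with a
branch length above every non-root node.  Under a time-reversible model
the likelihood does not depend on the root placement, so unrooted newick
trees are handled by treating the (possibly trifurcating) first node as
the root.  Branch lengths are expected substitutions per codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed trees or tree/alignment mismatches."""


@dataclass
class PhylogeneticTree:
    """Rooted tree over ``n_nodes`` nodes; node 0..n_leaves-1 are leaves.

    Attributes
    ----------
    taxa
        Leaf labels, index-aligned with node ids ``0..len(taxa)-1``.
    parent
        Parent node id per node; -1 for the root.
    lengths
        Branch length above each node (ignored for the root).
    postorder
        Node ids, children before parents, root last.
    edge_ids
        Stable label per non-root node's parent edge: the leaf name for
        terminal edges, ``"node<k>"`` for internal edges.
    """

    taxa: list[str]
    parent: np.ndarray
    lengths: np.ndarray
    postorder: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lengths[self._non_root_mask()] < 0):
            raise TreeError("negative branch length")

    def _non_root_mask(self) -> np.ndarray:
        return self.parent >= 0

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    def children(self, node: int) -> list[int]:
        return [int(i) for i in np.where(self.parent == node)[0]]

    @property
    def edge_ids(self) -> list[str]:
        """Edge label for every non-root node, in node-id order."""
        out = []
        for node in range(self.n_nodes):
            if self.parent[node] < 0:
                continue
            out.append(self.taxa[node] if node < self.n_leaves else f"node{node}")
        return out

    def edge_nodes(self) -> list[int]:
        """Node ids owning an edge (all non-root nodes), in node-id order."""
        return [int(i) for i in np.where(self._non_root_mask())[0]]

    @property
    def total_length(self) -> float:
        return float(self.lengths[self._non_root_mask()].sum())

    def with_lengths(self, lengths: np.ndarray) -> "PhylogeneticTree":
        """Copy of the tree with branch lengths replaced (edge-node order)."""
        new = self.lengths.copy()
        new[self.edge_nodes()] = np.asarray(lengths, dtype=float)
        return PhylogeneticTree(self.taxa, self.parent.copy(), new, self.postorder.copy())

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_length: float | None = None) -> "PhylogeneticTree":
        """Parse a newick string.

        Missing branch lengths raise :class:`TreeError` unless
        ``default_length`` is given.
        """
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls.from_dendropy(dtree, default_length=default_length)

    @classmethod
    def from_dendropy(
        cls, dtree: dendropy.Tree, default_length: float | None = None
    ) -> "PhylogeneticTree":
        leaves = [lf for lf in dtree.leaf_node_iter()]
        taxa = [lf.taxon.label if lf.taxon else "" for lf in leaves]
        if len(set(taxa)) != len(taxa) or "" in taxa:
            raise TreeError("leaf labels must be present and unique")
        node_id: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            node_id[id(lf)] = i
        next_id = len(leaves)
        for node in dtree.postorder_node_iter():
            if id(node) not in node_id:
                node_id[id(node)] = next_id
                next_id += 1
        n = next_id
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n, dtype=float)
        post = []
        for node in dtree.postorder_node_iter():
            nid = node_id[id(node)]
            post.append(nid)
            if node.parent_node is not None:
                parent[nid] = node_id[id(node.parent_node)]
                el = node.edge.length
                if el is None:
                    if default_length is None:
                        raise TreeError(
                            "branch without length (pass default_length to allow)"
                        )
                    el = default_length
                if el < 0:
                    raise TreeError(f"negative branch length {el}")
                lengths[nid] = float(el)
        return cls(taxa, parent, lengths, np.asarray(post, dtype=np.int64))

    def to_newick(self) -> str:
        def render(node: int) -> str:
            kids = self.children(node)
            label = self.taxa[node] if node < self.n_leaves else ""
            if kids:
                label = "(" + ",".join(render(k) for k in kids) + ")" + label
            if self.parent[node] >= 0:
                label += f":{self.lengths[node]:.6g}"
            return label

        return render(self.root) + ";"

    def check_taxa(self, taxa: list[str]) -> None:
        """Require every alignment taxon to be a leaf of this tree."""
        missing = sorted(set(taxa) - set(self.taxa))
        if missing:
            raise TreeError(f"taxa missing from tree: {missing}")
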