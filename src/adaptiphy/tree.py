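"""Rooted phylogenetic trees with branch lengths in expected substitutions/site.

Trees are parsed from Newick via dendropy and flattened into postorder
index arrays so the likelihood and simulation kernels can run on plain
numpy. Every non-root node defines one branch (the branch above it);
branches are addressed by name: a leaf branch carries the leaf's name, an
internal branch the '+'-joined sorted names of the leaves below it.
"""

from __future__ import annotations

import io

import numpy as np
import dendropy

__all__ = [
    "PhyloTree",
    "TreeError",
    "read_newick",
    "write_newick",
    "relative_branch_lengths",
    "DEFAULT_PRIMATE_NEWICK",
]

#: Default 5-taxon catarrhine topology with typical neutral branch lengths
#: (substitutions/site); the human branch matches the mean rate observed
#: for filtered genome-wide nonfunctional regions.
DEFAULT_PRIMATE_NEWICK = (
    "((((human:0.0072,chimp:0.0074):0.0030,gorilla:0.0088):0.0080,"
    "orangutan:0.0180):0.0120,macaque:0.0320);"
)


class TreeError(ValueError):
    """Malformed Newick or an operation on an unsuitable tree."""


class PhyloTree:
    """Rooted tree over named leaves, flattened to arrays.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 at the root
    children : list of child-index lists per node
    blen : (n_nodes,) float array; branch length *above* each node
        (nan when absent; the root entry is always nan)
    postorder : node indices, children before parents
    names : branch/leaf name per node (internal nodes get derived labels)
    """

    def __init__(self, parent, blen, names, leaf_mask):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.names = list(names)
        self.leaf_mask = np.asarray(leaf_mask, dtype=bool)
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                self.children[p].append(i)
        if root < 0:
            raise TreeError("tree has no root")
        self.root = root
        # postorder via iterative DFS
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        self.postorder = np.array(order[::-1], dtype=int)
        self.leaf_indices = {
            self.names[i]: i for i in range(n) if self.leaf_mask[i]
        }
        if len(self.leaf_indices) != int(self.leaf_mask.sum()):
            raise TreeError("duplicate leaf names")
        self._name_to_node = {self.names[i]: i for i in range(n)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.full(n, np.nan)
        names: list[str | None] = [None] * n
        leaf_mask = np.zeros(n, dtype=bool)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is not None:
                    blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                leaf_mask[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("leaf without a name")
                names[i] = nd.taxon.label.replace(" ", "_")
        # label internal nodes by their leaf sets
        for i in reversed(range(n)):  # children have higher preorder index
            if not leaf_mask[i]:
                below = sorted(
                    names[j]
                    for j in range(n)
                    if leaf_mask[j] and _is_descendant(parent, j, i)
                )
                names[i] = "+".join(below) if below else f"node{i}"
        return cls(parent, blen, names, leaf_mask)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise TreeError(f"invalid Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.leaf_indices)

    def branch_nodes(self) -> np.ndarray:
        """Node indices that carry a branch (everything but the root)."""
        return self.postorder[self.postorder != self.root]

    def branch_names(self) -> list[str]:
        return [self.names[i] for i in self.branch_nodes()]

    def branch_index(self, name: str) -> int:
        try:
            idx = self._name_to_node[name]
        except KeyError:
            raise TreeError(f"no branch named {name!r}") from None
        if idx == self.root:
            raise TreeError("the root carries no branch")
        return idx

    def branch_lengths(self) -> dict[str, float]:
        return {self.names[i]: float(self.blen[i]) for i in self.branch_nodes()}

    @property
    def total_length(self) -> float:
        bl = self.blen[self.branch_nodes()]
        return float(np.nansum(bl))

    def has_lengths(self) -> bool:
        return not np.isnan(self.blen[self.branch_nodes()]).any()

    def require_lengths(self) -> None:
        if not self.has_lengths():
            raise TreeError("tree is missing branch lengths")

    # -- derived trees ------------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(), self.blen.copy(), self.names, self.leaf_mask
        )

    def with_lengths(self, lengths) -> "PhyloTree":
        """New tree with branch lengths replaced.

        ``lengths`` is either a mapping branch-name -> length or an array
        aligned with :meth:`branch_nodes`.
        """
        blen = self.blen.copy()
        if isinstance(lengths, dict):
            for name, value in lengths.items():
                blen[self.branch_index(name)] = float(value)
        else:
            blen[self.branch_nodes()] = np.asarray(lengths, dtype=float)
        return PhyloTree(self.parent.copy(), blen, self.names, self.leaf_mask)

    def scaled(self, branches, alpha: float) -> "PhyloTree":
        """Multiply the lengths of the named branches by ``alpha``."""
        if alpha < 0:
            raise ValueError("scaling factor must be >= 0")
        if isinstance(branches, str):
            branches = [branches]
        blen = self.blen.copy()
        for name in branches:
            blen[self.branch_index(name)] *= alpha
        return PhyloTree(self.parent.copy(), blen, self.names, self.leaf_mask)

    # -- output -------------------------------------------------------

    def to_newick(self) -> str:
        self_root = self.root

        def render(node: int) -> str:
            if self.leaf_mask[node]:
                label = self.names[node]
            else:
                label = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self_root:
                return label
            t = self.blen[node]
            return label if np.isnan(t) else f"{label}:{t:.10g}"

        return render(self_root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.to_newick()!r})"


def _is_descendant(parent: np.ndarray, node: int, ancestor: int) -> bool:
    while node >= 0:
        if node == ancestor:
            return True
        node = parent[node]
    return False


def read_newick(source) -> PhyloTree:
    """Parse Newick from a string, open handle, or path."""
    if isinstance(source, io.IOBase):
        text = source.read()
    elif isinstance(source, str) and ("(" in source or ";" in source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def relative_branch_lengths(tree: PhyloTree) -> dict[str, float]:
    """Branch lengths divided by total tree length (sums to 1).

    The filtering statistic for proxy-neutral selection: it is invariant
    to the overall substitution rate, so slow and fast regions can be
    compared on one scale.
    """
    tree.require_lengths()
    total = tree.total_length
    if total <= 0:
        raise TreeError("relative branch lengths undefined for zero-length tree")
    return {name: t / total for name, t in tree.branch_lengths().items()}
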