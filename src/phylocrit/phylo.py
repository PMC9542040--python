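"""Phylogeny handling: Newick I/O, Grafen branch lengths, rho rescaling,
and the species-level correlation matrix used as the random-effect covariance.

Topologies come from a user-supplied Newick tree (e.g. an Open Tree of Life
induced subtree). Input branch lengths are irrelevant: node heights are
assigned by Grafen's method — height proportional to (number of descendant
tips − 1), normalized so tips sit at 0 and the root at 1 — and optionally
power-transformed by Grafen's rho. With rho < 1 every internal node moves
rootward in relative terms, stretching the branches near the tips so recent
divergences carry more weight.

Under a Brownian-motion trait model on such a tree the between-species
correlation of two tips equals the shared root-to-MRCA path length, which for
these normalized heights is simply 1 − height(MRCA). The resulting matrix has
a unit diagonal, making the phylogenetic variance parameter of the mixed
model directly interpretable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "PhyloCorrelation",
    "parse_newick",
    "write_newick",
    "prune",
    "grafen_heights",
    "rho_transform",
    "correlation_matrix",
    "DEFAULT_RHO",
]

#: Grafen's rho used throughout the pipeline (tip-branch expansion).
DEFAULT_RHO = 0.4

_HEIGHT_ATTR = "grafen_height"


@dataclass
class Tree:
    """A rooted tree with unique tip labels, wrapping a dendropy tree.

    ``heights_assigned`` is True once :func:`grafen_heights` has run; node
    heights live on each dendropy node as ``grafen_height`` and edge lengths
    are kept consistent with them.
    """

    dtree: dendropy.Tree
    heights_assigned: bool = False

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def height(self, node) -> float:
        return getattr(node, _HEIGHT_ATTR)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a rooted :class:`Tree`.

    Branch lengths present in the input are discarded (Grafen lengths
    replace them downstream). Duplicate tip labels are an error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various parse error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    dtree.is_rooted = True
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in dtree.preorder_edge_iter():
        edge.length = None
    return Tree(dtree=dtree)


def write_newick(tree: Tree, *, with_lengths: bool | None = None) -> str:
    """Serialize to Newick; branch lengths included once heights are assigned."""
    if with_lengths is None:
        with_lengths = tree.heights_assigned
    out = io.StringIO()
    tree.dtree.write(
        file=out,
        schema="newick",
        suppress_edge_lengths=not with_lengths,
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip()


def prune(tree: Tree, keep: set[str]) -> Tree:
    """Induced subtree on the tip set ``keep``; degree-2 nodes are suppressed.

    Raises if ``keep`` is empty or names tips absent from the tree (the
    missing names are listed).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    labels = set(tree.tip_labels)
    missing = sorted(keep - labels)
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    # work on a deep copy so the input tree is untouched
    dtree = dendropy.Tree(tree.dtree)
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    dtree.retain_taxa(taxa)
    dtree.purge_taxon_namespace()
    for edge in dtree.preorder_edge_iter():
        edge.length = None
    return Tree(dtree=dtree)


def grafen_heights(tree: Tree) -> Tree:
    """Assign Grafen node heights: (descendant tips − 1), normalized by (n − 1).

    Tips get height 0 and the root height 1; each branch length is
    height(parent) − height(child). Polytomies are handled as-is — the rule
    only counts descendant tips. Returns a new Tree; the input is untouched.
    """
    n = tree.n_tips
    if n < 2:
        raise ValueError("Grafen heights need at least 2 tips")
    dtree = dendropy.Tree(tree.dtree)
    out = Tree(dtree=dtree, heights_assigned=True)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            node.num_tips = 1
        else:
            node.num_tips = sum(ch.num_tips for ch in node.child_nodes())
        setattr(node, _HEIGHT_ATTR, (node.num_tips - 1) / (n - 1))
    _edges_from_heights(out)
    return out


def rho_transform(tree: Tree, rho: float = DEFAULT_RHO) -> Tree:
    """Power-transform Grafen heights: h ← h**rho; recompute branch lengths.

    rho < 1 raises every internal height (h in (0,1) ⇒ h**rho > h), which
    lengthens the tip-adjacent branches; rho = 1 is the identity.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if not tree.heights_assigned:
        raise ValueError("assign Grafen heights before rho transform")
    dtree = dendropy.Tree(tree.dtree)
    out = Tree(dtree=dtree, heights_assigned=True)
    _heights_from_edges(out)  # tree copies do not carry custom node attributes
    for node in dtree.preorder_node_iter():
        h = getattr(node, _HEIGHT_ATTR)
        setattr(node, _HEIGHT_ATTR, float(h) ** rho)
    _edges_from_heights(out)
    return out


def _heights_from_edges(tree: Tree) -> None:
    """Rebuild node heights from edge lengths (root height 1 by convention)."""
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            setattr(node, _HEIGHT_ATTR, 1.0)
        else:
            setattr(
                node,
                _HEIGHT_ATTR,
                getattr(node.parent_node, _HEIGHT_ATTR) - node.edge.length,
            )


def _edges_from_heights(tree: Tree) -> None:
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = getattr(node.parent_node, _HEIGHT_ATTR) - getattr(
                node, _HEIGHT_ATTR
            )


@dataclass
class PhyloCorrelation:
    """Species-by-species Brownian correlation matrix from an ultrametric tree."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("matrix diagonal is not 1 (heights not normalized?)")
        self.matrix = m

    def reorder(self, species: list[str]) -> "PhyloCorrelation":
        """Return the matrix restricted/reordered to ``species``."""
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)


def correlation_matrix(tree: Tree) -> PhyloCorrelation:
    """C[i, j] = shared root-to-MRCA path = 1 − height(MRCA(i, j)); C[i, i] = 1.

    Computed in one postorder sweep: at each internal node, every tip pair
    whose lineages first meet there (pairs across distinct child subtrees)
    gets 1 − height(node).
    """
    if not tree.heights_assigned:
        raise ValueError("assign Grafen heights (and optionally rho) first")
    tips = list(tree.dtree.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.eye(n)
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [index[id(node)]]
            continue
        child_sets = [ch._tipset for ch in node.child_nodes()]
        shared = 1.0 - tree.height(node)
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = shared
        node._tipset = [i for s in child_sets for i in s]
    for node in tree.dtree.postorder_node_iter():
        if hasattr(node, "_tipset"):
            del node._tipset
    return PhyloCorrelation(species=labels, matrix=C)
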