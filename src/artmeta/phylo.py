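"""Species-level correlation structure from a phylogenetic tree.

The meta-analytic model wants a species-by-species correlation matrix A with
unit diagonal.  Input supertrees typically lack meaningful branch lengths, so
the pipeline is: set every branch length to 1, make the tree ultrametric with
Grafen's node-height construction, then read off A as shared root-to-MRCA
path length divided by total depth.  Trees are dendropy ``Tree`` objects
throughout; Newick is the interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "read_tree",
    "write_tree",
    "unit_branch_lengths",
    "grafen_transform",
    "is_ultrametric",
    "vcv_from_tree",
    "prune",
    "attach_polytomy",
]

_ULTRAMETRIC_TOL = 1e-8


@dataclass
class PhyloCovariance:
    """Ordered species labels plus a symmetric PSD correlation matrix (unit
    diagonal)."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(m).min())
        if eigmin < -1e-8:
            raise ValueError(f"correlation matrix not PSD (min eigenvalue {eigmin:.3g})")
        self.matrix = m

    def submatrix(self, keep: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(s) for s in keep]
        return PhyloCovariance(list(keep), self.matrix[np.ix_(idx, idx)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def read_tree(source: str, *, from_string: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree (quoted labels and polytomies allowed)."""
    kwargs = {"data": source} if from_string else {"path": source}
    tree = dendropy.Tree.get(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        rooting="force-rooted",
        **kwargs,
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels must be unique")
    return tree


def write_tree(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True)


def _copy(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def unit_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a copy with every edge length set to 1 (root edge excluded)."""
    out = _copy(tree)
    for edge in out.preorder_edge_iter():
        if edge.head_node is not out.seed_node:
            edge.length = 1.0
    out.seed_node.edge.length = None
    return out


def grafen_transform(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Make the tree ultrametric by Grafen's node-height rule.

    Each node's height above the tips is ((n_descendant_tips - 1) ** rho)
    normalized by ((n_total_tips - 1) ** rho), so tips sit at height 0 and the
    root at height 1; branch lengths are recomputed from the heights.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    out = _copy(tree)
    n_tips = len(out.leaf_nodes())
    if n_tips < 2:
        raise ValueError("need at least two tips")
    denom = float(n_tips - 1) ** rho
    heights: dict[int, float] = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            heights[id(node)] = 0.0
        else:
            m = sum(1 for _ in node.leaf_iter())
            heights[id(node)] = float(m - 1) ** rho / denom
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            node.edge.length = None
        else:
            node.edge.length = heights[id(node.parent_node)] - heights[id(node)]
    return out


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depths[id(node)]
    return out


def is_ultrametric(tree: dendropy.Tree, tol: float = _ULTRAMETRIC_TOL) -> bool:
    d = np.array(list(_tip_depths(tree).values()))
    return bool(d.size and np.ptp(d) <= tol * max(1.0, d.max()))


def vcv_from_tree(tree: dendropy.Tree, tol: float = 1e-6) -> PhyloCovariance:
    """Correlation matrix: shared root-to-MRCA path of each tip pair divided by
    total depth.  The tree must be ultrametric (equal root-to-tip distances)."""
    tip_depths = _tip_depths(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    depth = float(np.mean(list(tip_depths.values())))
    if depth <= 0:
        raise ValueError("tree has zero depth")
    if not is_ultrametric(tree, tol):
        raise ValueError("tree is not ultrametric; apply grafen_transform first")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mat = np.eye(n)

    # Node depths from the root; pairs of tips split across different children
    # of a node have that node as MRCA.
    node_depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node_depth[id(node)] = node_depth[id(node.parent_node)] + (node.edge.length or 0.0)
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [index[node.taxon.label]]
        else:
            children = [tipsets[id(c)] for c in node.child_nodes()]
            share = node_depth[id(node)] / depth
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            mat[i, j] = mat[j, i] = share
            tipsets[id(node)] = [i for sub in children for i in sub]
    return PhyloCovariance(labels, mat)


def prune(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; degree-2 nodes collapsed, lengths summed."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(keep) - tips
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    out = _copy(tree)
    if set(keep) == tips:
        return out
    out.retain_taxa_with_labels(list(keep))
    return out


def attach_polytomy(
    tree: dendropy.Tree, new_species: list[str], at_clade: set[str]
) -> dendropy.Tree:
    """Attach species of uncertain placement as extra children of the crown
    node of a named monophyletic clade (a polytomy at the clade's base).

    Branch lengths are left at 1 for the new tips; re-run the unit-length +
    Grafen pipeline before building a covariance matrix.
    """
    out = _copy(tree)
    taxa = [t for t in out.taxon_namespace if t.label in at_clade]
    if len(taxa) != len(at_clade):
        raise ValueError("at_clade contains labels missing from the tree")
    mrca = out.mrca(taxa=taxa)
    clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if clade_tips != set(at_clade):
        raise ValueError(f"at_clade is not monophyletic (crown spans {sorted(clade_tips)})")
    for label in new_species:
        taxon = out.taxon_namespace.new_taxon(label)
        child = dendropy.Node(taxon=taxon)
        child.edge.length = 1.0
        mrca.add_child(child)
    return out
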