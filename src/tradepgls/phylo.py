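"""Phylogeny handling: parsing, pruning, and variance-covariance matrices.

Under a Brownian-motion model of trait evolution on a rooted tree, the
expected covariance between the trait values of two tips equals the branch
length shared on their root-to-tip paths, i.e. the depth of their most
recent common ancestor.  The resulting tip-by-tip matrix (the phylogenetic
VCV) is what generalized least squares consumes; Pagel's lambda rescales
its off-diagonal part to modulate the strength of phylogenetic signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "VCV",
    "parse_trees",
    "prune_to_taxa",
    "vcv_from_tree",
    "lambda_transform",
]


class TreeParseError(ValueError):
    """Raised when a tree file cannot be parsed."""


@dataclass
class VCV:
    """Phylogenetic variance-covariance matrix with its tip ordering.

    ``matrix[i, j]`` is the root-to-MRCA path length for tips ``taxa[i]``
    and ``taxa[j]``; the diagonal holds root-to-tip depths.
    """

    matrix: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("VCV matrix must be square")
        if self.taxa and len(self.taxa) != self.matrix.shape[0]:
            raise ValueError("taxon list length does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, taxa: list[str]) -> "VCV":
        """Restrict to ``taxa`` (in the given order)."""
        idx = [self.taxa.index(t) for t in taxa]
        return VCV(self.matrix[np.ix_(idx, idx)], list(taxa))

    def reorder(self, taxa: list[str]) -> "VCV":
        if set(taxa) != set(self.taxa):
            raise ValueError("reorder requires the same taxon set")
        return self.submatrix(list(taxa))


def _normalize_label(label: str, underscores: bool = True) -> str:
    label = label.strip()
    if underscores:
        label = label.replace(" ", "_")
    return label


def normalize_tip_labels(tree: dendropy.Tree, underscores: bool = True) -> dendropy.Tree:
    """Normalize tip labels in place (space/underscore unification)."""
    for taxon in tree.taxon_namespace:
        if taxon.label is not None:
            taxon.label = _normalize_label(taxon.label, underscores)
    return tree


def parse_trees(path: str | os.PathLike, schema: str | None = None,
                underscores: bool = True) -> list[dendropy.Tree]:
    """Read one or more rooted trees from a Newick or NEXUS file.

    Parameters
    ----------
    path
        Path to the tree file.  The schema is inferred from the extension
        (``.nex``/``.nexus``/``.trees`` -> NEXUS, otherwise Newick) unless
        given explicitly.
    schema
        ``"newick"`` or ``"nexus"``; overrides extension-based inference.
    underscores
        If True (default), tip labels are normalized by replacing spaces
        with underscores so labels match trait-table species ids.

    Returns
    -------
    list of dendropy.Tree, in file order, each with its own taxon namespace.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if schema is None:
        ext = os.path.splitext(path)[1].lower()
        schema = "nexus" if ext in {".nex", ".nexus", ".trees"} else "newick"
    with open(path) as fh:
        if not fh.read().strip():
            raise TreeParseError(f"no trees found in {path!r}")
    try:
        trees = dendropy.TreeList.get(
            path=path,
            schema=schema,
            preserve_underscores=True,
            taxon_namespace=dendropy.TaxonNamespace(),
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"could not parse {path!r} as {schema}: {exc}") from exc
    if len(trees) == 0:
        raise TreeParseError(f"no trees found in {path!r}")
    out = []
    for t in trees:
        # detach each tree onto its own namespace so pruning one tree never
        # mutates the taxa of another
        t2 = t.clone(depth=1)
        t2.migrate_taxon_namespace(dendropy.TaxonNamespace())
        normalize_tip_labels(t2, underscores)
        t2.is_rooted = True
        out.append(t2)
    return out


def parse_newick(newick: str, underscores: bool = True) -> dendropy.Tree:
    """Parse a single Newick string (convenience wrapper)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeParseError(f"could not parse newick string: {exc}") from exc
    normalize_tip_labels(tree, underscores)
    tree.is_rooted = True
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_taxa(tree: dendropy.Tree, taxa: list[str]) -> tuple[dendropy.Tree, list[str]]:
    """Prune ``tree`` down to the tips named in ``taxa``.

    Degree-two internal nodes created by pruning are collapsed with branch
    lengths summed, so root-to-tip depths (and hence the VCV entries of the
    retained tips) are preserved exactly.

    Returns the pruned tree and a mismatch report: the requested labels
    that were absent from the tree.  Absent labels are reported, never
    silently dropped.
    """
    present = set(tip_labels(tree))
    wanted = list(dict.fromkeys(taxa))  # preserve order, drop dupes
    missing = [t for t in wanted if t not in present]
    keep = [t for t in wanted if t in present]
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 requested taxa found in tree ({len(keep)} matched, "
            f"{len(missing)} missing)"
        )
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    pruned.migrate_taxon_namespace(dendropy.TaxonNamespace())
    pruned.is_rooted = True
    return pruned, missing


def vcv_from_tree(tree: dendropy.Tree) -> VCV:
    """Compute the phylogenetic variance-covariance matrix of a tree.

    Entry (i, j) is the summed branch length from the root to the most
    recent common ancestor of tips i and j; the diagonal holds root-to-tip
    depths.  Multifurcations are handled as-is.  A length on the root edge
    counts as history shared by every tip: pruning can collapse the old
    root path onto the root edge, and counting it keeps the pruned VCV
    equal to the corresponding submatrix of the full-tree VCV.
    """
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    # node depths from the root (root edge excluded)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = float(node.edge.length or 0.0)
        else:
            bl = node.edge.length
            if bl is None:
                bl = 0.0
            if bl < 0:
                raise ValueError(
                    f"negative branch length {bl} on edge above "
                    f"{node.taxon.label if node.taxon else 'internal node'}"
                )
            depth[id(node)] = depth[id(node.parent_node)] + bl
    M = np.zeros((n, n))
    # postorder sweep: tips below each child subtree share the parent depth
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = np.array([i], dtype=int)
            M[i, i] = depth[id(node)]
        else:
            groups = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    M[np.ix_(groups[a], groups[b])] = d
                    M[np.ix_(groups[b], groups[a])] = d
            tipsets[id(node)] = np.concatenate(groups)
    return VCV(M, labels)


def lambda_transform(V: VCV | np.ndarray, lam: float) -> VCV | np.ndarray:
    """Apply Pagel's lambda: multiply off-diagonal entries by ``lam``.

    lambda = 1 leaves the matrix unchanged (full Brownian-motion signal);
    lambda = 0 erases shared history, leaving a diagonal matrix of
    tip-specific variances.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if isinstance(V, VCV):
        return VCV(_lambda_matrix(V.matrix, lam), list(V.taxa))
    return _lambda_matrix(np.asarray(V, dtype=float), lam)


def _lambda_matrix(M: np.ndarray, lam: float) -> np.ndarray:
    W = M * lam
    np.fill_diagonal(W, np.diag(M))
    return W


def is_ultrametric(V: VCV, tol: float = 1e-9) -> bool:
    d = np.diag(V.matrix)
    return bool(np.ptp(d) <= tol * max(1.0, float(d.max())))
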