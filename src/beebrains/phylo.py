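"""Phylogenetic trees, covariance matrices and Pagel's lambda transform.

The phylogeny enters every comparative model through its variance-covariance
matrix: entry (i, j) is the branch length shared by the root-to-tip paths of
species i and j, so the diagonal holds root-to-tip distances.  Pagel's lambda
rescales the off-diagonal covariances towards phylogenetic independence
(``lam = 0`` yields a diagonal matrix, ``lam = 1`` leaves the Brownian-motion
covariance untouched).

Trees are stored as thin wrappers around :class:`dendropy.Tree`, validated on
construction (unique tip labels, non-negative branch lengths, at least two
tips).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "CovMatrix",
    "MatchReport",
    "NewickParseError",
    "TreeDataMismatchError",
    "read_newick",
    "phylo_covariance",
    "lambda_transform",
    "match_tips",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or fails validation."""


class TreeDataMismatchError(ValueError):
    """Raised when tree tips and trait/record species cannot be reconciled."""


class PhyloTree:
    """A rooted tree with branch lengths, validated for comparative analyses.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  The tree is used as-is (no cloning); callers
        that need to keep the original intact should pass a clone.
    require_lengths:
        If true (default), every non-root edge must carry a branch length.
        A missing root edge length is treated as zero.
    """

    def __init__(self, tree: dendropy.Tree, *, require_lengths: bool = True):
        self._tree = tree
        labels: list[str] = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not (leaf.taxon.label or "").strip():
                raise NewickParseError("tree contains an unlabelled tip")
            labels.append(leaf.taxon.label)
        if len(labels) < 2:
            raise NewickParseError(
                f"tree must have at least 2 tips, found {len(labels)}"
            )
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            length = nd.edge.length
            if length is None:
                if require_lengths:
                    raise NewickParseError(
                        f"edge above {_node_name(nd)!r} has no branch length"
                    )
            elif length < 0:
                raise NewickParseError(
                    f"negative branch length {length} above {_node_name(nd)!r}"
                )
        self._labels = labels

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in tree (leaf-iteration) order."""
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        depths = _node_depths(self._tree)
        return {
            leaf.taxon.label: depths[leaf]
            for leaf in self._tree.leaf_node_iter()
        }

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips})"


def _node_name(nd: dendropy.Node) -> str:
    if nd.taxon is not None and nd.taxon.label:
        return nd.taxon.label
    return "<internal node>"


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def read_newick(text: str, *, require_lengths: bool = True) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Raises :class:`NewickParseError` on malformed input (unbalanced
    parentheses, duplicate tip labels, missing branch lengths when
    ``require_lengths``), carrying dendropy's position information where
    available.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    return PhyloTree(tree, require_lengths=require_lengths)


@dataclass
class CovMatrix:
    """Phylogenetic covariance matrix with its species ordering."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in covariance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "CovMatrix":
        """Return the sub-matrix for ``labels`` in the given order."""
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise KeyError(f"labels absent from covariance matrix: {missing}")
        idx = np.array([index[l] for l in labels])
        return CovMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def phylo_covariance(tree: PhyloTree) -> CovMatrix:
    """Shared-path-length covariance matrix of a tree's tips.

    Entry (i, j) is the depth (root distance) of the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip distances.
    Rows follow the tree's tip order.
    """
    dtree = tree.dendropy_tree
    labels = tree.tip_labels
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    depths = _node_depths(dtree)
    tipsets: dict[dendropy.Node, list[int]] = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            i = index[nd.taxon.label]
            V[i, i] = depths[nd]
            tipsets[nd] = [i]
        else:
            children = [tipsets.pop(ch) for ch in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            tipsets[nd] = [i for ch in children for i in ch]
    return CovMatrix(labels, V)


def lambda_transform(V: CovMatrix, lam: float) -> CovMatrix:
    """Pagel's lambda transform: scale off-diagonal covariances by ``lam``.

    The diagonal is kept fixed (the convention of trait-signal estimation).
    For ``0 <= lam <= 1`` the result stays positive semi-definite because it
    is ``lam * V`` plus a non-negative diagonal.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * V.values
    np.fill_diagonal(out, np.diag(V.values))
    return CovMatrix(list(V.labels), out)


@dataclass
class MatchReport:
    """Reconciliation report from :func:`match_tips`."""

    kept: list[str]
    tips_dropped: list[str] = field(default_factory=list)
    species_missing_from_tree: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_kept": len(self.kept),
            "kept": self.kept,
            "tips_dropped": self.tips_dropped,
            "species_missing_from_tree": self.species_missing_from_tree,
        }


def _canon(label: str, normalize: bool) -> str:
    label = label.strip()
    return label.replace("_", " ") if normalize else label


def match_tips(
    tree: PhyloTree,
    species: set[str] | list[str],
    *,
    normalize: bool = False,
) -> tuple[PhyloTree, MatchReport]:
    """Prune ``tree`` to the species present in both tree and data.

    Matching is exact and case-sensitive after trimming surrounding
    whitespace; ``normalize=True`` additionally treats underscores and spaces
    as equivalent.  Raises :class:`TreeDataMismatchError` if fewer than three
    species remain (comparative fits are undefined below that).
    """
    species = list(species)
    if not species:
        raise TreeDataMismatchError("species set is empty")
    wanted = {_canon(s, normalize) for s in species}
    keep_tips = [t for t in tree.tip_labels if _canon(t, normalize) in wanted]
    tip_canon = {_canon(t, normalize) for t in tree.tip_labels}
    missing = sorted(s for s in species if _canon(s, normalize) not in tip_canon)
    dropped = sorted(set(tree.tip_labels) - set(keep_tips))
    if len(keep_tips) < 3:
        raise TreeDataMismatchError(
            f"only {len(keep_tips)} species shared between tree and data; "
            "at least 3 are required for comparative fits"
        )
    report = MatchReport(
        kept=keep_tips,
        tips_dropped=dropped,
        species_missing_from_tree=missing,
    )
    if not dropped:
        return tree, report
    pruned = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=keep_tips)
    return PhyloTree(pruned), report
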