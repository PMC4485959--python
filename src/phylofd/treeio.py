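"""Chronogram input/output and phylogenetic matrix machinery.

A chronogram is a rooted tree whose branch lengths are proportional to
time, so that all tips are equidistant from the root (ultrametric).  Every
downstream quantity in this package derives from it:

* the patristic distance matrix ``D`` (tip-to-tip path lengths), which
  drives the phylogenetic correlogram's distance classes;
* the Brownian-motion variance-covariance matrix ``V``, where ``V[i, j]``
  is the shared evolutionary time of tips *i* and *j* (root to their most
  recent common ancestor), the covariance structure under which Pagel's
  lambda is estimated;
* the phylogenetic correlation matrix ``C = D^{-1/2} V D^{-1/2}`` feeding
  the phylogenetic species variability (PSV) index.

Trees are parsed and serialized with :mod:`dendropy`; matrices are
returned as labelled :class:`pandas.DataFrame` objects so that species
alignment across the tree, trait table and community matrix is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickFormatError",
    "TreeValidationError",
    "LabelMismatchError",
    "Phylogeny",
    "read_newick",
    "write_newick",
    "check_ultrametric",
    "patristic_distances",
    "phylo_vcv",
    "vcv_to_correlation",
    "lambda_transform",
]

#: lower bound of the lambda domain used throughout the package
LAMBDA_EPS = 1e-7


class NewickFormatError(ValueError):
    """Raised when a newick source cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the chronogram contract."""


class LabelMismatchError(ValueError):
    """Raised when species labels disagree between tree, traits or plots."""

    def __init__(self, context: str, offenders: list[str]):
        self.offenders = sorted(offenders)
        super().__init__(f"{context}: offending species {self.offenders}")


@dataclass
class Phylogeny:
    """A validated rooted tree with branch lengths in relative time units.

    Wraps a :class:`dendropy.Tree`.  Construction validates that every
    non-root edge carries a nonnegative length and that tip labels are
    unique and nonempty.  Ultrametricity is *not* enforced here (some
    utilities tolerate non-ultrametric trees with a warning); use
    :func:`check_ultrametric` where the analysis requires it.
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        leaves = list(self.tree.leaf_node_iter())
        if not leaves:
            raise TreeValidationError("tree has no tips")
        labels = []
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeValidationError("tree contains an unlabeled tip")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue  # a root edge length, if any, is ignored
            if node.edge.length is None:
                raise TreeValidationError(
                    f"missing branch length on edge above {_describe(node)}"
                )
            if node.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length ({node.edge.length}) above {_describe(node)}"
                )
        self.tip_labels = labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> pd.Series:
        """Root-to-tip path length per tip, in tree order."""
        depth = _node_depths(self.tree)
        return pd.Series(
            {leaf.taxon.label: depth[leaf] for leaf in self.tree.leaf_node_iter()},
            name="depth",
        ).loc[self.tip_labels]

    @property
    def depth(self) -> float:
        """Mean root-to-tip distance (== tree height for a chronogram)."""
        return float(self.depths().mean())


def _describe(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"tip '{node.taxon.label}'"
    tips = [l.taxon.label for l in node.leaf_iter()][:3]
    return f"internal node above {tips}..."


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length
    return depth


def read_newick(source: str | Path) -> Phylogeny:
    """Read a rooted tree from a newick file path or literal newick text.

    Branch lengths are required on every non-root edge; comments in
    square brackets are ignored.  Tip labels are preserved verbatim
    (underscores are not translated to spaces).
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if not text.strip():
            raise NewickFormatError("empty newick source")
        if "(" not in text:
            p = Path(text)
            if not p.is_file():
                raise NewickFormatError(f"no such file and not newick text: {text!r}")
            text = p.read_text()
    if not text.strip():
        raise NewickFormatError("empty newick source")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickFormatError(f"newick parse failure: {exc}") from exc
    tree.is_rooted = True
    return Phylogeny(tree)


def write_newick(phy: Phylogeny, path: str | Path | None = None) -> str:
    """Serialize to newick with full float precision; optionally write a file."""
    text = phy.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def check_ultrametric(phy: Phylogeny, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Test whether all root-to-tip path lengths are equal.

    Returns ``(ok, max_rel_deviation)`` where the deviation is
    ``max |depth_i - mean depth| / mean depth``.  A single-tip tree is
    trivially ultrametric with deviation 0.
    """
    depths = phy.depths().to_numpy()
    if len(depths) < 2:
        return True, 0.0
    mean = depths.mean()
    if mean <= 0:
        raise TreeValidationError("tree has zero depth")
    dev = float(np.max(np.abs(depths - mean)) / mean)
    return dev <= rel_tol, dev


def _mrca_depth_matrix(phy: Phylogeny) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Tip depths and the matrix of MRCA depths for all tip pairs.

    Runs one postorder sweep, setting ``M[i, j]`` to the depth of the most
    recent common ancestor for every pair of tips drawn from distinct
    child subtrees of each internal node.  Polytomies are handled by
    iterating over all child-subtree pairs.
    """
    labels = phy.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth = _node_depths(phy.tree)
    tip_depth = np.zeros(n)
    M = np.zeros((n, n))
    subtree_tips: dict[dendropy.Node, np.ndarray] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            tip_depth[i] = depth[node]
            subtree_tips[node] = np.array([i])
            continue
        child_sets = [subtree_tips.pop(c) for c in node.child_nodes()]
        d = depth[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                M[np.ix_(child_sets[a], child_sets[b])] = d
                M[np.ix_(child_sets[b], child_sets[a])] = d
        subtree_tips[node] = np.concatenate(child_sets)
    np.fill_diagonal(M, tip_depth)
    return labels, tip_depth, M


def patristic_distances(phy: Phylogeny) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic distance) matrix.

    ``d(i, j)`` is the sum of branch lengths along the path joining tips
    *i* and *j*; equivalently ``depth_i + depth_j - 2 * depth(MRCA)``.
    """
    labels, tip_depth, M = _mrca_depth_matrix(phy)
    D = tip_depth[:, None] + tip_depth[None, :] - 2.0 * M
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


def phylo_vcv(phy: Phylogeny, rel_tol: float = 1e-6) -> pd.DataFrame:
    """Brownian-motion variance-covariance matrix V of the tree.

    ``V[i, j]`` is the shared root-to-MRCA path length of tips *i* and
    *j*; ``V[i, i]`` is the depth of tip *i*.  For an ultrametric tree
    this satisfies ``V[i, j] = T - d(i, j) / 2`` with ``T`` the tree
    depth.  Non-ultrametric trees are accepted with a warning — V is
    still well defined from shared path lengths.
    """
    ok, dev = check_ultrametric(phy, rel_tol)
    if not ok:
        warnings.warn(
            f"tree is not ultrametric (max relative tip-depth deviation {dev:.3g}); "
            "V computed from shared path lengths",
            stacklevel=2,
        )
    labels, _, M = _mrca_depth_matrix(phy)
    return pd.DataFrame(M, index=labels, columns=labels)


def vcv_to_correlation(V: pd.DataFrame) -> pd.DataFrame:
    """Scale V to a correlation matrix ``C[i,j] = V[i,j]/sqrt(V[i,i] V[j,j])``."""
    d = np.diag(V.to_numpy())
    if np.any(d <= 0):
        bad = [V.index[i] for i in np.flatnonzero(d <= 0)]
        raise TreeValidationError(f"zero-depth tips (V diagonal <= 0): {bad}")
    s = np.sqrt(d)
    C = V.to_numpy() / np.outer(s, s)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=V.index, columns=V.columns)


def lambda_transform(V: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Pagel's lambda branch-length transform of a VCV matrix.

    Multiplies all off-diagonal covariances by ``lam`` while leaving tip
    variances unchanged; ``lam = 1`` is unaltered Brownian motion,
    ``lam = 0`` a star phylogeny (independent tips).  ``lam`` must lie in
    [0, 1]: values above 1 can break positive semidefiniteness and have
    no interpretation on an ultrametric tree.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = V.to_numpy() * lam
    np.fill_diagonal(out, np.diag(V.to_numpy()))
    return pd.DataFrame(out, index=V.index, columns=V.columns)


def require_same_labels(
    found: list[str] | pd.Index,
    expected: list[str] | pd.Index,
    context: str,
) -> None:
    """Hard error listing species present in one label set but not the other."""
    found_s, expected_s = set(found), set(expected)
    missing = expected_s - found_s
    if missing:
        raise LabelMismatchError(context, sorted(missing))
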