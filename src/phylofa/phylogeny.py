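"""Phylogenetic trees and the Brownian-motion covariance they induce.

Under a Brownian-motion model of trait evolution on a rooted tree with
time-like branch lengths, the covariance between the trait values of two tips
equals the length of the root-to-tip path they share, i.e. the depth of their
most recent common ancestor.  All regression models in this package consume
that matrix, usually in normalized (unit-diagonal, correlation) form so the
phylogenetic standard deviation is identifiable on a common scale.

Trees are handled as :class:`dendropy.Tree` objects; this module adds
validation, pruning, and the covariance construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "tree_from_string",
    "prune_to",
    "vcv",
    "tree_height",
    "tip_labels",
    "PhyloCovariance",
]


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            # a root (stem) edge is optional; when present it is shared by
            # every tip and contributes to all covariance entries
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative root edge length {edge.length}")
            continue
        if edge.length is None:
            raise ValueError(
                "tree has edges without branch lengths; all non-root edges "
                "must carry a length"
            )
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def _parse(**kwargs) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(schema="newick", rooting="force-rooted", **kwargs)
    except dendropy.utility.error.DataParseError as err:
        if "Multiple occurrences" in str(err) or "duplicate" in str(err).lower():
            raise ValueError(f"duplicate tip labels in tree: {err}") from err
        raise ValueError(f"malformed Newick input: {err}") from err
    return _validate(tree)


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths."""
    return _parse(data=newick)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree file with branch lengths.

    Unlabelled internal nodes are tolerated; duplicate tips or missing branch
    lengths raise a descriptive error.
    """
    return _parse(path=str(path))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (including any stem edge)."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def prune_to(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Induced subtree on ``species``, with degree-2 nodes merged.

    Root-to-tip paths and pairwise shared paths among the retained species are
    preserved, so the covariance of the pruned tree equals the corresponding
    submatrix of the full tree's covariance.
    """
    have = set(tip_labels(tree))
    unknown = sorted(set(species) - have)
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")
    pruned = tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in set(species)]
    pruned.retain_taxa(taxa)
    # dendropy keeps the original root even when it becomes degree-1; collapse
    # such unifurcations so the root subtending edge lengths stay path-true.
    pruned.suppress_unifurcations()
    return _validate(pruned)


@dataclass
class PhyloCovariance:
    """Tip-labelled Brownian-motion (co)variance matrix.

    ``matrix[i, j]`` is the shared root-to-tip path length of tips ``i`` and
    ``j`` (raw form), or that value divided by the geometric mean of the two
    diagonals (normalized form, unit diagonal).
    """

    labels: list[str]
    matrix: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def align_to(self, species: list[str]) -> "PhyloCovariance":
        """Reordered (sub)matrix for the given species order."""
        idx = {l: i for i, l in enumerate(self.labels)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise ValueError(f"species not in covariance: {missing}")
        sel = np.array([idx[s] for s in species])
        return PhyloCovariance(list(species), self.matrix[np.ix_(sel, sel)],
                               self.normalized)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, normalized: bool = False) -> "PhyloCovariance":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), normalized)


def vcv(tree: dendropy.Tree, normalize: bool = False) -> PhyloCovariance:
    """Brownian-motion covariance matrix of a rooted tree.

    Entry (i, j) is the depth of the most recent common ancestor of tips i
    and j, accumulated clade by clade: every non-root edge adds its length to
    the covariance block of all tip pairs in the clade it subtends.  With
    ``normalize=True`` each entry is divided by the geometric mean of the two
    corresponding diagonals, giving a unit-diagonal correlation matrix (for an
    ultrametric tree this is simply division by tree height).
    """
    _validate(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    cov = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            if node.edge.length:  # stem edge shared by every tip
                cov += node.edge.length
            continue
        tips = np.array([index[id(l)] for l in node.leaf_iter()])
        cov[np.ix_(tips, tips)] += node.edge.length
    if normalize:
        d = np.sqrt(np.diag(cov))
        if np.any(d == 0):
            raise ValueError("zero root-to-tip path length; cannot normalize")
        heights = np.diag(cov)
        if not np.allclose(heights, heights[0], rtol=1e-6):
            warnings.warn(
                "tree is not ultrametric; normalizing by per-tip depths",
                stacklevel=2,
            )
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
    return PhyloCovariance(labels, cov, normalized=normalize)
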