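"""Species trees and the phylogenetic correlation matrix.

The multilevel model needs a species-by-species correlation matrix A whose
entry (i, j) is the proportion of the root-to-tip path shared by tips i and j
under an ultrametric tree of depth 1.  Trees arrive as Newick files, possibly
with polytomies and without branch lengths; preparation is

    resolve_polytomies (seeded randomisation)
      -> grafen_branch_lengths (node height = (descendant tips - 1)^rho,
         scaled to root height 1)
      -> correlation_matrix

mirroring the multi2di / compute.brlen route familiar from the R ``ape``
package.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloCorrelation",
    "read_tree",
    "normalize_species_name",
    "resolve_polytomies",
    "grafen_branch_lengths",
    "correlation_matrix",
    "prepare_tree",
]

ULTRAMETRIC_TOL = 1e-9


def normalize_species_name(name: str) -> str:
    """Case-insensitive, whitespace/underscore-normalized species key."""
    return re.sub(r"[\s_]+", "_", str(name).strip()).lower()


def read_tree(path) -> dendropy.Tree:
    """Read a single rooted tree from a Newick file."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Randomly resolve multifurcations into a binary tree.

    The resolution is a deterministic function of the seed; inserted edges get
    length 0 (branch lengths are reassigned afterwards).  Already-binary trees
    pass through topologically unchanged.
    """
    if tree.seed_node is None:
        raise ValueError("tree has no root; root it before resolving polytomies")
    out = tree.clone(depth=1)
    out.resolve_polytomies(limit=2, update_bipartitions=True,
                           rng=random.Random(int(seed)))
    for edge in out.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return out


def grafen_branch_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign Grafen (1989) branch lengths scaled to unit root height.

    Each internal node is placed at height ((number of descendant tips - 1)
    raised to ``rho``), tips at height 0, the whole tree rescaled so the root
    sits at height 1; edge lengths follow as parent height minus child height.
    The result is ultrametric with all tips at depth 1.
    """
    out = tree.clone(depth=1)
    heights: dict[int, float] = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            heights[id(node)] = 0.0
        else:
            n_tips = sum(1 for _ in node.leaf_iter())
            heights[id(node)] = float(n_tips - 1) ** rho
    root_h = heights[id(out.seed_node)]
    if root_h <= 0:
        raise ValueError("tree must have at least 2 tips")
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (heights[id(node.parent_node)] - heights[id(node)]) / root_h
    out.seed_node.edge.length = None
    return out


@dataclass
class PhyloCorrelation:
    """Species-by-species shared-ancestry correlation matrix.

    Unit diagonal, symmetric, entries in [0, 1], positive semidefinite.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def submatrix(self, species: list[str]) -> "PhyloCorrelation":
        """Reorder/subset to the given species list (normalized matching)."""
        index = {normalize_species_name(l): i for i, l in enumerate(self.labels)}
        missing = [s for s in species if normalize_species_name(s) not in index]
        if missing:
            raise KeyError(f"species not in phylogeny: {sorted(set(missing))}")
        idx = [index[normalize_species_name(s)] for s in species]
        return PhyloCorrelation(labels=list(species),
                                matrix=self.matrix[np.ix_(idx, idx)])


def _tip_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = 0.0 if parent is None else depths[id(parent)]
        depths[id(node)] = base + (node.edge.length or 0.0)
    return {leaf.taxon.label: depths[id(leaf)] for leaf in tree.leaf_node_iter()}


def correlation_matrix(tree: dendropy.Tree) -> PhyloCorrelation:
    """Convert an ultrametric tree into a shared-ancestry correlation matrix.

    Entry (i, j) is the root-to-MRCA path length of tips i and j divided by
    the (common) tip depth; the diagonal is exactly 1.  Non-ultrametric input
    is rejected.
    """
    depths = _tip_depths(tree)
    labels = sorted(depths)
    depth_vals = np.array([depths[l] for l in labels])
    depth = depth_vals.mean()
    if depth <= 0:
        raise ValueError("tree has zero depth; assign branch lengths first")
    if np.ptp(depth_vals) > max(ULTRAMETRIC_TOL, 1e-9 * depth):
        raise ValueError(
            f"tree is not ultrametric: tip depths span [{depth_vals.min()}, {depth_vals.max()}]")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            # shared path = depth - half the patristic distance, as a fraction
            A[i, j] = A[j, i] = max(0.0, 1.0 - d / (2.0 * depth))
    return PhyloCorrelation(labels=labels, matrix=A)


def prepare_tree(tree: dendropy.Tree, seed: int = 0, rho: float = 1.0
                 ) -> tuple[dendropy.Tree, PhyloCorrelation]:
    """Full preparation: resolve polytomies, Grafen lengths, correlation matrix."""
    binary = resolve_polytomies(tree, seed=seed)
    with_lengths = grafen_branch_lengths(binary, rho=rho)
    return with_lengths, correlation_matrix(with_lengths)
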