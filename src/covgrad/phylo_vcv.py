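"""Taxonomy-derived pseudo-phylogeny and species relatedness matrix.

Meta-analyses across many taxa rarely have a calibrated phylogeny for every
species; a standard fallback is a pseudo-phylogeny built from taxonomic rank:
every rank step contributes one unit of branch length, so all species within
a genus are equidistant, all genera within a family are equidistant, and so
on.  The resulting ultrametric tree is converted to a relatedness matrix A
(shared root-to-MRCA depth over total depth) that scales a phylogenetic
random effect in the hierarchical model.

Trees are dendropy objects throughout, so Newick serialization and path
length computations use the standard machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

DEFAULT_RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

__all__ = [
    "DEFAULT_RANKS",
    "TaxonLineage",
    "RelatednessMatrix",
    "rank_distance",
    "build_taxon_tree",
    "tree_to_relatedness",
    "lineages_to_relatedness",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered taxonomic classification of one species.

    ``taxa`` holds one name per rank in ``ranks`` order, ending at the
    species epithet.  Missing intermediate ranks should be filled with a
    placeholder unique to the child clade (see :meth:`from_mapping`), which
    preserves ultrametricity of the derived tree.
    """

    species: str
    taxa: tuple[str, ...]
    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.ranks):
            raise ValueError(
                f"lineage for {self.species!r} has {len(self.taxa)} taxa "
                f"for {len(self.ranks)} ranks"
            )
        if "species" not in self.ranks:
            raise ValueError("rank list must include the species level")

    @classmethod
    def from_mapping(
        cls,
        species: str,
        taxa: Mapping[str, str],
        ranks: Sequence[str] = DEFAULT_RANKS,
    ) -> "TaxonLineage":
        """Build a lineage from a rank->taxon mapping.

        A rank that is absent or empty is filled with a placeholder derived
        from the nearest named taxon below it, so the placeholder is unique
        to that child clade.
        """
        ranks = tuple(ranks)
        names: list[str | None] = [
            (taxa.get(r) or None) for r in ranks
        ]
        if names[ranks.index("species")] is None:
            names[ranks.index("species")] = species
        filled: list[str] = [""] * len(ranks)
        for i in range(len(ranks) - 1, -1, -1):
            if names[i]:
                filled[i] = str(names[i])
            else:
                below = filled[i + 1] if i + 1 < len(ranks) else species
                filled[i] = f"incertae_{ranks[i]}_{below}"
        return cls(species=species, taxa=tuple(filled), ranks=ranks)


@dataclass(frozen=True)
class RelatednessMatrix:
    """Species relatedness A: symmetric, unit diagonal, entries in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("relatedness matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValueError("relatedness matrix must have unit diagonal")
        if np.linalg.eigvalsh(a).min() < -1e-10:
            raise ValueError("relatedness matrix is not positive semidefinite")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _check_same_ranks(a: TaxonLineage, b: TaxonLineage) -> None:
    if a.ranks != b.ranks:
        raise ValueError("lineages use different rank lists")


def rank_distance(a: TaxonLineage, b: TaxonLineage) -> float:
    """Tip-to-tip distance in unit branch lengths on the rank tree.

    Equals 2 x (number of ranks below and including the first rank at which
    the lineages differ); 0 iff the lineages are identical.  All species
    within a genus are therefore equidistant, all genera within a family are
    equidistant, and so on up the ranks.
    """
    _check_same_ranks(a, b)
    for i, (ta, tb) in enumerate(zip(a.taxa, b.taxa)):
        if ta != tb:
            return 2.0 * (len(a.ranks) - i)
    return 0.0


def build_taxon_tree(
    lineages: Sequence[TaxonLineage],
    step: float = 1.0,
) -> dendropy.Tree:
    """Assemble the ultrametric pseudo-phylogeny from lineages.

    Internal nodes are the shared taxa at each rank; each rank step adds
    ``step`` branch length, so every tip sits at depth len(ranks) * step and
    tip-to-tip path lengths equal :func:`rank_distance` (scaled by ``step``).
    """
    if len(lineages) < 2:
        raise ValueError("need >= 2 lineages to build a tree")
    ranks = lineages[0].ranks
    for lin in lineages[1:]:
        if lin.ranks != ranks:
            raise ValueError("lineages use inconsistent rank lists")
    seen = [lin.species for lin in lineages]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate species labels in lineage list")

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    # one node per distinct rank prefix, chained below a common root
    nodes: dict[tuple[str, ...], dendropy.Node] = {(): tree.seed_node}
    for lin in lineages:
        parent = tree.seed_node
        for depth in range(1, len(ranks) + 1):
            prefix = lin.taxa[:depth]
            node = nodes.get(prefix)
            if node is None:
                node = dendropy.Node(edge_length=step)
                parent.add_child(node)
                nodes[prefix] = node
            parent = node
        parent.taxon = taxon_ns.new_taxon(lin.species)
    return tree


def tree_to_relatedness(tree: dendropy.Tree, tol: float = 1e-9) -> RelatednessMatrix:
    """Convert an ultrametric tree to the relatedness matrix A.

    A_ij = depth(MRCA(i, j)) / total depth; equivalently 1 - patristic(i, j)
    / (2 * depth) on an ultrametric tree.  Raises if the tree is not
    ultrametric (tips not equidistant from the root) or A fails the
    eigenvalue PSD check at -1e-10.
    """
    tree = dendropy.Tree(tree)  # work on a copy; distance calcs cache state
    depths = {
        leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    }
    labels = sorted(depths)
    depth_vals = np.array([depths[l] for l in labels])
    total = float(depth_vals.mean())
    if total <= 0:
        raise ValueError("tree has zero depth")
    if np.abs(depth_vals - total).max() > tol * max(1.0, total):
        raise ValueError("tree is not ultrametric: tips are not equidistant from root")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pat = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            a[i, j] = a[j, i] = 1.0 - pat / (2.0 * total)
    return RelatednessMatrix(labels=tuple(labels), values=a)


def lineages_to_relatedness(lineages: Sequence[TaxonLineage]) -> RelatednessMatrix:
    """Shortcut: taxonomy -> tree -> A."""
    return tree_to_relatedness(build_taxon_tree(lineages))


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
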