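"""Tree-based taxon delimitation and clustering-based richness estimation.

Every formal taxon here must form a monophyletic, least inclusive clade on
the support-annotated phylogram, and higher taxa additionally require
bootstrap support strictly above 95. Species richness within a lineage is
roughly estimated by single-linkage clustering of ITS2 p-distances at a
threshold taken from the type species' observed intraspecific variability.

Trees are handled through dendropy. Monophyly on unrooted trees is decided
per bipartition relative to a declared outgroup tip, which avoids rerooting
altogether (and the support-label migration problems that come with it).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alignment import AnnotatedAlignment
from .distances import DistancePolicy, max_intraspecific, pairwise_distance_matrix


class DelimitationError(ValueError):
    pass


@dataclass
class SupportTree:
    """A phylogram with tip labels and 0-100 internal support values."""

    tree: dendropy.Tree
    rooted: bool

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


@dataclass(frozen=True)
class CladeTest:
    """Monophyly / least-inclusive-clade / support verdict for a tip set."""

    tips: frozenset[str]
    monophyletic: bool
    mrca_tips: frozenset[str]
    support: float | None

    @property
    def passes_support(self) -> bool:
        """Bootstrap criterion, strict: support must exceed 95."""
        return self.support is not None and self.support > 95


@dataclass(frozen=True)
class ClusterResult:
    threshold: float
    linkage: str
    clusters: tuple[frozenset[str], ...]
    richness: int


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def read_newick(path_or_string: str, rooted: bool | None = None) -> SupportTree:
    """Parse a Newick tree with bootstrap supports as internal node labels.

    Supports on a 0-1 scale are rescaled to 0-100. Rootedness follows the
    ``[&R]``/``[&U]`` annotation unless overridden by *rooted*.
    """
    import os

    src = {"path": path_or_string} if os.path.exists(str(path_or_string)) else {
        "data": str(path_or_string)
    }
    try:
        tree = dendropy.Tree.get(schema="newick", suppress_internal_node_taxa=True, **src)
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise DelimitationError("ambiguous labels: duplicate tips") from exc
        raise DelimitationError(f"parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise DelimitationError("ambiguous labels: duplicate tips")
    supports = []
    for node in tree.preorder_internal_node_iter():
        s = _parse_support(node.label)
        if s is not None:
            supports.append(s)
    if supports and max(supports) <= 1.0:
        for node in tree.preorder_internal_node_iter():
            s = _parse_support(node.label)
            if s is not None:
                node.label = repr(s * 100.0)
    if rooted is None:
        rooted = bool(tree.is_rooted)
    return SupportTree(tree=tree, rooted=rooted)


def _clade_sides(
    stree: SupportTree, outgroup: str | None
) -> list[tuple[frozenset[str], float | None]]:
    """All candidate clades (leaf sets) with their supports.

    Rooted tree: the leaf set under each node. Unrooted tree: for each edge,
    the bipartition side not containing the outgroup tip.
    """
    tree = stree.tree
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    sides: list[tuple[frozenset[str], float | None]] = [(all_leaves, None)]
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        under = frozenset(l.taxon.label for l in node.leaf_iter())
        support = _parse_support(node.label) if not node.is_leaf() else None
        if stree.rooted or outgroup is None:
            sides.append((under, support))
        else:
            side = under if outgroup not in under else all_leaves - under
            if side:
                sides.append((side, support))
    return sides


def least_inclusive_clade(
    stree: SupportTree, tips: set[str] | frozenset[str], outgroup: str | None = None
) -> CladeTest:
    """The leaf set under the MRCA of *tips*, with monophyly and support.

    Unrooted trees require a named *outgroup* tip (not part of the query);
    the clade of an edge is then the bipartition side away from the outgroup.
    """
    tips = frozenset(tips)
    tree_tips = set(stree.tree.taxon_namespace.labels())
    missing = tips - tree_tips
    if missing:
        raise DelimitationError(f"tip not in tree: {sorted(missing)}")
    if not stree.rooted and outgroup is None:
        raise DelimitationError("rooting required: name an outgroup tip for unrooted trees")
    if outgroup is not None and outgroup in tips:
        raise DelimitationError("outgroup tip cannot be part of the query set")
    best: tuple[frozenset[str], float | None] | None = None
    for side, support in _clade_sides(stree, outgroup):
        if tips <= side and (best is None or len(side) < len(best[0])):
            best = (side, support)
    assert best is not None  # the full leaf set always contains the query
    mrca_tips, support = best
    return CladeTest(
        tips=tips,
        monophyletic=(mrca_tips == tips),
        mrca_tips=mrca_tips,
        support=support,
    )


@dataclass(frozen=True)
class CriteriaVerdict:
    passed: bool
    failed_criteria: tuple[str, ...]
    clade: CladeTest


def check_taxon_criteria(
    stree: SupportTree,
    tips: set[str],
    min_support: float = 95,
    outgroup: str | None = None,
) -> CriteriaVerdict:
    """Higher-taxon delimitation: monophyly AND support strictly > min_support."""
    clade = least_inclusive_clade(stree, tips, outgroup=outgroup)
    failed = []
    if not clade.monophyletic:
        failed.append("monophyly")
    if clade.support is None or not clade.support > min_support:
        failed.append("support")
    return CriteriaVerdict(passed=not failed, failed_criteria=tuple(failed), clade=clade)


def cluster_species(
    matrix: np.ndarray,
    ids: list[str],
    threshold: float,
    linkage: str = "single",
) -> ClusterResult:
    """Single-linkage clusters at a distance threshold.

    At single linkage these are exactly the connected components of the
    graph joining pairs with distance <= threshold (undefined/NaN distances
    never join). Richness = component count.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DelimitationError("invalid distances: matrix must be square")
    same_nan = np.isnan(matrix) == np.isnan(matrix.T)
    close = np.isclose(matrix, matrix.T, atol=1e-12) | np.isnan(matrix)
    if not (same_nan.all() and close.all()):
        raise DelimitationError("invalid distances: matrix must be symmetric")
    if linkage != "single":
        raise DelimitationError("only single linkage is implemented")
    if not (0.0 <= threshold <= 1.0):
        raise DelimitationError("threshold must be in [0, 1]")
    adj = np.nan_to_num(matrix, nan=np.inf) <= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = tuple(
        frozenset(ids[i] for i in np.nonzero(labels == c)[0]) for c in range(n_comp)
    )
    return ClusterResult(threshold=threshold, linkage=linkage, clusters=clusters, richness=n_comp)


def estimate_richness(
    aln: AnnotatedAlignment,
    region: str = "ITS2",
    threshold: float | None = None,
    type_species: str | None = None,
    policy: DistancePolicy = DistancePolicy(),
) -> ClusterResult:
    """Rough species richness of an alignment by threshold clustering.

    When *threshold* is None it is taken from the type species' maximum
    intraspecific p-distance in the region (the study's convention); a
    *type_species* name is then required.
    """
    if threshold is None:
        if type_species is None:
            raise DelimitationError("threshold 'auto' needs a type_species")
        threshold = max_intraspecific(aln, type_species, region, policy).max_intra or 0.0
    matrix, ids = pairwise_distance_matrix(aln, region, policy)
    return cluster_species(matrix, ids, threshold)
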