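"""Strain relationships from pooled RSCU vectors.

Each strain is represented by its pooled 59-codon RSCU vector; strains are
joined by agglomerative hierarchical clustering (default: squared
Euclidean distance with average linkage, i.e. between-groups UPGMA) and
the dendrogram is serialized to Newick. A Robinson-Foulds comparison
against an independently inferred (e.g. sequence-based) tree quantifies
topological agreement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .usage_indices import RSCUTable

logger = logging.getLogger(__name__)

DISTANCES = {"squared_euclidean": "sqeuclidean", "euclidean": "euclidean"}
LINKAGES = ("average", "complete", "ward")


def rscu_feature_matrix(strain_tables: Sequence[RSCUTable]) -> pd.DataFrame:
    """Stack per-strain pooled RSCU tables into a strains x 59 matrix.

    Column order is fixed (codons alphabetical within amino-acid order);
    undefined entries (unobserved families) are imputed as 0 with a log
    entry so distance computation stays defined.
    """
    if not strain_tables:
        raise ValueError("no RSCU tables given")
    table_ids = {t.code.table_id for t in strain_tables}
    if len(table_ids) != 1:
        raise ValueError(f"inconsistent genetic codes: {sorted(table_ids)}")
    code = strain_tables[0].code
    cols = list(code.degenerate_codons)
    rows = {}
    n_imputed = 0
    for t in strain_tables:
        vals = [t.rscu.get(c, float("nan")) for c in cols]
        n_imputed += sum(1 for v in vals if math.isnan(v))
        rows[t.source] = [0.0 if math.isnan(v) else v for v in vals]
    if n_imputed:
        logger.info("rscu_feature_matrix: imputed %d undefined entries as 0", n_imputed)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


@dataclass
class ClusterTree:
    """An agglomerative clustering result.

    ``merges`` lists (member_set_a, member_set_b, height) in merge order;
    ``newick`` carries branch lengths derived from merge heights (leaf
    height 0)."""

    leaves: List[str]
    merges: List[Tuple[FrozenSet[str], FrozenSet[str], float]]
    newick: str
    linkage_matrix: np.ndarray


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        a, b, h, _ = Z[node - n]
        a, b = int(a), int(b)
        pa = build(a)
        pb = build(b)
        return (f"({pa}:{h - heights[a]:.10g},{pb}:{h - heights[b]:.10g})")

    for i, (a, b, h, _) in enumerate(Z):
        heights[n + i] = h
    return build(2 * n - 2) + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "squared_euclidean",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of strain RSCU vectors.

    Ward linkage is only defined on Euclidean distances and is rejected
    with squared Euclidean input. Rows are processed in label-sorted order
    so equal-distance merges resolve identically across runs.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    matrix = matrix.sort_index()
    labels = list(matrix.index)
    d = pdist(matrix.to_numpy(dtype=float), metric=DISTANCES[distance])
    Z = hierarchy.linkage(d, method=linkage)
    members: Dict[int, FrozenSet[str]] = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    merges = []
    n = len(labels)
    for i, (a, b, h, _) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb, float(h)))
        members[n + i] = fa | fb
    return ClusterTree(
        leaves=labels,
        merges=merges,
        newick=_linkage_to_newick(Z, labels),
        linkage_matrix=Z,
    )


# ---------------------------------------------------------------------------
# Tree comparison
# ---------------------------------------------------------------------------

def _as_dendropy(tree: Union[ClusterTree, str], taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    nwk = tree.newick if isinstance(tree, ClusterTree) else str(tree)
    return dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=taxa)


def _bipartitions(tree: dendropy.Tree) -> Tuple[FrozenSet[str], Set[FrozenSet[FrozenSet[str]]]]:
    taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    splits: Set[FrozenSet[FrozenSet[str]]] = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(frozenset({side, taxa - side}))
    return taxa, splits


def compare_trees(
    tree_a: Union[ClusterTree, str],
    tree_b: Union[ClusterTree, str],
) -> Tuple[List[FrozenSet[FrozenSet[str]]], int]:
    """Shared bipartitions and Robinson-Foulds distance between two trees.

    Both trees are treated as unrooted topologies over the same leaf set;
    only non-trivial bipartitions (both sides >= 2 leaves) count. The RF
    distance is the size of the symmetric difference of the bipartition
    sets.
    """
    taxa_ns = dendropy.TaxonNamespace()
    ta = _as_dendropy(tree_a, taxa_ns)
    tb = _as_dendropy(tree_b, taxa_ns)
    leaves_a, splits_a = _bipartitions(ta)
    leaves_b, splits_b = _bipartitions(tb)
    if leaves_a != leaves_b:
        raise ValueError(
            f"leaf-set mismatch: {sorted(leaves_a ^ leaves_b)} not shared"
        )
    shared = sorted(splits_a & splits_b, key=lambda bp: sorted(map(sorted, bp)))
    rf = len(splits_a ^ splits_b)
    return shared, rf
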