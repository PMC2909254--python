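"""Distance-based tree estimation used by the pipeline.

Substitution-scale trees are estimated by neighbor joining on
Jukes-Cantor-corrected pairwise distances derived from global-alignment
identity.  This stands in for the likelihood tree searches whose outputs
the analysis consumes; topological accuracy at the scales used here is
ample for rate-scaling and grafting.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from ecmcomm.errors import ValidationError
from ecmcomm.otu import pairwise_identity
from ecmcomm.tree import PhyloTree

log = logging.getLogger(__name__)

_JC_MAX_P = 0.7499


def p_distance_matrix(ids: list[str], sequences: list[str]) -> np.ndarray:
    """Pairwise p-distances (1 - alignment identity)."""
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(sequences[i], sequences[j])
    return d


def jc_correct(p: np.ndarray) -> np.ndarray:
    """Jukes-Cantor distance correction, saturating safely near p=3/4."""
    clipped = np.minimum(p, _JC_MAX_P)
    if (p > _JC_MAX_P).any():
        log.warning("jc_correct: %d saturated distances clipped", int((p > _JC_MAX_P).sum()))
    with np.errstate(invalid="ignore"):
        d = -0.75 * np.log1p(-4.0 / 3.0 * clipped)
    np.fill_diagonal(d, 0.0)
    return d


def nj_tree(ids: list[str], distances: np.ndarray) -> PhyloTree:
    """Neighbor-joining tree; negative NJ branch lengths are clamped to 0."""
    if len(ids) < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids)
    newick = str(nj(dm))
    tree = dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    n_neg = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) < 0:
            node.edge.length = 0.0
            n_neg += 1
    if n_neg:
        log.debug("nj_tree: clamped %d negative branch lengths", n_neg)
    return PhyloTree(tree=tree, scale="substitutions")


def root_at_outgroup(ptree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root on the outgroup's terminal edge (midpoint of that edge)."""
    work = ptree.clone()
    tree = work.tree
    node = tree.find_node_with_taxon_label(outgroup_label)
    if node is None:
        raise ValidationError(f"outgroup {outgroup_label!r} absent from tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    # drop any leftover unifurcation
    root = tree.seed_node
    if len(root.child_nodes()) == 1:
        only = root.child_nodes()[0]
        only.parent_node = None
        tree.seed_node = only
    return PhyloTree(tree=tree, scale=ptree.scale)


def estimate_substitution_tree(
    ids: list[str], sequences: list[str], outgroup_label: str | None = None
) -> PhyloTree:
    """NJ tree from JC-corrected alignment distances, optionally rooted."""
    d = jc_correct(p_distance_matrix(ids, sequences))
    tree = nj_tree(ids, d)
    if outgroup_label is not None:
        tree = root_at_outgroup(tree, outgroup_label)
    return tree
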