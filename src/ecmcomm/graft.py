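"""Supertree assembly: marker rate scaling and grafting of species-level
crowns onto an ultrametric genus backbone.

Scale factors are estimated on the unsmoothed (substitution-scale) trees by
comparing outgroup-to-ingroup path lengths between the fast marker (ITS,
species trees) and the slow marker (LSU, genus backbone).  They are applied
as crown *fractions* of the smoothed attachment-node age, which keeps the
grafted supertree exactly ultrametric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from ecmcomm.errors import ValidationError
from ecmcomm.tree import PhyloTree

log = logging.getLogger(__name__)


@dataclass
class ScaleFactor:
    """Genus-specific LSU/ITS branch-length ratio."""

    genus: str
    s_g: float
    p_its: float  # mean ingroup-tip -> outgroup-tip patristic distance (ITS)
    p_lsu: float  # genus-tip -> outgroup-genus-tip patristic distance (backbone)

    def __post_init__(self) -> None:
        if self.s_g <= 0:
            raise ValidationError(f"scale factor for {self.genus} must be > 0")


@dataclass
class GraftPlan:
    genus: str
    attachment_age: float   # age of the genus tip's parent in the smoothed backbone
    crown_fraction: float   # f_g = s_g * D_its / L_lsu, capped
    scale_factor: float
    capped: bool


def _patristic(ptree: PhyloTree, a: str, b: str) -> float:
    labels, dm = ptree.patristic_matrix()
    try:
        return float(dm[labels.index(a), labels.index(b)])
    except ValueError as exc:
        missing = [x for x in (a, b) if x not in labels]
        raise ValidationError(f"tips not in tree: {missing}") from exc


def estimate_scale_factor(
    its_tree: PhyloTree,
    backbone: PhyloTree,
    genus: str,
    outgroup_genus: str,
    outgroup_labels: list[str],
) -> ScaleFactor:
    """Ratio of LSU to ITS path lengths through a shared outgroup.

    ``its_tree`` is the unsmoothed species-level tree containing ingroup
    tips plus outgroup tips (identified by ``outgroup_labels``); ``backbone``
    is the unsmoothed genus-level tree.  The first outgroup tip present is
    used (deterministic).
    """
    tips = its_tree.tip_labels()
    out_tips = [t for t in outgroup_labels if t in tips]
    if not out_tips:
        raise ValidationError(
            f"genus {genus}: no outgroup tip among {outgroup_labels} in ITS tree"
        )
    out_tip = out_tips[0]
    ingroup = [t for t in tips if t not in set(outgroup_labels)]
    if not ingroup:
        raise ValidationError(f"genus {genus}: ITS tree has no ingroup tips")
    labels, dm = its_tree.patristic_matrix()
    oi = labels.index(out_tip)
    p_its = float(np.mean([dm[labels.index(t), oi] for t in ingroup]))
    bb_tips = backbone.tip_labels()
    for need, which in ((genus, "genus"), (outgroup_genus, "outgroup genus")):
        if need not in bb_tips:
            raise ValidationError(f"{which} tip {need!r} absent from backbone")
    p_lsu = _patristic(backbone, genus, outgroup_genus)
    if p_its <= 0:
        raise ValidationError(f"genus {genus}: zero ITS outgroup path length")
    return ScaleFactor(genus=genus, s_g=p_lsu / p_its, p_its=p_its, p_lsu=p_lsu)


def mean_ingroup_depth(its_tree_pruned: PhyloTree) -> float:
    """Mean root-to-tip depth of the outgroup-pruned (crown) ITS tree."""
    depths = its_tree_pruned.tip_depths()
    return float(np.mean(list(depths.values())))


def plan_graft(
    genus: str,
    scale: ScaleFactor,
    its_tree_pruned: PhyloTree,
    backbone_sub: PhyloTree,
    backbone_time: PhyloTree,
    crown_cap_beta: float = 0.9,
) -> GraftPlan:
    """Compute the crown fraction and attachment age for one genus.

    The crown depth expected on the LSU scale is ``s_g * D_its``; expressed
    as a fraction of the genus stem length ``L_lsu`` in the unsmoothed
    backbone it transfers to the smoothed backbone as a fraction of the
    attachment-node age.  Fractions exceeding ``crown_cap_beta`` are capped
    with a warning.
    """
    d_its = mean_ingroup_depth(its_tree_pruned)
    node = backbone_sub.tree.find_node_with_taxon_label(genus)
    if node is None:
        raise ValidationError(f"genus tip {genus!r} absent from backbone")
    l_lsu = node.edge.length or 0.0
    if l_lsu <= 0:
        raise ValidationError(f"genus {genus}: zero stem length in backbone")
    node_t = backbone_time.tree.find_node_with_taxon_label(genus)
    if node_t is None:
        raise ValidationError(f"genus tip {genus!r} absent from smoothed backbone")
    ages = backbone_time.node_ages()
    a_g = float(ages[node_t.parent_node])
    f_g = scale.s_g * d_its / l_lsu
    capped = False
    if f_g > crown_cap_beta:
        log.warning(
            "genus %s: crown fraction %.3f exceeds cap %.2f; capping", genus, f_g,
            crown_cap_beta,
        )
        f_g, capped = crown_cap_beta, True
    if f_g <= 0:
        raise ValidationError(f"genus {genus}: non-positive crown fraction")
    return GraftPlan(
        genus=genus, attachment_age=a_g, crown_fraction=f_g,
        scale_factor=scale.s_g, capped=capped,
    )


def _copy_subtree(node: dendropy.Node, ns: dendropy.TaxonNamespace) -> dendropy.Node:
    new = dendropy.Node()
    new.edge.length = node.edge.length
    if node.taxon is not None:
        taxon = ns.get_taxon(node.taxon.label)
        if taxon is None:
            taxon = ns.new_taxon(label=node.taxon.label)
        new.taxon = taxon
    for child in node.child_nodes():
        new.add_child(_copy_subtree(child, ns))
    return new


def graft(
    backbone_time: PhyloTree,
    species_time_trees: dict[str, PhyloTree],
    plans: dict[str, GraftPlan],
    single_species: dict[str, str] | None = None,
    ultrametric_tol: float = 1e-8,
) -> PhyloTree:
    """Replace genus tips of the smoothed backbone with scaled crowns.

    ``species_time_trees`` maps genus -> ultrametric species tree (outgroups
    already pruned); ``single_species`` maps genus -> species label for
    genera represented by one species (tip relabel only).
    """
    single_species = single_species or {}
    if backbone_time.scale != "relative_time":
        raise ValidationError("backbone must be on the relative-time scale")
    if backbone_time.ultrametric_deviation() > ultrametric_tol:
        raise ValidationError("backbone is not ultrametric")
    work = backbone_time.clone()
    tree = work.tree
    ns = tree.taxon_namespace
    for genus in list(t.taxon.label for t in tree.leaf_node_iter() if t.taxon):
        if genus in single_species:
            node = tree.find_node_with_taxon_label(genus)
            node.taxon = ns.new_taxon(label=single_species[genus])
            continue
        if genus not in species_time_trees:
            raise ValidationError(f"no graft plan or species tree for genus {genus!r}")
        if genus not in plans:
            raise ValidationError(f"graft plan missing for genus {genus!r}")
        crown = species_time_trees[genus]
        dev = crown.ultrametric_deviation()
        if dev > ultrametric_tol * max(1.0, crown.root_age()):
            raise ValidationError(
                f"species tree for {genus!r} not ultrametric (deviation {dev:.3g})"
            )
        plan = plans[genus]
        target_age = plan.crown_fraction * plan.attachment_age
        factor = target_age / crown.root_age()
        scaled = crown.clone()
        scaled.scale_branch_lengths(factor)
        node = tree.find_node_with_taxon_label(genus)
        parent = node.parent_node
        sub_root = _copy_subtree(scaled.tree.seed_node, ns)
        sub_root.edge.length = plan.attachment_age - target_age
        parent.remove_child(node)
        parent.add_child(sub_root)
    # round-trip to clean the taxon namespace of replaced genus taxa
    out = PhyloTree.from_string(
        PhyloTree(tree=tree, scale="relative_time").as_newick(),
        scale="relative_time", allow_polytomy=True,
    )
    if out.ultrametric_deviation() > ultrametric_tol:
        raise ValidationError(
            f"grafted tree not ultrametric (deviation {out.ultrametric_deviation():.3g})"
        )
    return out


def prune_to_backbone(supertree: PhyloTree, genus_map: dict[str, str]) -> PhyloTree:
    """Collapse a supertree to one representative tip per genus.

    Representatives are the lexicographically first species of each genus;
    the retained tips are relabelled with their genus.  Topology does not
    depend on the representative choice because genera are monophyletic in
    the grafted tree.
    """
    if not genus_map:
        raise ValidationError("genus_map must be non-empty")
    tips = supertree.tip_labels()
    missing = [t for t in tips if t not in genus_map]
    if missing:
        raise ValidationError(f"tips missing from genus_map: {missing}")
    by_genus: dict[str, list[str]] = {}
    for tip in tips:
        by_genus.setdefault(genus_map[tip], []).append(tip)
    reps = {min(members): genus for genus, members in by_genus.items()}
    pruned = supertree.prune_tips([t for t in tips if t not in reps])
    for lf in pruned.tree.leaf_node_iter():
        lf.taxon = pruned.tree.taxon_namespace.new_taxon(label=reps[lf.taxon.label])
    return PhyloTree.from_string(
        pruned.as_newick(), scale=supertree.scale, allow_polytomy=True
    )
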