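"""Rooted phylogenetic trees with an explicit branch-length scale.

Thin wrapper around :mod:`dendropy` that records whether branch lengths are
substitutions per site or relative time (never inferred), and provides the
tree utilities the pipeline needs: depths, node ages, ultrametricity checks,
patristic distances, Robinson-Foulds comparison and Newick round-tripping.
A Newick file may carry a ``<name>.meta.json`` sidecar holding the scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from ecmcomm.errors import (
    DegenerateInputError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

SCALES = ("substitutions", "relative_time")


@dataclass
class PhyloTree:
    tree: dendropy.Tree
    scale: str = "substitutions"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_string(
        cls,
        newick: str,
        scale: str = "substitutions",
        allow_polytomy: bool = False,
        require_lengths: bool = True,
    ) -> "PhyloTree":
        newick = newick.strip()
        if not newick or newick == ";":
            raise EmptyInputError("empty Newick string")
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise FormatError(f"malformed Newick: {exc}") from exc
        if tree.seed_node is None or not tree.leaf_nodes():
            raise EmptyInputError("Newick parsed to an empty tree")
        obj = cls(tree=tree, scale=scale)
        obj._validate(allow_polytomy=allow_polytomy, require_lengths=require_lengths)
        return obj

    @classmethod
    def read(
        cls,
        path: str | Path,
        scale: str | None = None,
        allow_polytomy: bool = False,
        require_lengths: bool = True,
    ) -> "PhyloTree":
        """Read a single rooted Newick tree; scale from sidecar unless given."""
        path = Path(path)
        if scale is None:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            if sidecar.exists():
                scale = json.loads(sidecar.read_text()).get("scale", "substitutions")
            else:
                scale = "substitutions"
        return cls.from_string(
            path.read_text(), scale=scale,
            allow_polytomy=allow_polytomy, require_lengths=require_lengths,
        )

    def write(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        path.write_text(self.as_newick())
        if sidecar:
            meta = path.with_suffix(path.suffix + ".meta.json")
            meta.write_text(json.dumps({"scale": self.scale}, sort_keys=True) + "\n")

    def as_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
            ).strip()
            + "\n"
        )

    def _validate(self, allow_polytomy: bool, require_lengths: bool) -> None:
        root = self.tree.seed_node
        if len(root.child_nodes()) == 0:
            raise EmptyInputError("tree has no edges")
        if not allow_polytomy:
            for node in self.tree.preorder_node_iter():
                if len(node.child_nodes()) > 2:
                    where = "root" if node is root else self._node_name(node)
                    raise FormatError(
                        f"multifurcation at {where}; pass allow_polytomy to accept"
                    )
        if require_lengths:
            for node in self.tree.preorder_node_iter():
                if node is root:
                    continue
                if node.edge.length is None:
                    raise FormatError(
                        f"missing branch length on edge above node {self._node_name(node)!r}"
                    )
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels")

    @staticmethod
    def _node_name(node: dendropy.Node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        leaves = [lf.taxon.label for lf in node.leaf_iter() if lf.taxon]
        return "MRCA(" + ",".join(sorted(leaves)[:3]) + ")"

    # -- basic accessors ---------------------------------------------------

    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def clone(self) -> "PhyloTree":
        return PhyloTree(tree=self.tree.clone(depth=1), scale=self.scale)

    # -- geometry ----------------------------------------------------------

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Path length from the root to every node."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            lf.taxon.label: depths[lf] for lf in self.tree.leaf_node_iter()
        }

    def ultrametric_deviation(self) -> float:
        """Max over tips of |depth(tip) - mean tip depth|."""
        d = np.array(list(self.tip_depths().values()))
        return float(np.abs(d - d.mean()).max())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        return self.ultrametric_deviation() <= tol

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Height of each node above the (mean) tip level."""
        depths = self.node_depths()
        tip_mean = float(np.mean([depths[lf] for lf in self.tree.leaf_node_iter()]))
        return {node: tip_mean - depth for node, depth in depths.items()}

    def root_age(self) -> float:
        return self.node_ages()[self.tree.seed_node]

    def scale_branch_lengths(self, factor: float) -> None:
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is not None:
                node.edge.length *= factor

    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        """All-pairs path-length distances between tips (sorted tip order)."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and (node.edge.length or 0.0) < 0:
                raise ValidationError(
                    f"negative branch length above {self._node_name(node)!r}"
                )
        labels = sorted(self.tip_labels())
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dm = np.zeros((n, n))
        # Postorder accumulation: for each internal node, tips in different
        # child subtrees meet there; distance = sum of depths below the node.
        below: dict[dendropy.Node, list[tuple[int, float]]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = [(idx[node.taxon.label], 0.0)]
                continue
            groups = []
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                groups.append([(i, d + bl) for i, d in below.pop(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            dm[i, j] = dm[j, i] = di + dj
            below[node] = [pair for grp in groups for pair in grp]
        return labels, dm

    def prune_tips(self, drop: list[str]) -> "PhyloTree":
        keep = [t for t in self.tip_labels() if t not in set(drop)]
        if not keep:
            raise DegenerateInputError("pruning would remove all tips")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(keep)
        # collapse any unifurcation left at the root
        root = tree.seed_node
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            child.edge.length = None
            child.parent_node = None
            tree.seed_node = child
            root = child
        return PhyloTree(tree=tree, scale=self.scale)


def read_newick(
    path: str | Path,
    scale: str | None = None,
    allow_polytomy: bool = False,
) -> PhyloTree:
    return PhyloTree.read(path, scale=scale, allow_polytomy=allow_polytomy)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(path)


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson-Foulds (symmetric difference) distance."""
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.as_newick(), schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=b.as_newick(), schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
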