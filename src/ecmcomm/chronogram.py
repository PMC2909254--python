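"""Nonparametric rate smoothing: substitution trees -> relative-time trees.

Node ages are estimated by minimizing the sum of squared differences between
the per-branch substitution rates of parent and child branches; branches
hanging off the root are penalized by their deviation from the mean rate of
the root's children (the root has no ancestral rate).  Tip ages are fixed at
0 and the root age is normalized to 1, so the result is an ultrametric
relative-time tree.

Ages are parameterized as fractions of the parent age through a logistic
map, which enforces parent > child without explicit constraints; the
objective is minimized with L-BFGS-B from the depth-implied starting point
plus jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from ecmcomm.errors import DegenerateInputError
from ecmcomm.tree import PhyloTree

_EPS_DT = 1e-12


@dataclass
class SmoothingResult:
    tree: PhyloTree              # relative-time, ultrametric, root age 1
    objective: float             # W at the optimum
    rates: dict[str, float]      # per-branch rate keyed by child-node name


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "mrca:" + "|".join(leaves)


def _branch_rates(
    tree: dendropy.Tree, ages: dict[dendropy.Node, float]
) -> dict[dendropy.Node, float]:
    rates: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        dt = ages[node.parent_node] - ages[node]
        rates[node] = (node.edge.length or 0.0) / max(dt, _EPS_DT)
    return rates


def nprs_objective(tree: dendropy.Tree, ages: dict[dendropy.Node, float]) -> float:
    """Sum of squared rate changes, with the mean-rate device at the root."""
    rates = _branch_rates(tree, ages)
    root = tree.seed_node
    w = 0.0
    for node, r in rates.items():
        parent = node.parent_node
        if parent is root:
            continue
        w += (r - rates[parent]) ** 2
    root_rates = [rates[c] for c in root.child_nodes()]
    rbar = sum(root_rates) / len(root_rates)
    w += sum((r - rbar) ** 2 for r in root_rates)
    return w


def nprs_smooth(
    ptree: PhyloTree, n_restarts: int = 5, seed: int = 0
) -> SmoothingResult:
    """Smooth a substitution-scale tree into an ultrametric chronogram."""
    if ptree.n_tips < 2:
        raise DegenerateInputError("nprs_smooth requires at least 2 tips")
    work = ptree.clone()
    tree = work.tree
    root = tree.seed_node
    lengths = [
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    if all(bl <= 0 for bl in lengths):
        raise DegenerateInputError("all branch lengths are zero")

    free = [
        node
        for node in tree.preorder_node_iter()
        if node.parent_node is not None and not node.is_leaf()
    ]

    def ages_from_x(x: np.ndarray) -> dict[dendropy.Node, float]:
        ages: dict[dendropy.Node, float] = {root: 1.0}
        for node, xi in zip(free, x):
            ages[node] = ages[node.parent_node] * expit(xi)
        for lf in tree.leaf_node_iter():
            ages[lf] = 0.0
        return ages

    def objective(x: np.ndarray) -> float:
        return nprs_objective(tree, ages_from_x(x))

    if free:
        # start from the ages implied by raw depths (exact for clock input)
        depths = work.node_depths()
        max_depth = max(depths[lf] for lf in tree.leaf_node_iter())
        x0 = np.empty(len(free))
        age0: dict[dendropy.Node, float] = {root: 1.0}
        for i, node in enumerate(free):
            a = 1.0 - depths[node] / max_depth if max_depth > 0 else 0.5
            frac = a / age0[node.parent_node] if age0[node.parent_node] > 0 else 0.5
            frac = min(max(frac, 0.05), 0.95)
            age0[node] = age0[node.parent_node] * frac
            x0[i] = logit(frac)

        rng = np.random.default_rng(seed)
        best_x, best_w = None, np.inf
        starts = [x0] + [
            x0 + rng.normal(0.0, 0.5, size=len(free)) for _ in range(n_restarts - 1)
        ]
        for start in starts:
            res = minimize(
                objective,
                start,
                method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
            )
            if res.fun < best_w:
                best_w, best_x = res.fun, res.x
        ages = ages_from_x(best_x)
        w_opt = float(best_w)
    else:
        ages = ages_from_x(np.empty(0))
        w_opt = objective(np.empty(0))

    rates = _branch_rates(tree, ages)
    rate_report = {_node_key(node): float(r) for node, r in rates.items()}

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    smoothed = PhyloTree(tree=tree, scale="relative_time")
    return SmoothingResult(tree=smoothed, objective=w_opt, rates=rate_report)


def check_ultrametric(ptree: PhyloTree, tol: float = 1e-8) -> float:
    """Return max deviation of root-to-tip path sums from their mean."""
    return ptree.ultrametric_deviation()
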