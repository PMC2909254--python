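"""Phylogenetic community structure: MPD/MNTD, NRI/NTI and null models.

Communities default to pooled habitat species lists (one index per habitat,
matching a two-habitat comparison); a per-sample mode is available.  Three
null models are provided:

* ``independent_swap`` — Gotelli's independent (trial) swap on the full
  binary matrix: random 2x2 checkerboards are flipped, preserving sample
  richness and species frequency exactly; the community species pool is
  recomputed from each randomized matrix.
* ``phylogeny_shuffle`` — tip labels permuted on the distance matrix.
* ``pool_draw`` — equal-richness random draws from the species pool
  (exhaustive enumeration available for small cases).

Indices are sign-flipped so that phylogenetic clustering gives positive
values; p-values use the (1+k)/(n+1) convention, one-tailed toward
clustering, with a two-tailed variant also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from ecmcomm.config import RunConfig
from ecmcomm.errors import DegenerateInputError, ValidationError
from ecmcomm.matrix import CommunityMatrix
from ecmcomm.tree import PhyloTree

log = logging.getLogger(__name__)


@dataclass
class NullModelSpec:
    model: str = "independent_swap"
    n_runs: int = 999
    swap_burnin: int | None = None      # default 10 x number of matrix cells
    swaps_between: int | None = None    # default 1 x number of matrix cells
    exhaustive: bool = False            # pool_draw only: enumerate all subsets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 and not self.exhaustive:
            raise ValidationError("n_runs must be >= 1")


@dataclass
class CommunityStructureResult:
    community: str
    n_taxa: int
    mpd_obs: float
    mntd_obs: float
    mpd_null_mean: float
    mpd_null_sd: float
    mntd_null_mean: float
    mntd_null_sd: float
    nri: float
    nti: float
    p_mpd_one_tailed: float
    p_mpd_two_tailed: float
    p_mntd_one_tailed: float
    p_mntd_two_tailed: float
    n_runs: int
    model: str


def patristic_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """All-pairs patristic distances between tips (sorted label order)."""
    return tree.patristic_matrix()


def mean_phylo_distances(
    sample: list[str] | set[str], labels: list[str], dm: np.ndarray
) -> tuple[float, float]:
    """MPD (mean over unordered pairs) and MNTD (mean nearest-taxon distance)."""
    members = sorted(set(sample))
    if len(members) < 2:
        raise DegenerateInputError("MPD/MNTD undefined for fewer than 2 taxa")
    missing = [m for m in members if m not in labels]
    if missing:
        raise ValidationError(f"species missing from tree: {missing}")
    idx = np.array([labels.index(m) for m in members])
    sub = dm[np.ix_(idx, idx)]
    iu = np.triu_indices(len(members), k=1)
    mpd = float(sub[iu].mean())
    np.fill_diagonal(sub, np.inf)
    mntd = float(sub.min(axis=1).mean())
    return mpd, mntd


def _mpd_mntd_idx(idx: np.ndarray, dm: np.ndarray) -> tuple[float, float]:
    sub = dm[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    mpd = float(sub[iu].mean())
    sub = sub.copy()
    np.fill_diagonal(sub, np.inf)
    return mpd, float(sub.min(axis=1).mean())


class SwapChain:
    """Markov chain of trial checkerboard swaps on a binary matrix.

    The proposal (uniform random row pair and column pair) is symmetric, so
    the chain's stationary distribution is uniform over the margin-preserving
    matrices reachable by swaps.  Margins are asserted after every sampled
    state.
    """

    _BATCH = 8192

    def __init__(self, data: np.ndarray, rng: np.random.Generator) -> None:
        self.data = np.array(data, dtype=np.int8)
        self.rng = rng
        self._row_sums = self.data.sum(axis=1).copy()
        self._col_sums = self.data.sum(axis=0).copy()
        self.accepted = 0

    def step(self, n_trials: int) -> None:
        mat = self.data
        n, m = mat.shape
        if n < 2 or m < 2:
            return
        done = 0
        while done < n_trials:
            k = min(self._BATCH, n_trials - done)
            rows = self.rng.integers(0, n, size=(k, 2))
            cols = self.rng.integers(0, m, size=(k, 2))
            for (r1, r2), (c1, c2) in zip(rows, cols):
                if r1 == r2 or c1 == c2:
                    continue
                a = mat[r1, c1]
                d = mat[r2, c2]
                if a != d:
                    continue
                b = mat[r1, c2]
                if b == a or mat[r2, c1] != b:
                    continue
                mat[r1, c1] = b
                mat[r2, c2] = b
                mat[r1, c2] = a
                mat[r2, c1] = a
                self.accepted += 1
            done += k

    def snapshot(self) -> np.ndarray:
        assert (self.data.sum(axis=1) == self._row_sums).all(), "row sums drifted"
        assert (self.data.sum(axis=0) == self._col_sums).all(), "column sums drifted"
        return self.data.copy()


def independent_swap(
    matrix: CommunityMatrix, n_trial_swaps: int, seed: int | np.random.Generator = 0
) -> CommunityMatrix:
    """Randomize a presence/absence matrix preserving both margins exactly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chain = SwapChain(matrix.data, rng)
    chain.step(n_trial_swaps)
    if chain.accepted == 0:
        log.info("independent_swap: no checkerboard found; matrix unchanged")
    return CommunityMatrix(
        sample_ids=list(matrix.sample_ids),
        species_ids=list(matrix.species_ids),
        data=chain.snapshot(),
        forests=list(matrix.forests) if matrix.forests else None,
        habitats=list(matrix.habitats) if matrix.habitats else None,
    )


def _standardize(obs: float, null: np.ndarray, exhaustive: bool) -> tuple[float, float, float]:
    mean = float(null.mean())
    sd = float(null.std(ddof=0 if exhaustive else 1)) if len(null) > 1 else 0.0
    # a degenerate null (all replicates equal up to summation-order noise)
    # yields index 0 rather than a 0/0 artifact
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return mean, sd, 0.0
    return mean, sd, -(obs - mean) / sd


def _p_values(obs: float, null: np.ndarray) -> tuple[float, float]:
    n = len(null)
    k_low = int((null <= obs).sum())
    k_high = int((null >= obs).sum())
    p_one = (1 + k_low) / (n + 1)
    p_two = min(1.0, 2 * min((1 + k_low) / (n + 1), (1 + k_high) / (n + 1)))
    return p_one, p_two


def _null_distributions(
    matrix: CommunityMatrix,
    groups: dict[str, list[int]],
    labels: list[str],
    dm: np.ndarray,
    spec: NullModelSpec,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Null MPD/MNTD replicates per community group."""
    col_idx = np.array([labels.index(sp) for sp in matrix.species_ids])
    n_pool = len(labels)
    out: dict[str, list[tuple[float, float]]] = {g: [] for g in groups}

    if spec.model == "independent_swap":
        cells = matrix.data.size
        burnin = spec.swap_burnin if spec.swap_burnin is not None else 10 * cells
        between = spec.swaps_between if spec.swaps_between is not None else cells
        chain = SwapChain(matrix.data, rng)
        chain.step(burnin)
        for _ in range(spec.n_runs):
            chain.step(between)
            data = chain.snapshot()
            for name, rows in groups.items():
                present = data[rows].any(axis=0)
                idx = col_idx[present]
                out[name].append(_mpd_mntd_idx(idx, dm))
    elif spec.model == "phylogeny_shuffle":
        obs_idx = {
            name: col_idx[matrix.data[rows].any(axis=0)] for name, rows in groups.items()
        }
        for _ in range(spec.n_runs):
            perm = rng.permutation(n_pool)
            for name, idx in obs_idx.items():
                out[name].append(_mpd_mntd_idx(perm[idx], dm))
    elif spec.model == "pool_draw":
        sizes = {
            name: int(matrix.data[rows].any(axis=0).sum()) for name, rows in groups.items()
        }
        if spec.exhaustive:
            for name, size in sizes.items():
                if comb(n_pool, size) > 200_000:
                    raise ValidationError(
                        "exhaustive pool_draw infeasible for this pool/community size"
                    )
                for subset in combinations(range(n_pool), size):
                    out[name].append(_mpd_mntd_idx(np.array(subset), dm))
        else:
            pool = np.arange(n_pool)
            for _ in range(spec.n_runs):
                for name, size in sizes.items():
                    idx = rng.choice(pool, size=size, replace=False)
                    out[name].append(_mpd_mntd_idx(idx, dm))
    else:
        raise ValidationError(f"unknown null model {spec.model!r}")
    return {g: tuple(np.array(v).T) for g, v in out.items()}  # type: ignore[return-value]


def comstruct(
    matrix: CommunityMatrix,
    tree: PhyloTree,
    spec: NullModelSpec | None = None,
    by_sample: bool = False,
) -> list[CommunityStructureResult]:
    """NRI/NTI of each community against a null model.

    By default samples are pooled per habitat label into one species list
    per habitat; with ``by_sample`` each sample is its own community.
    """
    spec = spec or NullModelSpec()
    labels, dm = tree.patristic_matrix()
    missing = [sp for sp in matrix.species_ids if sp not in labels]
    if missing:
        raise ValidationError(f"species missing from tree: {missing}")
    if by_sample:
        groups = {sid: [i] for i, sid in enumerate(matrix.sample_ids)}
    elif matrix.habitats is not None:
        groups = {}
        for i, hab in enumerate(matrix.habitats):
            groups.setdefault(hab, []).append(i)
    else:
        groups = {"all": list(range(len(matrix.sample_ids)))}

    col_idx = np.array([labels.index(sp) for sp in matrix.species_ids])
    rng = np.random.default_rng(spec.seed)
    nulls = _null_distributions(matrix, groups, labels, dm, spec, rng)

    results: list[CommunityStructureResult] = []
    for name, rows in groups.items():
        present = matrix.data[rows].any(axis=0)
        idx = col_idx[present]
        if len(idx) < 2:
            raise DegenerateInputError(
                f"community {name!r} has fewer than 2 taxa"
            )
        mpd_obs, mntd_obs = _mpd_mntd_idx(idx, dm)
        mpd_null, mntd_null = nulls[name]
        mpd_mean, mpd_sd, nri = _standardize(mpd_obs, mpd_null, spec.exhaustive)
        mntd_mean, mntd_sd, nti = _standardize(mntd_obs, mntd_null, spec.exhaustive)
        p_mpd1, p_mpd2 = _p_values(mpd_obs, mpd_null)
        p_mntd1, p_mntd2 = _p_values(mntd_obs, mntd_null)
        results.append(
            CommunityStructureResult(
                community=name, n_taxa=len(idx),
                mpd_obs=mpd_obs, mntd_obs=mntd_obs,
                mpd_null_mean=mpd_mean, mpd_null_sd=mpd_sd,
                mntd_null_mean=mntd_mean, mntd_null_sd=mntd_sd,
                nri=nri, nti=nti,
                p_mpd_one_tailed=p_mpd1, p_mpd_two_tailed=p_mpd2,
                p_mntd_one_tailed=p_mntd1, p_mntd_two_tailed=p_mntd2,
                n_runs=len(mpd_null), model=spec.model,
            )
        )
    return results


def comstruct_from_config(
    matrix: CommunityMatrix, tree: PhyloTree, config: RunConfig, by_sample: bool = False
) -> list[CommunityStructureResult]:
    spec = NullModelSpec(
        model=config.null_model, n_runs=config.n_null_runs, seed=config.seed
    )
    return comstruct(matrix, tree, spec, by_sample=by_sample)
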