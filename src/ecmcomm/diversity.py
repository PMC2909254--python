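"""Diversity and ordination: rank/frequency curves, sample-based
accumulation curves with bootstrap intervals, habitat overlap, Bray-Curtis
dissimilarity on incidence data, connectivity filtering, and Kruskal
non-metric multidimensional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from ecmcomm.errors import DegenerateInputError, ValidationError
from ecmcomm.matrix import CommunityMatrix


@dataclass
class RankFrequency:
    species_ids: list[str]        # sorted by descending frequency, ties by id
    frequencies: list[int]
    singleton_fraction: float


def rank_frequency(matrix: CommunityMatrix) -> RankFrequency:
    """Species sample-frequency spectrum sorted into a rank curve."""
    freqs = matrix.data.sum(axis=0)
    order = sorted(
        range(len(matrix.species_ids)),
        key=lambda j: (-int(freqs[j]), matrix.species_ids[j]),
    )
    f_sorted = [int(freqs[j]) for j in order]
    singletons = sum(1 for f in f_sorted if f == 1)
    return RankFrequency(
        species_ids=[matrix.species_ids[j] for j in order],
        frequencies=f_sorted,
        singleton_fraction=singletons / len(f_sorted) if f_sorted else 0.0,
    )


@dataclass
class AccumulationCurve:
    depths: list[int]
    mean_richness: list[float]
    lower95: list[float]
    upper95: list[float]
    n_boot: int


def _mean_curve(data: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    n = data.shape[0]
    acc = np.zeros(n)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        acc += np.maximum.accumulate(data[perm], axis=0).sum(axis=1)
    return acc / n_perm


def accumulation_curve(
    matrix: CommunityMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    n_perm: int = 200,
    n_perm_boot: int = 10,
) -> AccumulationCurve:
    """Sample-based species accumulation with percentile bootstrap CIs.

    Mean richness at depth k averages over random sample orderings
    (Monte-Carlo estimate of sample-based rarefaction); the 95% interval
    comes from resampling samples with replacement.
    """
    if matrix.shape[0] < 2:
        raise DegenerateInputError("accumulation_curve requires >= 2 samples")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    data = matrix.data.astype(np.int8)
    n = data.shape[0]
    mean = _mean_curve(data, n_perm, rng)
    boot = np.empty((n_boot, n))
    for b in range(n_boot):
        resample = data[rng.integers(0, n, size=n)]
        boot[b] = _mean_curve(resample, n_perm_boot, rng)
    lower = np.percentile(boot, 2.5, axis=0)
    upper = np.percentile(boot, 97.5, axis=0)
    return AccumulationCurve(
        depths=list(range(1, n + 1)),
        mean_richness=[float(x) for x in mean],
        lower95=[float(x) for x in lower],
        upper95=[float(x) for x in upper],
        n_boot=n_boot,
    )


@dataclass
class OverlapStats:
    n_a: int
    n_b: int
    n_shared: int
    jaccard_pct: float
    sorensen_pct: float


def overlap(matrix_a: CommunityMatrix, matrix_b: CommunityMatrix) -> OverlapStats:
    """Species-set overlap between two habitats (Jaccard and Sorensen %)."""
    a = set(matrix_a.species_present())
    b = set(matrix_b.species_present())
    shared = len(a & b)
    union = len(a | b)
    jac = 100.0 * shared / union if union else 0.0
    sor = 200.0 * shared / (len(a) + len(b)) if (a or b) else 0.0
    return OverlapStats(
        n_a=len(a), n_b=len(b), n_shared=shared, jaccard_pct=jac, sorensen_pct=sor
    )


def bray_curtis(matrix: CommunityMatrix) -> np.ndarray:
    """Pairwise sample dissimilarity, 1 - Sorensen on presence/absence."""
    data = matrix.data.astype(float)
    sizes = data.sum(axis=1)
    if (sizes == 0).any():
        empty = [s for s, z in zip(matrix.sample_ids, sizes) if z == 0]
        raise ValidationError(f"all-zero sample rows: {empty}")
    shared = data @ data.T
    dis = 1.0 - 2.0 * shared / (sizes[:, None] + sizes[None, :])
    np.fill_diagonal(dis, 0.0)
    return dis


def connectivity_filter(dissim: np.ndarray) -> tuple[list[int], int]:
    """Keep the largest connected component of the share-a-species graph.

    Samples are connected when their dissimilarity is < 1.  Ties between
    equal-size components are broken in favor of the first-encountered
    (lowest first sample index) component.
    """
    n = dissim.shape[0]
    seen = [False] * n
    components: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if not seen[v] and v != u and dissim[u, v] < 1.0 - 1e-12:
                    seen[v] = True
                    stack.append(v)
        components.append(sorted(comp))
    best = max(components, key=lambda c: (len(c), -c[0]))
    return best, n - len(best)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    stress_pct: float            # Kruskal stress-1 x 100
    n_discarded: int
    n_restarts: int
    converged: bool
    per_restart_stress: list[float] = field(default_factory=list)


def _classical_mds(dissim: np.ndarray, k: int) -> np.ndarray:
    n = dissim.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dissim ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _nmds_single(
    dissim_condensed: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float]:
    order = np.argsort(dissim_condensed, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    ranks = np.arange(len(dissim_condensed), dtype=float)
    x = x0.copy()
    n = x.shape[0]
    d = pdist(x)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(ranks, d[order])
    stress = _stress1(d, dhat)
    for _ in range(max_iter):
        # Guttman transform toward the fitted disparities
        dm = squareform(d)
        dhat_m = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dm > 0, dhat_m / dm, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = b @ x / n
        d_new = pdist(x_new)
        dhat_new = np.empty_like(d_new)
        dhat_new[order] = iso.fit_transform(ranks, d_new[order])
        stress_new = _stress1(d_new, dhat_new)
        if stress_new > stress - 1e-15:
            break
        improved = stress - stress_new
        x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
        if improved < tol:
            break
    return x - x.mean(axis=0), stress


def nmds(
    dissim: np.ndarray,
    sample_ids: list[str] | None = None,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_discarded: int = 0,
) -> OrdinationResult:
    """Kruskal non-metric MDS on a symmetric dissimilarity matrix.

    The first start is the classical (metric) scaling solution; remaining
    starts are random.  Convergence is declared when at least two restarts
    agree within 1% relative stress.  Stress-1 is reported as a percentage.
    """
    dissim = np.asarray(dissim, dtype=float)
    n = dissim.shape[0]
    if dissim.shape != (n, n):
        raise ValidationError("dissimilarity matrix must be square")
    if not np.isfinite(dissim).all():
        raise ValidationError("non-finite dissimilarities")
    if k >= n - 1:
        raise ValidationError(f"k={k} too large for {n} samples")
    sample_ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    rng = np.random.default_rng(seed)
    condensed = squareform(dissim, checks=False)
    scale = condensed.max() or 1.0

    best_x, best_stress = None, np.inf
    stresses: list[float] = []
    for r in range(n_restarts):
        x0 = _classical_mds(dissim, k) if r == 0 else rng.normal(0.0, scale, size=(n, k))
        if r == 0 and np.allclose(x0, 0.0):
            x0 = rng.normal(0.0, scale, size=(n, k))
        x, stress = _nmds_single(condensed, x0, max_iter, tol)
        stresses.append(stress)
        if stress < best_stress:
            best_x, best_stress = x, stress
    near = sum(1 for s in stresses if s <= best_stress * 1.01 + 1e-12)
    return OrdinationResult(
        sample_ids=list(sample_ids),
        coordinates=best_x,
        stress_pct=100.0 * best_stress,
        n_discarded=n_discarded,
        n_restarts=n_restarts,
        converged=near >= 2 or n_restarts == 1,
        per_restart_stress=[100.0 * s for s in stresses],
    )
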