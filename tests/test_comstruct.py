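from itertools import combinations

import numpy as np
import pytest

from ecmcomm.comstruct import (
    NullModelSpec,
    SwapChain,
    _standardize,
    comstruct,
    independent_swap,
    mean_phylo_distances,
    patristic_distances,
)
from ecmcomm.errors import DegenerateInputError, ValidationError
from ecmcomm.matrix import CommunityMatrix


# -- distances -------------------------------------------------------------


def test_patristic_hand_sums(balanced_tree):
    labels, dm = patristic_distances(balanced_tree)
    i = {lab: k for k, lab in enumerate(labels)}
    assert dm[i["A"], i["B"]] == 2.0
    assert dm[i["A"], i["C"]] == 4.0


def test_patristic_star(star_tree):
    labels, dm = patristic_distances(star_tree)
    off = dm[~np.eye(len(labels), dtype=bool)]
    assert (off == 2.0).all()


def test_mpd_mntd_pair(balanced_tree):
    labels, dm = patristic_distances(balanced_tree)
    assert mean_phylo_distances({"A", "B"}, labels, dm) == (2.0, 2.0)


def test_mpd_mntd_triple_hand_enumeration(balanced_tree):
    labels, dm = patristic_distances(balanced_tree)
    mpd, mntd = mean_phylo_distances({"A", "B", "C"}, labels, dm)
    assert mpd == pytest.approx(10 / 3)      # (2+4+4)/3
    assert mntd == pytest.approx(8 / 3)      # (2+2+4)/3


def test_mpd_full_star(star_tree):
    labels, dm = patristic_distances(star_tree)
    mpd, mntd = mean_phylo_distances(set(labels), labels, dm)
    assert mpd == 2.0 and mntd == 2.0


def test_mpd_single_taxon_undefined(balanced_tree):
    labels, dm = patristic_distances(balanced_tree)
    with pytest.raises(DegenerateInputError):
        mean_phylo_distances({"A"}, labels, dm)


# -- independent swap ------------------------------------------------------


def test_single_accepted_swap_flips_checkerboard():
    chain = SwapChain(np.array([[1, 0], [0, 1]], dtype=np.int8), np.random.default_rng(0))
    while chain.accepted == 0:
        chain.step(1)
    assert chain.accepted == 1
    assert chain.snapshot().tolist() == [[0, 1], [1, 0]]


def test_swap_conserves_margins_large():
    rng = np.random.default_rng(1)
    data = (rng.random((12, 20)) < 0.3).astype(np.int8)
    data[data.sum(axis=1) == 0, 0] = 1
    m = CommunityMatrix(
        [f"s{i}" for i in range(12)],
        [f"sp{j}" for j in range(20)],
        data[:, data.sum(axis=0) > 0],
    )
    out = independent_swap(m, 100_000, seed=2)
    assert (out.data.sum(axis=1) == m.data.sum(axis=1)).all()
    assert (out.data.sum(axis=0) == m.data.sum(axis=0)).all()
    assert not (out.data == m.data).all()  # it actually moved


def test_swap_no_checkerboard_returns_unchanged():
    m = CommunityMatrix(["s1", "s2"], ["a", "b"], np.array([[1, 1], [1, 1]]))
    out = independent_swap(m, 1000, seed=0)
    assert (out.data == m.data).all()


def _enumerate_component(start: np.ndarray):
    """All margin-preserving matrices reachable from ``start`` by swaps."""
    def neighbors(mat):
        n, m = mat.shape
        for r1, r2 in combinations(range(n), 2):
            for c1, c2 in combinations(range(m), 2):
                sub = mat[np.ix_((r1, r2), (c1, c2))]
                if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] \
                        and sub[0, 0] != sub[0, 1]:
                    nxt = mat.copy()
                    nxt[np.ix_((r1, r2), (c1, c2))] = sub[::-1]
                    yield nxt
    seen = {start.tobytes()}
    frontier = [start]
    while frontier:
        mat = frontier.pop()
        for nxt in neighbors(mat):
            key = nxt.tobytes()
            if key not in seen:
                seen.add(key)
                frontier.append(nxt)
    return seen


@pytest.mark.parametrize(
    "start",
    [
        np.eye(3, dtype=np.int8),
        np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=np.int8),
    ],
)
def test_swap_chain_uniform_over_enumerated_states(start):
    from scipy.stats import chisquare

    states = sorted(_enumerate_component(start))
    assert len(states) >= 2
    chain = SwapChain(start, np.random.default_rng(7))
    counts = dict.fromkeys(states, 0)
    chain.step(200)
    for _ in range(10_000):
        chain.step(20)
        counts[chain.snapshot().tobytes()] += 1
    stat, p = chisquare(list(counts.values()))
    assert min(counts.values()) > 0
    assert p > 0.001


# -- NRI/NTI ---------------------------------------------------------------


def test_nri_arithmetic_definition():
    null = np.array([2.5, 3.0, 3.5])  # mean 3.0, sample sd 0.5
    mean, sd, nri = _standardize(2.0, null, exhaustive=False)
    assert (mean, sd) == (3.0, 0.5)
    assert nri == pytest.approx(2.0)


def test_nri_antisymmetry_under_null_reflection():
    rng = np.random.default_rng(0)
    null = rng.normal(3.0, 0.7, size=200)
    obs = 2.2
    _, _, nri = _standardize(obs, null, exhaustive=False)
    _, _, nri_reflected = _standardize(obs, 2 * obs - null, exhaustive=False)
    assert nri_reflected == pytest.approx(-nri)


def test_pool_draw_exhaustive_exact_nri(balanced_tree):
    # community {A,B}: exhaustive null over 6 pairs has MPDs {2,2,4,4,4,4}
    m = CommunityMatrix(
        ["s1"], ["A", "B"], np.array([[1, 1]]), habitats=["serpentine"]
    )
    (res,) = comstruct(
        m, balanced_tree, NullModelSpec(model="pool_draw", exhaustive=True, seed=0)
    )
    assert res.mpd_obs == 2.0
    assert res.mpd_null_mean == pytest.approx(10 / 3)
    assert res.mpd_null_sd == pytest.approx(np.sqrt(8 / 9))
    assert res.nri == pytest.approx(np.sqrt(2), abs=1e-3)
    assert res.n_runs == 6


def test_full_pool_shuffle_degenerate_nri_zero(balanced_tree):
    m = CommunityMatrix(
        ["s1"], ["A", "B", "C", "D"], np.array([[1, 1, 1, 1]]), habitats=["h"]
    )
    (res,) = comstruct(
        m, balanced_tree, NullModelSpec(model="phylogeny_shuffle", n_runs=199, seed=0)
    )
    assert res.nri == 0.0
    assert res.nti == 0.0


def test_species_missing_from_tree_listed(balanced_tree):
    m = CommunityMatrix(["s1"], ["A", "Z"], np.array([[1, 1]]))
    with pytest.raises(ValidationError, match="Z"):
        comstruct(m, balanced_tree, NullModelSpec(model="pool_draw", n_runs=9))


def test_p_value_convention(balanced_tree):
    m = CommunityMatrix(
        ["s1"], ["A", "B"], np.array([[1, 1]]), habitats=["serpentine"]
    )
    (res,) = comstruct(
        m, balanced_tree, NullModelSpec(model="pool_draw", exhaustive=True, seed=0)
    )
    # null MPDs {2,2,4,4,4,4}; obs 2: k_low=2 -> p = (1+2)/(6+1)
    assert res.p_mpd_one_tailed == pytest.approx(3 / 7)
    assert 0 < res.p_mpd_two_tailed <= 1


def test_habitat_grouping_pools_samples(balanced_tree):
    m = CommunityMatrix(
        ["s1", "s2", "s3"],
        ["A", "B", "C"],
        np.array([[1, 1, 0], [0, 1, 1], [1, 1, 0]]),
        habitats=["serp", "serp", "non"],
    )
    results = comstruct(
        m, balanced_tree, NullModelSpec(model="pool_draw", n_runs=49, seed=0)
    )
    by = {r.community: r for r in results}
    assert by["serp"].n_taxa == 3  # union {A,B,C}
    assert by["non"].n_taxa == 2


def test_independent_swap_null_runs(balanced_tree):
    m = CommunityMatrix(
        ["s1", "s2", "s3", "s4"],
        ["A", "B", "C", "D"],
        np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]]),
        habitats=["x", "x", "y", "y"],
    )
    results = comstruct(
        m, balanced_tree, NullModelSpec(model="independent_swap", n_runs=99, seed=3)
    )
    assert {r.community for r in results} == {"x", "y"}
    for r in results:
        assert r.n_runs == 99
        assert 0 < r.p_mpd_one_tailed <= 1
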