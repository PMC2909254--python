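import json

import numpy as np
import pytest

from ecmcomm.config import SyntheticConfig
from ecmcomm.errors import ValidationError
from ecmcomm.simulate import (
    assemble_communities,
    default_soil_summaries,
    evolve_sequences,
    generate_soil_table,
    generate_study,
    genus_partition,
    simulate_yule_tree,
    write_study,
)
from ecmcomm.soils import GroupSummary, SoilSummary


# -- Yule trees ------------------------------------------------------------


def test_yule_cherry():
    t = simulate_yule_tree(2, 1.0, 0)
    assert t.n_tips == 2
    assert t.is_ultrametric(1e-9)


def test_yule_seed_reproducible():
    assert simulate_yule_tree(10, 1.0, 5).as_newick() == simulate_yule_tree(10, 1.0, 5).as_newick()


def test_yule_rejects_small():
    with pytest.raises(ValidationError):
        simulate_yule_tree(1, 1.0, 0)


def test_yule_mean_root_age_matches_analytic_sum():
    """Monte-Carlo mean root age vs the exponential-epoch expectation
    sum_{k=2}^{n} 1/(lambda k), for n = 4 and 64."""
    lam = 1.0
    for n in (4, 64):
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        ages = [simulate_yule_tree(n, lam, seed).root_age() for seed in range(200)]
        se = np.std(ages, ddof=1) / np.sqrt(len(ages))
        assert abs(np.mean(ages) - expected) < 4 * se + 0.02
    small = sum(1.0 / k for k in range(2, 5))
    big = sum(1.0 / k for k in range(2, 65))
    assert big > small  # deeper trees for larger n


# -- sequence evolution ----------------------------------------------------


def test_rate_zero_all_identical():
    t = simulate_yule_tree(6, 1.0, 1)
    cfg = SyntheticConfig(seed=0, lsu_rate=0.0)
    seqs = evolve_sequences(t, "LSU", cfg, 2)
    assert len({s.residues for s in seqs}) == 1


def test_zero_length_rejected():
    t = simulate_yule_tree(4, 1.0, 1)
    cfg = SyntheticConfig(seed=0)
    cfg.seq_len_its = 0
    with pytest.raises(ValidationError):
        evolve_sequences(t, "ITS", cfg, 0)


def _mean_p_distance(seqs):
    arrs = [np.frombuffer(s.residues.encode(), dtype="S1") for s in seqs]
    n = len(arrs)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            vals.append(float((arrs[i] != arrs[j]).mean()))
    return np.mean(vals), dict(
        ((seqs[i].id, seqs[j].id), float((arrs[i] != arrs[j]).mean()))
        for i in range(n) for j in range(i + 1, n)
    )


def test_equal_rate_ratio_gives_equal_divergence():
    cfg = SyntheticConfig(seed=0, its_rate_ratio=1.0, lsu_rate=0.15,
                          seq_len_its=1500, seq_len_lsu=1500)
    its_means, lsu_means = [], []
    for seed in range(20):
        t = simulate_yule_tree(6, 1.0, seed)
        its, _ = _mean_p_distance(evolve_sequences(t, "ITS", cfg, 100 + seed))
        lsu, _ = _mean_p_distance(evolve_sequences(t, "LSU", cfg, 200 + seed))
        its_means.append(its)
        lsu_means.append(lsu)
    assert np.mean(its_means) == pytest.approx(np.mean(lsu_means), rel=0.10)


def test_fast_marker_exceeds_slow_marker_on_every_pair():
    cfg = SyntheticConfig(seed=0, its_rate_ratio=3.0, lsu_rate=0.1,
                          seq_len_its=1500, seq_len_lsu=1500)
    t = simulate_yule_tree(6, 1.0, 3)
    _, its_pairs = _mean_p_distance(evolve_sequences(t, "ITS", cfg, 11))
    _, lsu_pairs = _mean_p_distance(evolve_sequences(t, "LSU", cfg, 12))
    assert all(its_pairs[k] > lsu_pairs[k] for k in its_pairs)


def test_hky_base_composition_follows_freqs():
    cfg = SyntheticConfig(seed=0, base_freqs=(0.4, 0.1, 0.1, 0.4),
                          lsu_rate=0.5, seq_len_lsu=5000)
    t = simulate_yule_tree(4, 1.0, 2)
    seqs = evolve_sequences(t, "LSU", cfg, 3)
    pooled = "".join(s.residues for s in seqs)
    freq_a = pooled.count("A") / len(pooled)
    assert freq_a == pytest.approx(0.4, abs=0.03)


# -- community assembly ----------------------------------------------------


def _pool(seed=7, n=32):
    t = simulate_yule_tree(n, 1.0, seed)
    t.scale_branch_lengths(1.0 / t.root_age())
    return t


def test_filter_strength_zero_equals_random():
    pool = _pool()
    base = dict(seed=5, n_species_pool=32, n_samples_per_forest=6)
    m1, _ = assemble_communities(
        pool, SyntheticConfig(assembly_model="filtered", filter_strength=0.0, **base),
        "serpentine", 9,
    )
    m2, _ = assemble_communities(
        pool, SyntheticConfig(assembly_model="random", **base), "serpentine", 9
    )
    assert m1.species_ids == m2.species_ids
    assert (m1.data == m2.data).all()


def test_infinite_filter_confines_samples_to_clade():
    pool = _pool()
    cfg = SyntheticConfig(
        seed=5, n_species_pool=32, assembly_model="filtered",
        filter_strength=200.0, n_samples_per_forest=10,
    )
    m, truth = assemble_communities(pool, cfg, "serpentine", 4)
    clade = set(truth["filter_clade"])
    for sid in m.sample_ids:
        assert set(m.sample_species(sid)) <= clade


def test_filter_clade_too_small_errors():
    pool = _pool(n=8)
    cfg = SyntheticConfig(
        seed=0, n_species_pool=8, assembly_model="filtered", filter_strength=2.0,
        tips_per_sample_min=6, tips_per_sample_max=6, tips_per_sample_probs=(1.0,),
    )
    with pytest.raises(ValidationError, match="richness"):
        assemble_communities(pool, cfg, "serpentine", 0)


def test_random_inclusion_uniform_chi_square():
    """Under the random model each species' inclusion count is uniform."""
    from scipy.stats import chisquare

    pool = _pool(n=16)
    cfg = SyntheticConfig(seed=0, n_species_pool=16, n_forests_per_habitat=1,
                          n_samples_per_forest=50)
    counts = np.zeros(16)
    species = sorted(pool.tip_labels())
    idx = {sp: i for i, sp in enumerate(species)}
    for seed in range(50):  # 2500 samples, ~10^4 inclusion draws
        m, _ = assemble_communities(pool, cfg, "serpentine", seed)
        for j, sp in enumerate(m.species_ids):
            counts[idx[sp]] += m.data[:, j].sum()
    _, p = chisquare(counts)
    assert p > 0.001


def test_overdispersed_model_runs_and_differs():
    pool = _pool(n=16)
    base = dict(seed=2, n_species_pool=16, n_samples_per_forest=6)
    mo, truth = assemble_communities(
        pool, SyntheticConfig(assembly_model="overdispersed", filter_strength=3.0, **base),
        "serpentine", 3,
    )
    assert truth["model"] == "overdispersed"
    assert mo.data.sum(axis=1).min() >= 3


# -- soil table ------------------------------------------------------------


def test_soil_sd_zero_replicates_equal_mean():
    s = SoilSummary("x", GroupSummary(5.0, 0.0, 4), GroupSummary(2.0, 0.0, 4))
    rows = generate_soil_table([s], n_reps=3, seed=0)
    assert all(v in (5.0, 2.0) for _, _, v in rows)


def test_soil_seeded_reproducible():
    summaries = default_soil_summaries()[:3]
    assert generate_soil_table(summaries, seed=4) == generate_soil_table(summaries, seed=4)


def test_soil_negative_draws_clipped():
    s = SoilSummary("trace", GroupSummary(0.01, 5.0, 4), GroupSummary(0.01, 5.0, 4))
    rows = generate_soil_table([s], n_reps=50, seed=1)
    assert min(v for _, _, v in rows) >= 0.0


# -- genus partition -------------------------------------------------------


def test_genus_partition_covers_all_species():
    pool = _pool()
    gm = genus_partition(pool, 0.45)
    assert set(gm) == set(pool.tip_labels())
    # genera are clades: each genus's tips are monophyletic
    labels, dm = pool.patristic_matrix()
    for genus in set(gm.values()):
        members = [sp for sp, g in gm.items() if g == genus]
        others = [sp for sp in labels if sp not in members]
        if len(members) > 1 and others:
            within = max(
                dm[labels.index(a), labels.index(b)]
                for a in members for b in members if a != b
            )
            out = min(
                dm[labels.index(a), labels.index(o)] for a in members for o in others
            )
            assert within < out + 1e-9


# -- full study ------------------------------------------------------------


def test_study_design_counts():
    cfg = SyntheticConfig(seed=1, n_species_pool=32, seq_len_its=120, seq_len_lsu=120)
    study = generate_study(cfg)
    total = sum(m.shape[0] for m in study.matrices.values())
    assert total == 80  # 2 habitats x 2 forests x 20 soil cubes
    for m in study.matrices.values():
        assert set(m.species_ids) <= set(study.pool_tree.tip_labels())
        assert m.data.sum(axis=1).min() >= 3
        assert m.data.sum(axis=1).max() <= 6


def test_study_bit_identical_regeneration(tmp_path):
    cfg = SyntheticConfig(seed=9, n_species_pool=24, n_samples_per_forest=4,
                          seq_len_its=100, seq_len_lsu=100)
    p1 = write_study(generate_study(cfg), tmp_path / "a")
    p2 = write_study(generate_study(cfg), tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_study_truth_record(tmp_path):
    cfg = SyntheticConfig(
        seed=3, n_species_pool=32, n_samples_per_forest=4,
        seq_len_its=100, seq_len_lsu=100,
        assembly_model_by_habitat={"serpentine": "filtered"}, filter_strength=4.0,
    )
    study = generate_study(cfg)
    assert study.truth["habitats"]["serpentine"]["model"] == "filtered"
    assert study.truth["habitats"]["non_serpentine"]["model"] == "random"
    paths = write_study(study, tmp_path)
    truth = json.loads(paths["truth"].read_text())
    assert truth["habitats"]["serpentine"]["filter_clade"]
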