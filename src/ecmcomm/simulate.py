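"""Synthetic two-habitat study generator.

Produces everything the analysis consumes: an ultrametric species-pool tree
(Yule), ITS and LSU sequences evolved under HKY85 at different rates on a
shared tree (with an external outgroup lineage), per-habitat community
matrices assembled under habitat filtering / random draws / overdispersion,
taxonomy hit tables, and raw soil chemistry replicates for two groups.
All randomness flows from the single configuration seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import expm

from ecmcomm.config import HABITATS, SyntheticConfig
from ecmcomm.errors import ValidationError
from ecmcomm.matrix import CommunityMatrix, write_matrix
from ecmcomm.seqio import (
    SequenceRecord,
    TaxonomyHits,
    write_fasta,
    write_taxonomy_hits,
)
from ecmcomm.soils import SoilSummary, read_soil_summaries
from ecmcomm.tree import PhyloTree

log = logging.getLogger(__name__)

OUTGROUP_LABEL = "OUT"

_BASES = "ACGT"


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# -- tree simulation -------------------------------------------------------


def simulate_yule_tree(
    n_tips: int, birth_rate: float, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Pure-birth tree with ``n_tips`` extant tips.

    Epoch durations with k lineages are Exponential(birth_rate * k) for
    k = 2..n_tips, so the expected root age is sum_{k=2}^{n} 1/(birth_rate*k).
    """
    if n_tips < 2:
        raise ValidationError("simulate_yule_tree requires n_tips >= 2")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be > 0")
    rng = _as_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    lineages: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        lineages.append((child, 0.0))
    t = 0.0
    k = 2
    while True:
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_tips:
            break
        i = int(rng.integers(k))
        node, born = lineages.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            lineages.append((child, t))
        k += 1
    for node, born in lineages:
        node.edge.length = t - born
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"sp{i + 1:0{width}d}")
    out = PhyloTree(tree=tree, scale="relative_time")
    assert out.is_ultrametric(tol=1e-9 * max(t, 1.0))
    return out


# -- sequence evolution ----------------------------------------------------


def hky_rate_matrix(kappa: float, base_freqs: tuple[float, ...]) -> np.ndarray:
    """HKY85 instantaneous rate matrix normalized to one expected
    substitution per site per unit branch length."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float((pi * np.diag(q)).sum())
    return q / mu


def evolve_sequences(
    tree: PhyloTree,
    marker: str,
    config: SyntheticConfig,
    seed: int | np.random.Generator = 0,
) -> list[SequenceRecord]:
    """Site-independent HKY85 evolution along an ultrametric tree.

    Branch substitution lengths are branch time x marker rate; transition
    probabilities use the matrix exponential of the normalized rate matrix
    (not Gillespie), sampled per site.  ITS runs ``its_rate_ratio`` times
    faster than LSU.
    """
    if marker not in ("ITS", "LSU"):
        raise ValidationError(f"marker must be ITS or LSU, got {marker!r}")
    length = config.seq_len_its if marker == "ITS" else config.seq_len_lsu
    if length <= 0:
        raise ValidationError("sequence length must be positive")
    rate = config.lsu_rate * (config.its_rate_ratio if marker == "ITS" else 1.0)
    rng = _as_rng(seed)
    q = hky_rate_matrix(config.kappa, config.base_freqs)
    pi = np.asarray(config.base_freqs)

    states: dict[dendropy.Node, np.ndarray] = {}
    root = tree.tree.seed_node
    states[root] = rng.choice(4, size=length, p=pi)
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        t_sub = rate * (node.edge.length or 0.0)
        if t_sub == 0.0:
            states[node] = states[node.parent_node].copy()
            continue
        p = expm(q * t_sub)
        cum = p.cumsum(axis=1)
        cum[:, -1] = 1.0
        u = rng.random(length)
        parent = states[node.parent_node]
        states[node] = (u[:, None] > cum[parent]).sum(axis=1).astype(np.int64)
    records = []
    for leaf in tree.tree.leaf_node_iter():
        seq = "".join(_BASES[s] for s in states[leaf])
        records.append(SequenceRecord(id=leaf.taxon.label, marker=marker, residues=seq))
    records.sort(key=lambda r: r.id)
    return records


# -- community assembly ----------------------------------------------------


def _pick_filter_clade(
    pool_tree: PhyloTree, min_size: int, rng: np.random.Generator
) -> list[str]:
    """Smallest clade with at least ``min_size`` tips (seeded tie-break)."""
    candidates: list[list[str]] = []
    for node in pool_tree.tree.preorder_node_iter():
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        if len(tips) >= min_size:
            candidates.append(sorted(tips))
    if not candidates:
        raise ValidationError(
            f"no clade with >= {min_size} tips; lower the per-sample richness"
        )
    smallest = min(len(c) for c in candidates)
    finalists = sorted(c for c in candidates if len(c) == smallest)
    return finalists[int(rng.integers(len(finalists)))]


def assemble_communities(
    pool_tree: PhyloTree,
    config: SyntheticConfig,
    habitat_label: str,
    seed: int | np.random.Generator = 0,
) -> tuple[CommunityMatrix, dict]:
    """Sample per-cube species sets from the pool under an assembly model.

    Returns the matrix and a truth record (model, focal clade if any).
    ``filtered`` weights species by exp(filter_strength) inside a focal
    clade; ``random`` is the same draw with uniform weights; ``overdispersed``
    sequentially penalizes candidates close to already-chosen species.
    """
    model = config.model_for(habitat_label)
    rng_clade, rng_draw = _as_rng(seed).spawn(2)
    species = sorted(pool_tree.tip_labels())
    n_pool = len(species)
    sp_index = {sp: i for i, sp in enumerate(species)}

    richness_values = np.arange(
        config.tips_per_sample_min, config.tips_per_sample_max + 1
    )
    n_samples = config.n_forests_per_habitat * config.n_samples_per_forest
    richness = rng_draw.choice(
        richness_values, size=n_samples, p=np.asarray(config.tips_per_sample_probs)
    )

    focal: list[str] | None = None
    weights = np.ones(n_pool) / n_pool
    if model == "filtered":
        focal = _pick_filter_clade(
            pool_tree, 2 * config.tips_per_sample_max, rng_clade
        )
        ind = np.zeros(n_pool)
        ind[[sp_index[sp] for sp in focal]] = 1.0
        w = np.exp(config.filter_strength * (ind - 1.0))  # in-clade weight 1
        weights = w / w.sum()
    dm = None
    if model == "overdispersed":
        labels, dmat = pool_tree.patristic_matrix()
        reorder = [labels.index(sp) for sp in species]
        dm = dmat[np.ix_(reorder, reorder)]

    sample_ids: list[str] = []
    forests: list[str] = []
    rows = np.zeros((n_samples, n_pool), dtype=np.int8)
    s = 0
    for f in range(config.n_forests_per_habitat):
        forest = f"{habitat_label}-F{f + 1}"
        for c in range(config.n_samples_per_forest):
            sample_ids.append(f"{forest}-C{c + 1:02d}")
            forests.append(forest)
            rich = int(richness[s])
            if model in ("filtered", "random"):
                chosen = rng_draw.choice(n_pool, size=rich, replace=False, p=weights)
            else:
                chosen_list: list[int] = [int(rng_draw.integers(n_pool))]
                while len(chosen_list) < rich:
                    cand = np.array(
                        [i for i in range(n_pool) if i not in chosen_list]
                    )
                    d_nt = dm[np.ix_(cand, np.array(chosen_list))].min(axis=1)
                    if config.filter_strength > 0 and d_nt.max() > 0:
                        w = (d_nt / d_nt.max()) ** config.filter_strength
                        if w.sum() == 0:
                            w = np.ones(len(cand))
                    else:
                        w = np.ones(len(cand))
                    w = w / w.sum()
                    chosen_list.append(int(rng_draw.choice(cand, p=w)))
                chosen = np.array(chosen_list)
            rows[s, chosen] = 1
            s += 1

    present = rows.sum(axis=0) > 0
    matrix = CommunityMatrix(
        sample_ids=sample_ids,
        species_ids=[sp for sp, p in zip(species, present) if p],
        data=rows[:, present],
        forests=forests,
        habitats=[habitat_label] * n_samples,
    )
    truth = {"model": model, "filter_clade": focal, "habitat": habitat_label}
    return matrix, truth


# -- soil table ------------------------------------------------------------


def generate_soil_table(
    summaries: list[SoilSummary],
    n_reps: int = 4,
    seed: int | np.random.Generator = 0,
    groups: tuple[str, str] = ("serpentine", "non_serpentine"),
) -> list[tuple[str, str, float]]:
    """Normal replicate draws per parameter per group, clipped at zero.

    pH is exempt from clipping (it is not a concentration); clip counts are
    logged.
    """
    rng = _as_rng(seed)
    rows: list[tuple[str, str, float]] = []
    n_clipped = 0
    for summary in summaries:
        for group, gs in ((groups[0], summary.group_a), (groups[1], summary.group_b)):
            draws = rng.normal(gs.mean, gs.sd, size=n_reps)
            if summary.parameter.lower() != "ph":
                clipped = np.clip(draws, 0.0, None)
                n_clipped += int((draws < 0).sum())
                draws = clipped
            rows.extend((summary.parameter, group, float(v)) for v in draws)
    if n_clipped:
        log.warning("generate_soil_table: clipped %d negative draws to 0", n_clipped)
    return rows


def default_soil_summaries() -> list[SoilSummary]:
    """Built-in two-habitat soil chemistry summary table."""
    path = Path(__file__).parent / "data" / "soil_summary.tsv"
    return read_soil_summaries(path)


# -- genus partition -------------------------------------------------------


def genus_partition(pool_tree: PhyloTree, cut_age: float) -> dict[str, str]:
    """Assign species to genera by cutting the ultrametric tree at an age.

    Every lineage crossing ``cut_age`` founds one genus containing the tips
    below it; singleton genera arise from tip branches crossing the cut.
    """
    ages = pool_tree.node_ages()
    clades: list[list[str]] = []
    for node in pool_tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if ages[node] <= cut_age < ages[parent]:
            clades.append(sorted(lf.taxon.label for lf in node.leaf_iter()))
    clades.sort(key=lambda c: c[0])
    width = max(2, len(str(len(clades))))
    genus_map: dict[str, str] = {}
    for i, clade in enumerate(clades):
        for sp in clade:
            genus_map[sp] = f"G{i + 1:0{width}d}"
    return genus_map


# -- full study ------------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    pool_tree: PhyloTree                       # relative time, root age 1
    genus_map: dict[str, str]                  # species -> genus
    its_species_seqs: list[SequenceRecord]     # one ITS per pool species (+OUT)
    lsu_genus_seqs: list[SequenceRecord]       # one LSU per genus (+OUT)
    matrices: dict[str, CommunityMatrix]
    soil_rows: list[tuple[str, str, float]]
    truth: dict = field(default_factory=dict)

    def root_tip_records(self) -> list[SequenceRecord]:
        """Per-root-tip ITS records derived from the community matrices."""
        by_species = {r.id: r.residues for r in self.its_species_seqs}
        records: list[SequenceRecord] = []
        for habitat in HABITATS:
            matrix = self.matrices[habitat]
            for i, sample in enumerate(matrix.sample_ids):
                forest = matrix.forests[i] if matrix.forests else None
                present = [
                    sp for sp, v in zip(matrix.species_ids, matrix.data[i]) if v
                ]
                for j, sp in enumerate(sorted(present)):
                    records.append(
                        SequenceRecord(
                            id=f"{sample}.t{j + 1}",
                            marker="ITS",
                            residues=by_species[sp],
                            sample_id=sample,
                            forest_id=forest,
                            habitat=habitat,
                        )
                    )
        return records

    def taxonomy_hits(self, n_hits: int = 20) -> list[TaxonomyHits]:
        by_species = {r.id: r.residues for r in self.its_species_seqs}
        seq_to_species = {v: k for k, v in by_species.items()}
        hits: list[TaxonomyHits] = []
        for rec in self.root_tip_records():
            genus = self.genus_map[seq_to_species[rec.residues]]
            hits.append(TaxonomyHits(query_id=rec.id, hits=[genus] * n_hits))
        return hits


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full paired-habitat study from one seed."""
    master = np.random.default_rng(config.seed)
    (rng_tree, rng_its, rng_lsu, rng_hab_a, rng_hab_b, rng_soil) = master.spawn(6)

    pool = simulate_yule_tree(config.n_species_pool, config.birth_rate, rng_tree)
    root_age = pool.root_age()
    pool.scale_branch_lengths(1.0 / root_age)  # normalize root age to 1

    genus_map = genus_partition(pool, config.genus_cut_age)

    # extended tree with an external outgroup lineage for both markers
    ext_tree = pool.clone().tree
    new_root = dendropy.Node()
    old_root = ext_tree.seed_node
    out_node = dendropy.Node()
    out_node.taxon = ext_tree.taxon_namespace.new_taxon(label=OUTGROUP_LABEL)
    out_node.edge.length = config.outgroup_depth_factor
    new_root.add_child(out_node)
    new_root.add_child(old_root)
    old_root.edge.length = config.outgroup_depth_factor - 1.0
    ext_tree.seed_node = new_root
    extended = PhyloTree(tree=ext_tree, scale="relative_time")

    its_seqs = evolve_sequences(extended, "ITS", config, rng_its)
    lsu_all = evolve_sequences(extended, "LSU", config, rng_lsu)
    lsu_by_species = {r.id: r for r in lsu_all}

    genera = sorted(set(genus_map.values()))
    lsu_genus_seqs: list[SequenceRecord] = []
    genus_reps: dict[str, str] = {}
    for genus in genera:
        rep = min(sp for sp, g in genus_map.items() if g == genus)
        genus_reps[genus] = rep
        lsu_genus_seqs.append(
            SequenceRecord(
                id=genus, marker="LSU", residues=lsu_by_species[rep].residues
            )
        )
    lsu_genus_seqs.append(
        SequenceRecord(
            id=OUTGROUP_LABEL, marker="LSU",
            residues=lsu_by_species[OUTGROUP_LABEL].residues,
        )
    )

    matrices: dict[str, CommunityMatrix] = {}
    truth: dict = {
        "seed": config.seed,
        "genus_map": genus_map,
        "genus_representatives": genus_reps,
        "habitats": {},
    }
    for habitat, rng_hab in zip(HABITATS, (rng_hab_a, rng_hab_b)):
        matrices[habitat], hab_truth = assemble_communities(
            pool, config, habitat, rng_hab
        )
        truth["habitats"][habitat] = hab_truth

    soil_rows = generate_soil_table(
        default_soil_summaries(), n_reps=config.soil_n_reps, seed=rng_soil
    )

    return SyntheticStudy(
        config=config,
        pool_tree=pool,
        genus_map=genus_map,
        its_species_seqs=its_seqs,
        lsu_genus_seqs=lsu_genus_seqs,
        matrices=matrices,
        soil_rows=soil_rows,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study inputs as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "its_fasta": outdir / "its.fasta",
        "lsu_fasta": outdir / "lsu.fasta",
        "hits": outdir / "hits.tsv",
        "tree": outdir / "true_tree.nwk",
        "soil_raw": outdir / "soil_raw.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(study.root_tip_records(), paths["its_fasta"])
    write_fasta(study.lsu_genus_seqs, paths["lsu_fasta"])
    write_taxonomy_hits(study.taxonomy_hits(), paths["hits"])
    study.pool_tree.write(paths["tree"])
    with paths["soil_raw"].open("w") as fh:
        fh.write("parameter\tgroup\tvalue\n")
        for param, group, value in study.soil_rows:
            fh.write(f"{param}\t{group}\t{value!r}\n")
    for habitat, matrix in study.matrices.items():
        p = outdir / f"matrix_{habitat}.tsv"
        paths[f"matrix_{habitat}"] = p
        write_matrix(matrix, p)
    paths["truth"].write_text(json.dumps(study.truth, indent=1, sort_keys=True) + "\n")
    return paths
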