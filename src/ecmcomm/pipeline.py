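"""End-to-end pipeline: inputs -> OTUs -> supertree -> community structure,
diversity/ordination and soil ANOVA, with a plain-text + JSON run log.

The input bundle is a directory holding ``its.fasta`` (root-tip sequences),
``lsu.fasta`` (one LSU per genus plus the outgroup ``OUT``), ``hits.tsv``
(taxonomy hit table) and ``soil_raw.tsv``.  With ``synthetic_config`` the
bundle is generated first and then analyzed by the identical code path.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from ecmcomm.chronogram import nprs_smooth
from ecmcomm.comstruct import NullModelSpec, comstruct
from ecmcomm.config import RunConfig, SyntheticConfig
from ecmcomm.diversity import (
    accumulation_curve,
    bray_curtis,
    connectivity_filter,
    nmds,
    overlap,
    rank_frequency,
)
from ecmcomm.errors import ValidationError
from ecmcomm.graft import (
    GraftPlan,
    estimate_scale_factor,
    graft,
    plan_graft,
)
from ecmcomm.matrix import CommunityMatrix, write_matrix
from ecmcomm.njtree import estimate_substitution_tree
from ecmcomm.otu import OTU, assign_genus, cluster_otus
from ecmcomm.seqio import read_fasta, read_taxonomy_hits, write_fasta, SequenceRecord
from ecmcomm.simulate import OUTGROUP_LABEL, generate_study, write_study
from ecmcomm.soils import compare_soils, read_soil_raw, write_anova_results
from ecmcomm.tree import PhyloTree

log = logging.getLogger(__name__)

INPUT_FILES = ("its.fasta", "lsu.fasta", "hits.tsv", "soil_raw.tsv")


def _check_inputs(input_dir: Path) -> None:
    missing = [name for name in INPUT_FILES if not (input_dir / name).exists()]
    if missing:
        raise ValidationError(
            f"missing pipeline inputs in {input_dir}: {missing}; "
            "provide them or run with synthetic generation"
        )


def build_matrix_from_otus(
    otus: list[OTU], records: list[SequenceRecord]
) -> CommunityMatrix:
    """Incidence matrix of retained OTUs across all samples with metadata."""
    meta: dict[str, tuple[str | None, str | None]] = {}
    for rec in records:
        if rec.sample_id is not None:
            meta[rec.sample_id] = (rec.forest_id, rec.habitat)
    samples = sorted(meta)
    otus = [o for o in otus if o.samples]
    data = np.zeros((len(samples), len(otus)), dtype=np.int8)
    for j, otu in enumerate(otus):
        for sid in otu.samples:
            data[samples.index(sid), j] = 1
    keep_rows = data.sum(axis=1) > 0
    if not keep_rows.all():
        log.warning("dropping %d samples with no retained OTUs", int((~keep_rows).sum()))
    samples = [s for s, k in zip(samples, keep_rows) if k]
    return CommunityMatrix(
        sample_ids=samples,
        species_ids=[o.otu_id for o in otus],
        data=data[keep_rows],
        forests=[meta[s][0] or "" for s in samples],
        habitats=[meta[s][1] or "" for s in samples],
    )


def build_supertree(
    otus: list[OTU],
    lsu_records: list[SequenceRecord],
    config: RunConfig,
) -> tuple[PhyloTree, dict]:
    """Estimate the genus backbone and species trees, scale, smooth, graft.

    Returns the ultrametric supertree whose tips are OTU ids, plus a report
    of per-genus scale factors and crown fractions.
    """
    by_genus: dict[str, list[OTU]] = {}
    for otu in otus:
        if otu.genus is not None:
            by_genus.setdefault(otu.genus, []).append(otu)
    genera = sorted(by_genus)
    if len(genera) < 3:
        raise ValidationError(
            f"need >= 3 detected genera to build a backbone, got {len(genera)}"
        )
    lsu_by_id = {r.id: r for r in lsu_records}
    missing = [g for g in genera if g not in lsu_by_id]
    if missing:
        raise ValidationError(f"no LSU sequence for detected genera: {missing}")
    if OUTGROUP_LABEL not in lsu_by_id:
        raise ValidationError(f"LSU file lacks the outgroup record {OUTGROUP_LABEL!r}")

    bb_ids = genera + [OUTGROUP_LABEL]
    backbone_sub = estimate_substitution_tree(
        bb_ids, [lsu_by_id[g].residues for g in bb_ids], outgroup_label=OUTGROUP_LABEL
    )
    backbone_ing_sub = backbone_sub.prune_tips([OUTGROUP_LABEL])
    smoothing = nprs_smooth(backbone_ing_sub, seed=config.seed)
    backbone_time = smoothing.tree

    # sister genus = nearest backbone neighbor (deterministic tie-break)
    labels, dm = backbone_ing_sub.patristic_matrix()
    sisters: dict[str, str] = {}
    for genus in genera:
        i = labels.index(genus)
        order = sorted(
            (float(dm[i, j]), labels[j]) for j in range(len(labels)) if j != i
        )
        sisters[genus] = order[0][1]

    species_time_trees: dict[str, PhyloTree] = {}
    plans: dict[str, GraftPlan] = {}
    single_species: dict[str, str] = {}
    report: dict = {"genera": {}, "backbone_smoothing_W": smoothing.objective}
    for genus in genera:
        members = sorted(by_genus[genus], key=lambda o: o.otu_id)
        if len(members) == 1:
            single_species[genus] = members[0].otu_id
            report["genera"][genus] = {"n_species": 1}
            continue
        sister = sisters[genus]
        out_otu = min(by_genus[sister], key=lambda o: o.otu_id)
        ids = [o.otu_id for o in members] + [out_otu.otu_id]
        seqs = [o.consensus for o in members] + [out_otu.consensus]
        its_sub = estimate_substitution_tree(ids, seqs, outgroup_label=out_otu.otu_id)
        scale = estimate_scale_factor(
            its_sub, backbone_ing_sub, genus, sister, [out_otu.otu_id]
        )
        pruned = its_sub.prune_tips([out_otu.otu_id])
        plan = plan_graft(
            genus, scale, pruned, backbone_ing_sub, backbone_time,
            crown_cap_beta=config.crown_cap_beta,
        )
        plans[genus] = plan
        species_time_trees[genus] = nprs_smooth(pruned, seed=config.seed).tree
        report["genera"][genus] = {
            "n_species": len(members),
            "sister": sister,
            "scale_factor": scale.s_g,
            "crown_fraction": plan.crown_fraction,
            "attachment_age": plan.attachment_age,
            "capped": plan.capped,
        }
    supertree = graft(backbone_time, species_time_trees, plans, single_species)
    report["backbone_time"] = backbone_time
    report["genus_of_otu"] = {
        otu.otu_id: genus for genus, members in by_genus.items() for otu in members
    }
    return supertree, report


def _write_comstruct(results, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(
            "community\tn_taxa\tMPD_obs\tMNTD_obs\tMPD_null_mean\tMPD_null_sd\t"
            "MNTD_null_mean\tMNTD_null_sd\tNRI\tNTI\tp_MPD_one\tp_MPD_two\t"
            "p_MNTD_one\tp_MNTD_two\tn_runs\tmodel\n"
        )
        for r in results:
            fh.write(
                f"{r.community}\t{r.n_taxa}\t{r.mpd_obs!r}\t{r.mntd_obs!r}\t"
                f"{r.mpd_null_mean!r}\t{r.mpd_null_sd!r}\t{r.mntd_null_mean!r}\t"
                f"{r.mntd_null_sd!r}\t{r.nri!r}\t{r.nti!r}\t"
                f"{r.p_mpd_one_tailed!r}\t{r.p_mpd_two_tailed!r}\t"
                f"{r.p_mntd_one_tailed!r}\t{r.p_mntd_two_tailed!r}\t"
                f"{r.n_runs}\t{r.model}\n"
            )


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    input_dir: str | Path | None = None,
    synthetic_config: SyntheticConfig | None = None,
) -> dict[str, Path]:
    """Run every stage and write the result bundle; returns the path map."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if synthetic_config is not None:
        input_dir = outdir / "inputs"
        study = generate_study(synthetic_config)
        write_study(study, input_dir)
    elif input_dir is None:
        raise ValidationError("either an input directory or synthetic generation is required")
    input_dir = Path(input_dir)
    _check_inputs(input_dir)

    its_records = read_fasta(input_dir / "its.fasta")
    lsu_records = read_fasta(input_dir / "lsu.fasta")
    hits = {h.query_id: h for h in read_taxonomy_hits(input_dir / "hits.tsv")}

    # 1. OTU delimitation and genus assignment
    otus = cluster_otus(its_records, threshold=config.similarity_threshold)
    n_rejected = 0
    for otu in otus:
        member_hits = hits.get(otu.member_ids[0])
        if member_hits is None:
            n_rejected += 1
            continue
        assignment = assign_genus(member_hits, min_hits=config.min_hits)
        if assignment.assigned:
            otu.genus = assignment.genus
        else:
            n_rejected += 1
    retained = [o for o in otus if o.genus is not None]
    if not retained:
        raise ValidationError("no OTU passed the genus-confidence rule")

    paths: dict[str, Path] = {}
    paths["otu_table"] = outdir / "otu_table.tsv"
    with paths["otu_table"].open("w") as fh:
        fh.write("otu_id\tgenus\tn_members\tn_samples\tmember_ids\n")
        for otu in otus:
            fh.write(
                f"{otu.otu_id}\t{otu.genus or 'unassigned'}\t{len(otu.member_ids)}\t"
                f"{len(otu.samples)}\t{','.join(otu.member_ids)}\n"
            )
    paths["consensus_fasta"] = outdir / "otu_consensus.fasta"
    write_fasta(
        [SequenceRecord(id=o.otu_id, marker="ITS", residues=o.consensus) for o in otus],
        paths["consensus_fasta"],
    )

    # 2. community matrix from OTU incidence
    matrix = build_matrix_from_otus(retained, its_records)
    paths["matrix"] = outdir / "community_matrix.tsv"
    write_matrix(matrix, paths["matrix"])

    # 3. supertree
    supertree, tree_report = build_supertree(retained, lsu_records, config)
    paths["supertree"] = outdir / "supertree.nwk"
    supertree.write(paths["supertree"])

    # 4. community phylogenetic structure
    spec = NullModelSpec(
        model=config.null_model, n_runs=config.n_null_runs, seed=config.seed
    )
    results = comstruct(matrix, supertree, spec)
    paths["comstruct"] = outdir / "comstruct.tsv"
    _write_comstruct(results, paths["comstruct"])

    # 5. diversity and ordination
    habitats = sorted(set(matrix.habitats or []))
    hab_matrices = {
        hab: matrix.subset_samples(
            [s for s, h in zip(matrix.sample_ids, matrix.habitats) if h == hab]
        )
        for hab in habitats
    }
    paths["rank_frequency"] = outdir / "rank_frequency.tsv"
    with paths["rank_frequency"].open("w") as fh:
        fh.write("habitat\trank\tspecies\tfrequency\tsingleton_fraction\n")
        for hab in habitats:
            rf = rank_frequency(hab_matrices[hab])
            for rank, (sp, freq) in enumerate(zip(rf.species_ids, rf.frequencies), 1):
                fh.write(f"{hab}\t{rank}\t{sp}\t{freq}\t{rf.singleton_fraction!r}\n")
    paths["accumulation"] = outdir / "accumulation.tsv"
    with paths["accumulation"].open("w") as fh:
        fh.write("habitat\tdepth\tmean_richness\tlower95\tupper95\n")
        for hab in habitats:
            curve = accumulation_curve(hab_matrices[hab], seed=config.seed)
            for k, m, lo, hi in zip(
                curve.depths, curve.mean_richness, curve.lower95, curve.upper95
            ):
                fh.write(f"{hab}\t{k}\t{m!r}\t{lo!r}\t{hi!r}\n")
    paths["overlap"] = outdir / "overlap.json"
    if len(habitats) == 2:
        ov = overlap(hab_matrices[habitats[0]], hab_matrices[habitats[1]])
        paths["overlap"].write_text(json.dumps(asdict(ov), sort_keys=True) + "\n")
    else:
        paths["overlap"].write_text(json.dumps(None) + "\n")

    dissim = bray_curtis(matrix)
    kept_idx, n_discarded = connectivity_filter(dissim)
    kept_ids = [matrix.sample_ids[i] for i in kept_idx]
    ordination = nmds(
        dissim[np.ix_(kept_idx, kept_idx)],
        sample_ids=kept_ids,
        k=config.ordination_k,
        seed=config.seed,
        n_discarded=n_discarded,
    )
    paths["ordination"] = outdir / "ordination.tsv"
    with paths["ordination"].open("w") as fh:
        axes = "\t".join(f"axis{d + 1}" for d in range(config.ordination_k))
        fh.write(f"sample\thabitat\t{axes}\n")
        hab_of = dict(zip(matrix.sample_ids, matrix.habitats or []))
        for sid, row in zip(ordination.sample_ids, ordination.coordinates):
            coords = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{sid}\t{hab_of.get(sid, '')}\t{coords}\n")

    # 6. soil chemistry ANOVA
    soil = read_soil_raw(input_dir / "soil_raw.tsv")
    anova = compare_soils(soil)
    paths["soil_anova"] = outdir / "soil_anova.tsv"
    write_anova_results(anova, paths["soil_anova"])

    summary = {
        "config": config.to_dict(),
        "synthetic": synthetic_config.to_dict() if synthetic_config else None,
        "n_sequences": len(its_records),
        "n_otus": len(otus),
        "n_otus_retained": len(retained),
        "n_otus_rejected": n_rejected,
        "n_samples": len(matrix.sample_ids),
        "supertree_n_tips": supertree.n_tips,
        "tree_report": {
            k: v for k, v in tree_report.items() if k != "backbone_time"
        },
        "ordination_stress_pct": ordination.stress_pct,
        "ordination_n_discarded": ordination.n_discarded,
        "comstruct": {
            r.community: {"NRI": r.nri, "NTI": r.nti, "p_MPD": r.p_mpd_one_tailed,
                          "p_MNTD": r.p_mntd_one_tailed}
            for r in results
        },
    }
    paths["log"] = outdir / "run_log.json"
    paths["log"].write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return paths
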