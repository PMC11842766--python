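"""End-to-end pipeline orchestration with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, glm, networks, rdm, rsa, searchlight, simulate
from .io import PipelineConfig, write_rdm_csv, write_volume

log = logging.getLogger("foodnet")

__all__ = ["run_pipeline"]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages end to end, writing outputs and a manifest.

    Stages: simulate -> behav -> rdm -> cluster -> rsa -> searchlight ->
    glm.  All randomness flows from ``config.seed``; rerunning with the
    same configuration reproduces the outputs bit for bit, which the
    manifest (parameter echo + output hashes) makes checkable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.to_dict(), "stages": {}, "outputs": {}}

    cfg = simulate.SyntheticConfig(
        seed=config.seed, n_subjects=config.n_subjects, n_items=config.n_items
    )
    rng = cfg.rng()
    space = simulate.gen_food_space(cfg, rng)

    triplets = None
    if config.run_simulate:
        _stage_banner("simulate", {"seed": config.seed, "n_items": cfg.n_items})
        triplets = simulate.gen_triplet_responses(
            space, cfg.triplet_reps, cfg.choice_temperature, rng
        )
        triplets.to_csv(out / "triplets.tsv", sep="\t", index=False)
        truth = {
            "seed": config.seed,
            "category_label": space.category_label.tolist(),
            "processing_score": space.processing_score.tolist(),
            "hedonic_score": space.hedonic_score.tolist(),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest["stages"]["simulate"] = {"n_triplets": int(len(triplets))}

    models = {}
    if config.run_behavior:
        if triplets is None:
            tpath = out / "triplets.tsv"
            if not tpath.exists():
                raise FileNotFoundError(f"behav stage: missing input {tpath}")
            triplets = pd.read_csv(tpath, sep="\t")
        _stage_banner("behav", {"n_triplets": len(triplets)})
        sim_mat = behavior.triplet_similarity_matrix(triplets, cfg.n_items)
        pca = behavior.pca_similarity(sim_mat)
        labels, sil, chosen_k = behavior.select_k_kmeans(
            pca.scores[:, :2],
            k_range=range(config.behavior_k_min, config.behavior_k_max + 1),
            seed=config.seed,
        )
        pd.DataFrame(sim_mat.values).to_csv(out / "similarity.csv", index=False)
        pd.DataFrame(pca.scores).to_csv(out / "pca_scores.csv", index=False)
        pd.DataFrame({"item": space.item_labels(), "category": labels}).to_csv(
            out / "categories.csv", index=False
        )
        models = {
            "behavioral": behavior.similarity_rdm(sim_mat),
            "pc1": behavior.pc_rdm(pca, 1),
            "pc2": behavior.pc_rdm(pca, 2),
        }
        for name, m in models.items():
            write_rdm_csv(m, out / f"model_{name}.csv")
        manifest["stages"]["behav"] = {
            "chosen_k": int(chosen_k),
            "variance_pc12": float(pca.variance_fraction[:2].sum()),
        }

    cohort = None
    group_rdms = {}
    if config.run_rdm:
        _stage_banner("rdm", {"n_subjects": cfg.n_subjects, "n_rois": cfg.n_rois})
        cohort = simulate.gen_roi_patterns(cfg, space, rng)
        subject_rdms = {
            s: {r: rdm.compute_rdm(p) for r, p in rois.items()}
            for s, rois in cohort.patterns.items()
        }
        group_rdms = {
            r: rdm.average_rdms([subject_rdms[s][r] for s in cohort.subjects])
            for r in cohort.roi_ids
        }
        for r, g in group_rdms.items():
            write_rdm_csv(g, out / f"rdm_{r}.csv")
        manifest["stages"]["rdm"] = {"n_rois": len(group_rdms)}

    partition = None
    if config.run_cluster:
        if not group_rdms:
            raise RuntimeError("cluster stage requires the rdm stage outputs")
        _stage_banner("cluster", {"method": config.cluster_method})
        vectors = {r: rdm.upper_tri(g) for r, g in group_rdms.items()}
        report = networks.detect_outlier_rois(vectors, z_threshold=config.z_threshold)
        sim2 = networks.roi_similarity_matrix(group_rdms).subset(report.kept())
        partition = networks.cluster_rois(
            sim2,
            method=config.cluster_method,
            k_range=range(config.k_min, config.k_max + 1),
            seed=config.seed,
        )
        (out / "outliers.json").write_text(
            json.dumps({"excluded": report.excluded, "z": report.zscores.to_dict()}, indent=1)
        )
        (out / "partition.json").write_text(
            json.dumps(
                {
                    "labels": partition.labels,
                    "chosen_k": partition.chosen_k,
                    "silhouette_by_k": {str(k): v for k, v in partition.silhouette_by_k.items()},
                    "modularity_q": partition.modularity_q,
                },
                indent=1,
            )
        )
        manifest["stages"]["cluster"] = {
            "excluded": report.excluded,
            "chosen_k": partition.chosen_k,
        }

    if config.run_rsa:
        if cohort is None or not models or partition is None:
            raise RuntimeError("rsa stage requires simulate/behav/rdm/cluster outputs")
        _stage_banner("rsa", {"n_perm": config.n_perm})
        subject_rdms = {
            s: {r: rdm.compute_rdm(p) for r, p in rois.items()}
            for s, rois in cohort.patterns.items()
        }
        stats_table = rsa.rsa_table(
            subject_rdms, models, n_perm=config.n_perm, seed=config.seed
        )
        # excluded outlier ROIs carry no network label and leave the tests
        labelled = stats_table[stats_table["roi"].isin(partition.labels)]
        tests = rsa.network_level_tests(labelled, partition)
        stats_table.to_csv(out / "rsa_stats.tsv", sep="\t", index=False)
        tests.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        manifest["stages"]["rsa"] = {"n_tests": int(len(tests))}

    if config.run_searchlight:
        if not models:
            raise RuntimeError("searchlight stage requires the behav stage models")
        _stage_banner("searchlight", {"radius": config.radius})
        maps = []
        for s in range(config.n_searchlight_subjects):
            ds = simulate.gen_searchlight_dataset(cfg, rng, space=space)
            maps.append(
                searchlight.run_searchlight(
                    ds.volumes, ds.mask, ds.target_rdm,
                    radius=config.radius, min_voxels=config.min_voxels,
                )
            )
        group = searchlight.group_searchlight(maps, q=config.searchlight_q)
        write_volume(group.t, out / "searchlight_t.nii")
        write_volume(np.nan_to_num(group.p, nan=1.0), out / "searchlight_p.nii")
        write_volume(group.significant.astype(float), out / "searchlight_sig.nii")
        manifest["stages"]["searchlight"] = {
            "n_significant": int(group.significant.sum())
        }

    if config.run_glm:
        _stage_banner("glm", {"polort": config.polort})
        psc = simulate.gen_psc_dataset(cfg, space, rng)
        part_labels = partition.labels if partition is not None else psc.roi_network
        result = glm.psc_network_anova(psc.betas, part_labels)
        psc.betas.to_csv(out / "betas.tsv", sep="\t", index=False)
        result["anova"].to_json(out / "anova.json")
        manifest["stages"]["glm"] = {
            "interaction_p": float(result["anova"].loc["network:condition", "p"])
        }

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_banner(stage: str, params: dict) -> None:
    log.info("stage %s: %s", stage, params)
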