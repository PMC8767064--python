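"""End-to-end orchestration with provenance.

``run_all`` simulates the study, preprocesses both omics layers, runs the
effect decomposition, the distance trajectory, coexpression clustering and
enrichment, and writes every table plus a provenance record (config hash,
seed, package version, per-stage timings) to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .coexpression import enrich_modules, kmeans_modules
from .effects import decompose_all
from .io import (
    write_feature_matrix,
    write_gmt,
    write_results,
    write_sample_metadata,
)
from .preprocess import call_degs, filter_expressed, median_scale, zscore_profiles
from .synthetic import (
    generate_catalog,
    simulate_metabolome,
    simulate_transcriptome,
)
from .types import CatalogEntry, PathwaySets, catalog_to_frame

logger = logging.getLogger(__name__)


def classes_as_pathways(catalog: list[CatalogEntry]) -> PathwaySets:
    """Compound classes as feature sets, for class-level enrichment."""
    mapping: dict[str, tuple[str, list[str]]] = {}
    for entry in catalog:
        slug = entry.compound_class.replace(" ", "_")
        pid = f"CLASS:{slug}"
        mapping.setdefault(pid, (entry.compound_class, []))[1].append(
            entry.feature_id
        )
    return PathwaySets.from_mapping(mapping)


def run_all(
    cfg: PipelineConfig, outdir: str | Path, seed: int | None = None
) -> dict:
    """Run the configured pipeline end to end; returns the provenance dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator
    if seed is not None:
        gen = dataclasses.replace(gen, seed=seed)
    timings: dict[str, float] = {}

    def step(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    t0 = step("simulate")
    catalog = generate_catalog(gen)
    metab, truth_m, records_m = simulate_metabolome(gen, catalog)
    trans, truth_t, records_t = simulate_transcriptome(gen)
    catalog_to_frame(catalog).to_csv(
        outdir / "catalog.tsv", sep="\t", index=False
    )
    write_feature_matrix(metab, outdir / "metabolome.tsv")
    write_sample_metadata(records_m, outdir / "metabolome_metadata.tsv")
    write_feature_matrix(trans, outdir / "transcriptome.tsv")
    write_sample_metadata(records_t, outdir / "transcriptome_metadata.tsv")
    write_results(truth_m, outdir / "truth_metabolome.tsv")
    write_results(truth_t, outdir / "truth_transcriptome.tsv")
    timings["simulate"] = time.perf_counter() - t0
    logger.info(
        "simulate: %d metabolites x %d samples, %d genes x %d samples "
        "(%.2fs)",
        metab.n_features,
        metab.n_samples,
        trans.n_features,
        trans.n_samples,
        timings["simulate"],
    )

    t0 = step("preprocess")
    scaled = median_scale(metab)
    write_feature_matrix(scaled, outdir / "metabolome_scaled.tsv")
    expressed = filter_expressed(trans, cfg.preprocess)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = step("effects")
    calls = decompose_all(scaled, cfg.thresholds)
    write_results(calls, outdir / "effect_calls.tsv")
    stage0 = gen.stages[0]
    degs = call_degs(
        expressed,
        expressed.cell_columns("NB", "EnB", stage0),
        expressed.cell_columns("WT", "EnB", stage0),
        cfg.preprocess,
    )
    write_results(degs, outdir / f"degs_NB_EnB_vs_WT_EnB_{stage0}.tsv")
    timings["effects"] = time.perf_counter() - t0
    logger.info(
        "effects: %d feature x stage calls, %d DEGs (%.2fs)",
        len(calls),
        int(degs["is_deg"].sum()),
        timings["effects"],
    )

    t0 = step("trajectory")
    from .trajectory import endosperm_trajectories

    traj, pca = endosperm_trajectories(scaled, k=cfg.trajectory_k)
    write_results(traj, outdir / "trajectory.tsv")
    scores = pca.scores.copy()
    scores.insert(0, "sample_id", scores.index)
    write_results(scores, outdir / "pca_scores.tsv")
    timings["trajectory"] = time.perf_counter() - t0

    t0 = step("modules")
    profiles, excluded = zscore_profiles(
        scaled, by=("tissue", "stage"), tissues=cfg.cluster_tissues
    )
    assignments = kmeans_modules(
        profiles,
        k=cfg.cluster_k,
        seed=gen.seed,
        n_init=cfg.cluster_n_init,
        metric=cfg.cluster_metric,
        delta=cfg.cluster_delta,
    )
    write_results(assignments, outdir / "modules.tsv")
    timings["modules"] = time.perf_counter() - t0
    logger.info(
        "modules: %d features in %d modules, %d excluded (%.2fs)",
        len(assignments),
        assignments["module"].nunique(),
        len(excluded),
        timings["modules"],
    )

    t0 = step("enrich")
    pathways = classes_as_pathways(catalog)
    write_gmt(pathways, outdir / "class_pathways.gmt")
    enrichment = enrich_modules(
        assignments, pathways, alpha=cfg.enrich_alpha
    )
    write_results(enrichment, outdir / "enrichment.tsv")
    timings["enrich"] = time.perf_counter() - t0

    provenance = {
        "version": __version__,
        "seed": gen.seed,
        "config_hash": config_hash(cfg),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_metabolites": metab.n_features,
        "n_metabolome_samples": metab.n_samples,
        "n_genes": trans.n_features,
        "n_expressed_genes": expressed.n_features,
        "n_effect_calls": int(len(calls)),
        "n_modules": int(assignments["module"].nunique()),
    }
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return provenance
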