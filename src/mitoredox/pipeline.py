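"""End-to-end orchestration: simulate → aggregate → annotate → report.

``run_all`` stages everything into a temporary directory and only moves it
to the requested output directory on success, so a failed run leaves no
partial outputs behind. Identical config + seed gives byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, io, isotop, oxicat, synthetic_data
from .config import RunConfig

logger = logging.getLogger("mitoredox")

__all__ = ["run_all", "simulate_stage", "isotop_stage", "oxicat_stage", "report_stage"]

AMA_CONDITION = "AMA"
CONTROL_CONDITION = "control"


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate truth, annotations, and all observation tables."""
    t0 = time.perf_counter()
    rngs = _child_rngs(config.seed, 6)
    rng_prot, rng_truth, rng_ann, rng_perox, rng_ama, rng_oxicat = rngs

    if config.fasta:
        proteome = io.read_fasta(config.fasta)
    else:
        proteome = synthetic_data.random_proteome(
            config.n_proteins, config.protein_length, rng_prot
        )
    io.write_fasta(proteome, outdir / "proteome.fasta")

    sites = synthetic_data.build_sites(proteome)
    if not sites:
        raise ValueError("no quantifiable cysteines in the proteome")
    truths = synthetic_data.sample_truths(
        sites,
        rng_truth,
        reference_dose=max(config.doses_mM),
        class_bounds=config.class_bounds,
    )
    io.write_truths(truths, outdir / "truth.tsv")

    if config.annotations:
        annotations = list(io.read_annotations(config.annotations).values())
    else:
        annotations = synthetic_data.sample_annotations(
            [s.protein_id for s in sites], rng_ann, config.mito_fraction
        )
    io.write_annotations(annotations, outdir / "annotations.tsv")

    perox_obs = synthetic_data.simulate_isotop(
        truths,
        config.peroxide_conditions,
        config.peroxide_replicates,
        noise_cv=config.noise_cv,
        dropout_rate=config.dropout_rate,
        seed=rng_perox,
        cap=config.ratio_cap,
    )
    io.write_observations(perox_obs, outdir / "isotop_peroxide_obs.tsv")

    ama_obs = synthetic_data.simulate_isotop(
        truths,
        {AMA_CONDITION: config.ama_dose_mM},
        config.ama_replicates,
        noise_cv=config.noise_cv,
        dropout_rate=config.dropout_rate,
        seed=rng_ama,
        cap=config.ratio_cap,
    )
    io.write_observations(ama_obs, outdir / "isotop_ama_obs.tsv")

    oxicat_obs = synthetic_data.simulate_oxicat(
        truths,
        {CONTROL_CONDITION: 0.0, AMA_CONDITION: config.ama_dose_mM},
        config.oxicat_replicates,
        noise_cv=config.noise_cv,
        seed=rng_oxicat,
        cap=config.ratio_cap,
    )
    io.write_observations(oxicat_obs, outdir / "oxicat_obs.tsv")

    logger.info(
        "simulate: %d sites, %d+%d+%d observations in %.2fs",
        len(sites),
        len(perox_obs),
        len(ama_obs),
        len(oxicat_obs),
        time.perf_counter() - t0,
    )
    return {
        "n_sites": len(sites),
        "n_peroxide_obs": len(perox_obs),
        "n_ama_obs": len(ama_obs),
        "n_oxicat_obs": len(oxicat_obs),
    }


def isotop_stage(config: RunConfig, outdir: Path) -> dict:
    """Aggregate, filter, and classify both competitive-profiling arms."""
    t0 = time.perf_counter()
    annotations = io.read_annotations(outdir / "annotations.tsv")

    counts = {}
    for arm, presence in (
        ("peroxide", config.peroxide_presence),
        ("ama", config.ama_presence),
    ):
        observations = io.read_observations(outdir / f"isotop_{arm}_obs.tsv")
        summaries = isotop.aggregate_replicates(observations, presence)
        summaries = isotop.filter_changed(
            summaries, config.fold_threshold, config.cv_threshold
        )
        io.write_summaries(summaries, outdir / f"isotop_{arm}_summaries.tsv")
        mito, report = annotate.filter_mitochondrial(summaries, annotations)
        io.write_summaries(mito, outdir / f"isotop_{arm}_summaries_mito.tsv")
        medians_all = isotop.median_summary(summaries)
        medians_all.insert(0, "scope", "all")
        medians_mito = isotop.median_summary(mito)
        medians_mito.insert(0, "scope", "mitochondrial")
        io._write_versioned(
            pd.concat([medians_all, medians_mito], ignore_index=True),
            outdir / f"isotop_{arm}_medians.tsv",
            "medians",
        )
        counts[arm] = {"n_summaries": len(summaries), **report}

    perox_mito = io.read_summaries(outdir / "isotop_peroxide_summaries_mito.tsv")
    classes = isotop.classify_dose_series(
        perox_mito, config.peroxide_conditions, config.class_bounds
    )
    io._write_versioned(classes, outdir / "isotop_classification.tsv", "classification")
    counts["n_classified"] = len(classes)
    logger.info("isotop: %s in %.2fs", counts, time.perf_counter() - t0)
    return counts


def oxicat_stage(config: RunConfig, outdir: Path) -> dict:
    """Percent oxidation per site and the control/treated comparison."""
    t0 = time.perf_counter()
    observations = io.read_observations(outdir / "oxicat_obs.tsv")
    annotations = io.read_annotations(outdir / "annotations.tsv")
    percents = oxicat.observations_to_percents(observations, orientation="LH")
    records = oxicat.aggregate_oxidation(
        percents, config.oxicat_presence, config.sd_threshold
    )
    mito_ids = {pid for pid, a in annotations.items() if a.is_mitochondrial}
    records = [r for r in records if r.site.protein_id in mito_ids]
    io.write_oxidation(records, outdir / "oxicat_records.tsv")
    comparison = oxicat.compare_conditions(
        records, CONTROL_CONDITION, AMA_CONDITION, config.min_delta
    )
    io._write_versioned(comparison, outdir / "oxicat_comparison.tsv", "comparison")
    logger.info(
        "oxicat: %d records, %d compared in %.2fs",
        len(records),
        len(comparison),
        time.perf_counter() - t0,
    )
    return {"n_records": len(records), "n_compared": len(comparison)}


def report_stage(config: RunConfig, outdir: Path) -> dict:
    """Pathway bins and overrepresentation of high-sensitivity proteins."""
    t0 = time.perf_counter()
    annotations = io.read_annotations(outdir / "annotations.tsv")
    mito = io.read_summaries(outdir / "isotop_peroxide_summaries_mito.tsv")
    top_condition = max(config.peroxide_conditions, key=config.peroxide_conditions.get)
    top = [s for s in mito if s.condition == top_condition and s.retained]

    bins = annotate.bin_pathways(top, annotations, high_threshold=config.class_bounds[1])
    io._write_versioned(bins, outdir / "pathway_bins.tsv", "pathway_bins")

    background = {s.site.protein_id for s in top}
    foreground = {
        s.site.protein_id
        for s in top
        if s.mean_ratio is not None and s.mean_ratio >= config.class_bounds[1]
    }
    categories = {
        label: {
            pid
            for pid, a in annotations.items()
            if a.pathway_bin == label and pid in background
        }
        for label in annotate.PATHWAY_BINS
    }
    categories = {k: v for k, v in categories.items() if v}
    if categories:
        enrich = annotate.overrepresentation(foreground, background, categories)
        io._write_versioned(enrich, outdir / "overrepresentation.tsv", "overrepresentation")
    logger.info("report: %d bins in %.2fs", len(bins), time.perf_counter() - t0)
    return {
        "n_bins": len(bins),
        "n_high_sensitivity_proteins": len(foreground),
        "top_condition": top_condition,
    }


def run_all(config: RunConfig, outdir: str | Path, overwrite: bool = False) -> Path:
    """Run every stage into ``outdir`` atomically and write a manifest."""
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} is not empty")
    staging = outdir.parent / (outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        manifest = {
            "tool": "mitoredox",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": {},
        }
        manifest["stages"]["simulate"] = simulate_stage(config, staging)
        manifest["stages"]["isotop"] = isotop_stage(config, staging)
        manifest["stages"]["oxicat"] = oxicat_stage(config, staging)
        manifest["stages"]["report"] = report_stage(config, staging)
        (staging / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    return outdir
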