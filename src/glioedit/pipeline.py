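"""End-to-end pipeline: quantify -> mask -> select -> classify -> downstream.

Chains the library stages over files on disk, writing one artifact per
result plus a manifest recording inputs, thresholds, seed, package version
and per-stage record counts.  Given the same config and seed the artifacts
are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .classify import (
    CVConfig, TaskSpec, build_feature_matrix, identify_misclassified,
    make_task_labels, repeated_selected_sites, run_cv,
)
from .downstream import hypergeometric_enrichment, km_logrank, quartile_groups
from .quant import (
    GlioeditError, VariantMask, apply_variant_masks,
    compute_site_editing_levels, compute_total_editing_level,
    pairwise_subtype_ks,
)
from .selection import classify_site_sample_types, select_discriminative_sites

log = logging.getLogger("glioedit")


@dataclass
class PipelineConfig:
    """Paths, thresholds and run settings for the end-to-end pipeline."""

    edited: str = ""
    total: str = ""
    catalog: str = ""
    annotations: str = ""
    mask: str | None = None
    outdir: str = "glioedit_out"
    seed: int = 0
    # selection thresholds
    p0: float = 1e-3
    alpha: float = 0.05
    max_frac_III: float = 0.25
    min_frac_I: float = 0.25
    fdr_family: str = "all_cells"
    # classification
    n_folds: int = 10
    learners: list[str] = field(default_factory=lambda: ["svm", "random_forest", "adaboost"])
    feature_selection: str = "in_fold"
    min_repeat: int = 5
    tasks: list[str] = field(default_factory=lambda: ["idh", "codel"])
    codel_restriction: str = "idh_mutant_only"
    # downstream
    survival_site: str | None = None
    survival_horizon: float = 10.0
    enrichment_learner: str = "random_forest"

    def __post_init__(self) -> None:
        for name in ("p0", "alpha", "max_frac_III", "min_frac_I"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise GlioeditError(f"{name}={v} must lie in (0,1)")
        unknown = set(self.learners) - {"svm", "random_forest", "adaboost"}
        if unknown:
            raise GlioeditError(f"unknown learners {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {
            "edited": config.edited, "total": config.total,
            "catalog": config.catalog, "annotations": config.annotations,
            "mask": config.mask,
        },
        "config": asdict(config),
        "version": __version__,
        "seed": config.seed,
        "counts": {},
    }

    t0 = _stage("load")
    counts = gio.read_counts(config.edited, config.total)
    catalog = gio.read_catalog(config.catalog)
    cohort = gio.read_annotations(config.annotations)
    mask = gio.read_mask(config.mask) if config.mask else VariantMask()
    missing_sites = counts.site_ids.difference(catalog.index)
    if len(missing_sites):
        raise GlioeditError(
            f"load: {len(missing_sites)} count sites absent from catalog")
    cohort = cohort.reindex(counts.sample_ids)
    manifest["counts"]["load"] = {
        "n_sites": int(counts.shape[0]), "n_samples": int(counts.shape[1])}
    log.info("load done in %.2fs", time.perf_counter() - t0)

    # --- quantify: sample-specific masking, levels, total editing, KS ---
    t0 = _stage("quantify")
    counts_ss = apply_variant_masks(counts, mask, mode="sample_specific")
    total_editing = compute_total_editing_level(counts_ss)
    total_editing.to_csv(out / "total_editing.tsv", sep="\t",
                         index_label="sample_id", na_rep=gio.NA)
    ks = pd.concat(
        [pairwise_subtype_ks(total_editing, cohort, by_grade=False),
         pairwise_subtype_ks(total_editing, cohort, by_grade=True)],
        ignore_index=True,
    )
    ks.to_csv(out / "ks_tests.tsv", sep="\t", index=False)
    manifest["counts"]["quantify"] = {"n_ks_tests": int(len(ks))}
    log.info("quantify done in %.2fs", time.perf_counter() - t0)

    # --- global masking: known variants from catalog plus global mask ---
    t0 = _stage("mask")
    global_sites = set(catalog.index[catalog["known_variant"]]) | mask.global_sites
    gmask = VariantMask(global_sites=global_sites & set(counts_ss.site_ids))
    counts_masked = apply_variant_masks(counts_ss, gmask, mode="global")
    if counts_masked.shape[0] == 0:
        raise GlioeditError("mask: no sites left after global variant removal")
    levels = compute_site_editing_levels(counts_masked)
    gio.write_levels(levels, out / "levels.tsv")
    manifest["counts"]["mask"] = {
        "n_sites_removed": int(counts.shape[0] - counts_masked.shape[0]),
        "n_sites_kept": int(counts_masked.shape[0]),
    }
    log.info("mask done in %.2fs", time.perf_counter() - t0)

    # --- site selection ---
    t0 = _stage("select")
    types = classify_site_sample_types(
        counts_masked, p0=config.p0, alpha=config.alpha, fdr_family=config.fdr_family)
    selection = select_discriminative_sites(
        types, levels, max_frac_III=config.max_frac_III, min_frac_I=config.min_frac_I)
    gio.write_selection(selection, out / "selection.tsv", out / "selection_thresholds.json")
    manifest["counts"]["select"] = {"n_retained": len(selection.retained_site_ids)}
    log.info("select done in %.2fs (%d sites retained)",
             time.perf_counter() - t0, len(selection.retained_site_ids))
    if not selection.retained_site_ids:
        raise GlioeditError("classify: no features (no site passed selection)")

    # --- classification ---
    t0 = _stage("classify")
    features_all = build_feature_matrix(levels, selection.retained_site_ids)
    summaries: dict = {}
    repeated: dict[str, dict[str, list[str]]] = {}
    for task in config.tasks:
        spec = TaskSpec(task=task,
                        cohort_restriction=(config.codel_restriction
                                            if task == "codel" else "all"))
        labels = make_task_labels(cohort, spec)
        feats = features_all.loc[labels.index]
        runs = []
        summaries[task] = {}
        repeated[task] = {}
        for learner in config.learners:
            cv = CVConfig(n_folds=config.n_folds, seed=config.seed, learner=learner,
                          feature_selection=config.feature_selection)
            folds, summary = run_cv(feats, labels, cv)
            runs.append(folds)
            pred = pd.concat(
                [pd.DataFrame({
                    "sample_id": f.test_ids, "fold": f.fold_index,
                    "score": f.scores.to_numpy(),
                    "predicted": f.predicted.to_numpy(),
                    "true": labels.loc[f.test_ids].to_numpy()})
                 for f in folds], ignore_index=True)
            pred.to_csv(out / f"predictions_{task}_{learner}.tsv", sep="\t", index=False)
            np.savetxt(out / f"roc_{task}_{learner}.tsv", summary.roc,
                       delimiter="\t", header="fpr\ttpr", comments="")
            rep = sorted(repeated_selected_sites(folds, min_count=config.min_repeat))
            repeated[task][learner] = rep
            (out / f"repeated_sites_{task}_{learner}.txt").write_text(
                "\n".join(rep) + ("\n" if rep else ""))
            summaries[task][learner] = {
                "acc": summary.acc, "sen": summary.sen, "spe": summary.spe,
                "auc": summary.auc, "confusion": summary.confusion,
                "n_repeated_sites": len(rep),
            }
        mis = sorted(identify_misclassified(runs, labels))
        (out / f"misclassified_{task}.txt").write_text(
            "\n".join(mis) + ("\n" if mis else ""))
        summaries[task]["misclassified"] = mis
    (out / "summary.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True) + "\n")
    manifest["counts"]["classify"] = {
        t: {l: summaries[t][l]["confusion"] for l in config.learners}
        for t in config.tasks}
    log.info("classify done in %.2fs", time.perf_counter() - t0)

    # --- downstream: enrichment + survival ---
    t0 = _stage("downstream")
    background = selection.retained_site_ids
    for task in config.tasks:
        rep = repeated[task].get(config.enrichment_learner, [])
        if rep:
            enr = hypergeometric_enrichment(rep, background, catalog)
            enr.to_csv(out / f"enrichment_{task}.tsv", sep="\t", index=False)
    site = config.survival_site
    if site is None:
        # deterministic default: highest-MAD_3Q site among repeatedly
        # selected ones, falling back to the retained set
        pool = sorted({s for t in repeated.values() for l in t.values() for s in l})
        if not pool:
            pool = background
        site = selection.diagnostics.loc[pool, "mad3q"].idxmax()
    surv_out: dict = {"site": site}
    groups = quartile_groups(levels, site)
    for prefix in ("os", "pfi"):
        comp = km_logrank(cohort[f"{prefix}_time"], cohort[f"{prefix}_event"],
                          groups.dropna(), horizon=config.survival_horizon)
        surv_out[prefix] = {
            "logrank_statistic": comp.statistic, "p_value": comp.p_value,
            "n_excluded": comp.n_excluded, "group_sizes": comp.group_sizes,
        }
        curves = pd.concat(
            [c.assign(group=g) for g, c in sorted(comp.curves.items())],
            ignore_index=True)
        curves.to_csv(out / f"km_{prefix}.tsv", sep="\t", index=False)
    (out / "survival.json").write_text(
        json.dumps(surv_out, indent=2, sort_keys=True) + "\n")
    manifest["counts"]["downstream"] = {"survival_site": site}
    log.info("downstream done in %.2fs", time.perf_counter() - t0)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
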