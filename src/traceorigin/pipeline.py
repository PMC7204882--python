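"""End-to-end orchestration: simulate → preprocess → fit → assign → cluster.

Everything is driven by a :class:`~traceorigin.datamodel.RunConfig` plus a
:class:`~traceorigin.synthetic.SynthConfig`; a single integer seed controls
all randomness (generator sub-streams are derived from it), so a run report
is exactly reproducible from its configuration.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .assignment import assign_origin, summarize_by_context
from .clustering import agglomerate, cut, multiscale_bootstrap, pairwise_distance
from .datamodel import RunConfig, SampleTable
from .discriminant import (FingerprintLibrary, fit_canonical, loo_crossvalidate,
                           stepwise_select)
from .manova import manova_wilks
from .preprocess import apply_scaler, fit_scaler, normalize_to_calcium
from .synthetic import SynthConfig, generate_library, generate_problem_birds

logger = logging.getLogger(__name__)

__all__ = ["build_library", "run_full"]


def build_library(table: SampleTable, config: RunConfig) -> FingerprintLibrary:
    """Train a fingerprint library from known-origin (juvenile) birds."""
    ratio = normalize_to_calcium(table)
    scaler = fit_scaler(ratio)
    zm = apply_scaler(scaler, ratio)
    labels = zm.meta["site"].to_numpy()
    trace = stepwise_select(zm.z, labels,
                            criterion=config.selection_criterion,
                            f_enter=config.f_enter, f_remove=config.f_remove)
    if trace.flagged_empty:
        raise ValueError("stepwise selection retained no elements")
    site_order = [str(s) for s in pd.unique(labels)]
    fit = fit_canonical(
        zm.z[trace.selected], labels, site_order=site_order,
        retention_threshold=config.eigenvalue_retention_threshold)
    return FingerprintLibrary(panel=table.panel, scaler=scaler, trace=trace,
                              fit=fit, config=config.to_dict())


def run_full(config: RunConfig, synth: SynthConfig | None = None,
             n_problem: int = 118, bootstrap: bool = True) -> dict:
    """Run the whole workflow on synthetic data and return the run report.

    The report is a plain JSON-serializable dict; identical config + seed
    give an identical report.
    """
    if synth is None:
        synth = SynthConfig(seed=config.seed)
    else:
        synth = dataclasses.replace(synth, seed=config.seed)
    library_table = generate_library(synth)
    problem = generate_problem_birds(synth, n_total=n_problem)

    ratio = normalize_to_calcium(library_table)
    scaler = fit_scaler(ratio)
    zm = apply_scaler(scaler, ratio)
    labels = zm.meta["site"].to_numpy()

    man = manova_wilks(zm.values, labels)
    lib = build_library(library_table, config)
    report_cls = loo_crossvalidate(
        zm.z, labels, selected=lib.trace.selected,
        site_order=lib.fit.site_order,
        retention_threshold=config.eigenvalue_retention_threshold)

    # problem birds into the library reference frame
    if config.problem_zscore_mode == "library":
        meta_p, scores_p = lib.scores_for(problem.table)
    else:  # pooled: z-score juveniles + problem birds together
        all_rows = pd.concat([library_table.data, problem.table.data],
                             ignore_index=True)
        pooled = SampleTable(all_rows, library_table.panel)
        pr = normalize_to_calcium(pooled)
        psc = fit_scaler(pr)
        pz = apply_scaler(psc, pr)
        mask = pz.meta["season"].to_numpy() == "fall"
        meta_p = pz.meta.loc[mask].reset_index(drop=True)
        scores_p = lib.fit.transform(pz.z.loc[mask])
    assign = assign_origin(lib, scores_p, bird_ids=meta_p["bird_id"],
                           method="ratio",
                           immigrant_alpha=config.immigrant_alpha)
    summaries = summarize_by_context(assign, meta_p["context"],
                                     regions=config.regions or None)

    # juvenile tree (primary linkage) and all-birds two-way split
    tree_juv = agglomerate(pairwise_distance(zm.values, config.cluster_metric),
                           config.cluster_linkage,
                           labels=list(zm.meta["bird_id"]),
                           metric=config.cluster_metric)
    all_rows = pd.concat([library_table.data, problem.table.data],
                         ignore_index=True)
    pooled = SampleTable(all_rows, library_table.panel)
    pr = normalize_to_calcium(pooled)
    pz = apply_scaler(fit_scaler(pr), pr)
    tree_all = agglomerate(pairwise_distance(pz.values, config.cluster_metric),
                           config.cluster_linkage,
                           labels=list(pz.meta["bird_id"]),
                           metric=config.cluster_metric)
    two_way = cut(tree_all, k=2)
    is_problem = (pz.meta["season"] == "fall").to_numpy()
    # which of the two top-level clusters is problem-bird dominated?
    frac = [is_problem[two_way == c].mean() for c in (0, 1)]
    problem_cluster = int(np.argmax(frac))
    n_problem_separate = int(np.sum(is_problem & (two_way == problem_cluster)))

    support_summary = None
    if bootstrap:
        sup = multiscale_bootstrap(
            zm, metric=config.support_metric, linkage=config.support_linkage,
            scales=config.bootstrap_scales, B=config.bootstrap_B,
            seed=config.seed)
        support_summary = {
            "n_nodes": int(len(sup.table)),
            "n_strong": int((sup.table["au"] >= 0.95).sum()),
            "au": [round(float(a), 6) if np.isfinite(a) else None
                   for a in sup.table["au"]],
            "bp": [round(float(b), 6) if np.isfinite(b) else None
                   for b in sup.table["bp"]],
        }

    from . import __version__

    report = {
        "software_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "synth_config": {**dataclasses.asdict(synth),
                         "sites": list(synth.sites)},
        "manova": dataclasses.asdict(man),
        "stepwise": {
            "selected": list(lib.trace.selected),
            "n_selected": len(lib.trace.selected),
            "steps": [dataclasses.asdict(s) for s in lib.trace.steps],
        },
        "discriminant": {
            "eigenvalues": lib.fit.eigenvalues.tolist(),
            "canonical_correlations": lib.fit.canonical_correlations.tolist(),
            "variance_shares": lib.fit.variance_shares.tolist(),
            "retained": lib.fit.retained,
            "wilks_lambda": lib.fit.wilks_lambda,
        },
        "classification": {
            "overall_pct_loo": report_cls.overall_pct_loo,
            "overall_pct_resub": report_cls.overall_pct_resub,
            "per_site_pct_loo": report_cls.per_site_pct_loo.to_dict(),
            "press_q": report_cls.press_q,
            "press_q_p": report_cls.press_q_p,
            "confusion_loo": report_cls.confusion_loo.to_dict("split"),
        },
        "assignment": {
            "tau": assign.tau,
            "n_flagged": int(assign.flagged.sum()),
            "pct_flagged": float(assign.flagged.mean() * 100.0),
            "by_context": {
                ctx: {"counts": s.counts.to_dict(),
                      "percentages": {k: round(v, 4)
                                      for k, v in s.percentages.items()}}
                for ctx, s in summaries.items()
            },
        },
        "clustering": {
            "juvenile_tree_height": float(tree_juv.heights[-1]),
            "all_birds_two_way": {
                "n_problem_in_problem_cluster": n_problem_separate,
                "pct_problem_separate": 100.0 * n_problem_separate
                / int(is_problem.sum()),
            },
            "support": support_summary,
        },
        "objects": {
            "library": lib,
            "assignments": assign,
            "classification_report": report_cls,
            "juvenile_tree": tree_juv,
            "all_birds_tree": tree_all,
            "problem_truth": problem.true_origin,
        },
    }
    return report


def report_without_objects(report: dict) -> dict:
    """JSON-serializable copy of a run report (heavy objects stripped)."""
    return {k: v for k, v in report.items() if k != "objects"}
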