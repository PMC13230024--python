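"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes the enabled stages in dependency order on either
simulated cohorts (the default) or user-supplied TSV/newick inputs, writes
each stage's tabular outputs under the configured directory, and records a
JSON manifest with the configuration, derived per-stage seeds and a SHA-256
checksum per output file.

One global seed is expanded into per-stage seeds through a fixed counter
scheme (``stage_seed = (global_seed * 1009 + stage_index) mod 2**31``) so
any stage can be re-run in isolation and reproduce its output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffab, diversity, ibd, meta_effects, mlval, networks, permanova
from .core_data import (
    CohortSet,
    cohort_summary,
    filter_min_depth,
    rarefy,
    read_feature_table,
    read_metadata,
    read_tree,
    write_feature_table,
    write_metadata,
    write_tree,
)
from .ibd import ModuleDefinition
from .synthetic import (
    CrossSectionalSimConfig,
    PairedSimConfig,
    simulate_ibd_cohorts,
    simulate_paired_cohorts,
    simulate_tree,
)

logger = logging.getLogger(__name__)

STAGES = ("summary", "diversity", "permanova", "diffab", "network", "ml", "ibd")


@dataclass
class PipelineConfig:
    """All thresholds default to the pipeline's standard analysis settings."""

    out_dir: str = "rsmeta_out"
    seed: int = 0
    stages: tuple = STAGES
    # input paths; None -> simulate
    table_paths: dict | None = None  # study_id -> counts TSV
    metadata_paths: dict | None = None  # study_id -> metadata TSV
    tree_path: str | None = None
    module_path: str | None = None
    # simulation configs used when no inputs are given
    paired_sim: PairedSimConfig | None = None
    ibd_sim: CrossSectionalSimConfig | None = None
    # analysis thresholds
    min_depth: int = 1000
    rarefaction_depth: int = 1000
    prevalence: float = 0.10
    pseudocount: float = 1.0
    fdr_alpha: float = 0.05
    edge_min_r: float = 0.1
    edge_max_p: float = 0.05
    rewiring_high: float = 0.12
    n_perm: int = 999
    n_perm_network: int = 50
    max_network_features: int = 50
    cv_k: int = 5
    beta_metrics: tuple = ("bray_curtis", "jaccard")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGES.index(stage)) % 2**31


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohorts(cfg: PipelineConfig) -> CohortSet:
    studies = {}
    for sid, tpath in cfg.table_paths.items():
        table = read_feature_table(tpath)
        meta = read_metadata(cfg.metadata_paths[sid], "paired")
        studies[sid] = (table, meta)
    tree = read_tree(cfg.tree_path) if cfg.tree_path else None
    return CohortSet(studies, tree=tree)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages; returns (and writes) the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if not isinstance(v, dict) or v is None
        },
        "stages": {},
    }
    written: dict = {}

    def emit(stage, name, frame):
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.setdefault(stage, []).append(path)

    t0 = time.time()
    if cfg.table_paths:
        cohorts = _load_cohorts(cfg)
        truth = None
    else:
        sim_cfg = cfg.paired_sim or PairedSimConfig(seed=cfg.seed)
        cohorts, truth = simulate_paired_cohorts(sim_cfg)
        cohorts.tree = simulate_tree(sim_cfg.n_features, seed=sim_cfg.seed + 1)
    logger.info("inputs ready in %.1fs", time.time() - t0)

    if "summary" in cfg.stages:
        emit("summary", "cohort_summary", cohort_summary(cohorts))

    if "diversity" in cfg.stages:
        seed = cfg.stage_seed("diversity")
        alpha = meta_effects.pool_alpha_diversity(
            cohorts,
            rarefaction_depth=cfg.rarefaction_depth,
            min_depth=cfg.min_depth,
            seed=seed,
        )
        emit("diversity", "alpha_pooled_effects", alpha)
        paired_rows = []
        for sid, (table, meta) in cohorts.items():
            filt = filter_min_depth(table, cfg.min_depth)
            rare = rarefy(filt, depth=cfg.rarefaction_depth, seed=seed)
            meta_kept = meta.select_samples(rare.sample_ids)
            for metric in cfg.beta_metrics:
                paired_rows.append(
                    diversity.paired_beta_distance(rare, meta_kept, metric)
                )
        emit("diversity", "paired_beta_distances", pd.concat(paired_rows))

    if "permanova" in cfg.stages:
        seed = cfg.stage_seed("permanova")
        rows = []
        for metric in cfg.beta_metrics:
            tables, metas = [], []
            for sid, (table, meta) in cohorts.items():
                filt = filter_min_depth(table, cfg.min_depth)
                rare = rarefy(filt, depth=cfg.rarefaction_depth, seed=seed)
                tables.append(rare.counts)
                metas.append(meta.select_samples(rare.sample_ids).table)
            pooled_counts = pd.concat(tables)
            pooled_meta = pd.concat(metas)
            from .core_data import FeatureTable

            pooled = FeatureTable(pooled_counts)
            base_ids = pooled_meta.loc[
                pooled_meta["timepoint"] == "baseline", "sample_id"
            ]
            dm = diversity.beta_distance(pooled, metric, tree=cohorts.tree)
            dm_base = dm.filter(list(base_ids))
            studies = pooled_meta.set_index("sample_id").loc[dm_base.ids, "study_id"]
            res = permanova.study_variance(
                dm_base, studies.to_numpy(), n_perm=cfg.n_perm, seed=seed
            )
            rows.append(
                {
                    "analysis": "study_clustering_baseline",
                    "metric": metric,
                    "R2": res.R2,
                    "pseudo_F": res.pseudo_F,
                    "p": res.p,
                }
            )
            complete = pooled_meta.groupby("subject_id")["sample_id"].count() == 2
            keep_subj = complete[complete].index
            kept = pooled_meta[pooled_meta["subject_id"].isin(keep_subj)]
            dm_pairs = dm.filter(list(kept["sample_id"]))
            km = kept.set_index("sample_id").loc[dm_pairs.ids]
            res_rm = permanova.rm_permanova(
                dm_pairs,
                km["timepoint"].to_numpy(),
                km["subject_id"].to_numpy(),
                n_perm=cfg.n_perm,
                seed=seed,
            )
            rows.append(
                {
                    "analysis": "rm_timepoint_combined",
                    "metric": metric,
                    "R2": res_rm.R2,
                    "pseudo_F": res_rm.pseudo_F,
                    "p": res_rm.p,
                }
            )
        emit("permanova", "permanova", pd.DataFrame(rows))

    results = None
    if "diffab" in cfg.stages:
        delta = diffab.delta_clr(
            cohorts, prevalence=cfg.prevalence, pseudocount=cfg.pseudocount
        )
        results = diffab.run_differential_abundance(delta, alpha=cfg.fdr_alpha)
        emit("diffab", "differential_abundance", diffab.results_frame(results))
        emit(
            "diffab",
            "consistency",
            diffab.consistency_table(results, delta, alpha=cfg.fdr_alpha),
        )
        sig = diffab.significant_features(results, cfg.fdr_alpha)
        module_path = out / "depleted_module.txt"
        if sig:
            ModuleDefinition([r.feature_id for r in sig]).write(module_path)
            written.setdefault("diffab", []).append(module_path)

    if "network" in cfg.stages:
        seed = cfg.stage_seed("network")
        scores, sizes = {}, {}
        edge_frames = []
        for sid, (table, meta) in cohorts.items():
            cond = meta.condition_of()
            # one shared feature set per cohort so rewiring compares like
            # with like: the most abundant post-filter features
            from .core_data import filter_prevalence

            filt = filter_prevalence(table, cfg.prevalence)
            top = (
                filt.counts.sum()
                .sort_values(ascending=False)
                .index[: cfg.max_network_features]
            )
            per_condition = {}
            for condition in ("baseline", "endpoint"):
                ids = cond[cond == condition].index
                sub = table.select_samples(ids).select_features(top)
                net = networks.sparcc(
                    sub,
                    seed=seed,
                    min_prevalence=0.0,
                    provenance=(sid, condition),
                )
                networks.permutation_pvalues(
                    sub.select_features(net.feature_ids),
                    net,
                    n_perm=cfg.n_perm_network,
                    seed=seed,
                )
                edges = networks.filter_edges(net, cfg.edge_min_r, cfg.edge_max_p)
                edges.insert(0, "condition", condition)
                edges.insert(0, "cohort", sid)
                edge_frames.append(edges)
                per_condition[condition] = edges
            union = pd.concat(per_condition.values())
            partition = networks.detect_modules(union, nodes=list(top))
            scores[sid] = networks.rewiring_score(
                per_condition["baseline"], per_condition["endpoint"], partition
            )
            sizes[sid] = len(cond)
        combined = networks.combine_rewiring(scores, sizes)
        combined.high_threshold = cfg.rewiring_high
        emit("network", "edges", pd.concat(edge_frames))
        emit(
            "network",
            "rewiring_scores",
            pd.DataFrame(
                {
                    "feature_id": combined.combined.index,
                    "combined_score": combined.combined.to_numpy(),
                    "high": combined.high_flag.to_numpy(),
                }
            ),
        )

    if "ml" in cfg.stages:
        seed = cfg.stage_seed("ml")
        all_results = (
            mlval.within_study_cv(cohorts, k=cfg.cv_k, seed=seed)
            + mlval.cross_study_validation(cohorts, seed=seed)
            + mlval.loso(cohorts, seed=seed)
        )
        emit("ml", "ml_auc", mlval.results_frame(all_results))

    if "ibd" in cfg.stages:
        seed = cfg.stage_seed("ibd")
        if cfg.module_path:
            module = ModuleDefinition.read(cfg.module_path)
        elif results is not None and diffab.significant_features(results, cfg.fdr_alpha):
            module = ModuleDefinition(
                [
                    r.feature_id
                    for r in diffab.significant_features(results, cfg.fdr_alpha)
                ]
            )
        else:
            module = None
        if module is not None:
            ibd_cfg = cfg.ibd_sim or CrossSectionalSimConfig(seed=seed)
            ibd_cohorts, _ = simulate_ibd_cohorts(ibd_cfg)
            res = ibd.module_analysis(ibd_cohorts, module)
            emit(
                "ibd",
                "ibd_marginal_means",
                res.marginal_means.rename_axis("diagnosis")
                .rename("adjusted_mean")
                .reset_index(),
            )
            emit("ibd", "ibd_contrasts", res.contrasts)

    for stage, paths in written.items():
        manifest["stages"][stage] = {
            "seed": cfg.stage_seed(stage) if stage in STAGES else cfg.seed,
            "outputs": {p.name: _sha256(p) for p in sorted(paths)},
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write small on-disk fixtures: a tiny simulated paired cohort pair
    (tables + metadata + tree + ground-truth sidecar) and the cohort-roster
    bookkeeping tables."""
    from .bookkeeping import ibd_roster_cohorts, intervention_roster_cohorts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PairedSimConfig(
        n_studies=2,
        subjects_per_study=[6, 6],
        n_features=30,
        n_module=5,
        depth_range=(2000, 4000),
        seed=seed,
    )
    cohorts, truth = simulate_paired_cohorts(cfg)
    tree = simulate_tree(cfg.n_features, seed=seed + 1)
    files = {}
    for sid, (table, meta) in cohorts.items():
        tp = out / f"{sid}_counts.tsv"
        mp = out / f"{sid}_metadata.tsv"
        write_feature_table(table, tp)
        write_metadata(meta, mp)
        files[f"{sid}_counts"] = str(tp)
        files[f"{sid}_metadata"] = str(mp)
    write_tree(tree, out / "tree.nwk")
    files["tree"] = str(out / "tree.nwk")
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "module_features": truth.module_features,
                "delta": truth.delta.to_dict(),
            },
            indent=2,
        )
    )
    files["ground_truth"] = str(out / "ground_truth.json")
    cohort_summary(intervention_roster_cohorts()).to_csv(
        out / "intervention_roster_summary.tsv", sep="\t", index=False
    )
    cohort_summary(ibd_roster_cohorts()).to_csv(
        out / "ibd_roster_summary.tsv", sep="\t", index=False
    )
    files["intervention_roster_summary"] = str(out / "intervention_roster_summary.tsv")
    files["ibd_roster_summary"] = str(out / "ibd_roster_summary.tsv")
    return files
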