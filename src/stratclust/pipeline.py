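"""Configuration-driven orchestration of the two analysis arms.

The pipeline reproduces the full workflow on one cohort: load (or simulate)
genotypes, recode to minor alleles, assign ancestry against a labelled
reference panel, compute ancestry PCs from the AIM panel, then cluster the
disease SNPs twice — once unadjusted and once after projecting out the top
PCs — and run the association battery (population x cluster tests,
subphenotype scans, pairwise adjusted Rand indices).

Every stochastic stage receives a seed derived deterministically from the
global seed and the stage name, so adding a stage never perturbs the
earlier ones and a run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust, assoc, cluster, datasets, lca
from .genotypes import (SampleTable, drop_monomorphic, read_genotypes_tsv,
                        recode_to_minor, standardize)
from .simdata import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "published_class_population_test", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    # data source: either a simulation config or file paths
    sim: SimConfig | None = None
    genotypes_path: str | None = None
    aim_path: str | None = None
    metadata_path: str | None = None
    panel_path: str | None = None
    panel_metadata_path: str | None = None
    population_column: str = "population"
    # adjustment
    n_pcs: int = 2
    adjustment_mode: str = "available_case"
    adjust_standardized: bool = True
    # clustering
    methods: tuple = ("lca", "pam", "ward")
    lca_on_adjusted: bool = False  # adjusted values are continuous, not counts
    lca_select_mode: str = "bic"
    lca_K_max: int = 6
    lca_B: int = 100
    lca_restarts: int = 5
    pamk_range: tuple = (2, 6)
    heights_window: int = 10
    # association
    assoc_B: int = 9999
    drop_categories: tuple = ("Missing",)
    bonferroni: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in raw.items()})
        if sim is not None:
            cfg.sim = SimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                   for k, v in sim.items()})
        return cfg


@dataclass
class RunReport:
    partitions: dict = field(default_factory=dict)      # name -> labels array
    selection: dict = field(default_factory=dict)       # name -> trace
    population_tables: dict = field(default_factory=dict)
    population_tests: dict = field(default_factory=dict)
    subpheno_tests: dict = field(default_factory=dict)  # name -> DataFrame
    ari_matrix: pd.DataFrame | None = None
    pc_coords: pd.DataFrame | None = None
    ancestry: object = None
    log: list = field(default_factory=list)
    config: PipelineConfig | None = None

    def summary(self) -> dict:
        out = {
            "partitions": {k: int(v.max()) for k, v in self.partitions.items()},
            "population_tests": {k: {"p_value": t.p_value, "statistic": t.statistic}
                                 for k, t in self.population_tests.items()},
        }
        if self.ari_matrix is not None:
            out["ari"] = self.ari_matrix.round(4).to_dict()
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, labels in self.partitions.items():
            pd.DataFrame({"cluster": labels}).to_csv(
                outdir / f"partition_{name}.tsv", sep="\t", index_label="row")
        for name, frame in self.subpheno_tests.items():
            frame.to_csv(outdir / f"subpheno_{name}.tsv", sep="\t", index=False)
        for name, tab in self.population_tables.items():
            tab.to_frame().to_csv(outdir / f"population_by_cluster_{name}.tsv",
                                  sep="\t")
        if self.ari_matrix is not None:
            self.ari_matrix.to_csv(outdir / "ari_matrix.tsv", sep="\t")
        if self.pc_coords is not None:
            self.pc_coords.to_csv(outdir / "pc_coordinates.tsv", sep="\t",
                                  index_label="sample_id")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=str)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, default=str)


def _log_stage(report: RunReport, stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "runtime_s": round(time.time() - t0, 3), **info}
    report.log.append(entry)
    logger.info("stage %s: %s", stage, entry)


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        cohort = simulate_cohort(config.sim, seed=stage_seed(config.seed, "simulate"))
        meta = pd.DataFrame({"population": cohort.truth.population},
                            index=cohort.disease.sample_ids)
        if cohort.truth.subphenotypes is not None:
            meta = meta.join(cohort.truth.subphenotypes.frame)
        return (cohort.disease, cohort.aim, SampleTable(meta),
                cohort.panel, pd.Series(cohort.panel_labels,
                                        index=cohort.panel.sample_ids))
    if config.genotypes_path is None or config.aim_path is None:
        raise ValueError("either a simulation config or genotype/AIM paths required")
    disease = read_genotypes_tsv(config.genotypes_path)
    aim = read_genotypes_tsv(config.aim_path)
    meta = (SampleTable.read_tsv(config.metadata_path)
            if config.metadata_path else None)
    panel = panel_labels = None
    if config.panel_path:
        panel = read_genotypes_tsv(config.panel_path)
        panel_meta = SampleTable.read_tsv(config.panel_metadata_path)
        panel_labels = panel_meta.column(config.population_column,
                                         sample_ids=panel.sample_ids)
    return disease, aim, meta, panel, panel_labels


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute both arms and the association battery; fully seeded."""
    report = RunReport(config=config)
    t0 = time.time()
    disease, aim, meta, panel, panel_labels = _load_inputs(config)
    _log_stage(report, "load", t0, n=disease.n, m_disease=disease.m, m_aim=aim.m)

    population = None
    if meta is not None and "population" in meta.columns:
        population = meta.column("population", sample_ids=disease.sample_ids)
    if panel is not None and panel_labels is not None:
        # before any per-cohort recoding: query and panel must keep the same
        # allele orientation, which they share as loaded
        t0 = time.time()
        ancestry = adjust.assign_ancestry(aim, panel, panel_labels,
                                          seed=stage_seed(config.seed, "ancestry"))
        report.ancestry = ancestry
        population = ancestry.labels
        _log_stage(report, "ancestry", t0, pure=ancestry.panel_pure)

    t0 = time.time()
    disease, _ = recode_to_minor(disease)
    aim, _ = recode_to_minor(aim)
    disease, dropped_d = drop_monomorphic(disease)
    aim, dropped_a = drop_monomorphic(aim)
    _log_stage(report, "recode", t0, dropped_disease=len(dropped_d),
               dropped_aim=len(dropped_a))

    t0 = time.time()
    S_aim = standardize(aim)
    pcs = adjust.compute_pcs(S_aim, k=config.n_pcs)
    report.pc_coords = pcs.to_frame()
    _log_stage(report, "pca", t0,
               explained=[round(float(f), 4) for f in pcs.explained_fraction])

    # analysis matrices per arm: standardised disease values with missing
    # entries restored (distances apply the proportional scaling rule)
    S_dis = standardize(disease)
    unadj = S_dis.values.copy()
    unadj[S_dis.source_missing_mask] = np.nan

    t0 = time.time()
    adjusted = adjust.adjust_genotypes(disease, pcs, mode=config.adjustment_mode,
                                       standardized=config.adjust_standardized)
    _log_stage(report, "adjust", t0, mode=config.adjustment_mode)

    arms = {"unadjusted": unadj, "adjusted": adjusted.values}
    for arm, X in arms.items():
        if "pam" in config.methods:
            t0 = time.time()
            D = cluster.pairwise_distance(X, metric="euclidean")
            lo, hi = config.pamk_range
            res = cluster.pamk_select(D, range(lo, hi + 1),
                                      seed=stage_seed(config.seed, f"pam:{arm}"))
            report.partitions[f"pam_{arm}"] = res.partition.labels
            report.selection[f"pam_{arm}"] = res.silhouette_trace
            _log_stage(report, f"pam:{arm}", t0, k=res.partition.k,
                       avg_silhouette=round(res.avg_silhouette, 4))
        if "ward" in config.methods:
            t0 = time.time()
            D2 = cluster.pairwise_distance(X, metric="squared_euclidean")
            dend = cluster.ward_linkage(D2)
            window = min(config.heights_window, disease.n - 2)
            k = cluster.select_k_heights(dend, window)
            part = cluster.cut_tree(dend, k)
            report.partitions[f"ward_{arm}"] = part.labels
            report.selection[f"ward_{arm}"] = cluster.pct_change_heights(dend, window)
            _log_stage(report, f"ward:{arm}", t0, k=k)
        if "lca" in config.methods and (arm == "unadjusted" or config.lca_on_adjusted):
            if arm == "adjusted":
                logger.warning("LCA on adjusted (continuous) values was requested; "
                               "the binomial model treats them as counts only "
                               "after recoding — interpret with care")
                continue
            t0 = time.time()
            K, trace = lca.select_k(disease, mode=config.lca_select_mode,
                                    K_max=config.lca_K_max, B=config.lca_B,
                                    n_restarts=config.lca_restarts,
                                    seed=stage_seed(config.seed, "lca_select"))
            model, post = lca.lca_fit(disease, K, n_restarts=config.lca_restarts,
                                      seed=stage_seed(config.seed, "lca_fit"))
            report.partitions["lca_unadjusted"] = post.modal_label
            report.selection["lca_unadjusted"] = trace
            _log_stage(report, "lca", t0, K=K)

    # association battery
    rng = np.random.default_rng(stage_seed(config.seed, "assoc"))
    for name, labels in report.partitions.items():
        if population is not None:
            tab = assoc.crosstab(labels, population.to_numpy()
                                 if hasattr(population, "to_numpy") else population)
            try:
                tab_t = tab.drop_columns(config.drop_categories)
            except ValueError:
                tab_t = tab
            report.population_tables[name] = tab
            report.population_tests[name] = assoc.chisq_mc(
                tab_t, B=config.assoc_B, seed=int(rng.integers(2**31)))
        if meta is not None:
            pheno_cols = [c for c in meta.columns if c != "population"]
            if pheno_cols:
                report.subpheno_tests[name] = assoc.association_scan(
                    labels, meta, columns=pheno_cols, B=config.assoc_B,
                    seed=int(rng.integers(2**31)),
                    drop_categories=config.drop_categories,
                    bonferroni=config.bonferroni,
                    sample_ids=disease.sample_ids)

    names = list(report.partitions)
    ari = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            val = assoc.adjusted_rand_index(report.partitions[a],
                                            report.partitions[b])
            ari.loc[a, b] = ari.loc[b, a] = val
    report.ari_matrix = ari
    return report


def published_class_population_test(B: int = 99_999, seed: int = 0,
                                    drop_missing: bool = True) -> assoc.TestResult:
    """Monte-Carlo chi-squared on the bundled latent-class x population table.

    With B = 99999 the association is so strong that the resampled p-value
    hits its attainable minimum 1/(B+1) = 0.00001.
    """
    table = datasets.class_population_table()
    if drop_missing:
        table = table.drop_columns(["Missing"])
    return assoc.chisq_mc(table, B=B, seed=seed)
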