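"""End-to-end orchestration: raw table -> normalized matrix -> candidate markers.

Stage order: read (or simulate) -> log2 -> batch mean-centering ->
completeness partition -> correlation clustering -> LLS imputation ->
normalizer selection (stability + group p + exclusion list) -> NSF ->
mixed-model interaction testing + SGoF -> GEE cross-check -> time-point
screens -> delta profiles -> t-SNE / affinity propagation -> clinical
correlation screen -> (optional) MRM validation.  Every stage emits plain
TSV/JSON artifacts; a manifest records the seed and all parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import compare_baseline_characteristics, derive_response_labels
from .containers import (
    AbundanceMatrix,
    ClinicalTable,
    read_abundance_table,
    read_clinical_table,
    read_mrm_table,
    write_abundance_table,
)
from .correlate import CorrelationResult, correlate_indices, multi_index_screen
from .normalize import NSFNormalizer, normfinder_stability
from .preprocess import LLSImputer, batch_mean_center, log_transform, unlog_transform
from .simulate import CohortConfig, generate_cohort, generate_mrm_cohort
from .stats import (
    fit_gee,
    fit_lmm,
    lmm_group_pvalues,
    screen_summary,
    screen_timepoints,
    select_mrm_candidates,
    sgof_bayesian,
    wilcoxon_mrm_validation,
)
from .trajectories import cluster_trajectories, compute_delta_profiles


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters plus either input paths or a simulation config."""

    seed: int = 0
    simulate: bool = True
    cohort: CohortConfig = None
    abundance_path: str | None = None
    clinical_path: str | None = None
    covariates_path: str | None = None
    mrm_path: str | None = None
    k_clusters: int = 15
    n_normalizers: int = 6
    exclusion_list: tuple = ()
    nsf_aggregate: str = "median"
    sgof_alpha: float = 0.05
    sgof_gamma: float = 0.05
    sgof_p0: float = 0.5
    sgof_a0: float = 1.0
    sgof_b0: float = 1.0
    screen_alpha: float = 0.05
    perplexity: float = 2.0
    ap_damping: float = 0.9
    ap_preference: float | None = None
    correlation_B: int = 1000
    correlation_alpha: float = 0.05
    run_mrm: bool = True

    def __post_init__(self):
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclasses.dataclass
class PipelineResult:
    labels: object
    baseline_table: pd.DataFrame
    partition: object
    clustering: object
    selection: object
    normalized_runs: AbundanceMatrix
    normalized_samples: AbundanceMatrix
    lmm: object
    sgof: object
    significant_proteins: list
    gee: object
    screen: pd.DataFrame
    screen_summary: dict
    profiles: pd.DataFrame
    assignment: object
    correlation: CorrelationResult
    multi_index: pd.DataFrame
    mrm_validation: pd.DataFrame | None
    mrm_candidates: dict | None
    truth: object | None
    manifest: dict


def _stage_log(manifest, stage, **info):
    manifest["stages"].append({"stage": stage, **info})


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full analysis; optionally write artifacts under ``outdir``."""
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": json.loads(json.dumps(config.to_dict(), default=str)),
        "stages": [],
    }
    truth = None
    mrm_table = None
    if config.simulate:
        matrix, clinical, truth = generate_cohort(config.cohort)
        if config.run_mrm:
            mrm_table, _ = generate_mrm_cohort(seed=config.cohort.seed + 1)
    else:
        matrix = read_abundance_table(config.abundance_path)
        clinical = read_clinical_table(config.clinical_path, config.covariates_path)
        if config.run_mrm and config.mrm_path:
            mrm_table = read_mrm_table(config.mrm_path)
    _stage_log(manifest, "input", n_proteins=matrix.n_proteins, n_runs=matrix.n_runs)

    labels = derive_response_labels(clinical)
    baseline_table = compare_baseline_characteristics(clinical, labels)
    _stage_log(manifest, "response_labels",
               n_responders=len(labels.responders),
               n_non_responders=len(labels.non_responders))

    log2 = log_transform(matrix)
    centered = batch_mean_center(log2)
    imputer = LLSImputer(k=config.k_clusters)
    imputed_samples = imputer.fit_transform(centered)
    partition = imputer.partition_
    _stage_log(manifest, "preprocess",
               n_complete=len(partition.complete_ids),
               n_incomplete=len(partition.incomplete_ids),
               n_excluded=len(partition.excluded_ids))

    candidates = partition.complete_ids
    stability = normfinder_stability(
        imputed_samples.values.loc[candidates],
        imputed_samples.runs["group"],
    )
    group_p = lmm_group_pvalues(centered, proteins=candidates)
    raw_samples = unlog_transform(imputed_samples)
    normalizer = NSFNormalizer(
        n_normalizers=config.n_normalizers,
        aggregate=config.nsf_aggregate,
        ratio_summary=config.nsf_aggregate,
        exclusion_list=config.exclusion_list,
    ).fit(raw_samples, stability, group_p)
    selection = normalizer.selection_
    normalized_samples = log_transform(normalizer.transform(raw_samples))
    normalized_runs = log_transform(normalizer.transform(unlog_transform(centered)))
    # drop the normalizer panel itself from downstream marker testing
    analyzed = [p for p in normalized_runs.protein_ids
                if p not in set(selection.selected_ids)
                and p not in set(partition.excluded_ids)]
    _stage_log(manifest, "normalize", selected=list(selection.selected_ids),
               n_analyzed=len(analyzed))

    lmm = fit_lmm(normalized_runs, proteins=analyzed)
    ok = lmm.table[lmm.table.converged]
    sgof = sgof_bayesian(
        ok["interaction_p"].to_numpy(float),
        alpha=config.sgof_alpha, gamma=config.sgof_gamma,
        p0=config.sgof_p0, a0=config.sgof_a0, b0=config.sgof_b0,
    )
    significant = sorted(ok.index[sgof.flags])
    _stage_log(manifest, "lmm", n_converged=int(len(ok)),
               n_significant=len(significant))

    gee = fit_gee(normalized_samples, proteins=analyzed)
    screen = screen_timepoints(normalized_samples, labels)
    summary = screen_summary(screen, alpha=config.screen_alpha)
    _stage_log(manifest, "screens", **{k: v for k, v in summary["venn"].items()})

    profiled = significant if len(significant) >= 4 else sorted(ok.index)
    profiles = compute_delta_profiles(normalized_samples, labels, profiled)
    assignment = cluster_trajectories(
        profiles, preference=config.ap_preference, damping=config.ap_damping,
        perplexity=config.perplexity, seed=config.seed,
    )
    _stage_log(manifest, "clustering", n_clusters=assignment.n_clusters,
               converged=assignment.converged)

    correlation = correlate_indices(
        normalized_samples, clinical, B=config.correlation_B, seed=config.seed
    )
    multi = multi_index_screen(correlation, alpha=config.correlation_alpha)
    _stage_log(manifest, "correlation", n_multi_index=len(multi))

    mrm_validation = None
    mrm_candidates = None
    if mrm_table is not None:
        mrm_validation = wilcoxon_mrm_validation(mrm_table)
        mrm_candidates = select_mrm_candidates(screen, significant)
        _stage_log(manifest, "mrm",
                   n_validated=int(mrm_validation["validated"].sum()),
                   n_candidates=len(mrm_candidates["candidates"]))

    result = PipelineResult(
        labels=labels, baseline_table=baseline_table, partition=partition,
        clustering=imputer.clustering_, selection=selection,
        normalized_runs=normalized_runs, normalized_samples=normalized_samples,
        lmm=lmm, sgof=sgof, significant_proteins=significant, gee=gee,
        screen=screen, screen_summary=summary, profiles=profiles,
        assignment=assignment, correlation=correlation, multi_index=multi,
        mrm_validation=mrm_validation, mrm_candidates=mrm_candidates,
        truth=truth, manifest=manifest,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    labels_df = pd.DataFrame({"group": result.labels.labels})
    labels_df.join(result.labels.reductions.add_prefix("reduction_w")).to_csv(
        out / "response_labels.tsv", sep="\t")
    result.baseline_table.to_csv(out / "baseline_comparison.tsv", sep="\t", index=False)

    write_abundance_table(result.normalized_runs, out / "abundance_normalized.tsv")
    with open(out / "partition.json", "w") as fh:
        json.dump({"complete": result.partition.complete_ids,
                   "incomplete": result.partition.incomplete_ids,
                   "excluded": result.partition.excluded_ids}, fh, indent=2)
    with open(out / "normalizer_selection.json", "w") as fh:
        json.dump(result.selection.to_dict(), fh, indent=2, sort_keys=True)

    result.lmm.table.to_csv(out / "lmm_results.tsv", sep="\t")
    with open(out / "sgof.json", "w") as fh:
        json.dump({"n_significant": int(result.sgof.n_significant),
                   "significant_proteins": result.significant_proteins}, fh, indent=2)
    result.gee.table.to_csv(out / "gee_results.tsv", sep="\t")
    result.screen.to_csv(out / "screen.tsv", sep="\t", index=False)
    with open(out / "screen_summary.json", "w") as fh:
        json.dump(result.screen_summary, fh, indent=2, sort_keys=True)

    result.profiles.to_csv(out / "delta_profiles.tsv", sep="\t")
    pd.DataFrame({"cluster": result.assignment.labels}).to_csv(
        out / "clusters.tsv", sep="\t")
    if result.assignment.embedding is not None:
        result.assignment.embedding.to_csv(out / "embedding.tsv", sep="\t")
    with open(out / "exemplars.json", "w") as fh:
        json.dump({"exemplars": result.assignment.exemplars,
                   "preference": result.assignment.preference}, fh, indent=2)

    result.correlation.rho.to_csv(out / "correlation_rho.tsv", sep="\t")
    result.correlation.p.to_csv(out / "correlation_p.tsv", sep="\t")
    result.correlation.p_adj.to_csv(out / "correlation_p_adj.tsv", sep="\t")
    result.multi_index.to_csv(out / "multi_index_screen.tsv", sep="\t", index=False)

    if result.mrm_validation is not None:
        result.mrm_validation.to_csv(out / "mrm_validation.tsv", sep="\t")
        with open(out / "mrm_candidates.json", "w") as fh:
            json.dump({"candidates": result.mrm_candidates["candidates"],
                       "venn": result.mrm_candidates["venn"]}, fh, indent=2)

    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
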