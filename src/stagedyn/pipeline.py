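"""End-to-end orchestration of the staged transcriptomic dynamics analysis.

Order of stages: preprocess (filter + size factors + normalize) ->
differential expression -> PCA / covariate association -> transition
classification -> trend clustering -> co-expression network -> enrichment.
Each stage writes its tabular outputs under the output directory and the run
finishes with a JSON manifest (config echo, seeds, output row counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, diffexpr, enrichment, pca, preprocess, transitions, trends

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with study defaults.

    Defaults follow the study design where stated: fold change > 2 and
    FDR < 0.05 for DEG calling, CPM < 1 strict-majority inactive-gene filter,
    top 1,000 trend genes, 10,000 stage-label permutations.
    """

    counts_path: str = ""
    samples_path: str = ""
    gene_sets_path: str | None = None
    out_dir: str = "stagedyn_out"
    # preprocess
    cpm_threshold: float = 1.0
    # diffexpr
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    prior_count: float = 0.5
    exact_total_cap: int = 5000
    # pca (2000 genes so the 1000 trend genes below all carry loadings)
    n_top_var_genes: int = 2000
    n_pcs: int = 4
    # transitions
    tau: float = 1.0
    # trends
    n_trend_genes: int = 1000
    k_min: int = 1
    k_max: int = 10
    k_override: int | None = None
    # coexpression
    network_n_genes: int = 2000
    beta: float = 12.0
    cut_height: float = 0.8
    min_module_size: int = 30
    n_permutations: int = 10_000
    n_preservation_null: int = 200
    n_hubs: int = 20
    # global
    seed: int = 0


@dataclass
class PipelineResult:
    filtered_counts: pd.DataFrame
    size_factors: pd.Series
    normalized: preprocess.NormalizedMatrix
    contrasts: diffexpr.StageContrastTable
    overlap: dict
    pca_result: pca.PCAResult
    covariates: pca.CovariateAssociation
    transition_profiles: transitions.TransitionProfileTable | None
    trend_clusters: trends.TrendClustering
    network: coexpression.NetworkModel
    modules: coexpression.ModuleSet
    eigengenes: pd.DataFrame
    hubs: dict[int, list[str]]
    stage_association: pd.DataFrame
    preservation: pd.DataFrame
    enrichment_results: dict[str, pd.DataFrame]
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute every stage on the given (or loaded) inputs.

    ``counts``/``sheet`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": {}, "warnings": []}

    if counts is None:
        counts = preprocess.read_counts(config.counts_path)
    if sheet is None:
        sheet = preprocess.read_sample_sheet(config.samples_path)
    elif "stage" not in sheet.columns:
        sheet = preprocess.add_stage_labels(sheet)

    # --- preprocess
    logger.info("filtering %d genes x %d samples", *counts.shape)
    filtered = preprocess.filter_low_expression(counts, cpm_threshold=config.cpm_threshold)
    size_factors = preprocess.estimate_size_factors(filtered)
    norm = preprocess.normalize(filtered, size_factors)
    manifest["outputs"]["filtered_genes"] = int(filtered.shape[0])

    # --- per-stage differential expression
    lfc_threshold = float(np.log2(config.fc_threshold))
    contrasts = diffexpr.call_stage_degs(
        filtered,
        size_factors,
        sheet,
        lfc_threshold=lfc_threshold,
        fdr_threshold=config.fdr_threshold,
        prior_count=config.prior_count,
        exact_total_cap=config.exact_total_cap,
    )
    overlap = diffexpr.stage_overlap(contrasts)
    manifest["outputs"]["deg_union"] = overlap["union"]

    # --- PCA and covariate association
    pca_result = pca.compute_pca(norm, n_top_var_genes=config.n_top_var_genes)
    covariates = pca.covariate_association(pca_result, sheet, n_pcs=config.n_pcs)

    # --- transition classification on the DEG union
    deg_union = sorted(contrasts.deg_union())
    profiles: transitions.TransitionProfileTable | None = None
    if len(deg_union) >= 2:
        lrc = transitions.compute_lrc(contrasts, deg_union)
        profiles = transitions.classify_transitions(lrc, tau=config.tau)
    else:
        manifest["warnings"].append("fewer than 2 DEGs; transition classification skipped")

    # --- trend clustering on top-loading genes
    trend_genes = trends.select_trend_genes(pca_result, n=config.n_trend_genes)
    trend_clusters = trends.trend_cluster(
        norm,
        sheet,
        trend_genes,
        k_range=range(config.k_min, config.k_max + 1),
        seed=config.seed,
        k_override=config.k_override,
    )

    # --- co-expression network on tumor samples, preservation in controls
    tumor_ids = sheet.loc[sheet["condition"] == "tumor", "sample_id"].tolist()
    control_ids = sheet.loc[sheet["condition"] == "control", "sample_id"].tolist()
    logx = norm.log2
    tumor_var = logx[tumor_ids].var(axis=1)
    net_genes = tumor_var.sort_values(ascending=False, kind="stable").index[: config.network_n_genes]
    network = coexpression.build_network(logx.loc[net_genes, tumor_ids], beta=config.beta)
    modules = coexpression.detect_modules(
        network, cut_height=config.cut_height, min_size=config.min_module_size
    )
    eig_rows = {}
    assoc_rows = []
    for m in modules.modules():
        members = modules.members(m)
        eig, var_exp = coexpression.module_eigengene(logx.loc[:, tumor_ids + control_ids], members)
        eig_rows[m] = eig
        rho, p = coexpression.stage_association_permtest(
            eig, sheet, n_permutations=config.n_permutations, seed=config.seed + m
        )
        assoc_rows.append(
            {"module": m, "rho": rho, "pvalue": p, "B": config.n_permutations,
             "seed": config.seed + m, "variance_explained": var_exp}
        )
    eigengenes = pd.DataFrame(eig_rows).T
    eigengenes.index.name = "module"
    stage_association = pd.DataFrame(assoc_rows)
    hubs = coexpression.hub_genes(network, modules, n=config.n_hubs)
    if modules.modules() and control_ids:
        preservation = coexpression.preservation_z(
            network, modules, logx.loc[net_genes, control_ids],
            n_null=config.n_preservation_null, seed=config.seed,
        ).table
    else:
        preservation = pd.DataFrame(
            columns=["module", "z_density", "z_connectivity", "z_summary", "flag"]
        )

    # --- enrichment of per-stage DEG lists against optional GMT collections
    enrichment_results: dict[str, pd.DataFrame] = {}
    if config.gene_sets_path:
        collection = enrichment.read_gmt(config.gene_sets_path)
        universe = list(filtered.index)
        for week, degs in contrasts.deg_sets().items():
            if degs:
                enrichment_results[f"w{week}"] = enrichment.ora_test(degs, universe, collection)

    if write:
        _write_outputs(
            out, manifest, size_factors, contrasts, overlap, pca_result, covariates,
            profiles, trend_clusters, modules, eigengenes, hubs, stage_association,
            preservation, enrichment_results, filtered,
        )

    return PipelineResult(
        filtered_counts=filtered,
        size_factors=size_factors,
        normalized=norm,
        contrasts=contrasts,
        overlap=overlap,
        pca_result=pca_result,
        covariates=covariates,
        transition_profiles=profiles,
        trend_clusters=trend_clusters,
        network=network,
        modules=modules,
        eigengenes=eigengenes,
        hubs=hubs,
        stage_association=stage_association,
        preservation=preservation,
        enrichment_results=enrichment_results,
        manifest=manifest,
    )


def _write_outputs(
    out: Path, manifest: dict, size_factors, contrasts, overlap, pca_result, covariates,
    profiles, trend_clusters, modules, eigengenes, hubs, stage_association,
    preservation, enrichment_results, filtered,
) -> None:
    filtered.to_csv(out / "filtered_counts.tsv", sep="\t")
    preprocess.write_size_factors(size_factors, out / "size_factors.csv")
    for week, sub in contrasts.table.groupby("week"):
        sub.to_csv(out / f"contrasts_w{week}.tsv", sep="\t", index=False)
    (out / "deg_overlap.json").write_text(json.dumps(overlap, indent=2))
    pca_result.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pd.Series(pca_result.variance_ratio, name="variance_fraction").rename_axis("component").to_csv(
        out / "pca_variance.tsv", sep="\t"
    )
    covariates.neglog10_p.rename_axis("covariate").to_csv(out / "covariate_association.tsv", sep="\t")
    if profiles is not None:
        profiles.table.rename_axis("gene_id").to_csv(out / "transitions.tsv", sep="\t")
    trend_out = trend_clusters.ratios.copy()
    trend_out["cluster"] = trend_clusters.labels
    trend_out.to_csv(out / "trend_clusters.tsv", sep="\t")
    pd.Series(trend_clusters.wss, name="wss").rename_axis("k").to_csv(out / "trend_wss.csv")
    modules.assignment.rename_axis("gene_id").to_csv(out / "modules.tsv", sep="\t")
    eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    hub_rows = [
        {"module": m, "rank": i + 1, "gene_id": g}
        for m, genes in hubs.items()
        for i, g in enumerate(genes)
    ]
    pd.DataFrame(hub_rows, columns=["module", "rank", "gene_id"]).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    stage_association.to_csv(out / "stage_association.tsv", sep="\t", index=False)
    preservation.to_csv(out / "preservation.tsv", sep="\t", index=False)
    for name, table in enrichment_results.items():
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.csv")):
        with open(f) as fh:
            manifest["outputs"][f.name] = sum(1 for _ in fh) - 1
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
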