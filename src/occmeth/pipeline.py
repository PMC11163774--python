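"""End-to-end orchestration of the selection funnel.

Mirrors the study's analysis flow on simulated input: quality filtration ->
per-sample-set moderated differential methylation -> >=2-of-4 consensus ->
region annotation -> methylation-expression integration -> three pre-ranked
GSEAs with triple consensus and leading-edge intersection -> dependency
prioritization and the tumor/cell-line consistency filter -> the
Table-2-shaped candidate report.  Every stage is deterministic given the
simulation seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusteringResult, fisher_association, hierarchical_cluster
from .diffmeth import (DMThresholds, ModerationEstimate, annotate_and_count,
                       call_dm, consensus_dm, moderated_dm_test)
from .gsea import (GeneSetCollection, GseaResult, GseaThresholds, RankedList,
                   consensus_leading_edge, consensus_sets, preranked_gsea)
from .integrate import ExpressionMatrix, assemble_links, correct_batch
from .preprocess import FilterRules, MethylationMatrix, filter_probes
from .select import (DependencyTable, build_candidate_table, consistency_filter,
                     group_dependency_means, module_heatmap_order)
from .simdata import (SimConfig, SimTruth, simulate_beta_matrix,
                      simulate_dependency, simulate_expression, simulate_genesets)

__all__ = ["PipelineThresholds", "PipelineResult", "run_end_to_end", "gene_rankings"]

#: the three pre-ranked GSEA metrics, in their canonical order
METRICS = ("meth_log2fc", "expr_log2fc", "me_spearman")


@dataclass(frozen=True)
class PipelineThresholds:
    """Every cutoff of the selection funnel, with the study defaults."""

    dm: DMThresholds = field(default_factory=DMThresholds)
    min_consensus_sets: int = 2
    rho_cutoff: float = 0.25
    gsea: GseaThresholds = field(default_factory=GseaThresholds)
    n_perm: int = 1000
    gsea_weight: float = 1.0
    min_set_size: int = 5
    max_set_size: int = 500


@dataclass
class PipelineResult:
    """Everything the funnel produces, stage by stage."""

    config: SimConfig
    truth: SimTruth
    meth: MethylationMatrix
    filter_report: pd.Series
    clustering: ClusteringResult
    cluster_fisher_p: float
    per_set_results: dict[str, pd.DataFrame]
    moderation: dict[str, ModerationEstimate]
    per_set_calls: dict[str, pd.DataFrame]
    consensus: pd.DataFrame
    region_counts: pd.DataFrame
    n_consensus_genes: int
    expression: ExpressionMatrix
    links: pd.DataFrame
    rankings: dict[str, RankedList]
    collection: GeneSetCollection
    gsea_results: dict[str, list[GseaResult]]
    consensus_gene_sets: pd.DataFrame
    leading_edge_genes: list[str]
    dependency: DependencyTable
    dependency_means: pd.DataFrame
    consistent_genes: list[str]
    candidates: pd.DataFrame
    heatmap_membership: pd.DataFrame


def gene_rankings(links: pd.DataFrame) -> dict[str, RankedList]:
    """Per-gene scores for the three pre-ranked GSEAs.

    Each gene is represented by its consensus link with the largest
    |methylation log2FC|; that link supplies the gene's methylation score
    and its M-E Spearman rho, while the expression log2FC is the gene's own.
    Genes with any missing score are dropped so all three rankings share one
    universe.
    """
    if links.empty:
        return {}
    idx = links.groupby("gene")["meth_log2fc"].apply(lambda s: s.abs().idxmax())
    rep = links.loc[idx.to_numpy()].set_index("gene")
    rep = rep.dropna(subset=["meth_log2fc", "expr_log2fc", "rho"])
    return {
        "meth_log2fc": RankedList.from_scores("meth_log2fc", rep["meth_log2fc"]),
        "expr_log2fc": RankedList.from_scores("expr_log2fc", rep["expr_log2fc"]),
        "me_spearman": RankedList.from_scores("me_spearman", rep["rho"]),
    }


def run_end_to_end(
    config: SimConfig,
    thresholds: PipelineThresholds | None = None,
    filter_rules: FilterRules | None = None,
    n_decoy_sets: int = 50,
    decoy_size: int = 25,
) -> PipelineResult:
    """Simulate one study and run the complete selection funnel on it."""
    th = thresholds or PipelineThresholds()

    meth, truth = simulate_beta_matrix(config)
    meth, report = filter_probes(meth, filter_rules or FilterRules())

    # genome-wide clustering of tumors + ARID1A association (descriptive arm)
    tumors = [s for s, g in truth.sample_groups.items() if g.startswith("tumor")]
    clustering = hierarchical_cluster(meth.subset_samples(tumors), k=2)
    arid1a = pd.Series(
        {s: ("mt" if truth.sample_groups[s] == "tumor_mt" else "wt") for s in tumors},
        name="ARID1A",
    )
    fisher = fisher_association(clustering.labels, arid1a)

    per_set_results: dict[str, pd.DataFrame] = {}
    moderation: dict[str, ModerationEstimate] = {}
    per_set_calls: dict[str, pd.DataFrame] = {}
    for set_def in truth.sample_sets:
        res, mod = moderated_dm_test(meth, set_def)
        per_set_results[set_def.set_id] = res
        moderation[set_def.set_id] = mod
        per_set_calls[set_def.set_id] = call_dm(res, th.dm)

    consensus = consensus_dm(per_set_calls, min_sets=th.min_consensus_sets)
    counts, _, n_genes = annotate_and_count(consensus, truth.probe_annotation)

    expr = correct_batch(simulate_expression(truth, meth, config))
    layout = config.sample_layout()
    cell_samples = layout["cell_mt"] + layout["cell_wt"]
    links = assemble_links(
        consensus, truth.probe_annotation, per_set_results["cell_lines"],
        meth, expr, cell_samples, layout["cell_mt"], layout["cell_wt"],
        rho_cutoff=th.rho_cutoff,
    )

    rankings = gene_rankings(links)
    universe = list(rankings["meth_log2fc"].genes) if rankings else []
    # decoys drawn from the ranked universe so they compete in the GSEAs
    # (sets from outside it would be size-filtered away after intersection)
    collection = simulate_genesets(
        truth, config, n_decoy_sets=n_decoy_sets, decoy_size=decoy_size,
        universe=universe if len(universe) >= decoy_size else None)
    gsea_results = {
        metric: preranked_gsea(
            rankings[metric], collection, n_perm=th.n_perm, seed=config.seed,
            weight=th.gsea_weight, min_size=th.min_set_size,
            max_size=th.max_set_size,
        )
        for metric in METRICS if metric in rankings
    }
    cons_sets = consensus_sets(gsea_results, th.gsea)
    le_genes = consensus_leading_edge(gsea_results, th.gsea)

    dependency = simulate_dependency(truth, config)
    dep_means = group_dependency_means(dependency, le_genes)
    consistent = consistency_filter(consensus, truth.probe_annotation)
    candidates = build_candidate_table(links, consistent, le_genes, dep_means)
    membership, _, _ = module_heatmap_order(list(candidates.index), collection)

    return PipelineResult(
        config=config,
        truth=truth,
        meth=meth,
        filter_report=report,
        clustering=clustering,
        cluster_fisher_p=fisher.p,
        per_set_results=per_set_results,
        moderation=moderation,
        per_set_calls=per_set_calls,
        consensus=consensus,
        region_counts=counts,
        n_consensus_genes=n_genes,
        expression=expr,
        links=links,
        rankings=rankings,
        collection=collection,
        gsea_results=gsea_results,
        consensus_gene_sets=cons_sets,
        leading_edge_genes=le_genes,
        dependency=dependency,
        dependency_means=dep_means,
        consistent_genes=consistent,
        candidates=candidates,
        heatmap_membership=membership,
    )
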