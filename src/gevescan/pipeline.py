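"""End-to-end orchestration: from classified calls to classified islands
and the silencing/reactivation tables.

This is thin glue over the analysis modules; every step can also be run on
its own. Spike-in control contigs are excluded from genome-wide statistics
and used only for conversion QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import (
    island_detection,
    methylome_context,
    silencing_analysis,
    viral_annotation,
)
from .types import ExpressionTable, GenomeSequence, UNCLASSIFIED


@dataclass
class PipelineResult:
    context_summary: dict = field(default_factory=dict)   # condition -> summary frame
    global_cg: dict = field(default_factory=dict)         # condition -> float
    conversion_qc: tuple | None = None
    tracks: dict = field(default_factory=dict)
    islands: list = field(default_factory=list)
    classifications: list = field(default_factory=list)
    contribution: pd.DataFrame | None = None
    census: tuple | None = None
    promoter_records: pd.DataFrame | None = None
    decile_table: pd.DataFrame | None = None
    categories: pd.DataFrame | None = None
    reactivation: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None


def analysis_genome(genome: GenomeSequence, spike_chroms=()) -> GenomeSequence:
    keep = {c: s for c, s in genome.sequences.items() if c not in set(spike_chroms)}
    return GenomeSequence(keep, name=genome.name)


def run_full_analysis(
    genome: GenomeSequence,
    sites_by_condition: dict[str, pd.DataFrame],
    genes: list,
    tes: list,
    expr: ExpressionTable | None = None,
    de: pd.DataFrame | None = None,
    domains: pd.DataFrame | None = None,
    *,
    untreated_condition: str,
    treatment_condition: str | None = None,
    spike_sites: dict | None = None,
    spike_chroms: tuple = (),
    placed_chroms: set | None = None,
    unplaced_chroms: set | None = None,
    window_size_bp: int = island_detection.DEFAULT_WINDOW_BP,
    theta: float = island_detection.DEFAULT_THETA,
    max_gap_windows: int = island_detection.DEFAULT_MAX_GAP_WINDOWS,
    min_island_bp: int = island_detection.DEFAULT_MIN_ISLAND_BP,
    subwindow_bp: int = island_detection.DEFAULT_SUBWINDOW_BP,
    marker_catalog: pd.DataFrame | None = None,
    promoter_bp: int = silencing_analysis.DEFAULT_PROMOTER_BP,
    fdr: float = silencing_analysis.DEFAULT_FDR,
) -> PipelineResult:
    """Run the whole discovery pipeline on one untreated methylome, with
    optional treated methylome and expression/DE/domain tables."""
    res = PipelineResult()
    ana = analysis_genome(genome, spike_chroms)

    classified = {}
    for cond, sites in sites_by_condition.items():
        if (sites["context"] == UNCLASSIFIED).any():
            sites = methylome_context.classify_sites(genome, sites)
        sites = sites.loc[~sites["chrom"].isin(set(spike_chroms))]
        classified[cond] = sites
        res.context_summary[cond] = methylome_context.weighted_methylation(sites)
        res.global_cg[cond] = methylome_context.global_cg_level(sites)

    if spike_sites is not None:
        res.conversion_qc = methylome_context.conversion_qc(
            spike_sites["unmethylated"], spike_sites["methylated"]
        )

    untreated = classified[untreated_condition]
    res.tracks = island_detection.window_track(
        untreated, ana, window_size_bp=window_size_bp
    )
    called = island_detection.call_islands(
        res.tracks, theta=theta, max_gap_windows=max_gap_windows,
        min_island_bp=min_island_bp,
    )
    refined = island_detection.refine_islands(
        called, untreated, ana, subwindow_bp=subwindow_bp, theta=theta,
        window_size_bp=window_size_bp,
    )
    res.islands = island_detection.annotate_secondary_te(refined, tes)

    if domains is not None:
        catalog = (marker_catalog if marker_catalog is not None
                   else viral_annotation.load_marker_catalog())
        res.classifications = viral_annotation.classify_islands(
            res.islands, genes, domains, catalog
        )
        res.contribution = viral_annotation.contribution_stats(
            res.classifications, ana, genes
        )
        if placed_chroms is not None and unplaced_chroms is not None:
            res.census = viral_annotation.insertion_census(
                res.islands, set(placed_chroms), set(unplaced_chroms)
            )

    res.promoter_records = silencing_analysis.promoter_methylation(
        genes, untreated, ana, promoter_bp=promoter_bp
    )
    if de is not None:
        res.decile_table = silencing_analysis.decile_response_table(
            res.promoter_records, de, fdr=fdr
        )
    if expr is not None and treatment_condition is not None:
        baseline = [c for c in expr.tpm.columns if c != treatment_condition]
        res.categories = silencing_analysis.reactivation_categories(
            expr, [treatment_condition], baseline
        )
        if res.classifications:
            gene_classes = {}
            for c in res.classifications:
                for g in c.genes_inside:
                    gene_classes[g] = c.island_class
            res.reactivation = silencing_analysis.reactivation_summary(
                res.categories, gene_classes
            )
    if domains is not None and res.classifications:
        island_genes = {g for c in res.classifications for g in c.genes_inside}
        background = {g.gene_id for g in genes}
        res.enrichment = silencing_analysis.fisher_domain_enrichment(
            domains, island_genes, background
        )
    return res
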