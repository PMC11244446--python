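"""Quantify the 5mC-silencing relationship under demethylating treatment.

Three linked analyses:

* promoter-methylation deciles crossed with differential-expression
  direction after 5-azacytidine: if 5mC silences, genes with hypermethylated
  promoters should be almost exclusively up-regulated once methylation is
  removed;
* reactivation categories for viral/TE genes: "Aza" (transcribed only upon
  treatment), "Broad" (expressed in some baseline condition), "No" (never
  reaches the TPM threshold);
* two-sided Fisher exact enrichment of protein domains in island-encoded
  genes, with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .types import CG_OTHER, CG_SYM, ExpressionTable, GeneModel, GenomeSequence

log = logging.getLogger(__name__)

DEFAULT_PROMOTER_BP = 1_000
DEFAULT_MIN_PROMOTER_SITES = 5
DEFAULT_FDR = 0.01       # DE calls: adjusted p strictly below this
DEFAULT_TPM_THRESHOLD = 1.0

CATEGORY_AZA = "Aza"
CATEGORY_BROAD = "Broad"
CATEGORY_NO = "No"


def promoter_interval(gene: GeneModel, promoter_bp: int, chrom_length: int) -> tuple[int, int]:
    """Promoter = promoter_bp upstream of the TSS on the gene strand,
    truncated (not dropped) at contig edges."""
    if gene.strand == "-":
        start, end = gene.interval.end, gene.interval.end + promoter_bp
    else:
        start, end = gene.interval.start - promoter_bp, gene.interval.start
    return max(0, start), min(end, chrom_length)


def promoter_methylation(
    genes: list[GeneModel],
    sites: pd.DataFrame,
    genome: GenomeSequence,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    min_promoter_sites: int = DEFAULT_MIN_PROMOTER_SITES,
) -> pd.DataFrame:
    """Pooled promoter CG methylation per gene, with decile assignment.

    All CG contexts (CG_sym + CG_other) are pooled. Genes with fewer than
    ``min_promoter_sites`` informative promoter sites are excluded. Deciles
    are assigned by level rank with ties broken by gene id (stable); decile
    10 is the most methylated.
    """
    cg = sites.loc[sites["context"].isin((CG_SYM, CG_OTHER))]
    by_chrom = {}
    for chrom, grp in cg.groupby("chrom", sort=False):
        g = grp.sort_values("pos", kind="mergesort")
        by_chrom[chrom] = (
            g["pos"].to_numpy(), g["n_meth"].to_numpy(), g["n_total"].to_numpy()
        )
    rows = []
    for gene in genes:
        chrom = gene.interval.chrom
        start, end = promoter_interval(gene, promoter_bp, genome.length(chrom))
        if chrom not in by_chrom or end <= start:
            continue
        pos, meth, total = by_chrom[chrom]
        lo, hi = np.searchsorted(pos, (start, end))
        n_sites = hi - lo
        if n_sites < min_promoter_sites:
            continue
        t = total[lo:hi].sum()
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": chrom,
                "promoter_start": start,
                "promoter_end": end,
                "weighted_level": meth[lo:hi].sum() / t if t else np.nan,
                "n_sites": int(n_sites),
            }
        )
    columns = ["gene_id", "chrom", "promoter_start", "promoter_end",
               "weighted_level", "n_sites"]
    if not rows:
        return pd.DataFrame(columns=columns + ["decile"])
    records = pd.DataFrame(rows).dropna(subset=["weighted_level"])
    if len(records) == 0:
        return pd.DataFrame(columns=columns + ["decile"])
    records = records.sort_values(
        ["weighted_level", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(records)
    records["decile"] = (np.arange(n) * 10) // n + 1
    return records


def decile_response_table(
    records: pd.DataFrame,
    de: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    lfc_min: float = 0.0,
) -> pd.DataFrame:
    """10x3 table of DE direction (up / down / not_de) per promoter decile.

    A gene is DE iff padj < fdr (strict) and |log2FC| > lfc_min; direction is
    the sign of log2FC. Genes absent from the DE table count as not_de with
    a logged warning.
    """
    de_map = de.set_index("gene_id")
    missing = ~records["gene_id"].isin(de_map.index)
    if missing.any():
        log.warning("%d scored genes missing from DE table; counted not_de",
                    int(missing.sum()))
    table = pd.DataFrame(
        0, index=pd.RangeIndex(1, 11, name="decile"), columns=["up", "down", "not_de"]
    )
    joined = records.join(de_map, on="gene_id")
    padj = joined["padj"].to_numpy()
    lfc = joined["log2FC"].to_numpy()
    is_de = np.isfinite(padj) & (padj < fdr) & (np.abs(lfc) > lfc_min)
    direction = np.where(~is_de, "not_de", np.where(lfc > 0, "up", "down"))
    for dec, grp in pd.Series(direction).groupby(joined["decile"].to_numpy()):
        counts = grp.value_counts()
        for col in table.columns:
            table.loc[dec, col] = int(counts.get(col, 0))
    return table


def reactivation_categories(
    expr: ExpressionTable,
    treatment_conditions: list[str],
    baseline_conditions: list[str],
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each gene one transcriptional-response category.

    Broad iff any baseline TPM >= threshold; else Aza iff any treatment TPM
    >= threshold; else No. Requesting a gene absent from the table raises.
    """
    for c in (*treatment_conditions, *baseline_conditions):
        if c not in expr.tpm.columns:
            raise ValueError(f"unknown condition {c!r}")
    if genes is not None:
        unknown = [g for g in genes if g not in expr.tpm.index]
        if unknown:
            raise ValueError(f"genes absent from expression table: {unknown[:5]}")
        tpm = expr.tpm.loc[list(genes)]
    else:
        tpm = expr.tpm
    base = (tpm[list(baseline_conditions)] >= tpm_threshold).any(axis=1)
    treat = (tpm[list(treatment_conditions)] >= tpm_threshold).any(axis=1)
    category = np.where(base, CATEGORY_BROAD, np.where(treat, CATEGORY_AZA, CATEGORY_NO))
    return pd.DataFrame({"gene_id": tpm.index.to_numpy(), "category": category})


def reactivation_summary(
    categories: pd.DataFrame,
    gene_classes: dict[str, str],
    classes: tuple | None = None,
) -> pd.DataFrame:
    """Category counts and within-class percentages per gene class.

    ``gene_classes`` maps gene_id -> class label (e.g. GEVE, adintovirus,
    TE_ORF). Classes with zero genes keep a zero row.
    """
    if classes is None:
        classes = tuple(sorted(set(gene_classes.values())))
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    rows = []
    for cls in classes:
        members = [g for g, c in gene_classes.items() if c == cls]
        counts = {CATEGORY_AZA: 0, CATEGORY_BROAD: 0, CATEGORY_NO: 0}
        for g in members:
            cat = cat_map.get(g)
            if cat is not None:
                counts[cat] += 1
        total = sum(counts.values())
        row = {"class": cls, "n_genes": total}
        for cat, n in counts.items():
            row[f"n_{cat.lower()}"] = n
            row[f"pct_{cat.lower()}"] = 100.0 * n / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def fisher_domain_enrichment(
    domains: pd.DataFrame,
    gene_set: set,
    background_genes: set,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of each domain in ``gene_set``.

    The 2x2 table per domain is (in-set with domain, in-set without,
    out-set with, out-set without). Domains with no carrier inside the
    background are skipped (counted in the log). q-values are
    Benjamini-Hochberg across tested domains; output sorted by p.
    """
    gene_set = set(gene_set)
    background_genes = set(background_genes)
    if not gene_set <= background_genes:
        raise ValueError("gene_set must be a subset of background_genes")
    n_set = len(gene_set)
    n_out = len(background_genes) - n_set
    dom_in_bg = domains.loc[domains["gene_id"].isin(background_genes)]
    skipped = domains.loc[~domains["gene_id"].isin(background_genes),
                          "domain_accession"].nunique()
    if skipped:
        log.info("%d domains had no carrier in the background; skipped", skipped)
    rows = []
    for (acc, name), grp in dom_in_bg.groupby(["domain_accession", "domain_name"]):
        carriers = set(grp["gene_id"])
        a = len(carriers & gene_set)
        b = n_set - a
        c = len(carriers) - a
        d = n_out - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "domain_accession": acc, "domain_name": name,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds, "p_value": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result) == 0:
        return result
    result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.sort_values(
        ["p_value", "domain_accession"], kind="mergesort"
    ).reset_index(drop=True)
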