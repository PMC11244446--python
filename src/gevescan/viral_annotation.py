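"""Classify hypermethylated islands into viral/repeat categories.

Endogenized giant viral elements (GEVEs), adintovirus insertions and
"Plavaka" giant tandem repeats share a signature that separates them from
ordinary host chromatin: they are gene-dense, their genes are intron-poor
(host genes average ~7 exons, viral genes mostly 1), and they carry
recognisable marker genes (e.g. the poxvirus late transcription factor
VLTF3, A32-like packaging ATPase, D5 primase and NCLDV major capsid for
giant viruses; family-B DNA polymerase and capsid proteins for
adintoviruses; tyrosine recombinases flanked by a Plavaka transposase for
the giant repeats). Marker evidence comes from an input domain-hits table
intersected with a shipped, editable marker catalog; the classification
itself is a short ordered rule list with every evaluated rule logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .types import GeneModel, GenomeSequence, Island

CLASS_GEVE = "GEVE"
CLASS_ADINTO = "adintovirus"
CLASS_PLAVAKA = "plavaka"
CLASS_TE_RICH = "te_rich"
CLASS_UNCLASSIFIED = "unclassified"
ISLAND_CLASSES = (CLASS_GEVE, CLASS_ADINTO, CLASS_PLAVAKA, CLASS_TE_RICH, CLASS_UNCLASSIFIED)


def load_marker_catalog(path=None) -> pd.DataFrame:
    """Marker catalog: domain_accession, domain_name, marker_class, weight.

    Without a path, the catalog shipped with the package is used. Each marker
    maps to exactly one class.
    """
    if path is None:
        with resources.files("gevescan.data").joinpath("markers.tsv").open() as fh:
            cat = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        cat = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("domain_accession", "marker_class"):
        if col not in cat.columns:
            raise ValueError(f"marker catalog missing column {col!r}")
    if cat["domain_accession"].duplicated().any():
        raise ValueError("a marker maps to more than one class in the catalog")
    return cat


@dataclass
class RulesConfig:
    """Thresholds of the ordered classification rules (config defaults,
    approximations of the published manual curation, not recovered values)."""

    mean_exons_max: float = 2.0      # viral genes are intron-poor
    adinto_max_bp: int = 60_000      # complete adintovirus insertions are ~30 kb
    te_fraction_min: float = 0.6     # TE-dominated islands without viral markers
    gene_overlap_fraction: float = 0.5  # gene belongs to island iff >=50% span inside


@dataclass
class IslandClassification:
    island_id: str
    island: Island
    island_class: str
    evidence: list = field(default_factory=list)  # (feature, value, rule fired)
    genes_inside: list = field(default_factory=list)
    features: dict = field(default_factory=dict)


def island_gene_features(
    island: Island,
    genes: list[GeneModel],
    domains: pd.DataFrame | None = None,
    catalog: pd.DataFrame | None = None,
    min_overlap_fraction: float = 0.5,
) -> dict:
    """Gene-architecture features of one island.

    A gene is assigned to the island iff at least ``min_overlap_fraction`` of
    its span overlaps it. Features: mean_exons_per_gene (NaN-flagged when no
    genes), gene_density per 10 kb, island_length_bp, te_fraction, and marker
    hit counts per class (domain hits intersected with the catalog).
    """
    inside = []
    for g in genes:
        ov = g.interval.overlap(island.interval)
        if ov / g.interval.length >= min_overlap_fraction:
            inside.append(g)
    n_genes = len(inside)
    mean_exons = (
        float(np.mean([g.n_exons for g in inside])) if n_genes else float("nan")
    )
    features = {
        "island_length_bp": island.length,
        "n_genes": n_genes,
        "gene_density": n_genes / (island.length / 10_000),
        "mean_exons_per_gene": mean_exons,
        "te_fraction": float(island.interval.attrs.get("te_fraction", 0.0)),
        "genes_inside": [g.gene_id for g in inside],
    }
    marker_hits = {c: 0 for c in (CLASS_GEVE, CLASS_ADINTO, CLASS_PLAVAKA)}
    marker_domains: dict[str, list] = {c: [] for c in marker_hits}
    if domains is not None and catalog is not None and n_genes:
        gene_ids = set(features["genes_inside"])
        acc_to_class = dict(zip(catalog["domain_accession"], catalog["marker_class"]))
        hits = domains.loc[domains["gene_id"].isin(gene_ids)]
        for row in hits.itertuples(index=False):
            cls = acc_to_class.get(row.domain_accession)
            if cls in marker_hits:
                marker_hits[cls] += 1
                marker_domains[cls].append(row.domain_accession)
    features["marker_hits"] = marker_hits
    features["marker_domains"] = marker_domains
    return features


def classify_island(
    features: dict,
    catalog: pd.DataFrame,
    rules: RulesConfig | None = None,
) -> tuple[str, list]:
    """Apply the ordered rule list to one island's features.

    Decision order (first match wins; every evaluated rule is logged):
      1. any GEVE marker AND mean_exons_per_gene <= mean_exons_max -> GEVE
      2. any adintovirus marker AND island_length <= adinto_max_bp -> adintovirus
      3. any plavaka marker -> plavaka
      4. te_fraction >= te_fraction_min AND no viral markers -> te_rich
      5. otherwise unclassified
    """
    if catalog is None or len(catalog) == 0:
        raise ValueError("empty marker catalog")
    rules = rules or RulesConfig()
    hits = features["marker_hits"]
    mean_ex = features["mean_exons_per_gene"]
    evidence = []

    rule1 = hits[CLASS_GEVE] > 0 and np.isfinite(mean_ex) and mean_ex <= rules.mean_exons_max
    evidence.append(("geve_markers_and_intron_poor",
                     (hits[CLASS_GEVE], mean_ex), rule1))
    if rule1:
        return CLASS_GEVE, evidence

    rule2 = (hits[CLASS_ADINTO] > 0
             and features["island_length_bp"] <= rules.adinto_max_bp)
    evidence.append(("adinto_markers_and_compact",
                     (hits[CLASS_ADINTO], features["island_length_bp"]), rule2))
    if rule2:
        return CLASS_ADINTO, evidence

    rule3 = hits[CLASS_PLAVAKA] > 0
    evidence.append(("plavaka_markers", hits[CLASS_PLAVAKA], rule3))
    if rule3:
        return CLASS_PLAVAKA, evidence

    any_viral = hits[CLASS_GEVE] > 0 or hits[CLASS_ADINTO] > 0 or hits[CLASS_PLAVAKA] > 0
    rule4 = features["te_fraction"] >= rules.te_fraction_min and not any_viral
    evidence.append(("te_dominated_no_markers",
                     (features["te_fraction"], any_viral), rule4))
    if rule4:
        return CLASS_TE_RICH, evidence

    evidence.append(("fallback", None, True))
    return CLASS_UNCLASSIFIED, evidence


def classify_islands(
    islands: list[Island],
    genes: list[GeneModel],
    domains: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    rules: RulesConfig | None = None,
) -> list[IslandClassification]:
    """Feature extraction + rule classification for every island."""
    catalog = catalog if catalog is not None else load_marker_catalog()
    rules = rules or RulesConfig()
    out = []
    ordered = sorted(islands, key=lambda x: x.interval.sort_key())
    for i, isl in enumerate(ordered, 1):
        island_id = isl.interval.attrs.get("island_id", f"island_{i:03d}")
        isl.interval.attrs["island_id"] = island_id
        feats = island_gene_features(
            isl, genes, domains, catalog, min_overlap_fraction=rules.gene_overlap_fraction
        )
        cls, evidence = classify_island(feats, catalog, rules)
        out.append(
            IslandClassification(
                island_id=island_id, island=isl, island_class=cls,
                evidence=evidence, genes_inside=feats["genes_inside"], features=feats,
            )
        )
    return out


def contribution_stats(
    classifications: list[IslandClassification],
    genome: GenomeSequence,
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Per-class and overall contribution to assembly bases and gene counts.

    Also summarises the per-class insertion-size distribution (median, IQR).
    """
    genome_bp = sum(genome.length(c) for c in genome.sequences)
    n_genes_total = len(genes)
    rows = []
    for cls in (*ISLAND_CLASSES, "all"):
        group = (
            classifications
            if cls == "all"
            else [c for c in classifications if c.island_class == cls]
        )
        sizes = np.array([c.island.length for c in group], dtype=float)
        gene_count = sum(len(c.genes_inside) for c in group)
        rows.append(
            {
                "class": cls,
                "n_islands": len(group),
                "total_bp": int(sizes.sum()) if len(sizes) else 0,
                "pct_genome": 100.0 * sizes.sum() / genome_bp if len(sizes) else 0.0,
                "n_genes": gene_count,
                "pct_genes": 100.0 * gene_count / n_genes_total if n_genes_total else 0.0,
                "median_size_bp": float(np.median(sizes)) if len(sizes) else float("nan"),
                "iqr_size_bp": float(np.subtract(*np.percentile(sizes, [75, 25])))
                if len(sizes) else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def insertion_census(
    islands: list[Island],
    placed_chroms: set,
    unplaced_chroms: set,
) -> tuple[int, int]:
    """Count insertions on placed chromosomes vs unplaced contigs.

    An island on a sequence id in neither set is an error (misconfigured
    placement lists rather than silently miscounted).
    """
    n_chromosomal = n_unplaced = 0
    for isl in islands:
        if isl.chrom in placed_chroms:
            n_chromosomal += 1
        elif isl.chrom in unplaced_chroms:
            n_unplaced += 1
        else:
            raise ValueError(f"island on unknown sequence id {isl.chrom!r}")
    return n_chromosomal, n_unplaced


def classifications_to_table(classifications: list[IslandClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append(
            {
                "island_id": c.island_id,
                "chrom": c.island.chrom,
                "start": c.island.start,
                "end": c.island.end,
                "length_bp": c.island.length,
                "class": c.island_class,
                "mean_level": c.island.mean_level,
                "n_genes": c.features.get("n_genes", 0),
                "mean_exons_per_gene": c.features.get("mean_exons_per_gene", float("nan")),
                "gene_density_per_10kb": c.features.get("gene_density", 0.0),
                "te_fraction": c.features.get("te_fraction", 0.0),
                "genes_inside": ",".join(c.genes_inside),
            }
        )
    return pd.DataFrame(rows)
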