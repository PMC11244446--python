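"""Desk-scale synthetic methylome generator with full ground truth.

The generator emulates the statistical structure the analysis assumes:

* an intron-rich host genome whose gene bodies are methylated by extended
  CG context (CGC/GCG ~0.7, other CG ~0.2, giving a ~0.4 global CG level);
* age-stratified methylated TEs (methylation decaying with divergence);
* implanted intron-poor, gene-dense, uniformly hypermethylated islands of
  four kinds (GEVE, adintovirus, Plavaka repeat, TE-rich cluster), each
  carrying class-appropriate marker domains;
* a promoter-methylation continuum across genes with a configured monotone
  up-regulation dose-response in the simulated demethylation experiment;
* binomial read sampling at negative-binomial coverage, with a small
  conversion-error false-positive rate and unmethylated-lambda /
  methylated-pUC19 spike-in contigs;
* a treated condition whose methylation is reduced by a multiplicative
  factor (default 0.375, i.e. a ~0.40 -> ~0.15 global drop).

Everything is drawn from one seeded generator: a seed fully determines the
bundle, and every emitted feature appears in exactly one ground-truth
record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .methylome_context import classify_sites
from .types import (
    CG_OTHER,
    CG_SYM,
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    Island,
)
from .viral_annotation import (
    CLASS_ADINTO,
    CLASS_GEVE,
    CLASS_PLAVAKA,
    CLASS_TE_RICH,
)

GEVE_MARKERS = ("PF04947", "PF04665", "PF03288", "PF04451")
ADINTO_REQUIRED = ("PF00136", "ADV_MCP", "ADV_mCP")
ADINTO_SUPPORTING = ("PF05869",)
PLAVAKA_MARKERS = ("PF00589", "PLV_TPASE")
JMJC = "PF02373"
HOST_DOMAIN_POOL = (
    "PF00069", "PF00076", "PF00400", "PF07690", "PF00153", "PF00005",
    "PF00271", "PF04851", "PF00149", "PF00560", "PF00226", "PF00568",
    "PF01535", "PF00169", "PF00018",
)


@dataclass
class SimConfig:
    """All knobs of the simulation; the seed fully determines the bundle."""

    seed: int = 1
    chrom_bp: dict = field(
        default_factory=lambda: {"chr1": 1_800_000, "scaffold_1": 200_000}
    )
    placed_chroms: tuple = ("chr1",)
    unplaced_chroms: tuple = ("scaffold_1",)
    gc_content: float = 0.45

    # host genes (intron-rich, methylated gene bodies)
    n_host_genes: int = 160
    host_exons_per_gene_mean: float = 7.2
    host_exon_bp: tuple = (80, 300)
    host_intron_bp: tuple = (80, 300)

    # host TEs (age-stratified methylation)
    n_host_tes: int = 40
    host_te_bp: tuple = (500, 2_000)
    host_te_divergence: tuple = (2.0, 30.0)

    # implanted islands
    n_geve: int = 6
    n_adinto: int = 4
    n_plavaka: int = 2
    n_te_rich: int = 2
    geve_bp: tuple = (30_000, 80_000)
    adinto_bp: tuple = (20_000, 40_000)
    plavaka_bp: tuple = (20_000, 45_000)
    te_rich_bp: tuple = (20_000, 35_000)
    island_margin_bp: int = 35_000
    island_halo_bp: int = 12_000   # host features keep this clearance around islands
    island_gene_density_per_10kb: float = 4.0
    te_rich_gene_density_per_10kb: float = 1.5
    island_gene_bp: tuple = (700, 1_300)

    # methylation probabilities
    p_cg_sym_host: float = 0.7
    p_cg_other_host: float = 0.2
    p_island: float = 0.8
    p_te_max: float = 0.9
    te_divergence_slope: float = 0.02     # p_te = p_te_max - slope * divergence
    host_promoter_p: tuple = (0.02, 0.75)  # continuum; >= silent_promoter_p => silent
    island_promoter_p: tuple = (0.55, 0.95)
    silent_promoter_p: float = 0.5
    promoter_bp: int = 1_000

    # read sampling
    coverage_mean: float = 20.0
    coverage_dispersion: float = 10.0     # negative-binomial size parameter
    conversion_error: float = 0.005
    treatment_factor: float = 0.375       # multiplicative 5mC reduction under treatment
    chg_emit_fraction: float = 0.05
    chh_emit_fraction: float = 0.02

    # conditions
    baseline_conditions: tuple = ("control", "development")
    treatment_condition: str = "aza"

    # spike-ins
    lambda_bp: int = 5_000
    puc19_bp: int = 2_700
    lambda_chrom: str = "lambda_spike"
    puc19_chrom: str = "puc19_spike"

    # expression / reactivation design
    aza_fraction: dict = field(
        default_factory=lambda: {
            CLASS_GEVE: 0.26, CLASS_ADINTO: 0.32, CLASS_PLAVAKA: 0.25, CLASS_TE_RICH: 0.25,
        }
    )
    broad_fraction: float = 0.05
    up_fraction_by_decile: tuple = (
        0.02, 0.05, 0.10, 0.18, 0.28, 0.40, 0.52, 0.66, 0.80, 0.95,
    )
    down_fraction_by_decile: tuple = (
        0.30, 0.26, 0.22, 0.18, 0.14, 0.10, 0.06, 0.04, 0.02, 0.01,
    )

    def analysis_chroms(self) -> tuple:
        return tuple(self.chrom_bp)


@dataclass
class GroundTruth:
    """Ground truth for every emitted feature."""

    islands: list            # GenomicInterval with attrs true_class, island_id
    gene_category: dict      # gene_id -> Aza/Broad/No
    gene_class: dict         # gene_id -> island class or "host"
    promoter_p: dict         # gene_id -> true promoter methylation probability
    de_status: dict          # gene_id -> up/down/none
    sites: pd.DataFrame      # chrom,pos,strand,context,region,p_true (untreated)
    config: SimConfig


@dataclass
class SimBundle:
    genome: GenomeSequence
    genes: list
    tes: list
    sites_by_condition: dict          # condition -> classified sites frame
    spike_sites_by_condition: dict    # condition -> {unmethylated, methylated} frames
    expression: ExpressionTable
    de: pd.DataFrame
    domains: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir) -> dict:
        """Write the bundle in the standard external formats; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["fasta"] = out / "genome.fa"
        io_formats.write_fasta(self.genome, paths["fasta"])
        paths["gff3"] = out / "genes.gff3"
        io_formats.write_gff3(self.genes, paths["gff3"])
        paths["te_table"] = out / "tes.tsv"
        io_formats.write_te_table(self.tes, paths["te_table"])
        for cond, sites in self.sites_by_condition.items():
            spikes = self.spike_sites_by_condition[cond]
            full = pd.concat(
                [sites, spikes["unmethylated"], spikes["methylated"]], ignore_index=True
            ).sort_values(["chrom", "pos", "strand"], kind="mergesort")
            paths[f"cgmap_{cond}"] = out / f"{cond}.cgmap"
            io_formats.write_cgmap(full, paths[f"cgmap_{cond}"])
        paths["tpm"] = out / "tpm.tsv"
        self.expression.tpm.rename_axis("gene_id").reset_index().to_csv(
            paths["tpm"], sep="\t", index=False
        )
        paths["groups"] = out / "condition_groups.tsv"
        pd.DataFrame(
            {"condition": list(self.expression.groups),
             "group": list(self.expression.groups.values())}
        ).to_csv(paths["groups"], sep="\t", index=False)
        paths["de"] = out / "de.tsv"
        self.de.to_csv(paths["de"], sep="\t", index=False)
        paths["domains"] = out / "domains.tsv"
        self.domains.to_csv(paths["domains"], sep="\t", index=False)
        paths["truth_islands"] = out / "truth_islands.tsv"
        pd.DataFrame(
            [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "class": iv.attrs["true_class"], "island_id": iv.attrs["island_id"]}
                for iv in self.truth.islands
            ]
        ).to_csv(paths["truth_islands"], sep="\t", index=False)
        paths["truth_genes"] = out / "truth_genes.tsv"
        pd.DataFrame(
            {
                "gene_id": list(self.truth.gene_category),
                "category": list(self.truth.gene_category.values()),
                "gene_class": [self.truth.gene_class[g] for g in self.truth.gene_category],
                "promoter_p": [self.truth.promoter_p[g] for g in self.truth.gene_category],
                "de_status": [self.truth.de_status[g] for g in self.truth.gene_category],
            }
        ).to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.6f")
        paths["config"] = out / "sim_config.json"
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        paths["config"].write_text(json.dumps(cfg, indent=2, default=str))
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return codes.tobytes().decode("ascii")


def _place_on_chrom(rng, chrom_len: int, lengths: list[int], margin: int) -> list[int]:
    """Non-overlapping starts with >= margin between/around; raises if unfit."""
    k = len(lengths)
    slack = chrom_len - sum(lengths) - (k + 1) * margin
    if slack < 0:
        raise ValueError(
            f"islands (total {sum(lengths)} bp + margins) do not fit in {chrom_len} bp"
        )
    extra = rng.multinomial(slack, np.full(k + 1, 1 / (k + 1)))
    starts, cursor = [], 0
    for i, L in enumerate(lengths):
        cursor += margin + int(extra[i])
        starts.append(cursor)
        cursor += L
    return starts


def _interval_complement(chrom_len: int, occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    free, cursor = [], 0
    for s, e in sorted(occupied):
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < chrom_len:
        free.append((cursor, chrom_len))
    return free


def _count_round(fraction: float, n: int) -> int:
    return int(round(fraction * n))


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate(config: SimConfig | None = None, out_dir=None) -> SimBundle:
    """Generate a full bundle (genome, annotations, methylomes, tables, truth)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    sequences = {c: _random_sequence(rng, L, cfg.gc_content)
                 for c, L in cfg.chrom_bp.items()}
    sequences[cfg.lambda_chrom] = _random_sequence(rng, cfg.lambda_bp, 0.5)
    sequences[cfg.puc19_chrom] = _random_sequence(rng, cfg.puc19_bp, 0.5)
    genome = GenomeSequence(sequences, name=f"sim_seed{cfg.seed}")

    truth_islands = _plan_islands(rng, cfg)
    genes, tes, gene_meta = _plan_annotation(rng, cfg, genome, truth_islands)
    expr, de, domains, truth_tables = _design_experiment(rng, cfg, gene_meta)
    sites_by_condition, spike_by_condition, truth_sites = _sample_methylomes(
        rng, cfg, genome, truth_islands, tes, gene_meta
    )

    truth = GroundTruth(
        islands=truth_islands,
        gene_category=truth_tables["category"],
        gene_class=truth_tables["gene_class"],
        promoter_p=truth_tables["promoter_p"],
        de_status=truth_tables["de_status"],
        sites=truth_sites,
        config=cfg,
    )
    bundle = SimBundle(
        genome=genome, genes=genes, tes=tes,
        sites_by_condition=sites_by_condition,
        spike_sites_by_condition=spike_by_condition,
        expression=expr, de=de, domains=domains, truth=truth, config=cfg,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _plan_islands(rng, cfg: SimConfig) -> list[GenomicInterval]:
    specs = []  # (class, length)
    for cls, n, rng_bp in (
        (CLASS_GEVE, cfg.n_geve, cfg.geve_bp),
        (CLASS_ADINTO, cfg.n_adinto, cfg.adinto_bp),
        (CLASS_PLAVAKA, cfg.n_plavaka, cfg.plavaka_bp),
        (CLASS_TE_RICH, cfg.n_te_rich, cfg.te_rich_bp),
    ):
        for _ in range(n):
            specs.append((cls, int(rng.integers(rng_bp[0], rng_bp[1] + 1))))
    # one adintovirus + one plavaka live on the unplaced contig (when available)
    unplaced = []
    for want in (CLASS_ADINTO, CLASS_PLAVAKA):
        for i, (cls, L) in enumerate(specs):
            if cls == want and i not in unplaced:
                unplaced.append(i)
                break
    chrom_of = {}
    placed_chrom = cfg.placed_chroms[0]
    unplaced_chrom = cfg.unplaced_chroms[0] if cfg.unplaced_chroms else placed_chrom
    for i in range(len(specs)):
        chrom_of[i] = unplaced_chrom if i in unplaced and cfg.unplaced_chroms else placed_chrom

    islands: list[GenomicInterval] = []
    idx = 0
    for chrom in cfg.chrom_bp:
        members = [i for i in range(len(specs)) if chrom_of[i] == chrom]
        if not members:
            continue
        order = rng.permutation(len(members))
        members = [members[int(o)] for o in order]
        lengths = [specs[i][1] for i in members]
        starts = _place_on_chrom(rng, cfg.chrom_bp[chrom], lengths, cfg.island_margin_bp)
        for i, start in zip(members, starts):
            idx += 1
            cls, L = specs[i]
            islands.append(
                GenomicInterval(
                    chrom, start, start + L, ".", kind="island",
                    attrs={"true_class": cls, "island_id": f"truth_{idx:02d}"},
                )
            )
    return sorted(islands, key=lambda iv: iv.sort_key())


def _make_gene(rng, cfg, chrom, start, strand, gene_id, n_exons, exon_bp, intron_bp):
    exon_lens = rng.integers(exon_bp[0], exon_bp[1] + 1, size=n_exons)
    intron_lens = (
        rng.integers(intron_bp[0], intron_bp[1] + 1, size=n_exons - 1)
        if n_exons > 1 else np.array([], dtype=int)
    )
    exons, cursor = [], start
    for i, L in enumerate(exon_lens):
        exons.append((cursor, cursor + int(L)))
        cursor += int(L)
        if i < len(intron_lens):
            cursor += int(intron_lens[i])
    interval = GenomicInterval(chrom, start, cursor, strand, kind="gene",
                               attrs={"gene_id": gene_id})
    return GeneModel(
        gene_id=gene_id,
        interval=interval,
        exons=[GenomicInterval(chrom, s, e, strand, kind="exon") for s, e in exons],
    )


def _plan_annotation(rng, cfg: SimConfig, genome: GenomeSequence, islands):
    """Genes (island + host), TEs, and per-gene design metadata."""
    genes: list[GeneModel] = []
    tes: list[GenomicInterval] = []
    gene_meta: list[dict] = []  # gene_id, class, promoter interval, island_id

    # --- island genes and island TEs
    v_counter = 0
    for isl in islands:
        cls = isl.attrs["true_class"]
        density = (
            cfg.te_rich_gene_density_per_10kb if cls == CLASS_TE_RICH
            else cfg.island_gene_density_per_10kb
        )
        n_genes = max(1, int(isl.length * density / 10_000))
        pitch = isl.length / n_genes
        if cls == CLASS_TE_RICH:
            # tile with young TEs (the hypermethylation source is TE-like)
            cursor = isl.start + int(rng.integers(20, 120))
            while cursor + 800 < isl.end:
                L = int(rng.integers(1_000, 2_500))
                e = min(cursor + L, isl.end - 10)
                div = float(rng.uniform(0.0, 5.0))
                span = float(rng.uniform(0.8, 1.0))
                tes.append(GenomicInterval(
                    isl.chrom, cursor, e, rng.choice(["+", "-"]), kind="TE",
                    attrs={"family": "TErich#LTR/Gypsy", "divergence": div,
                           "consensus_length": int((e - cursor) / span),
                           "consensus_span_fraction": span,
                           "in_island": isl.attrs["island_id"]},
                ))
                cursor = e + int(rng.integers(50, 200))
        elif cls == CLASS_GEVE and rng.random() < 0.5:
            # occasional secondary TE insertions inside GEVEs
            for _ in range(int(rng.integers(1, 3))):
                s = int(rng.integers(isl.start + 2_000, isl.end - 4_000))
                L = int(rng.integers(500, 1_500))
                div = float(rng.uniform(0.0, 10.0))
                tes.append(GenomicInterval(
                    isl.chrom, s, s + L, rng.choice(["+", "-"]), kind="TE",
                    attrs={"family": "Secondary#DNA/hAT", "divergence": div,
                           "consensus_length": int(L / 0.9),
                           "consensus_span_fraction": 0.9,
                           "in_island": isl.attrs["island_id"]},
                ))
        for j in range(n_genes):
            # fixed slots: gene + its 1-kb promoter stay inside the slot, so
            # promoter intervals of neighbouring island genes never overlap
            slot_start = isl.start + int(j * pitch)
            slot_end = isl.start + int((j + 1) * pitch)
            max_len = min(cfg.island_gene_bp[1], slot_end - slot_start - cfg.promoter_bp - 150)
            if max_len < cfg.island_gene_bp[0] or slot_end > isl.end:
                continue
            v_counter += 1
            gid = f"v{v_counter:04d}"
            gene_len = int(rng.integers(cfg.island_gene_bp[0], max_len + 1))
            strand = str(rng.choice(["+", "-"]))
            if strand == "+":
                g_start = slot_start + cfg.promoter_bp + int(rng.integers(0, 50))
            else:
                g_start = slot_start + 50 + int(rng.integers(0, 50))
            n_ex = 1 if rng.random() < 0.7 else 2
            if n_ex == 1:
                exon_spans = [(g_start, g_start + gene_len)]
            else:
                intron = int(rng.integers(60, 150))
                a = (gene_len - intron) // 2
                exon_spans = [(g_start, g_start + a),
                              (g_start + a + intron, g_start + gene_len)]
            gene = GeneModel(
                gene_id=gid,
                interval=GenomicInterval(isl.chrom, g_start, g_start + gene_len,
                                         strand, kind="gene", attrs={"gene_id": gid}),
                exons=[GenomicInterval(isl.chrom, s, e, strand, kind="exon")
                       for s, e in exon_spans],
            )
            genes.append(gene)
            gene_meta.append({
                "gene_id": gid, "gene_class": cls, "gene": gene,
                "island_id": isl.attrs["island_id"],
            })

    # --- host genes and host TEs share the non-island space; the clearance
    # around islands keeps boundary refinement against clean background
    halo = cfg.island_halo_bp
    occupied = {c: [] for c in cfg.chrom_bp}
    for isl in islands:
        occupied[isl.chrom].append((isl.start - halo, isl.end + halo))
    free: list[tuple[str, int, int]] = []
    for chrom, L in cfg.chrom_bp.items():
        for s, e in _interval_complement(L, occupied[chrom]):
            if e - s > 6_000:
                free.append((chrom, s + 500, e - 500))

    items = (["gene"] * cfg.n_host_genes) + (["te"] * cfg.n_host_tes)
    items = [items[int(i)] for i in rng.permutation(len(items))]
    h_counter = t_counter = 0
    fi = 0
    chrom, cursor, limit = free[0][0], free[0][1], free[0][2]
    for item in items:
        placed = False
        while not placed:
            if item == "gene":
                n_ex = 1 + int(rng.poisson(cfg.host_exons_per_gene_mean - 1))
                need_probe = cfg.promoter_bp + 50
                gene_try = _make_gene(
                    rng, cfg, chrom, cursor + need_probe, str(rng.choice(["+", "-"])),
                    f"h{h_counter + 1:04d}", n_ex, cfg.host_exon_bp, cfg.host_intron_bp,
                )
                need = need_probe + gene_try.interval.length + cfg.promoter_bp + 50
            else:
                te_len = int(rng.integers(*cfg.host_te_bp))
                need = te_len + int(rng.integers(800, 2_500))
            if cursor + need <= limit:
                if item == "gene":
                    h_counter += 1
                    genes.append(gene_try)
                    gene_meta.append({
                        "gene_id": gene_try.gene_id, "gene_class": "host",
                        "gene": gene_try, "island_id": None,
                    })
                else:
                    t_counter += 1
                    div = float(rng.uniform(*cfg.host_te_divergence))
                    span = float(rng.uniform(0.5, 1.0))
                    tes.append(GenomicInterval(
                        chrom, cursor, cursor + te_len, str(rng.choice(["+", "-"])),
                        kind="TE",
                        attrs={"family": f"Host#LTR/Copia_{t_counter % 5}",
                               "divergence": div,
                               "consensus_length": int(te_len / span),
                               "consensus_span_fraction": span,
                               "in_island": None},
                    ))
                cursor += need
                placed = True
            else:
                fi += 1
                if fi >= len(free):
                    raise ValueError(
                        "ran out of genome space placing host features; "
                        "reduce n_host_genes/n_host_tes or enlarge chrom_bp"
                    )
                chrom, cursor, limit = free[fi][0], free[fi][1], free[fi][2]
    genes.sort(key=lambda g: g.interval.sort_key())
    tes.sort(key=lambda t: t.sort_key())
    return genes, tes, gene_meta


def _design_experiment(rng, cfg: SimConfig, gene_meta):
    """Promoter-methylation continuum, DE flags, categories, TPMs, domains."""
    n = len(gene_meta)
    for m in gene_meta:
        if m["gene_class"] == "host":
            m["promoter_p"] = float(rng.uniform(*cfg.host_promoter_p))
        else:
            m["promoter_p"] = float(rng.uniform(*cfg.island_promoter_p))

    # DE flags along the true promoter-methylation ranking. The configured
    # per-decile up fractions are interpolated into a smooth dose-response
    # f(q) and realised by systematic (cumulative-floor) sampling: local up
    # density equals f exactly, with no extra selection noise, so the
    # configured monotone response is a property of the design, not of luck.
    order = sorted(range(n), key=lambda i: (gene_meta[i]["promoter_p"],
                                            gene_meta[i]["gene_id"]))
    q = (np.arange(n) + 0.5) / n
    centers = (np.arange(10) + 0.5) / 10
    f_up = np.interp(q, centers, np.asarray(cfg.up_fraction_by_decile))
    cum = np.cumsum(f_up)
    up_mark = np.floor(cum) > np.floor(np.concatenate(([0.0], cum[:-1])))
    de_status = {m["gene_id"]: "none" for m in gene_meta}
    for r, i in enumerate(order):
        if up_mark[r]:
            de_status[gene_meta[i]["gene_id"]] = "up"
    for dec in range(10):
        lo, hi = (dec * n) // 10, ((dec + 1) * n) // 10
        block = [order[i] for i in range(lo, hi)]
        rest = [i for i in block if de_status[gene_meta[i]["gene_id"]] == "none"]
        k_dn = min(len(rest), _count_round(cfg.down_fraction_by_decile[dec], len(block)))
        downs = list(rng.choice(rest, size=k_dn, replace=False)) if k_dn else []
        for i in downs:
            de_status[gene_meta[i]["gene_id"]] = "down"

    # transcriptional-response categories
    category = {}
    by_class: dict[str, list] = {}
    for m in gene_meta:
        by_class.setdefault(m["gene_class"], []).append(m["gene_id"])
    for cls, members in by_class.items():
        if cls == "host":
            continue
        members = sorted(members)
        k_aza = _count_round(cfg.aza_fraction.get(cls, 0.25), len(members))
        k_broad = _count_round(cfg.broad_fraction, len(members))
        picks = list(rng.choice(members, size=min(len(members), k_aza + k_broad),
                                replace=False))
        for g in picks[:k_aza]:
            category[g] = "Aza"
        for g in picks[k_aza:]:
            category[g] = "Broad"
        for g in members:
            category.setdefault(g, "No")
    for m in gene_meta:
        if m["gene_class"] != "host":
            continue
        gid = m["gene_id"]
        if m["promoter_p"] < cfg.silent_promoter_p:
            category[gid] = "Broad"
        elif de_status[gid] == "up":
            category[gid] = "Aza"
        else:
            category[gid] = "No"

    # TPM table: margins keep the category decision unambiguous
    def expressed_tpm(size):
        return 1.5 + rng.lognormal(mean=1.0, sigma=0.8, size=size)

    def silent_tpm(size):
        return rng.uniform(0.0, 0.4, size=size)

    gene_ids = [m["gene_id"] for m in gene_meta]
    cols = {}
    cat_arr = np.array([category[g] for g in gene_ids])
    broad = cat_arr == "Broad"
    aza_cat = cat_arr == "Aza"
    for cond in cfg.baseline_conditions:
        col = silent_tpm(n)
        col[broad] = expressed_tpm(int(broad.sum()))
        cols[cond] = col
    lfc = np.empty(n)
    padj = np.empty(n)
    for i, g in enumerate(gene_ids):
        s = de_status[g]
        if s == "up":
            lfc[i] = rng.uniform(1.0, 3.5)
            padj[i] = 10 ** rng.uniform(-6.0, -2.21)
        elif s == "down":
            lfc[i] = -rng.uniform(1.0, 3.5)
            padj[i] = 10 ** rng.uniform(-6.0, -2.21)
        else:
            lfc[i] = rng.normal(0.0, 0.2)
            padj[i] = rng.uniform(0.02, 1.0)
    treat = cols[cfg.baseline_conditions[0]] * np.exp2(lfc)
    treat[aza_cat] = expressed_tpm(int(aza_cat.sum()))
    no_cat = cat_arr == "No"
    treat[no_cat] = np.minimum(treat[no_cat], 0.9)
    cols[cfg.treatment_condition] = treat

    tpm = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    groups = {c: ("control" if c == "control" else "development")
              for c in cfg.baseline_conditions}
    groups[cfg.treatment_condition] = "treatment"
    expr = ExpressionTable(tpm=tpm, groups=groups)
    de = pd.DataFrame({"gene_id": gene_ids, "log2FC": lfc, "padj": padj})

    # domain hits
    hits: set[tuple[str, str]] = set()
    by_island: dict[str, list] = {}
    for m in gene_meta:
        if m["island_id"] is not None:
            by_island.setdefault(m["island_id"], []).append(m)
    for island_id, members in sorted(by_island.items()):
        cls = members[0]["gene_class"]
        ids = sorted(m["gene_id"] for m in members)
        if cls == CLASS_GEVE:
            k = min(len(ids), int(rng.integers(3, 6)))
            carriers = rng.choice(ids, size=k, replace=False)
            for g in carriers:
                hits.add((g, str(rng.choice(GEVE_MARKERS))))
            for g in ids:
                if rng.random() < 0.20:
                    hits.add((g, JMJC))
        elif cls == CLASS_ADINTO:
            carriers = rng.choice(ids, size=min(len(ids), 3), replace=False)
            hits.add((carriers[0], ADINTO_REQUIRED[0]))  # DNA pol B always present
            for g in carriers[1:]:
                hits.add((g, str(rng.choice(ADINTO_REQUIRED + ADINTO_SUPPORTING))))
        elif cls == CLASS_PLAVAKA:
            for g in ids:
                if rng.random() < 0.3:
                    hits.add((g, PLAVAKA_MARKERS[0]))
            hits.add((ids[0], PLAVAKA_MARKERS[1]))
    for m in gene_meta:
        if m["gene_class"] == "host":
            for _ in range(int(rng.poisson(1.0))):
                hits.add((m["gene_id"], str(rng.choice(HOST_DOMAIN_POOL))))
            if rng.random() < 0.01:
                hits.add((m["gene_id"], JMJC))
    domains = pd.DataFrame(sorted(hits), columns=["gene_id", "domain_accession"])
    domains["domain_name"] = domains["domain_accession"]

    truth_tables = {
        "category": category,
        "gene_class": {m["gene_id"]: m["gene_class"] for m in gene_meta},
        "promoter_p": {m["gene_id"]: m["promoter_p"] for m in gene_meta},
        "de_status": de_status,
    }
    return expr, de, domains, truth_tables


def _cytosine_positions(arr: np.ndarray):
    """(plus_pos, minus_pos) of every cytosine on each strand."""
    plus = np.flatnonzero(arr == ord("C"))
    minus = np.flatnonzero(arr == ord("G"))
    return plus, minus


def _sample_methylomes(rng, cfg: SimConfig, genome, islands, tes, gene_meta):
    frames = []
    for chrom in cfg.chrom_bp:
        arr = genome.as_array(chrom)
        plus, minus = _cytosine_positions(arr)
        # thin non-CG cytosines; CG cytosines all kept
        next_is_g = np.zeros(len(arr), dtype=bool)
        next_is_g[:-1] = arr[1:] == ord("G")
        prev_is_c = np.zeros(len(arr), dtype=bool)
        prev_is_c[1:] = arr[:-1] == ord("C")
        plus_cg = plus[next_is_g[plus]]
        minus_cg = minus[prev_is_c[minus]]
        plus_non = plus[~next_is_g[plus]]
        minus_non = minus[~prev_is_c[minus]]
        keep_frac = (cfg.chg_emit_fraction + cfg.chh_emit_fraction) / 2
        plus_non = rng.choice(plus_non, size=int(len(plus_non) * keep_frac), replace=False)
        minus_non = rng.choice(minus_non, size=int(len(minus_non) * keep_frac), replace=False)
        pos = np.concatenate([plus_cg, plus_non, minus_cg, minus_non])
        strand = np.array(
            ["+"] * (len(plus_cg) + len(plus_non)) + ["-"] * (len(minus_cg) + len(minus_non))
        )
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64), "strand": strand,
            "context": "unclassified",
            "n_meth": 0, "n_total": 1,
        }))
    sites = pd.concat(frames, ignore_index=True)
    sites = classify_sites(genome, sites)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)

    # true methylation probability and region label per site
    p_true = np.where(sites["context"] == CG_SYM, cfg.p_cg_sym_host,
                      np.where(sites["context"] == CG_OTHER, cfg.p_cg_other_host, 0.0))
    region = np.full(len(sites), "background", dtype=object)
    is_cg = sites["context"].isin((CG_SYM, CG_OTHER)).to_numpy()

    pos_by_chrom = {c: grp for c, grp in sites.groupby("chrom", sort=False)}

    def _apply(chrom, start, end, p, label, cg_only=True):
        grp = pos_by_chrom.get(chrom)
        if grp is None:
            return
        idx0 = grp.index[0]
        lo = np.searchsorted(grp["pos"].to_numpy(), start)
        hi = np.searchsorted(grp["pos"].to_numpy(), end)
        sel = np.arange(idx0 + lo, idx0 + hi)
        if cg_only:
            sel = sel[is_cg[sel]]
        p_true[sel] = p
        region[sel] = label

    for isl in islands:
        if isl.attrs["true_class"] != CLASS_TE_RICH:
            _apply(isl.chrom, isl.start, isl.end, cfg.p_island, "island")
        else:
            _apply(isl.chrom, isl.start, isl.end, cfg.p_island, "island")
    for te in tes:
        p_te = max(0.0, cfg.p_te_max - cfg.te_divergence_slope * te.attrs["divergence"])
        _apply(te.chrom, te.start, te.end, p_te, "te")
    from .silencing_analysis import promoter_interval
    for m in gene_meta:
        g = m["gene"]
        s, e = promoter_interval(g, cfg.promoter_bp, genome.length(g.interval.chrom))
        label = "promoter_island" if m["island_id"] is not None else "promoter"
        _apply(g.interval.chrom, s, e, m["promoter_p"], label)

    truth_sites = sites[["chrom", "pos", "strand", "context"]].copy()
    truth_sites["region"] = region
    truth_sites["p_true"] = p_true

    # read sampling per condition
    nb_p = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    conds = list(cfg.baseline_conditions[:1]) + [cfg.treatment_condition]
    sites_by_condition = {}
    for cond in conds:
        factor = cfg.treatment_factor if cond == cfg.treatment_condition else 1.0
        p_cond = np.clip(p_true * factor, 0.0, 1.0)
        p_eff = p_cond + (1.0 - p_cond) * cfg.conversion_error
        cov = rng.negative_binomial(cfg.coverage_dispersion, nb_p, size=len(sites))
        keep = cov > 0
        meth = rng.binomial(cov[keep], p_eff[keep])
        frame = sites.loc[keep, ["chrom", "pos", "strand", "context"]].copy()
        frame["n_meth"] = meth.astype(np.int64)
        frame["n_total"] = cov[keep].astype(np.int64)
        sites_by_condition[cond] = frame.reset_index(drop=True)

    spike_by_condition = {}
    for cond in conds:
        spike_by_condition[cond] = {
            "unmethylated": _spike_frame(rng, cfg, genome, cfg.lambda_chrom, 0.0, nb_p),
            "methylated": _spike_frame(rng, cfg, genome, cfg.puc19_chrom, 1.0, nb_p),
        }
    return sites_by_condition, spike_by_condition, truth_sites


def _spike_frame(rng, cfg, genome, chrom, p, nb_p):
    arr = genome.as_array(chrom)
    plus, minus = _cytosine_positions(arr)
    pos = np.concatenate([plus, minus])
    strand = np.array(["+"] * len(plus) + ["-"] * len(minus))
    frame = pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(np.int64), "strand": strand,
        "context": "unclassified", "n_meth": 0, "n_total": 1,
    })
    frame = classify_sites(genome, frame)
    p_eff = p * (1 - cfg.conversion_error) + (1 - p) * cfg.conversion_error
    cov = rng.negative_binomial(cfg.coverage_dispersion, nb_p, size=len(frame))
    keep = cov > 0
    frame = frame.loc[keep].copy()
    frame["n_total"] = cov[keep].astype(np.int64)
    frame["n_meth"] = rng.binomial(cov[keep], p_eff).astype(np.int64)
    return frame.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# evaluation against truth
# ---------------------------------------------------------------------------

def truth_eval(
    detected_islands: list[Island] | None = None,
    classifications=None,
    categories: pd.DataFrame | None = None,
    decile_table: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
    genome: GenomeSequence | None = None,
) -> dict:
    """Metrics of pipeline output against ground truth.

    Island metrics are base-level (precision / recall / Jaccard) over the
    analysis chromosomes; class accuracy matches each truth island to the
    detected island with the largest overlap; category accuracy compares
    per-gene labels; the decile trend checks that the up-regulated fraction
    strictly increases across the top five promoter-methylation deciles.
    """
    if truth is None:
        raise ValueError("truth required")
    metrics: dict = {}
    cfg = truth.config

    if detected_islands is not None:
        if genome is None:
            raise ValueError("genome required for island metrics")
        inter = union_t = union_d = 0
        bg_hit = bg_total = 0
        for chrom in cfg.analysis_chroms():
            L = genome.length(chrom)
            t_mask = np.zeros(L, dtype=bool)
            d_mask = np.zeros(L, dtype=bool)
            for iv in truth.islands:
                if iv.chrom == chrom:
                    t_mask[iv.start:iv.end] = True
            for isl in detected_islands:
                if isl.chrom == chrom:
                    d_mask[isl.start:isl.end] = True
            inter += int((t_mask & d_mask).sum())
            union_t += int(t_mask.sum())
            union_d += int(d_mask.sum())
            bg_hit += int((d_mask & ~t_mask).sum())
            bg_total += int((~t_mask).sum())
        metrics["island_recall"] = inter / union_t if union_t else float("nan")
        metrics["island_precision"] = inter / union_d if union_d else float("nan")
        denom = union_t + union_d - inter
        metrics["island_jaccard"] = inter / denom if denom else float("nan")
        metrics["background_base_fpr"] = bg_hit / bg_total if bg_total else 0.0

    if classifications is not None:
        correct = 0
        for iv in truth.islands:
            best, best_ov = None, 0
            for c in classifications:
                ov = c.island.interval.overlap(iv)
                if ov > best_ov:
                    best, best_ov = c, ov
            if best is not None and best.island_class == iv.attrs["true_class"]:
                correct += 1
        metrics["class_accuracy"] = correct / len(truth.islands) if truth.islands else float("nan")

    if categories is not None:
        unknown = [g for g in categories["gene_id"] if g not in truth.gene_category]
        if unknown:
            raise ValueError(f"categories contain unknown gene ids: {unknown[:5]}")
        hits = sum(
            1 for g, c in zip(categories["gene_id"], categories["category"])
            if truth.gene_category[g] == c
        )
        metrics["category_accuracy"] = hits / len(categories) if len(categories) else float("nan")

    if decile_table is not None:
        totals = decile_table.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (decile_table["up"] / totals).to_numpy()
        metrics["up_fraction_by_decile"] = [float(x) for x in frac]
        top = frac[5:]
        metrics["decile_trend_strictly_increasing"] = bool(
            np.all(np.isfinite(top)) and np.all(np.diff(top) > 0)
        )
    return metrics
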