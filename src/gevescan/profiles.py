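"""Expression-stratified metagene and TE methylation profiles.

Gene bodies are scaled to a fixed number of bins in 5'->3' orientation
(minus-strand genes are mirrored), flanks use fixed-bp bins, and each bin
reports the pooled weighted level over all profiled features' sites. This is
the standard TSS->TES "metagene" view used to show that active gene bodies
carry CGC/GCG methylation while silent genes and TEs are hypermethylated in
every CG context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionTable, GenomicInterval

log = logging.getLogger(__name__)

NOT_EXPRESSED = "not_expressed"
DEFAULT_TPM_THRESHOLD = 1.0  # strict: TPM < 1 means not expressed
DEFAULT_MIN_SPAN_FRACTION = 0.7


@dataclass
class ProfileLayout:
    """Bin layout: fixed-bp flanks around a body scaled to n_body_bins."""

    upstream_bp: int = 2000
    downstream_bp: int = 2000
    n_flank_bins: int = 20
    n_body_bins: int = 20

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    def labels(self) -> list[str]:
        up = [f"up_{i}" for i in range(self.n_flank_bins)]
        body = [f"body_{i}" for i in range(self.n_body_bins)]
        down = [f"down_{i}" for i in range(self.n_flank_bins)]
        return up + body + down


@dataclass
class MetageneProfile:
    stratum: str
    layout: ProfileLayout
    bins: pd.DataFrame = field(repr=False)
    # columns: bin_index, bin_label, level, n_sites, sum_meth, sum_total
    n_features: int = 0
    n_skipped: int = 0

    def levels(self) -> np.ndarray:
        return self.bins["level"].to_numpy()


def stratify_genes_by_expression(
    expr: ExpressionTable,
    condition: str,
    breaks: int = 3,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> dict[str, set]:
    """Partition genes into a not-expressed class plus TPM rank strata.

    Genes with TPM < tpm_threshold (strictly) in ``condition`` are
    "not_expressed"; the remaining genes are sorted by (TPM, gene_id) and cut
    into ``breaks`` near-equal rank chunks labelled expr_q1 (lowest) ..
    expr_q<breaks> (highest).
    """
    if len(expr.tpm) == 0:
        raise ValueError("empty expression table")
    if condition not in expr.tpm.columns:
        raise ValueError(f"unknown condition {condition!r}")
    tpm = expr.tpm[condition]
    strata: dict[str, set] = {NOT_EXPRESSED: set(tpm.index[tpm < tpm_threshold])}
    expressed = tpm.loc[tpm >= tpm_threshold]
    order = expressed.reset_index().sort_values(
        [condition, "gene_id"], kind="mergesort"
    )["gene_id"].tolist()
    for i, chunk in enumerate(np.array_split(order, breaks), start=1):
        strata[f"expr_q{i}"] = set(chunk)
    return strata


def _bin_positions(pos: np.ndarray, start: int, end: int, strand: str,
                   layout: ProfileLayout) -> np.ndarray:
    """Map site positions to bin indices for one feature; -1 = outside.

    Bin edges are half-open; each site lands in exactly one bin. Minus-strand
    features are mirrored so bin 0 is always the far 5' flank.
    """
    L = layout
    flank_w_up = L.upstream_bp / L.n_flank_bins
    flank_w_dn = L.downstream_bp / L.n_flank_bins
    body_len = end - start
    out = np.full(pos.shape, -1, dtype=np.int64)

    if strand == "-":
        # distance from TSS (= end-1) moving 5'->3' along the gene
        d = (end - 1) - pos
    else:
        d = pos - start

    before = d < 0          # 5' flank
    after = d >= body_len   # 3' flank
    body = ~before & ~after

    b = np.floor(d[body] * L.n_body_bins / body_len).astype(np.int64)
    out[body] = L.n_flank_bins + np.clip(b, 0, L.n_body_bins - 1)

    up_off = np.floor((-d[before] - 1) / flank_w_up).astype(np.int64)
    ok = up_off < L.n_flank_bins
    idx = np.flatnonzero(before)[ok]
    out[idx] = L.n_flank_bins - 1 - up_off[ok]

    dn_off = np.floor((d[after] - body_len) / flank_w_dn).astype(np.int64)
    ok = dn_off < L.n_flank_bins
    idx = np.flatnonzero(after)[ok]
    out[idx] = L.n_flank_bins + L.n_body_bins + dn_off[ok]
    return out


def _profile_features(
    features: list[tuple[str, int, int, str]],
    sites: pd.DataFrame,
    layout: ProfileLayout,
    context_filter,
    stratum: str,
) -> MetageneProfile:
    if context_filter is not None:
        sites = sites.loc[sites["context"].isin(context_filter)]
    by_chrom = {
        chrom: grp.sort_values("pos", kind="mergesort")
        for chrom, grp in sites.groupby("chrom", sort=False)
    }
    arrays = {
        chrom: (g["pos"].to_numpy(), g["n_meth"].to_numpy(), g["n_total"].to_numpy())
        for chrom, g in by_chrom.items()
    }
    sum_meth = np.zeros(layout.n_bins)
    sum_total = np.zeros(layout.n_bins)
    n_sites = np.zeros(layout.n_bins, dtype=np.int64)
    n_used = n_skipped = 0
    for chrom, start, end, strand in features:
        if end - start < layout.n_body_bins:
            n_skipped += 1
            continue
        n_used += 1
        if chrom not in arrays:
            continue
        pos, meth, total = arrays[chrom]
        lo = np.searchsorted(pos, start - layout.upstream_bp - layout.downstream_bp)
        hi = np.searchsorted(pos, end + layout.upstream_bp + layout.downstream_bp)
        if lo == hi:
            continue
        bins = _bin_positions(pos[lo:hi], start, end, strand, layout)
        keep = bins >= 0
        np.add.at(sum_meth, bins[keep], meth[lo:hi][keep])
        np.add.at(sum_total, bins[keep], total[lo:hi][keep])
        np.add.at(n_sites, bins[keep], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(sum_total > 0, sum_meth / sum_total, np.nan)
    bins_df = pd.DataFrame(
        {
            "bin_index": np.arange(layout.n_bins),
            "bin_label": layout.labels(),
            "level": level,
            "n_sites": n_sites,
            "sum_meth": sum_meth.astype(np.int64),
            "sum_total": sum_total.astype(np.int64),
        }
    )
    if n_skipped:
        log.info("%s: skipped %d features shorter than n_body_bins", stratum, n_skipped)
    return MetageneProfile(
        stratum=stratum, layout=layout, bins=bins_df,
        n_features=n_used, n_skipped=n_skipped,
    )


def metagene_profile(
    genes,
    sites: pd.DataFrame,
    layout: ProfileLayout | None = None,
    context_filter=None,
    stratum: str = "all",
) -> MetageneProfile:
    """Pooled metagene profile over a set of GeneModel features.

    Genes shorter than ``n_body_bins`` bases are skipped (counted). Sites are
    pooled across genes per bin (weighted level = pooled counts).
    """
    layout = layout or ProfileLayout()
    feats = [
        (g.interval.chrom, g.interval.start, g.interval.end, g.strand) for g in genes
    ]
    return _profile_features(feats, sites, layout, context_filter, stratum)


def te_profile(
    tes: list[GenomicInterval],
    sites: pd.DataFrame,
    layout: ProfileLayout | None = None,
    context_filter=None,
    min_span_fraction: float | None = DEFAULT_MIN_SPAN_FRACTION,
    stratum: str = "TE",
) -> MetageneProfile:
    """Metagene-style profile over TE copies passing the consensus-span filter.

    Only TE copies spanning at least ``min_span_fraction`` of their consensus
    model contribute (the filter avoids fragmented copies dominating edges).
    Pass ``min_span_fraction=None`` to disable.
    """
    layout = layout or ProfileLayout()
    if min_span_fraction is not None:
        missing = [t for t in tes if "consensus_span_fraction" not in t.attrs]
        if missing:
            raise ValueError(
                "consensus_span_fraction missing on TE intervals; cannot apply span filter"
            )
        kept = [t for t in tes if t.attrs["consensus_span_fraction"] >= min_span_fraction]
    else:
        kept = list(tes)
    if not kept:
        raise ValueError(
            f"no TE passes the consensus span filter (min_span_fraction={min_span_fraction})"
        )
    feats = [(t.chrom, t.start, t.end, t.strand) for t in kept]
    return _profile_features(feats, sites, layout, context_filter, stratum)


def methylation_vs_divergence(
    tes: list[GenomicInterval],
    sites: pd.DataFrame,
    divergence_bins=(0, 5, 10, 15, 20, 25, 30),
    context_filter=("CG_sym", "CG_other"),
    min_sites_flag: int = 50,
) -> pd.DataFrame:
    """Pooled CG level over TE-copy sites, per divergence bin.

    Returns one row per bin (half-open [lo, hi); last bin closed) with the
    pooled level, site count, and a low-coverage flag for bins with fewer
    than ``min_sites_flag`` sites. Young (low-divergence) insertions are
    expected to be the most methylated.
    """
    for t in tes:
        if "divergence" not in t.attrs:
            raise ValueError(f"TE at {t.chrom}:{t.start}-{t.end} lacks divergence")
    if context_filter is not None:
        sites = sites.loc[sites["context"].isin(context_filter)]
    by_chrom = {
        chrom: grp.sort_values("pos", kind="mergesort")
        for chrom, grp in sites.groupby("chrom", sort=False)
    }
    edges = np.asarray(divergence_bins, dtype=float)
    nb = len(edges) - 1
    sum_meth = np.zeros(nb)
    sum_total = np.zeros(nb)
    n_sites = np.zeros(nb, dtype=np.int64)
    for t in tes:
        d = float(t.attrs["divergence"])
        b = int(np.searchsorted(edges, d, side="right") - 1)
        if b == nb and d == edges[-1]:
            b = nb - 1
        if not 0 <= b < nb:
            continue
        grp = by_chrom.get(t.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, t.start)
        hi = np.searchsorted(pos, t.end)
        sum_meth[b] += grp["n_meth"].to_numpy()[lo:hi].sum()
        sum_total[b] += grp["n_total"].to_numpy()[lo:hi].sum()
        n_sites[b] += hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(sum_total > 0, sum_meth / sum_total, np.nan)
    return pd.DataFrame(
        {
            "div_lo": edges[:-1],
            "div_hi": edges[1:],
            "level": level,
            "n_sites": n_sites,
            "low_coverage": n_sites < min_sites_flag,
        }
    )


def profile_to_long(profiles: list[MetageneProfile]) -> pd.DataFrame:
    """Long-format TSV payload: stratum, bin_index, bin_label, level, n_sites."""
    frames = []
    for p in profiles:
        df = p.bins[["bin_index", "bin_label", "level", "n_sites"]].copy()
        df.insert(0, "stratum", p.stratum)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_profile(profiles: list[MetageneProfile], path=None):
    """Minimal line-plot helper (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for p in profiles:
        ax.plot(p.bins["bin_index"], p.bins["level"], label=p.stratum)
    L = profiles[0].layout
    ax.axvline(L.n_flank_bins - 0.5, color="grey", lw=0.5)
    ax.axvline(L.n_flank_bins + L.n_body_bins - 0.5, color="grey", lw=0.5)
    ax.set_xlabel("bin (5' flank | body | 3' flank)")
    ax.set_ylabel("weighted mCG level")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
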