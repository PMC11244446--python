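import numpy as np
import pandas as pd
import pytest

from gevescan import profiles
from gevescan.types import (
    CG_OTHER,
    CG_SYM,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    MethylationSite,
    sites_frame,
)

from _oracles import oracle_metagene_bins, oracle_stratify


def _expr(tpms: dict) -> ExpressionTable:
    tpm = pd.DataFrame({"ctrl": pd.Series(tpms)})
    tpm.index.name = "gene_id"
    return ExpressionTable(tpm=tpm, groups={"ctrl": "control"})


def _gene(chrom, start, end, strand="+", gid="g1"):
    iv = GenomicInterval(chrom, start, end, strand, kind="gene")
    return GeneModel(gene_id=gid, interval=iv,
                     exons=[GenomicInterval(chrom, start, end, strand, kind="exon")])


def _uniform_sites(chrom, start, end, step, m, t, context=CG_SYM):
    return sites_frame([
        MethylationSite(chrom, p, "+", m, t, context=context)
        for p in range(start, end, step)
    ])


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_stratify_examples_and_strict_threshold():
    strata = profiles.stratify_genes_by_expression(
        _expr({"a": 0.5, "b": 2.0, "c": 20.0, "d": 200.0}), "ctrl"
    )
    assert strata["not_expressed"] == {"a"}
    assert strata["expr_q1"] == {"b"}
    assert strata["expr_q2"] == {"c"}
    assert strata["expr_q3"] == {"d"}
    # TPM exactly 1.0 counts as expressed (threshold is strict <)
    strata = profiles.stratify_genes_by_expression(_expr({"a": 1.0, "b": 5.0}), "ctrl")
    assert "a" not in strata["not_expressed"]


def test_stratify_empty_table_is_error():
    with pytest.raises(ValueError):
        profiles.stratify_genes_by_expression(
            ExpressionTable(tpm=pd.DataFrame(columns=["ctrl"]),
                            groups={"ctrl": "control"}),
            "ctrl",
        )


def test_stratify_matches_sort_and_split_oracle(rng):
    tpms = {f"g{i:03d}": float(t) for i, t in enumerate(rng.gamma(1.0, 20.0, size=97))}
    got = profiles.stratify_genes_by_expression(_expr(tpms), "ctrl", breaks=4)
    expect = oracle_stratify(tpms, breaks=4)
    assert got.keys() == expect.keys()
    for k in expect:
        assert got[k] == expect[k], k


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

def test_uniform_methylation_gives_flat_body():
    gene = _gene("c1", 10_000, 12_000)
    sites = _uniform_sites("c1", 6_000, 16_000, 20, 5, 10)
    prof = profiles.metagene_profile([gene], sites)
    body = prof.bins.iloc[20:40]
    assert np.allclose(body["level"], 0.5)


def test_minus_strand_tss_signal_lands_in_first_body_bins():
    gene = _gene("c1", 10_000, 12_000, strand="-")
    # methylation only near the minus-strand TSS (pos near interval end)
    sites = sites_frame([
        MethylationSite("c1", p, "+", 9, 10, context=CG_SYM)
        for p in range(11_900, 12_000, 5)
    ])
    prof = profiles.metagene_profile([gene], sites)
    body = prof.bins.iloc[20:40]["level"].to_numpy()
    assert body[0] == pytest.approx(0.9)
    assert np.isnan(body[-1])  # nothing at the TES end


def test_short_gene_skipped_with_counter():
    gene = _gene("c1", 100, 110)
    prof = profiles.metagene_profile([gene], _uniform_sites("c1", 0, 200, 5, 1, 2))
    assert prof.n_skipped == 1
    assert prof.n_features == 0


def test_metagene_matches_per_gene_loop_oracle(rng):
    layout = profiles.ProfileLayout(upstream_bp=500, downstream_bp=500,
                                    n_flank_bins=5, n_body_bins=8)
    feats, genes = [], []
    for i in range(20):
        start = int(rng.integers(1_000, 50_000))
        length = int(rng.integers(200, 3_000))
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(("c1", start, start + length, strand))
        genes.append(_gene("c1", start, start + length, strand, gid=f"g{i}"))
    n = 4000
    pos = rng.integers(0, 55_000, size=n)
    totals = rng.integers(1, 20, size=n)
    frame = pd.DataFrame({
        "chrom": "c1", "pos": pos, "strand": "+", "context": CG_SYM,
        "n_meth": rng.integers(0, totals + 1), "n_total": totals,
    })
    prof = profiles.metagene_profile(genes, frame, layout=layout)
    recs = list(zip(frame["chrom"], frame["pos"], frame["n_meth"], frame["n_total"]))
    exp_m, exp_t = oracle_metagene_bins(feats, recs, layout)
    assert prof.bins["sum_meth"].tolist() == exp_m
    assert prof.bins["sum_total"].tolist() == exp_t


def test_pooling_property_bins_recompose_global_level():
    """Site-weighted mean of bin levels equals the pooled level of all binned sites."""
    gene = _gene("c1", 10_000, 14_000)
    sites = _uniform_sites("c1", 8_000, 16_000, 13, 3, 7)
    prof = profiles.metagene_profile([gene], sites)
    b = prof.bins.dropna(subset=["level"])
    pooled = (b["level"] * b["sum_total"]).sum() / b["sum_total"].sum()
    assert pooled == pytest.approx(b["sum_meth"].sum() / b["sum_total"].sum(), abs=1e-12)


# ---------------------------------------------------------------------------
# TE profile
# ---------------------------------------------------------------------------

def _te(chrom, start, end, span, div=5.0):
    return GenomicInterval(chrom, start, end, "+", kind="TE",
                           attrs={"family": "f", "divergence": div,
                                  "consensus_span_fraction": span})


def test_te_span_filter_is_inclusive_at_boundary():
    tes = [_te("c1", 0, 700, 0.69), _te("c1", 1_000, 1_700, 0.70),
           _te("c1", 2_000, 2_950, 0.95)]
    sites = _uniform_sites("c1", 0, 3_000, 10, 1, 1)
    layout = profiles.ProfileLayout(500, 500, 5, 5)
    prof = profiles.te_profile(tes, sites, layout=layout)
    assert prof.n_features == 2


def test_te_profile_no_copies_pass_filter_is_error():
    with pytest.raises(ValueError, match="span filter"):
        profiles.te_profile([_te("c1", 0, 500, 0.5)], _uniform_sites("c1", 0, 600, 10, 1, 1))


def test_te_profile_filter_noop_when_all_pass():
    tes = [_te("c1", 0, 700, 0.8), _te("c1", 1_000, 1_800, 0.9)]
    sites = _uniform_sites("c1", 0, 2_500, 7, 2, 3)
    layout = profiles.ProfileLayout(200, 200, 4, 6)
    on = profiles.te_profile(tes, sites, layout=layout, min_span_fraction=0.7)
    off = profiles.te_profile(tes, sites, layout=layout, min_span_fraction=None)
    pd.testing.assert_frame_equal(on.bins, off.bins)


def test_saturated_tes_profile_near_one(small_bundle):
    """Fully methylated young TE copies give body bins close to 1."""
    sites = sites_frame([])
    tes = [_te("c1", 1_000, 3_000, 0.9)]
    sites = _uniform_sites("c1", 1_000, 3_000, 9, 20, 20)
    prof = profiles.te_profile(tes, sites, layout=profiles.ProfileLayout(500, 500, 5, 10))
    assert np.nanmin(prof.bins.iloc[5:15]["level"]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# methylation vs divergence
# ---------------------------------------------------------------------------

def test_divergence_bins_recover_decay(small_bundle):
    """Generator sets p_te = p_max - slope*divergence: bin means decrease."""
    sites = small_bundle.sites_by_condition["control"]
    host_tes = [t for t in small_bundle.tes if t.attrs.get("in_island") is None]
    table = profiles.methylation_vs_divergence(
        host_tes, sites, divergence_bins=(2, 12, 21, 30)
    )
    levels = table.loc[~table["low_coverage"], "level"].to_numpy()
    assert len(levels) >= 2
    assert np.all(np.diff(levels) < 0)


def test_single_bin_equals_global_te_level():
    tes = [_te("c1", 0, 1_000, 0.9, div=3.0), _te("c1", 2_000, 3_000, 0.9, div=9.0)]
    sites = _uniform_sites("c1", 0, 3_000, 11, 4, 9, context=CG_OTHER)
    table = profiles.methylation_vs_divergence(tes, sites, divergence_bins=(0, 10))
    in_te = sites[(sites["pos"] < 1_000) | (sites["pos"] >= 2_000)]
    assert table["level"].iloc[0] == pytest.approx(
        in_te["n_meth"].sum() / in_te["n_total"].sum()
    )


def test_empty_divergence_bin_flagged():
    tes = [_te("c1", 0, 1_000, 0.9, div=3.0)]
    sites = _uniform_sites("c1", 0, 1_000, 10, 1, 2, context=CG_OTHER)
    table = profiles.methylation_vs_divergence(tes, sites, divergence_bins=(0, 5, 10))
    assert table["low_coverage"].iloc[1]
    assert np.isnan(table["level"].iloc[1])


def test_missing_divergence_is_error():
    te = GenomicInterval("c1", 0, 100, "+", kind="TE", attrs={"family": "f"})
    with pytest.raises(ValueError, match="divergence"):
        profiles.methylation_vs_divergence([te], _uniform_sites("c1", 0, 100, 10, 1, 2))


# ---------------------------------------------------------------------------
# qualitative silencing signature
# ---------------------------------------------------------------------------

def test_not_expressed_stratum_has_higher_promoter_flank(small_bundle):
    """Silent genes carry promoter methylation; expressed genes do not."""
    strata = profiles.stratify_genes_by_expression(
        small_bundle.expression, "control"
    )
    genes_by_id = {g.gene_id: g for g in small_bundle.genes}
    sites = small_bundle.sites_by_condition["control"]

    def near_tss_flank(stratum):
        sel = [genes_by_id[g] for g in strata[stratum] if g in genes_by_id]
        prof = profiles.metagene_profile(sel, sites,
                                         context_filter=(CG_OTHER,))
        return np.nanmean(prof.bins.iloc[12:20]["level"])  # flank bins at the TSS

    assert near_tss_flank("not_expressed") > near_tss_flank("expr_q3") + 0.1
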