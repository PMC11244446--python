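import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gevescan import silencing_analysis as sa
from gevescan.types import (
    CG_OTHER,
    CG_SYM,
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    MethylationSite,
    sites_frame,
)

from _oracles import oracle_category, oracle_deciles, oracle_fisher_two_sided


def _gene(gid, start, end, strand="+", chrom="c1"):
    iv = GenomicInterval(chrom, start, end, strand, kind="gene")
    return GeneModel(gene_id=gid, interval=iv,
                     exons=[GenomicInterval(chrom, start, end, strand, kind="exon")])


# ---------------------------------------------------------------------------
# promoter methylation
# ---------------------------------------------------------------------------

def test_minus_strand_promoter_is_downstream_interval():
    g = _gene("g1", 100, 200, strand="-")
    assert sa.promoter_interval(g, 50, 1_000) == (200, 250)


def test_promoter_truncated_at_contig_start():
    g = _gene("g1", 300, 900)
    assert sa.promoter_interval(g, 1_000, 5_000) == (0, 300)


def test_ten_distinct_levels_give_one_gene_per_decile():
    genome = GenomeSequence({"c1": "A" * 100_000})
    genes, records = [], []
    frames = []
    for i in range(10):
        start = 2_000 + i * 5_000
        genes.append(_gene(f"g{i}", start, start + 1_000))
        frames.append(sites_frame([
            MethylationSite("c1", start - 1_000 + 50 * j, "+", i, 10, context=CG_SYM)
            for j in range(10)
        ]))
    sites = pd.concat(frames, ignore_index=True)
    rec = sa.promoter_methylation(genes, sites, genome)
    assert sorted(rec["decile"]) == list(range(1, 11))
    top = rec.loc[rec["decile"] == 10, "gene_id"].iloc[0]
    assert top == "g9"  # most methylated promoter


def test_low_site_promoters_excluded():
    genome = GenomeSequence({"c1": "A" * 10_000})
    genes = [_gene("g1", 2_000, 3_000)]
    sites = sites_frame([
        MethylationSite("c1", 1_500 + i, "+", 1, 2, context=CG_SYM) for i in range(3)
    ])
    rec = sa.promoter_methylation(genes, sites, genome, min_promoter_sites=5)
    assert len(rec) == 0


def test_decile_ties_match_stable_sort_oracle(rng):
    genome = GenomeSequence({"c1": "A" * 1_000_000})
    genes, frames = [], []
    levels = {}
    for i in range(73):
        start = 2_000 + i * 3_000
        gid = f"g{i:03d}"
        genes.append(_gene(gid, start, start + 500))
        lvl = float(rng.choice([0.0, 0.2, 0.2, 0.5, 0.8]))  # deliberate ties
        m = int(lvl * 10)
        levels[gid] = m / 10
        frames.append(sites_frame([
            MethylationSite("c1", start - 1_000 + 80 * j, "+", m, 10, context=CG_OTHER)
            for j in range(8)
        ]))
    rec = sa.promoter_methylation(genes, pd.concat(frames, ignore_index=True), genome)
    expect = oracle_deciles(levels)
    got = dict(zip(rec["gene_id"], rec["decile"]))
    assert got == expect


# ---------------------------------------------------------------------------
# decile x DE response
# ---------------------------------------------------------------------------

def _records(deciles):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(deciles))],
        "weighted_level": np.linspace(0, 1, len(deciles)),
        "n_sites": 10,
        "decile": deciles,
    })


def test_de_direction_counting_and_padj_boundary():
    rec = _records([10, 10, 1])
    de = pd.DataFrame({
        "gene_id": ["g0", "g1", "g2"],
        "log2FC": [2.0, -1.0, 3.0],
        "padj": [0.005, 0.01, 0.5],   # 0.01 is NOT significant (strict <)
    })
    table = sa.decile_response_table(rec, de, fdr=0.01)
    assert table.loc[10, "up"] == 1
    assert table.loc[10, "not_de"] == 1   # padj == 0.01
    assert table.loc[1, "not_de"] == 1


def test_genes_missing_from_de_counted_not_de():
    rec = _records([5])
    de = pd.DataFrame({"gene_id": [], "log2FC": [], "padj": []})
    table = sa.decile_response_table(rec, de)
    assert table.loc[5, "not_de"] == 1


def test_decile_table_marginals_conserved(default_result):
    table = default_result.decile_table
    rec = default_result.promoter_records
    assert int(table.sum().sum()) == len(rec)
    row_sums = table.sum(axis=1)
    decile_counts = rec["decile"].value_counts()
    for dec in range(1, 11):
        assert row_sums.loc[dec] == decile_counts.get(dec, 0)


# ---------------------------------------------------------------------------
# reactivation categories
# ---------------------------------------------------------------------------

def _expr(rows, conditions):
    tpm = pd.DataFrame(rows, columns=conditions,
                       index=[f"g{i}" for i in range(len(rows))])
    tpm.index.name = "gene_id"
    groups = {c: ("treatment" if c == "aza" else "control") for c in conditions}
    return ExpressionTable(tpm=tpm, groups=groups)


@pytest.mark.parametrize(
    "row,expected",
    [
        ((0.0, 0.0, 5.0), "Aza"),
        ((2.0, 0.0, 8.0), "Broad"),
        ((0.0, 0.0, 0.0), "No"),
        ((0.0, 1.0, 0.0), "Broad"),   # any baseline >= threshold
    ],
)
def test_category_truth_table(row, expected):
    expr = _expr([row], ["dev", "ctrl", "aza"])
    cats = sa.reactivation_categories(expr, ["aza"], ["dev", "ctrl"])
    assert cats["category"].iloc[0] == expected


def test_requesting_unknown_gene_is_error():
    expr = _expr([(1.0, 1.0, 1.0)], ["dev", "ctrl", "aza"])
    with pytest.raises(ValueError, match="absent"):
        sa.reactivation_categories(expr, ["aza"], ["dev", "ctrl"], genes=["nope"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 10), st.floats(0, 10), st.floats(0, 10)),
                min_size=1, max_size=20))
def test_categories_match_oracle_on_random_tables(rows):
    expr = _expr(rows, ["dev", "ctrl", "aza"])
    cats = sa.reactivation_categories(expr, ["aza"], ["dev", "ctrl"])
    for (dev, ctrl, aza), got in zip(rows, cats["category"]):
        assert got == oracle_category([dev, ctrl], [aza])


def test_category_partition_is_complete(default_result):
    cats = default_result.categories
    assert set(cats["category"]) <= {"Aza", "Broad", "No"}
    assert cats["gene_id"].is_unique
    counts = cats["category"].value_counts()
    assert counts.sum() == len(cats)


def test_reactivation_summary_counts_and_empty_class():
    cats = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(100)],
        "category": ["Aza"] * 26 + ["No"] * 74,
    })
    gene_classes = {f"g{i}": "GEVE" for i in range(100)}
    summary = sa.reactivation_summary(cats, gene_classes, classes=("GEVE", "adintovirus"))
    assert summary.loc["GEVE", "n_aza"] == 26
    assert summary.loc["GEVE", "pct_aza"] == pytest.approx(26.0)
    assert summary.loc["adintovirus", "n_genes"] == 0   # zero row retained


def test_reactivation_summary_matches_groupby_oracle(rng):
    genes = [f"g{i}" for i in range(200)]
    cats = pd.DataFrame({
        "gene_id": genes,
        "category": [str(c) for c in rng.choice(["Aza", "Broad", "No"], size=200)],
    })
    gene_classes = {g: str(c) for g, c in
                    zip(genes, rng.choice(["GEVE", "adintovirus", "TE_ORF"], size=200))}
    summary = sa.reactivation_summary(cats, gene_classes)
    df = cats.assign(cls=[gene_classes[g] for g in genes])
    expect = df.groupby(["cls", "category"]).size()
    for cls in ("GEVE", "adintovirus", "TE_ORF"):
        for cat in ("Aza", "Broad", "No"):
            assert summary.loc[cls, f"n_{cat.lower()}"] == expect.get((cls, cat), 0)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def _domains(mapping):
    rows = [(g, d, d) for g, ds in mapping.items() for d in ds]
    return pd.DataFrame(rows, columns=["gene_id", "domain_accession", "domain_name"])


def test_fisher_degenerate_table_p_one():
    assert oracle_fisher_two_sided(0, 10, 0, 90) == pytest.approx(1.0)
    domains = _domains({"g0": ["D"]})
    bg = {f"g{i}" for i in range(100)}
    out = sa.fisher_domain_enrichment(domains, {"g0"} | {f"g{i}" for i in range(1, 10)}, bg)
    # a=1,b=9,c=0,d=90
    assert out["p_value"].iloc[0] == pytest.approx(
        oracle_fisher_two_sided(1, 9, 0, 90), rel=1e-10
    )


def test_fisher_symmetry_in_set_labels():
    a, b, c, d = 7, 13, 4, 26
    assert oracle_fisher_two_sided(a, b, c, d) == pytest.approx(
        oracle_fisher_two_sided(c, d, a, b), rel=1e-12
    )
    from scipy.stats import fisher_exact
    p1 = fisher_exact([[a, b], [c, d]])[1]
    p2 = fisher_exact([[c, d], [a, b]])[1]
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_gene_set_must_be_subset_of_background():
    with pytest.raises(ValueError, match="subset"):
        sa.fisher_domain_enrichment(_domains({"g0": ["D"]}), {"gX"}, {"g0"})


def test_fisher_against_enumeration_oracle_moderate_margins():
    from scipy.stats import fisher_exact

    for a in range(0, 12, 3):
        for b in range(0, 12, 4):
            for c in range(0, 12, 3):
                for d in range(0, 12, 4):
                    if a + b == 0 or c + d == 0:
                        continue
                    p = fisher_exact([[a, b], [c, d]])[1]
                    assert p == pytest.approx(
                        oracle_fisher_two_sided(a, b, c, d), rel=1e-9, abs=1e-12
                    )


def test_bh_qvalues_monotone_in_p_rank(default_result):
    enr = default_result.enrichment
    assert enr is not None and len(enr) > 3
    ordered = enr.sort_values("p_value")
    assert (ordered["q_value"].diff().dropna() >= -1e-12).all()
    assert (ordered["q_value"] >= ordered["p_value"] - 1e-12).all()


def test_jmjc_enriched_in_island_genes(default_bundle, default_result):
    """The simulated GEVE regions are seeded with JmjC-domain genes."""
    enr = default_result.enrichment
    row = enr.loc[enr["domain_accession"] == "PF02373"]
    assert len(row) == 1
    assert row["odds_ratio"].iloc[0] > 1
    assert row["q_value"].iloc[0] < 0.01
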