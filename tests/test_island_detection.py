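import numpy as np
import pandas as pd
import pytest

from gevescan import island_detection as isd
from gevescan.types import (
    CG_OTHER,
    GenomeSequence,
    GenomicInterval,
    Island,
    MethylationSite,
    sites_frame,
)

from _oracles import oracle_call_islands, oracle_te_fraction, oracle_window_track


def _sites(records):
    return sites_frame([
        MethylationSite("c1", p, "+", m, t, context=CG_OTHER) for p, m, t in records
    ])


def _genome_of_len(n, chrom="c1"):
    return GenomeSequence({chrom: "A" * n})


# ---------------------------------------------------------------------------
# window track
# ---------------------------------------------------------------------------

def test_window_tiling_with_terminal_short_window():
    tracks = isd.window_track(_sites([]), _genome_of_len(25_000), window_size_bp=10_000)
    w = tracks["c1"].windows
    assert list(zip(w["start"], w["end"])) == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]


def test_window_level_pools_counts():
    sites = _sites([(100, 8, 10), (200, 0, 10)])
    tracks = isd.window_track(sites, _genome_of_len(10_000), window_size_bp=10_000,
                              min_sites_per_window=1)
    assert tracks["c1"].windows["level"].iloc[0] == pytest.approx(0.4)


def test_window_size_floor():
    with pytest.raises(ValueError):
        isd.window_track(_sites([]), _genome_of_len(1_000), window_size_bp=50)


def test_window_track_matches_loop_oracle(rng):
    n = 800
    chrom_len = 57_500
    pos = np.sort(rng.integers(0, chrom_len, size=n))
    totals = rng.integers(1, 30, size=n)
    contexts = rng.choice(["CG_other", "CG_sym"], size=n)
    frame = pd.DataFrame({
        "chrom": "c1", "pos": pos, "strand": "+", "context": contexts,
        "n_meth": rng.integers(0, totals + 1), "n_total": totals,
    })
    tracks = isd.window_track(frame, _genome_of_len(chrom_len),
                              window_size_bp=5_000, min_sites_per_window=4)
    recs = list(zip(frame["pos"], frame["context"], frame["n_meth"], frame["n_total"]))
    expect = oracle_window_track(recs, chrom_len, 5_000, {"CG_other"}, 4)
    w = tracks["c1"].windows
    assert len(w) == len(expect)
    for i, e in enumerate(expect):
        assert (w["start"].iloc[i], w["end"].iloc[i]) == (e["start"], e["end"])
        assert w["n_sites"].iloc[i] == e["n_sites"]
        assert bool(w["missing"].iloc[i]) == e["missing"]
        if e["n_sites"]:
            assert w["level"].iloc[i] == pytest.approx(e["level"], abs=1e-12)


# ---------------------------------------------------------------------------
# island calling
# ---------------------------------------------------------------------------

def _track_from_levels(levels, ws=10_000, missing=None):
    n = len(levels)
    missing = missing or [False] * n
    windows = pd.DataFrame({
        "start": np.arange(n) * ws,
        "end": (np.arange(n) + 1) * ws,
        "level": levels,
        "n_sites": [0 if m else 100 for m in missing],
        "sum_meth": [int(1000 * (l if np.isfinite(l) else 0)) for l in levels],
        "sum_total": [1000] * n,
        "missing": missing,
    })
    return {"c1": isd.WindowTrack("c1", ws, (CG_OTHER,), windows)}


def test_simple_island_called():
    tracks = _track_from_levels([0.1, 0.1, 0.8, 0.9, 0.1])
    islands = isd.call_islands(tracks, theta=0.4, max_gap_windows=0, min_island_bp=10_000)
    assert len(islands) == 1
    assert (islands[0].start, islands[0].end) == (20_000, 40_000)
    assert islands[0].n_windows == 2


def test_no_windows_above_theta_yields_empty():
    assert isd.call_islands(_track_from_levels([0.1, 0.2, 0.3])) == []


def test_gap_semantics():
    tracks = _track_from_levels([0.8, 0.1, 0.8])
    merged = isd.call_islands(tracks, theta=0.4, max_gap_windows=1, min_island_bp=10_000)
    assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 30_000)
    split = isd.call_islands(tracks, theta=0.4, max_gap_windows=0, min_island_bp=20_000)
    assert split == []  # two 10-kb runs, both below the 20-kb minimum


def test_missing_windows_bridgeable_but_never_seed():
    tracks = _track_from_levels([0.8, 0.9, 0.1], missing=[False, True, False])
    islands = isd.call_islands(tracks, theta=0.4, max_gap_windows=1, min_island_bp=10_000)
    # window 1 is high but missing: it may be bridged, never flagged
    assert len(islands) == 1
    assert (islands[0].start, islands[0].end) == (0, 10_000)


def test_theta_bounds():
    with pytest.raises(ValueError):
        isd.call_islands(_track_from_levels([0.5]), theta=1.5)


def test_island_calling_matches_enumeration_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(5, 40))
        levels = rng.uniform(0, 1, size=n)
        missing = rng.random(n) < 0.15
        max_gap = int(rng.integers(0, 3))
        min_bp = int(rng.choice([10_000, 20_000, 30_000]))
        tracks = _track_from_levels(list(levels), missing=list(missing))
        got = [(i.start, i.end) for i in
               isd.call_islands(tracks, theta=0.4, max_gap_windows=max_gap,
                                min_island_bp=min_bp)]
        flags = [(not m) and l >= 0.4 for l, m in zip(levels, missing)]
        starts = [i * 10_000 for i in range(n)]
        ends = [(i + 1) * 10_000 for i in range(n)]
        assert got == oracle_call_islands(flags, starts, ends, max_gap, min_bp)


def test_theta_monotonicity_on_simulated_track(small_bundle):
    from gevescan.pipeline import analysis_genome

    cfg = small_bundle.config
    genome = analysis_genome(small_bundle.genome, (cfg.lambda_chrom, cfg.puc19_chrom))
    sites = small_bundle.sites_by_condition["control"]
    tracks = isd.window_track(sites, genome)
    total_bases = None
    for theta in (0.3, 0.4, 0.5, 0.6, 0.7):
        bases = sum(i.length for i in isd.call_islands(tracks, theta=theta))
        if total_bases is not None:
            assert bases <= total_bases
        total_bases = bases


def test_island_calling_invariant_to_site_order(small_bundle, rng):
    from gevescan.pipeline import analysis_genome

    cfg = small_bundle.config
    genome = analysis_genome(small_bundle.genome, (cfg.lambda_chrom, cfg.puc19_chrom))
    sites = small_bundle.sites_by_condition["control"]
    shuffled = sites.sample(frac=1, random_state=123).reset_index(drop=True)
    a = isd.call_islands(isd.window_track(sites, genome))
    b = isd.call_islands(isd.window_track(shuffled, genome))
    assert [(i.chrom, i.start, i.end, i.mean_level) for i in a] == \
           [(i.chrom, i.start, i.end, i.mean_level) for i in b]


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------

def _island(start, end):
    return Island(GenomicInterval("c1", start, end, ".", kind="island"),
                  mean_level=0.8, n_windows=(end - start) // 10_000,
                  supporting_sites=0)


def _block_sites(true_start, true_end, chrom_len, step=25):
    recs = []
    for p in range(0, chrom_len, step):
        inside = true_start <= p < true_end
        recs.append((p, 16 if inside else 4, 20))
    return _sites(recs)


def test_refinement_recovers_implanted_edges_within_one_subwindow():
    chrom_len = 80_000
    sites = _block_sites(14_500, 43_200, chrom_len)
    called = _island(10_000, 50_000)
    refined = isd.refine_boundaries(called, sites, chrom_len, subwindow_bp=1_000)
    assert abs(refined.start - 14_500) <= 1_000
    assert abs(refined.end - 43_200) <= 1_000
    assert refined.refined


def test_refinement_extends_when_call_undershoots():
    chrom_len = 80_000
    sites = _block_sites(14_500, 43_200, chrom_len)
    called = _island(20_000, 40_000)
    refined = isd.refine_boundaries(called, sites, chrom_len)
    assert abs(refined.start - 14_500) <= 1_000
    assert abs(refined.end - 43_200) <= 1_000


def test_refinement_idempotent():
    chrom_len = 80_000
    sites = _block_sites(14_500, 43_200, chrom_len)
    once = isd.refine_boundaries(_island(10_000, 50_000), sites, chrom_len)
    twice = isd.refine_boundaries(once, sites, chrom_len)
    assert (once.start, once.end) == (twice.start, twice.end)


def test_refinement_fixed_point_when_flush():
    chrom_len = 60_000
    sites = _block_sites(10_000, 40_000, chrom_len)
    refined = isd.refine_boundaries(_island(10_000, 40_000), sites, chrom_len)
    assert (refined.start, refined.end) == (10_000, 40_000)


def test_refinement_subwindow_must_be_smaller_than_window():
    with pytest.raises(ValueError):
        isd.refine_boundaries(_island(0, 20_000), _sites([]), 50_000,
                              subwindow_bp=10_000, window_size_bp=10_000)


# ---------------------------------------------------------------------------
# secondary-TE annotation
# ---------------------------------------------------------------------------

def _te(chrom, s, e):
    return GenomicInterval(chrom, s, e, "+", kind="TE", attrs={})


def test_te_fraction_arithmetic():
    isl = _island(0, 10_000)
    isd.annotate_secondary_te([isl], [_te("c1", 2_000, 4_000)])
    assert isl.interval.attrs["te_fraction"] == pytest.approx(0.2)


def test_te_fraction_union_counts_overlaps_once():
    isl = _island(0, 10_000)
    isd.annotate_secondary_te(
        [isl], [_te("c1", 2_000, 5_000), _te("c1", 3_000, 6_000), _te("c1", 3_500, 4_000)]
    )
    assert isl.interval.attrs["te_fraction"] == pytest.approx(0.4)


def test_te_fraction_zero_without_tes():
    isl = _island(0, 10_000)
    isd.annotate_secondary_te([isl], [])
    assert isl.interval.attrs["te_fraction"] == 0.0


def test_te_fraction_matches_base_by_base_oracle(rng):
    for _ in range(25):
        s = int(rng.integers(0, 5_000))
        e = s + int(rng.integers(1_000, 8_000))
        spans = []
        for _ in range(int(rng.integers(0, 8))):
            a = int(rng.integers(0, 12_000))
            spans.append((a, a + int(rng.integers(100, 3_000))))
        isl = _island(s, e)
        isd.annotate_secondary_te([isl], [_te("c1", a, b) for a, b in spans])
        assert isl.interval.attrs["te_fraction"] == pytest.approx(
            oracle_te_fraction(s, e, spans), abs=1e-12
        )
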