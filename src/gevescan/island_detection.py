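"""Hypermethylation island detection from the non-CGC/GCG CpG signal.

This is the bespoke algorithm of the package. Background non-CGC/GCG
methylation sits around 20% genome-wide, while silenced blocks (viral
insertions, TE clusters) approach TE-like hypermethylation (>= 70-80%), so
a fixed-width window track of pooled non-CGC/GCG levels is strongly bimodal.
Detection proceeds in three deterministic steps:

1. ``window_track``  - tile each chromosome with fixed windows (default
   10 kb) and pool the weighted level of sites in the chosen context set.
2. ``call_islands``  - threshold windows at theta, merge runs of flagged
   windows across small gaps, and drop runs shorter than a minimum length.
3. ``refine_boundaries`` - greedily extend/trim each island edge in
   sub-window steps (default 1 kb) against the same pooled signal, making
   the block demarcation reproducible down to sub-window resolution. The
   refinement is idempotent.

Islands never seed in windows with too few informative sites ("missing"
windows, e.g. assembly gaps); missing windows are bridgeable during merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CG_OTHER, GenomeSequence, GenomicInterval, Island

DEFAULT_WINDOW_BP = 10_000
DEFAULT_THETA = 0.4
DEFAULT_MAX_GAP_WINDOWS = 1
DEFAULT_MIN_ISLAND_BP = 10_000
DEFAULT_MIN_SITES_PER_WINDOW = 10
DEFAULT_SUBWINDOW_BP = 1_000
DEFAULT_CONTEXT_FILTER = (CG_OTHER,)


@dataclass
class WindowTrack:
    """Per-chromosome fixed-width window methylation summary."""

    chrom: str
    window_size_bp: int
    context_filter: tuple
    windows: pd.DataFrame = field(repr=False)
    # columns: start, end, level, n_sites, sum_meth, sum_total, missing

    def __len__(self) -> int:
        return len(self.windows)


def _sorted_context_sites(sites: pd.DataFrame, chrom: str, context_filter) -> pd.DataFrame:
    sel = sites.loc[(sites["chrom"] == chrom) & sites["context"].isin(context_filter)]
    return sel.sort_values("pos", kind="mergesort")


def window_track(
    sites: pd.DataFrame,
    genome: GenomeSequence,
    window_size_bp: int = DEFAULT_WINDOW_BP,
    context_filter=DEFAULT_CONTEXT_FILTER,
    min_sites_per_window: int = DEFAULT_MIN_SITES_PER_WINDOW,
) -> dict[str, WindowTrack]:
    """Tile every chromosome and pool site levels per window.

    Windows with fewer than ``min_sites_per_window`` contributing sites are
    marked missing: they never pass thresholding but may be bridged when
    merging flagged runs.
    """
    if window_size_bp < 100:
        raise ValueError("window_size_bp must be >= 100")
    tracks: dict[str, WindowTrack] = {}
    for chrom in genome.sequences:
        chrom_len = genome.length(chrom)
        n_win = int(np.ceil(chrom_len / window_size_bp))
        starts = np.arange(n_win, dtype=np.int64) * window_size_bp
        ends = np.minimum(starts + window_size_bp, chrom_len)
        sel = _sorted_context_sites(sites, chrom, context_filter)
        idx = (sel["pos"].to_numpy() // window_size_bp).astype(np.int64)
        n_sites = np.bincount(idx, minlength=n_win).astype(np.int64)
        sum_meth = np.bincount(idx, weights=sel["n_meth"].to_numpy(), minlength=n_win)
        sum_total = np.bincount(idx, weights=sel["n_total"].to_numpy(), minlength=n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(sum_total > 0, sum_meth / sum_total, np.nan)
        windows = pd.DataFrame(
            {
                "start": starts,
                "end": ends,
                "level": level,
                "n_sites": n_sites,
                "sum_meth": sum_meth.astype(np.int64),
                "sum_total": sum_total.astype(np.int64),
                "missing": n_sites < min_sites_per_window,
            }
        )
        tracks[chrom] = WindowTrack(
            chrom=chrom, window_size_bp=window_size_bp,
            context_filter=tuple(context_filter), windows=windows,
        )
    return tracks


def call_islands(
    tracks: dict[str, WindowTrack],
    theta: float = DEFAULT_THETA,
    max_gap_windows: int = DEFAULT_MAX_GAP_WINDOWS,
    min_island_bp: int = DEFAULT_MIN_ISLAND_BP,
) -> list[Island]:
    """Threshold the window track and merge flagged runs into islands.

    A window is flagged when it is not missing and its level >= theta. Runs
    of flagged windows are merged across at most ``max_gap_windows``
    intervening unflagged-or-missing windows; merged runs spanning fewer than
    ``min_island_bp`` bases are discarded. Island mean_level pools the reads
    of every window in the merged run (gap windows included).
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be inside (0, 1)")
    islands: list[Island] = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        w = track.windows
        flagged = (~w["missing"].to_numpy()) & (
            np.nan_to_num(w["level"].to_numpy(), nan=-1.0) >= theta
        )
        hits = np.flatnonzero(flagged)
        if hits.size == 0:
            continue
        runs: list[tuple[int, int]] = []
        run_start = prev = hits[0]
        for i in hits[1:]:
            if i - prev - 1 <= max_gap_windows:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        for i0, i1 in runs:
            start = int(w["start"].iloc[i0])
            end = int(w["end"].iloc[i1])
            if end - start < min_island_bp:
                continue
            block = w.iloc[i0 : i1 + 1]
            sum_meth = int(block["sum_meth"].sum())
            sum_total = int(block["sum_total"].sum())
            islands.append(
                Island(
                    interval=GenomicInterval(chrom, start, end, ".", kind="island"),
                    mean_level=sum_meth / sum_total if sum_total else float("nan"),
                    n_windows=i1 - i0 + 1,
                    supporting_sites=int(block["n_sites"].sum()),
                )
            )
    return islands


class _PooledSignal:
    """Fast pooled-level queries over one chromosome's context-filtered sites."""

    def __init__(self, sites: pd.DataFrame, chrom: str, context_filter):
        sel = _sorted_context_sites(sites, chrom, context_filter)
        self.pos = sel["pos"].to_numpy()
        self.cum_meth = np.concatenate(([0], np.cumsum(sel["n_meth"].to_numpy())))
        self.cum_total = np.concatenate(([0], np.cumsum(sel["n_total"].to_numpy())))

    def level(self, start: int, end: int) -> tuple[float, int, int]:
        """(pooled level, n_sites, sum_total) over [start, end); NaN if empty."""
        i = np.searchsorted(self.pos, start, side="left")
        j = np.searchsorted(self.pos, end, side="left")
        total = int(self.cum_total[j] - self.cum_total[i])
        meth = int(self.cum_meth[j] - self.cum_meth[i])
        if total == 0:
            return float("nan"), 0, 0
        return meth / total, int(j - i), total


def refine_boundaries(
    island: Island,
    sites: pd.DataFrame,
    chrom_length: int,
    subwindow_bp: int = DEFAULT_SUBWINDOW_BP,
    theta: float = DEFAULT_THETA,
    theta_site: float | None = None,
    context_filter=DEFAULT_CONTEXT_FILTER,
    window_size_bp: int = DEFAULT_WINDOW_BP,
    _signal: "_PooledSignal | None" = None,
) -> Island:
    """Refine one island's edges in sub-window steps.

    From each edge, outward extension continues while the adjacent outside
    sub-window's pooled level stays >= max(theta, theta_site); then inward
    trimming removes edge sub-windows whose level is < theta_site (sub-windows
    without any informative site trim as unsupported). The result is clamped
    to the chromosome, never empty, and the procedure is idempotent.
    """
    if subwindow_bp >= window_size_bp:
        raise ValueError("subwindow_bp must be smaller than window_size_bp")
    if theta_site is None:
        theta_site = theta
    theta_ext = max(theta, theta_site)
    sig = _signal or _PooledSignal(sites, island.chrom, context_filter)

    start, end = island.start, island.end

    def _lvl(a: int, b: int) -> float:
        return sig.level(max(a, 0), min(b, chrom_length))[0]

    # outward extension
    while end < chrom_length:
        lvl = _lvl(end, end + subwindow_bp)
        if np.isnan(lvl) or lvl < theta_ext:
            break
        end = min(end + subwindow_bp, chrom_length)
    while start > 0:
        lvl = _lvl(start - subwindow_bp, start)
        if np.isnan(lvl) or lvl < theta_ext:
            break
        start = max(start - subwindow_bp, 0)
    # inward trimming (keep at least one sub-window)
    while end - start > subwindow_bp:
        lvl = _lvl(end - subwindow_bp, end)
        if not np.isnan(lvl) and lvl >= theta_site:
            break
        end -= subwindow_bp
    while end - start > subwindow_bp:
        lvl = _lvl(start, start + subwindow_bp)
        if not np.isnan(lvl) and lvl >= theta_site:
            break
        start += subwindow_bp

    mean_level, n_sites, _ = sig.level(start, end)
    return Island(
        interval=GenomicInterval(
            island.chrom, start, end, ".", kind="island", attrs=dict(island.interval.attrs)
        ),
        mean_level=mean_level,
        n_windows=island.n_windows,
        supporting_sites=n_sites,
        refined=True,
    )


def refine_islands(
    islands: list[Island],
    sites: pd.DataFrame,
    genome: GenomeSequence,
    **kwargs,
) -> list[Island]:
    """Refine a list of islands (shares the pooled-signal index per chromosome)."""
    out = []
    signals: dict[str, _PooledSignal] = {}
    context_filter = kwargs.get("context_filter", DEFAULT_CONTEXT_FILTER)
    for isl in islands:
        if isl.chrom not in signals:
            signals[isl.chrom] = _PooledSignal(sites, isl.chrom, context_filter)
        out.append(
            refine_boundaries(
                isl, sites, genome.length(isl.chrom),
                _signal=signals[isl.chrom], **kwargs,
            )
        )
    return out


def annotate_secondary_te(islands: list[Island], tes: list[GenomicInterval]) -> list[Island]:
    """Record, per island, the fraction of its bases covered by TE intervals.

    Overlapping/nested TEs count once (interval union). Stored in the island
    interval attrs as ``te_fraction``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
    for spans in by_chrom.values():
        spans.sort()
    for isl in islands:
        covered = 0
        cur_s = cur_e = None
        for s, e in by_chrom.get(isl.chrom, ()):
            s, e = max(s, isl.start), min(e, isl.end)
            if s >= e:
                continue
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        isl.interval.attrs["te_fraction"] = covered / isl.length
    return islands


def otsu_threshold(tracks: dict[str, WindowTrack], n_bins: int = 64) -> float:
    """Otsu-style automatic threshold on the window-level histogram.

    Provided as an optional alternative to the fixed default theta; not used
    unless explicitly requested.
    """
    levels = np.concatenate(
        [t.windows.loc[~t.windows["missing"], "level"].dropna().to_numpy() for t in tracks.values()]
    )
    if levels.size == 0:
        raise ValueError("no informative windows")
    hist, edges = np.histogram(levels, bins=n_bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = DEFAULT_THETA, -1.0
    for k in range(1, n_bins):
        w0, w1 = p[:k].sum(), p[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (p[:k] * centers[:k]).sum() / w0
        m1 = (p[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, edges[k]
    return float(best_t)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def islands_to_bed(islands: list[Island], path) -> None:
    """Write islands as BED6+2 (name, score = floor(1000*mean_level))."""
    with open(path, "w") as fh:
        for i, isl in enumerate(sorted(islands, key=lambda x: x.interval.sort_key()), 1):
            name = isl.interval.attrs.get("island_id", f"island_{i:03d}")
            score = int(np.floor(1000 * isl.mean_level)) if np.isfinite(isl.mean_level) else 0
            te_frac = isl.interval.attrs.get("te_fraction", "")
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t{name}\t{score}\t.\t"
                f"{isl.n_windows}\t{te_frac}\n"
            )


def track_to_bedgraph(tracks: dict[str, WindowTrack], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            for row in tracks[chrom].windows.itertuples(index=False):
                if np.isnan(row.level):
                    continue
                fh.write(f"{chrom}\t{row.start}\t{row.end}\t{row.level:.4f}\n")
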