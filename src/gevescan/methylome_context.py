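"""Extended CG-trinucleotide context classification and weighted methylation.

The organism studied here methylates CpG dinucleotides at two very different
levels depending on the extended trinucleotide context: the symmetric
CGC/GCG family (a CpG followed by C, equivalently preceded by G on the other
strand) is hypermethylated genome-wide (~70%), while the remaining CpGs
("non-CGC/GCG") carry ~20% methylation except over silenced regions. The
non-CGC/GCG signal is therefore the discriminative channel for island
detection; this module provides the classifier and the pooled ("weighted")
methylation statistics everything downstream builds on.

Classification reads, on the site's own strand, the bases
(up, c, d1, d2) at offsets (-1, 0, +1, +2) from the cytosine:

* CG context  iff d1 == G
* CHG         iff d1 != G and d2 == G
* CHH         otherwise
* within CG:  CG_sym iff d2 == C or up == G, else CG_other
* ambiguous   if a base needed for the decision is N or out of range

Minus-strand sites are read on the reverse complement; coordinates stay on
the Watson strand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    AMBIGUOUS,
    CG_OTHER,
    CG_SYM,
    CHG,
    CHH,
    CONTEXT_CLASSES,
    GenomeSequence,
    MethylationSite,
)

log = logging.getLogger(__name__)

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")
_COMP = np.zeros(256, dtype=np.uint8)
_COMP[:] = _N
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


def _fetch(arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bases at idx, with out-of-range positions reading as N."""
    out = np.full(idx.shape, _N, dtype=np.uint8)
    ok = (idx >= 0) & (idx < len(arr))
    out[ok] = arr[idx[ok]]
    return out


def _classify_codes(up: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Vectorised context decision from own-strand flanking bases."""
    ctx = np.full(up.shape, AMBIGUOUS, dtype=object)
    d1_known = d1 != _N
    is_cg = d1_known & (d1 == _G)
    non_cg = d1_known & (d1 != _G)

    sym = is_cg & ((up == _G) | (d2 == _C))
    other = is_cg & ~sym & (up != _N) & (d2 != _N)
    ctx[sym] = CG_SYM
    ctx[other] = CG_OTHER

    chg = non_cg & (d2 == _G)
    chh = non_cg & (d2 != _G) & (d2 != _N)
    ctx[chg] = CHG
    ctx[chh] = CHH
    return ctx


def classify_sites(genome: GenomeSequence, sites: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the sites frame with the context column assigned.

    Sites with strand '.' get their strand resolved from the reference base
    first (C -> +, G -> -). A site whose reference base is not a cytosine on
    its recorded strand indicates corrupt calls and raises.
    """
    sites = sites.reset_index(drop=True)
    contexts = np.empty(len(sites), dtype=object)
    strands = sites["strand"].to_numpy(dtype=object, copy=True)
    pos_all = sites["pos"].to_numpy()
    for chrom, grp in sites.groupby("chrom", sort=False):
        arr = genome.as_array(chrom)
        rows = grp.index.to_numpy()
        loc = sites.index.get_indexer(rows)
        pos = pos_all[loc]
        if len(pos) and (pos.min() < 0 or pos.max() >= len(arr)):
            raise ValueError(f"site position out of range on {chrom}")
        base = arr[pos]
        st = strands[loc]
        undecided = st == "."
        if undecided.any():
            b = base[undecided]
            inferred = np.where(b == _C, "+", np.where(b == _G, "-", "?"))
            if (inferred == "?").any():
                raise ValueError(f"reference base not C/G at a '.'-strand site on {chrom}")
            st[undecided] = inferred
            strands[loc] = st
        plus = st == "+"
        minus = st == "-"
        if not (plus | minus).all():
            raise ValueError("strand must be '+', '-' or '.'")
        if (base[plus] != _C).any() or (base[minus] != _G).any():
            raise ValueError(
                f"{chrom}: reference base is not a cytosine on the recorded strand "
                "(corrupt methylation calls?)"
            )
        up = np.empty(len(pos), dtype=np.uint8)
        d1 = np.empty(len(pos), dtype=np.uint8)
        d2 = np.empty(len(pos), dtype=np.uint8)
        p = pos[plus]
        up[plus] = _fetch(arr, p - 1)
        d1[plus] = _fetch(arr, p + 1)
        d2[plus] = _fetch(arr, p + 2)
        m = pos[minus]
        up[minus] = _COMP[_fetch(arr, m + 1)]
        d1[minus] = _COMP[_fetch(arr, m - 1)]
        d2[minus] = _COMP[_fetch(arr, m - 2)]
        contexts[loc] = _classify_codes(up, d1, d2)
    sites["context"] = contexts
    sites["strand"] = strands
    return sites


def classify_context(genome: GenomeSequence, site: MethylationSite) -> str:
    """Context class of a single site (scalar convenience wrapper)."""
    from .types import sites_frame

    frame = classify_sites(genome, sites_frame([site]))
    return frame["context"].iloc[0]


# ---------------------------------------------------------------------------
# Weighted methylation statistics
# ---------------------------------------------------------------------------

def weighted_methylation(sites: pd.DataFrame, min_coverage: int = 1) -> pd.DataFrame:
    """Pooled ("weighted") methylation level per context class.

    Per class over sites with ``n_total >= min_coverage``:
    ``weighted_level = sum(n_meth) / sum(n_total)``. Classes with no
    contributing reads get ``weighted_level = NaN`` (flagged, no division).

    Returns a frame indexed by context with columns
    n_sites, sum_meth, sum_total, weighted_level.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    use = sites.loc[sites["n_total"] >= min_coverage]
    grouped = use.groupby("context")
    agg = grouped.agg(
        n_sites=("n_total", "size"),
        sum_meth=("n_meth", "sum"),
        sum_total=("n_total", "sum"),
    )
    agg = agg.reindex(list(CONTEXT_CLASSES)).fillna(0).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["weighted_level"] = np.where(
            agg["sum_total"] > 0, agg["sum_meth"] / agg["sum_total"], np.nan
        )
    chh = agg.loc[CHH]
    if chh["sum_total"] > 0 and chh["weighted_level"] > 0.02:
        log.warning(
            "CHH weighted level %.3f exceeds 0.02: possible conversion failure",
            chh["weighted_level"],
        )
    return agg


def pooled_level(sites: pd.DataFrame, contexts=None) -> tuple[float, int]:
    """Pooled level (and site count) over an optional context subset."""
    if contexts is not None:
        sites = sites.loc[sites["context"].isin(contexts)]
    total = int(sites["n_total"].sum())
    if total == 0:
        return float("nan"), 0
    return float(sites["n_meth"].sum() / total), len(sites)


def global_cg_level(sites: pd.DataFrame) -> float:
    """Global weighted CG level (CG_sym + CG_other pooled)."""
    return pooled_level(sites, (CG_SYM, CG_OTHER))[0]


def conversion_qc(
    spike_sites_unmethylated: pd.DataFrame,
    spike_sites_methylated: pd.DataFrame,
) -> tuple[float, float]:
    """Spike-in QC from unmethylated (lambda) and methylated (pUC19) controls.

    conversion_efficiency = 1 - weighted level on the unmethylated control;
    overconversion        = 1 - weighted level on the methylated control.
    A warning fires when conversion efficiency drops below 0.98.
    """
    if len(spike_sites_unmethylated) == 0 or len(spike_sites_methylated) == 0:
        raise ValueError("missing spike-in control sites")
    lam, _ = pooled_level(spike_sites_unmethylated)
    puc, _ = pooled_level(spike_sites_methylated)
    conversion_efficiency = 1.0 - lam
    overconversion = 1.0 - puc
    if conversion_efficiency < 0.98:
        log.warning("conversion efficiency %.4f < 0.98", conversion_efficiency)
    return conversion_efficiency, overconversion


def compare_treatments(summaries: dict[str, list]) -> pd.DataFrame:
    """Summarise replicate global CG levels per condition.

    ``summaries`` maps condition -> list of replicate global levels (floats,
    or objects exposing ``weighted_level``). Returns a frame sorted by
    condition with mean, min, max and range.
    """
    rows = []
    for condition in sorted(summaries):
        reps = summaries[condition]
        if len(reps) == 0:
            raise ValueError(f"condition {condition!r} has zero replicates")
        vals = np.asarray(
            [r.weighted_level if hasattr(r, "weighted_level") else float(r) for r in reps]
        )
        rows.append(
            {
                "condition": condition,
                "n_replicates": len(vals),
                "mean_level": float(vals.mean()),
                "min_level": float(vals.min()),
                "max_level": float(vals.max()),
                "range": float(vals.max() - vals.min()),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def merge_cpg_pairs(sites: pd.DataFrame) -> pd.DataFrame:
    """Optionally merge +/- calls of the same CpG dinucleotide.

    The + strand C at position p and the - strand C at p+1 belong to one CpG;
    counts are summed and reported at the + strand coordinate. Off by default
    everywhere because CG_sym membership is defined per strand.
    """
    cg = sites.loc[sites["context"].isin((CG_SYM, CG_OTHER))].copy()
    key = np.where(cg["strand"] == "-", cg["pos"] - 1, cg["pos"])
    cg["cpg_pos"] = key
    merged = (
        cg.groupby(["chrom", "cpg_pos"], sort=True)
        .agg(n_meth=("n_meth", "sum"), n_total=("n_total", "sum"),
             context=("context", "first"))
        .reset_index()
        .rename(columns={"cpg_pos": "pos"})
    )
    merged["strand"] = "+"
    return merged[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]
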