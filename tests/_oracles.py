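"""Independent brute-force oracles used to verify the vectorised implementations.

Every function here is deliberately written as a plain scalar loop (or an
exhaustive enumeration) straight from the operation's definition, sharing no
code with the package.
"""

from __future__ import annotations

import math
from collections import defaultdict

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def oracle_classify(seq: str, pos: int, strand: str) -> str:
    """Context by explicitly building the site's own-strand sequence."""
    if strand == "-":
        rc = revcomp(seq)
        p = len(seq) - 1 - pos
        s = rc
    else:
        p = pos
        s = seq

    def base(i):
        if 0 <= i < len(s):
            return s[i]
        return "N"

    if base(p) != "C":
        raise ValueError("not a cytosine on its strand")
    up, d1, d2 = base(p - 1), base(p + 1), base(p + 2)
    if d1 == "N":
        return "ambiguous"
    if d1 == "G":
        if up == "G" or d2 == "C":
            return "CG_sym"
        if up == "N" or d2 == "N":
            return "ambiguous"
        return "CG_other"
    if d2 == "G":
        return "CHG"
    if d2 == "N":
        return "ambiguous"
    return "CHH"


def oracle_weighted(records, min_coverage=1):
    """records: iterable of (context, n_meth, n_total) -> {context: level}."""
    sums = defaultdict(lambda: [0, 0])
    for ctx, m, t in records:
        if t >= min_coverage:
            sums[ctx][0] += m
            sums[ctx][1] += t
    return {ctx: (m / t if t else float("nan")) for ctx, (m, t) in sums.items()}


def oracle_window_track(records, chrom_len, window_size, contexts, min_sites):
    """records: (pos, context, n_meth, n_total) for one chromosome."""
    n_win = math.ceil(chrom_len / window_size)
    out = []
    for w in range(n_win):
        s, e = w * window_size, min((w + 1) * window_size, chrom_len)
        m = t = k = 0
        for pos, ctx, nm, nt in records:
            if s <= pos < e and ctx in contexts:
                m += nm
                t += nt
                k += 1
        out.append({
            "start": s, "end": e,
            "level": m / t if t else float("nan"),
            "n_sites": k, "missing": k < min_sites,
        })
    return out


def oracle_call_islands(flags, starts, ends, max_gap, min_island_bp):
    """Exhaustive enumeration of maximal valid flagged spans."""
    n = len(flags)
    valid = []
    for i in range(n):
        if not flags[i]:
            continue
        for j in range(i, n):
            if not flags[j]:
                continue
            gap, ok = 0, True
            for k in range(i, j + 1):
                if flags[k]:
                    gap = 0
                else:
                    gap += 1
                    if gap > max_gap:
                        ok = False
                        break
            if ok:
                valid.append((i, j))
    maximal = [
        s for s in valid
        if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in valid)
    ]
    return [
        (starts[i], ends[j])
        for i, j in sorted(maximal)
        if ends[j] - starts[i] >= min_island_bp
    ]


def oracle_te_fraction(island_start, island_end, te_spans):
    """Base-by-base coverage of the island by the TE span union."""
    covered = [False] * (island_end - island_start)
    for s, e in te_spans:
        for p in range(max(s, island_start), min(e, island_end)):
            covered[p - island_start] = True
    return sum(covered) / (island_end - island_start)


def _log_comb(n, k):
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def oracle_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [
        math.exp(_log_comb(r1, x) + _log_comb(r2, c1 - x) - _log_comb(n, c1))
        for x in range(lo, hi + 1)
    ]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def oracle_deciles(levels_by_gene):
    """dict gene -> level; deciles by stable (level, gene) rank, 10 = most."""
    ordered = sorted(levels_by_gene, key=lambda g: (levels_by_gene[g], g))
    n = len(ordered)
    return {g: (i * 10) // n + 1 for i, g in enumerate(ordered)}


def oracle_category(baseline_tpms, treatment_tpms, threshold=1.0):
    if any(t >= threshold for t in baseline_tpms):
        return "Broad"
    if any(t >= threshold for t in treatment_tpms):
        return "Aza"
    return "No"


def oracle_stratify(tpms_by_gene, breaks=3, threshold=1.0):
    """Sort-and-split partition of expressed genes into rank chunks."""
    out = {"not_expressed": {g for g, t in tpms_by_gene.items() if t < threshold}}
    expressed = sorted(
        (g for g, t in tpms_by_gene.items() if t >= threshold),
        key=lambda g: (tpms_by_gene[g], g),
    )
    n = len(expressed)
    base, rem = divmod(n, breaks)
    cursor = 0
    for i in range(1, breaks + 1):
        size = base + (1 if i <= rem else 0)
        out[f"expr_q{i}"] = set(expressed[cursor:cursor + size])
        cursor += size
    return out


def oracle_metagene_bins(features, records, layout):
    """Per-feature loop assigning each site to a bin and pooling counts.

    features: (chrom, start, end, strand); records: (chrom, pos, n_meth,
    n_total). layout has upstream_bp/downstream_bp/n_flank_bins/n_body_bins.
    Returns (sum_meth, sum_total) lists per bin.
    """
    nb = 2 * layout.n_flank_bins + layout.n_body_bins
    sum_m = [0] * nb
    sum_t = [0] * nb
    wu = layout.upstream_bp / layout.n_flank_bins
    wd = layout.downstream_bp / layout.n_flank_bins
    for chrom, start, end, strand in features:
        body = end - start
        if body < layout.n_body_bins:
            continue
        for rchrom, pos, m, t in records:
            if rchrom != chrom:
                continue
            d = ((end - 1) - pos) if strand == "-" else (pos - start)
            if 0 <= d < body:
                b = layout.n_flank_bins + int(d * layout.n_body_bins // body)
            elif d < 0:
                off = int((-d - 1) // wu)
                if off >= layout.n_flank_bins:
                    continue
                b = layout.n_flank_bins - 1 - off
            else:
                off = int((d - body) // wd)
                if off >= layout.n_flank_bins:
                    continue
                b = layout.n_flank_bins + layout.n_body_bins + off
            sum_m[b] += m
            sum_t[b] += t
    return sum_m, sum_t
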