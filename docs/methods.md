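# Methods

## Context model

Every methylation call is classified from the bases on the cytosine's own
strand at offsets (−1, 0, +1, +2): CG context iff the +1 base is G; CHG iff
+1 ≠ G and +2 = G; CHH otherwise. Within CG, the symmetric CGC/GCG family
("CG_sym") is defined by (+2 = C) **or** (−1 = G): a CpG followed by C on one
strand is preceded by G on the other, so membership is strand-symmetric even
though the flanking bases differ. Any needed base that is N or out of range
makes the site `ambiguous`. Minus-strand sites are read on the reverse
complement but keep Watson coordinates. Cytosines are scored per strand; a
CpG-pair merge utility exists but is off by default, because CG_sym
membership is defined per strand.

Methylation levels are always *weighted* (count-pooled):
`sum(n_meth) / sum(n_total)` over a site set, never the mean of per-site
fractions. Pooling is robust to coverage variation and matches what pooled
callers emit. Defaults: `min_coverage = 1` for pooled global levels and 5
for any per-site use. Non-CG levels are computed only as QC; a warning fires
when CHH exceeds 0.02, which in enzymatic/bisulfite data indicates
conversion failure. Conversion QC uses spike-ins: conversion efficiency
= 1 − level on the unmethylated lambda control (warn below 0.98);
overconversion = 1 − level on the fully methylated pUC19 control.

## Island segmentation

The detection signal is the pooled level of CG_other ("non-CGC/GCG") sites
in fixed tiling windows (default 10 kb). Host background sits near 0.2 while
silenced insertions approach 0.8, so the window histogram is strongly
bimodal; the default threshold theta = 0.4 is the midpoint separating the
modes on simulated data. Theta is an explicit, documented parameter — no
numeric cutoff is inherited from observational work — and an Otsu-style
automatic threshold on the window histogram is available but off by default.

Windows with fewer than `min_sites_per_window = 10` informative sites are
*missing*: they can be bridged when merging but never seed or extend an
island, which prevents calls inside assembly gaps. Runs of flagged windows
merge across at most `max_gap_windows = 1` unflagged-or-missing windows;
merged runs shorter than `min_island_bp = 10,000` (one window) are dropped.

Boundary refinement replaces window-grid edges with sub-window-resolution
ones (default 1 kb): from each edge, extend outward while the adjacent
outside sub-window's pooled level stays at or above theta, then trim inward
while the edge sub-window is below theta (sub-windows with no informative
site count as unsupported and are trimmed). A greedy, deterministic scheme
was chosen over an HMM because the refined edge then has a direct
definition — the outermost sub-window still supported by the signal — and
the procedure is provably idempotent, which the tests assert. Trimming
always leaves at least one sub-window, so refinement never empties an
island. Note one documented consequence of greediness: an isolated
hypermethylated feature (e.g. a young TE) lying exactly at the called grid
edge can stop inward trimming early; demarcation is exact when island flanks
are ordinary background.

## Island classification

A gene belongs to an island iff at least 50% of its span overlaps it
(symmetric, order-independent). Features per island: mean exons per gene
(hosts here average ~7 exons; viral genes mostly 1), gene density per 10 kb,
length, TE base fraction (interval union), and marker hits per class from
the domain-hits table intersected with the shipped, editable catalog
(`src/gevescan/data/markers.tsv`): VLTF3 / A32-like ATPase / D5 primase /
NCLDV major capsid support GEVE; family-B DNA polymerase, capsids and Dam
methyltransferase support adintovirus; tyrosine recombinase and the Plavaka
transposase support the giant tandem repeats. Ordered rules, first match
wins, every evaluation logged:

1. any GEVE marker and mean exons ≤ 2 → GEVE
2. any adintovirus marker and length ≤ 60 kb → adintovirus (complete
   adintovirus insertions are ~30 kb; 60 kb leaves headroom for degenerate
   copies)
3. any Plavaka marker → plavaka
4. TE fraction ≥ 0.6 with no viral markers → te_rich
5. otherwise unclassified

The three thresholds are config defaults chosen to separate the simulated
classes cleanly; they are declared approximations of a manual curation
process, not recovered empirical constants.

## Silencing analysis

Promoters are the 1,000 bp upstream of the TSS on the gene strand (truncated
at contig edges, not dropped); promoter methylation pools both CG classes;
genes with fewer than 5 informative promoter sites are excluded. Deciles are
assigned by rank with ties broken by gene id (stable; decile 10 most
methylated). A gene is differentially expressed iff adjusted p < 0.01
(strict) and |log2FC| > 0; direction is the sign of log2FC. Reactivation
categories: Broad iff any baseline condition reaches 1 TPM; else Aza iff any
treatment condition does; else No. Domain enrichment uses the two-sided
Fisher exact test (minimum-likelihood convention: sum of point probabilities
≤ the observed table's, with ~1e−7 relative tie tolerance) via SciPy, and an
independent exhaustive hypergeometric enumeration verifies it in the tests
for every table with total ≤ 30. Benjamini–Hochberg q-values are shipped by
default (raw p retained). The default enrichment background is the full gene
set of the annotation; island genes are the foreground.

## Synthetic data

The generator emits a desk-scale study: by default one 1.8-Mb chromosome
plus a 0.2-Mb unplaced contig (to exercise the census), lambda/pUC19 spike
contigs, 160 intron-rich host genes (1 + Poisson(6.2) exons, mean 7.2), 40
host TEs, and 14 implanted islands (6 GEVE 30–80 kb, 4 adintovirus 20–40 kb,
2 Plavaka 20–45 kb, 2 TE-rich clusters 20–35 kb) with class-appropriate
marker domains and intron-poor genes at ~4 genes/10 kb. Sequence composition
is uniform (GC 0.45) everywhere, so detection can only use the methylation
signal, never sequence content.

True methylation probabilities: host background CG_sym 0.7 and CG_other 0.2
(global CG ≈ 0.4); islands 0.8 in all CG contexts; TEs 0.9 − 0.02·divergence
(age-stratified); per-gene promoter probabilities form a continuum —
U(0.02, 0.75) for host genes (promoters ≥ 0.5 define silent genes, mean
~0.63, mirroring hypermethylated silent-gene promoters), U(0.55, 0.95)
inside islands. Reads are binomial at negative-binomial coverage (mean 20,
dispersion 10 — overdispersion deliberately stresses the weighted-vs-mean
estimator difference), with a 0.005 conversion-error false-positive rate.
The treated condition multiplies every probability by 0.375, reproducing a
~40% → ~15%-style global drop. Host features keep a 12-kb clearance around
implanted islands so that boundary refinement is evaluated against clean
background (see the greediness note above); island spacing (≥ 35 kb)
guarantees distinct insertions are never gap-bridged.

The expression design fixes ground truth before sampling: up-regulation
follows a smooth dose-response over the true promoter-methylation ranking
(per-decile fractions 0.02 → 0.95, interpolated and realised by systematic
cumulative-floor sampling, so the configured monotone response is a property
of the design rather than of sampling luck); down-regulation concentrates in
unmethylated deciles; island genes get Aza/Broad/No categories at
class-specific rates (GEVE 26%, adintovirus 32%) and TPM values keep a
margin around the 1-TPM threshold so category truth is unambiguous.
GEVE islands are additionally seeded with JmjC-domain genes (a histone
demethylase family that real giant-virus insertions carry and reactivate),
which the enrichment analysis recovers.

What the generator does **not** emulate: realistic sequence composition or
TE sequence models, read-level data, partially degraded island methylation,
sub-kilobase insertions, or correlated biological replicates. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under the stated statistical conditions, not performance on real
libraries — in particular, real island boundaries flanked by methylated
features will be demarcated only to window/sub-window resolution.

## Numerical and degenerate-input conventions

All internal coordinates are 0-based half-open; conversion happens only at
parse/write boundaries (GFF3 and CGmap are 1-based). Zero-coverage sites are
dropped at parse time and counted. Empty pooled sums yield NaN
("undefined-and-flagged"), never division by zero. Multi-isoform genes use
the longest mRNA (ties by coordinate then id; configurable by editing the
annotation). Bin edges and window edges are half-open, so every site lands
in exactly one bin. Island calling and refinement are deterministic and
invariant to input record order; the simulator is byte-reproducible from its
seed.

## Problem sizes

Default analyses run on the 2-Mb simulated genome (~227,000 CG-site calls
per condition); the test suite additionally uses a 0.65-Mb configuration for
module-level checks. These sizes give every statistical check at least
10,000 sites per context class while keeping the full suite and the
acceptance run fast on a single CPU.
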