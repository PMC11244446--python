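"""Readers/writers for the external formats the pipeline touches.

Dialects handled
----------------
* FASTA (genome), via Biopython.
* GFF3 gene models (gene/mRNA/exon), via gffutils; exons are taken from the
  longest mRNA of each gene.
* Per-cytosine methylation calls:
  - ``cgmap``: CGmapTools output, 1-based, one line per cytosine on either
    strand; the second column is the Watson-strand base ("C" -> + strand,
    "G" -> - strand).
  - ``bedgraph_cov``: 6 columns chrom/start/end/percent/n_meth/n_unmeth,
    0-based half-open.
  - ``bedmethyl``: ENCODE-style 9+2 columns (coverage in col 10, percent
    methylation in col 11).
* TE annotations: RepeatMasker ``.out`` or a headered "bed_plus" TSV.
* Plain TSV tables: expression (TPM), differential expression, domain hits.

All parsers normalise to 0-based half-open coordinates and validate count
invariants (n_meth <= n_total); zero-coverage sites are dropped and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    UNCLASSIFIED,
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    empty_sites_frame,
)

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


@dataclass
class ParseReport:
    """Counters a parser accumulates (exposed by `gevescan validate`)."""

    n_records: int = 0
    n_warnings: int = 0
    n_dropped_zero_coverage: int = 0
    notes: tuple = ()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, name: str | None = None, report: ParseReport | None = None) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a logged warning count. Duplicate headers and empty files are errors.
    """
    sequences: dict[str, str] = {}
    n_bad = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID_BASES:
            cleaned = "".join(c if c in _VALID_BASES else "N" for c in seq)
            n_bad += sum(1 for a, b in zip(seq, cleaned) if a != b)
            seq = cleaned
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    if n_bad:
        log.warning("%d non-ACGTN characters mapped to N in %s", n_bad, path)
    if report is not None:
        report.n_records = len(sequences)
        report.n_warnings = n_bad
    return GenomeSequence(sequences, name=name or str(path))


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Methylation calls
# ---------------------------------------------------------------------------

def read_methylation_calls(
    path,
    dialect: str = "cgmap",
    genome: GenomeSequence | None = None,
    report: ParseReport | None = None,
) -> pd.DataFrame:
    """Parse per-cytosine calls into a sites frame.

    Positions are normalised to 0-based cytosine coordinates on the named
    strand. Sites with zero total coverage are dropped (counted in the
    report). ``n_meth > n_total`` is a hard error naming the offending line.

    For the strand-less bedGraph dialect, a ``genome`` may be supplied to
    infer strand from the reference base (C -> +, G -> -); otherwise strand
    is recorded as '.'.
    """
    if dialect == "cgmap":
        frame, dropped = _read_cgmap(path)
    elif dialect == "bedgraph_cov":
        frame, dropped = _read_bedgraph_cov(path)
    elif dialect == "bedmethyl":
        frame, dropped = _read_bedmethyl(path)
    else:
        raise ValueError(f"unknown methylation dialect: {dialect!r}")

    if genome is not None and len(frame) and (frame["strand"] == ".").any():
        frame = _infer_strand(frame, genome)
    if dropped:
        log.info("%s: dropped %d zero-coverage sites", path, dropped)
    if report is not None:
        report.n_records = len(frame)
        report.n_dropped_zero_coverage = dropped
    return frame.reset_index(drop=True)


def _finish_sites(df: pd.DataFrame, path) -> tuple[pd.DataFrame, int]:
    bad = df["n_meth"] > df["n_total"]
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise ValueError(f"{path}: line {line}: n_meth > n_total")
    zero = df["n_total"] == 0
    dropped = int(zero.sum())
    df = df.loc[~zero].copy()
    df["context"] = UNCLASSIFIED
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_total"] = df["n_total"].astype(np.int64)
    return df[["chrom", "pos", "strand", "context", "n_meth", "n_total"]], dropped


def _read_cgmap(path):
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "watson_base", "pos1", "ctx", "dinuc", "level", "n_meth", "n_total"],
        dtype={"chrom": str, "watson_base": str},
    )
    if df.empty:
        return empty_sites_frame(), 0
    bad = ~df["watson_base"].isin(["C", "G"])
    if bad.any():
        raise ValueError(f"{path}: line {int(df.index[bad][0]) + 1}: Watson base must be C or G")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos1"] - 1,  # CGmap is 1-based
            "strand": np.where(df["watson_base"] == "C", "+", "-"),
            "n_meth": df["n_meth"],
            "n_total": df["n_total"],
        }
    )
    return _finish_sites(out, path)


def _read_bedgraph_cov(path):
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    if df.empty:
        return empty_sites_frame(), 0
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"],
            "strand": ".",
            "n_meth": df["n_meth"],
            "n_total": df["n_meth"] + df["n_unmeth"],
        }
    )
    return _finish_sites(out, path)


def _read_bedmethyl(path):
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.empty:
        return empty_sites_frame(), 0
    if df.shape[1] < 11:
        raise ValueError(f"{path}: bedMethyl needs >= 11 columns, found {df.shape[1]}")
    cov = df.iloc[:, 9].astype(np.int64)
    pct = df.iloc[:, 10].astype(float)
    n_meth = np.rint(cov * pct / 100.0).astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0],
            "pos": df.iloc[:, 1],
            "strand": df.iloc[:, 5],
            "n_meth": n_meth,
            "n_total": cov,
        }
    )
    return _finish_sites(out, path)


def _infer_strand(frame: pd.DataFrame, genome: GenomeSequence) -> pd.DataFrame:
    frame = frame.copy()
    todo = frame["strand"] == "."
    for chrom, grp in frame.loc[todo].groupby("chrom", sort=False):
        arr = genome.as_array(chrom)
        pos = grp["pos"].to_numpy()
        if pos.max() >= len(arr):
            raise ValueError(f"site position beyond end of {chrom}")
        base = arr[pos]
        strands = np.where(base == ord("C"), "+", np.where(base == ord("G"), "-", "?"))
        if (strands == "?").any():
            i = int(pos[strands == "?"][0])
            raise ValueError(f"reference base at {chrom}:{i} is not C/G; cannot infer strand")
        frame.loc[grp.index, "strand"] = strands
    return frame


_CGMAP_CTX = {"CG_sym": "CG", "CG_other": "CG", "CHG": "CHG", "CHH": "CHH",
              "ambiguous": "--", "unclassified": "--"}


def write_cgmap(frame: pd.DataFrame, path) -> None:
    """Write a sites frame in CGmap layout (inverse of the cgmap dialect)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(frame["n_total"] > 0, frame["n_meth"] / frame["n_total"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "watson_base": np.where(frame["strand"] == "+", "C", "G"),
            "pos1": frame["pos"] + 1,
            "ctx": frame["context"].map(_CGMAP_CTX).fillna("--"),
            "dinuc": frame["context"].map(_CGMAP_CTX).fillna("--"),
            "level": np.round(level, 4),
            "n_meth": frame["n_meth"],
            "n_total": frame["n_total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph_cov(frame: pd.DataFrame, path) -> None:
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(frame["n_total"] > 0,
                       100.0 * frame["n_meth"] / frame["n_total"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["pos"],
            "end": frame["pos"] + 1,
            "pct": np.round(pct, 2),
            "n_meth": frame["n_meth"],
            "n_unmeth": frame["n_total"] - frame["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path, report: ParseReport | None = None) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based inclusive -> 0-based half-open).

    One :class:`GeneModel` per gene; exons come from the gene's longest mRNA
    (span length; ties broken by (start, end, id)). Genes lacking mRNA/exon
    children get a single exon equal to the gene span, with a warning. An exon
    extending outside its gene span is a hard error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique",
        keep_order=True, sort_attribute_values=False,
    )
    genes: list[GeneModel] = []
    n_span_exon = 0
    for g in db.features_of_type("gene", order_by=("seqid", "start", "end")):
        gid = g.id
        interval = GenomicInterval(
            chrom=g.seqid, start=g.start - 1, end=g.end, strand=g.strand or ".",
            kind="gene", attrs={"gene_id": gid},
        )
        mrnas = list(db.children(g, featuretype="mRNA", order_by=("start", "end")))
        exon_feats = []
        if mrnas:
            best = max(mrnas, key=lambda m: (m.end - m.start + 1, -m.start, -m.end))
            exon_feats = list(db.children(best, featuretype="exon", order_by="start"))
        else:
            exon_feats = list(db.children(g, featuretype="exon", order_by="start"))
        if not exon_feats:
            n_span_exon += 1
            exons = [GenomicInterval(g.seqid, g.start - 1, g.end, interval.strand, kind="exon")]
        else:
            exons = []
            for e in exon_feats:
                if e.start < g.start or e.end > g.end:
                    raise ValueError(
                        f"exon {e.start}-{e.end} outside gene {gid} span {g.start}-{g.end}"
                    )
                exons.append(
                    GenomicInterval(g.seqid, e.start - 1, e.end, interval.strand, kind="exon")
                )
        genes.append(GeneModel(gene_id=gid, interval=interval, exons=exons))
    if n_span_exon:
        log.warning("%d genes lacked exon features; used gene span as single exon", n_span_exon)
    if report is not None:
        report.n_records = len(genes)
        report.n_warnings = n_span_exon
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tgevescan\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\tgevescan\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for i, e in enumerate(sorted(g.exons, key=lambda e: e.start), 1):
                fh.write(
                    f"{iv.chrom}\tgevescan\texon\t{e.start + 1}\t{e.end}\t.\t{iv.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# TE tables
# ---------------------------------------------------------------------------

def read_te_table(path, dialect: str = "bed_plus",
                  report: ParseReport | None = None) -> list[GenomicInterval]:
    """Read TE annotations into intervals with family/divergence attrs.

    ``bed_plus``: headered TSV with columns chrom, start, end, strand, family,
    divergence, consensus_length (0-based half-open).
    ``repeatmasker_out``: the RepeatMasker .out fixed-column layout (1-based
    inclusive query coordinates; consensus length recovered from the
    repeat-coordinate columns).

    attrs carry family, divergence, consensus_length and
    consensus_span_fraction = (end - start) / consensus_length.
    """
    if dialect == "bed_plus":
        tes = _read_te_bed_plus(path)
    elif dialect == "repeatmasker_out":
        tes = _read_repeatmasker_out(path)
    else:
        raise ValueError(f"unknown TE dialect: {dialect!r}")
    if report is not None:
        report.n_records = len(tes)
    return tes


def _te_interval(chrom, start, end, strand, family, divergence, consensus_length):
    attrs = {"family": family, "divergence": float(divergence)}
    if consensus_length is not None and consensus_length > 0:
        attrs["consensus_length"] = int(consensus_length)
        attrs["consensus_span_fraction"] = (end - start) / consensus_length
    return GenomicInterval(chrom, int(start), int(end), strand, kind="TE", attrs=attrs)


def _read_te_bed_plus(path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "family", "divergence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TE columns {sorted(missing)}")
    tes = []
    for row in df.itertuples(index=False):
        cons = getattr(row, "consensus_length", None)
        cons = None if cons is None or (isinstance(cons, float) and math.isnan(cons)) else cons
        tes.append(
            _te_interval(row.chrom, row.start, row.end, getattr(row, "strand", "."),
                         row.family, row.divergence, cons)
        )
    return tes


def _read_repeatmasker_out(path) -> list[GenomicInterval]:
    tes = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].replace(".", "").isdigit():
                continue  # header / blank lines
            # score div del ins query qbegin qend qleft strand repeat class
            #   rbegin rend rleft [id]
            div = float(parts[1])
            chrom = parts[4]
            qbegin, qend = int(parts[5]), int(parts[6])
            strand_raw = parts[8]
            strand = "+" if strand_raw == "+" else "-"
            family = f"{parts[9]}#{parts[10]}"
            if strand == "+":
                rbegin, rend, rleft = parts[11], parts[12], parts[13]
            else:  # C strand prints (left) end begin
                rleft, rend, rbegin = parts[11], parts[12], parts[13]
            rend_i = int(rend)
            rleft_i = int(rleft.strip("()"))
            consensus_length = rend_i + rleft_i
            tes.append(
                _te_interval(chrom, qbegin - 1, qend, strand, family, div, consensus_length)
            )
    return tes


def write_te_table(tes: list[GenomicInterval], path) -> None:
    rows = []
    for te in tes:
        rows.append(
            {
                "chrom": te.chrom, "start": te.start, "end": te.end,
                "strand": te.strand, "family": te.attrs.get("family", "."),
                "divergence": te.attrs.get("divergence", float("nan")),
                "consensus_length": te.attrs.get("consensus_length", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plain TSV tables
# ---------------------------------------------------------------------------

def read_expression_table(path, groups: dict[str, str]) -> ExpressionTable:
    """TSV with a gene_id column and one TPM column per condition."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expression table needs a gene_id column")
    df = df.set_index("gene_id")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative TPM values")
    return ExpressionTable(tpm=df, groups=dict(groups))


def write_expression_table(expr: ExpressionTable, path) -> None:
    expr.tpm.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_de_table(path) -> pd.DataFrame:
    """Differential expression results: gene_id, log2FC, padj (one row/gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2FC", "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: DE table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in DE table")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError(f"{path}: padj outside [0, 1]")
    return df


def read_domain_hits(path) -> pd.DataFrame:
    """Domain hits: gene_id, domain_accession[, domain_name]; pairs unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "domain_accession"):
        if col not in df.columns:
            raise ValueError(f"{path}: domain table missing column {col!r}")
    if "domain_name" not in df.columns:
        df["domain_name"] = df["domain_accession"]
    if df.duplicated(subset=["gene_id", "domain_accession"]).any():
        raise ValueError(f"{path}: duplicate (gene_id, domain_accession) pairs")
    return df[["gene_id", "domain_accession", "domain_name"]]
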