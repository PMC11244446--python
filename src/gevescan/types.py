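"""Shared domain types.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based formats (GFF3, CGmap) happens only at parse/write boundaries.

Per-cytosine methylation calls are carried as a :class:`pandas.DataFrame` of
site records ("sites frame") with columns

    chrom (str), pos (int, 0-based cytosine position), strand ('+'/'-'/'.'),
    context (one of CONTEXT_CLASSES or 'unclassified'), n_meth (int), n_total (int)

A scalar :class:`MethylationSite` dataclass is provided for record-level APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Extended CG-trinucleotide context classes.
CG_SYM = "CG_sym"        # symmetric CGC / GCG family (mCGC and GmCG)
CG_OTHER = "CG_other"    # CG dinucleotides outside the CGC/GCG family
CHG = "CHG"
CHH = "CHH"
AMBIGUOUS = "ambiguous"  # a required flanking base is N or out of range
UNCLASSIFIED = "unclassified"

CONTEXT_CLASSES = (CG_SYM, CG_OTHER, CHG, CHH, AMBIGUOUS)

SITE_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")


class GenomeSequence:
    """A named genome: chromosome id -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str], name: str = "genome"):
        if not sequences:
            raise ValueError("genome has no sequences")
        for chrom, seq in sequences.items():
            if len(seq) < 1:
                raise ValueError(f"sequence {chrom!r} is empty")
        self.name = name
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self._arrays: dict[str, np.ndarray] = {}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 0-based position; raises for out-of-range lookups."""
        seq = self.sequences[chrom]
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} out of range for {chrom} (len {len(seq)})")
        return seq[pos]

    def as_array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.sequences[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]


@dataclass
class MethylationSite:
    """One cytosine's call: coordinates on its own strand plus read counts."""

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_total: int
    context: str = UNCLASSIFIED

    def __post_init__(self):
        if self.n_meth > self.n_total:
            raise ValueError(f"n_meth {self.n_meth} > n_total {self.n_total}")
        if self.n_meth < 0:
            raise ValueError("negative read count")


def empty_sites_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "context": pd.Series(dtype=object),
            "n_meth": pd.Series(dtype=np.int64),
            "n_total": pd.Series(dtype=np.int64),
        }
    )


def sites_frame(sites) -> pd.DataFrame:
    """Build a sites frame from an iterable of MethylationSite records."""
    sites = list(sites)
    if not sites:
        return empty_sites_frame()
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": np.asarray([s.pos for s in sites], dtype=np.int64),
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "n_meth": np.asarray([s.n_meth for s in sites], dtype=np.int64),
            "n_total": np.asarray([s.n_total for s in sites], dtype=np.int64),
        }
    )


def iter_sites(frame: pd.DataFrame):
    """Iterate a sites frame as MethylationSite records."""
    for row in frame.itertuples(index=False):
        yield MethylationSite(
            chrom=row.chrom, pos=int(row.pos), strand=row.strand,
            n_meth=int(row.n_meth), n_total=int(row.n_total), context=row.context,
        )


@dataclass
class GenomicInterval:
    """Strand-aware 0-based half-open interval (genes, TEs, windows, islands...)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    """A gene with its exon structure (exons from one representative mRNA)."""

    gene_id: str
    interval: GenomicInterval
    exons: list  # GenomicInterval, sorted 5'->3' on the gene strand

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        fwd = sorted(self.exons, key=lambda e: e.start)
        for e in fwd:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(
                    f"exon {e.start}-{e.end} outside gene {self.gene_id} span "
                    f"{self.interval.start}-{self.interval.end}"
                )
        for a, b in zip(fwd, fwd[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        # store 5'->3' on the gene strand
        self.exons = fwd if self.strand != "-" else fwd[::-1]

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1


@dataclass
class ExpressionTable:
    """TPM per gene per condition, with a condition -> group labelling."""

    tpm: pd.DataFrame                 # index gene_id, columns = condition ids
    groups: dict[str, str]            # condition -> {control, development, treatment}

    def __post_init__(self):
        if self.tpm.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        missing = [c for c in self.tpm.columns if c not in self.groups]
        if missing:
            raise ValueError(f"conditions without a group label: {missing}")

    def conditions(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.tpm.columns)
        return [c for c in self.tpm.columns if self.groups[c] == group]


@dataclass
class Island:
    """A detected hypermethylated block."""

    interval: GenomicInterval
    mean_level: float
    n_windows: int
    supporting_sites: int
    refined: bool = False

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length
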