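"""Core in-memory containers for the enrichment pipeline.

Coordinate conventions
----------------------
GWAS summary statistics carry 1-based positions (the convention of published
summary-statistic files); all genomic intervals (annotations, transcripts,
derived association intervals) are 0-based half-open, as in BED.  The single
conversion point is interval lookup: a SNP at 1-based position ``pos`` falls
in ``[start, end)`` iff ``start <= pos - 1 < end``.

Chromosome names are normalised to the ``chr``-prefixed form on construction
(``"6" -> "chr6"``) so that tables and annotations from different sources
compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "pvalue", "maf", "allele1", "allele2"]

#: conventional genome-wide significance threshold for GWAS p-values
GENOME_WIDE_SIG = 5e-8

#: extended MHC region masked in the schizophrenia analyses (hg19)
MHC_REGION = ("chr6", 25_000_000, 35_000_000)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyInputError(ValueError):
    """Raised when an input holds no usable records."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if not chrom:
        raise FormatError("empty chromosome name")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.end:
            raise FormatError(
                f"interval start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if not self.label:
            object.__setattr__(self, "label", f"{self.chrom}:{self.start}-{self.end}")

    def contains_pos1(self, chrom: str, pos1: int) -> bool:
        """Membership test for a 1-based SNP position (the 0/1-based seam)."""
        return chrom == self.chrom and self.start <= pos1 - 1 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GwasTable:
    """Per-SNP summary statistics for a single trait.

    ``records`` is a DataFrame with columns ``snp_id, chrom, pos, pvalue,
    maf, allele1, allele2`` (``maf``/alleles may be missing).  Invariants:
    unique SNP ids, ``pos >= 1``, ``0 < pvalue <= 1``, ``maf in [0, 0.5]``
    when present.
    """

    trait_name: str
    records: pd.DataFrame
    build: str = "hg19"
    n_rejected: int = 0

    def __post_init__(self):
        df = self.records.copy()
        for col in GWAS_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("maf",) else pd.NA
        df = df[GWAS_COLUMNS]
        df["snp_id"] = df["snp_id"].astype(str)
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        df["pvalue"] = df["pvalue"].astype(float)
        df["maf"] = df["maf"].astype(float)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id in GWAS table: {dup!r}")
        if (df["pos"] < 1).any():
            raise FormatError("GWAS positions must be >= 1 (1-based)")
        if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
            raise FormatError("GWAS p-values must lie in (0, 1]")
        maf = df["maf"].dropna()
        if ((maf < 0) | (maf > 0.5)).any():
            raise FormatError("MAF must lie in [0, 0.5]")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> set:
        return set(self.records["snp_id"])

    @property
    def pvalues(self) -> np.ndarray:
        return self.records["pvalue"].to_numpy()

    def positions(self) -> Mapping[str, tuple]:
        """snp_id -> (chrom, 1-based pos)."""
        r = self.records
        return dict(zip(r["snp_id"], zip(r["chrom"], r["pos"])))

    def subset(self, ids: Iterable[str], trait_name: Optional[str] = None) -> "GwasTable":
        ids = set(ids)
        df = self.records[self.records["snp_id"].isin(ids)]
        return GwasTable(trait_name or self.trait_name, df, build=self.build)

    def with_pvalues(self, pvalues: np.ndarray) -> "GwasTable":
        df = self.records.copy()
        df["pvalue"] = np.asarray(pvalues, dtype=float)
        return GwasTable(self.trait_name, df, build=self.build)

    def sorted_by_position(self) -> "GwasTable":
        df = self.records.sort_values(["chrom", "pos"], kind="mergesort")
        return GwasTable(self.trait_name, df, build=self.build)


@dataclass
class AnnotationSet:
    """A named evolutionary annotation: genomic intervals or scored markers."""

    name: str
    kind: str  # "interval" | "marker"
    intervals: list = field(default_factory=list)
    markers: list = field(default_factory=list)  # [(snp_id, score-or-None)]

    def __post_init__(self):
        if self.kind not in ("interval", "marker"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.kind == "interval":
            if self.markers or not self.intervals:
                raise ValueError("interval annotation must populate intervals only")
        else:
            if self.intervals or not self.markers:
                raise ValueError("marker annotation must populate markers only")

    def __len__(self) -> int:
        return len(self.intervals) if self.kind == "interval" else len(self.markers)

    @property
    def marker_ids(self) -> list:
        if self.kind != "marker":
            raise TypeError(f"annotation {self.name!r} is not marker-kind")
        return [m for m, _ in self.markers]


class LDStore:
    """Symmetric pairwise r² relation over SNP ids.

    Self-pairs are implicit with r² = 1; ``neighbors`` therefore always
    includes the query SNP itself.
    """

    def __init__(self, pairs: Iterable[tuple] = ()):
        adj: dict = {}
        self._adj = adj
        for a, b, r2 in pairs:
            r2 = float(r2)
            if not 0.0 <= r2 <= 1.0:
                raise FormatError(f"r² out of [0,1] for pair ({a}, {b}): {r2}")
            if a == b:
                continue
            for x, y in ((a, b), (b, a)):
                dx = adj.get(x)
                if dx is None:
                    adj[x] = {y: r2}
                else:
                    prev = dx.get(y)
                    if prev is None or r2 > prev:
                        dx[y] = r2

    @classmethod
    def from_blocks(cls, blocks: Iterable[tuple]) -> "LDStore":
        """Build a store from (ids, r2) blocks: all within-block pairs share r2."""
        store = cls()
        adj = store._adj
        for ids, r2 in blocks:
            r2 = float(r2)
            if not 0.0 <= r2 <= 1.0:
                raise FormatError(f"block r² out of [0,1]: {r2}")
            ids = list(ids)
            for i, a in enumerate(ids):
                d = adj.setdefault(a, {})
                for j, b in enumerate(ids):
                    if i != j:
                        prev = d.get(b)
                        if prev is None or r2 > prev:
                            d[b] = r2
        return store

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    @property
    def snps(self) -> set:
        return set(self._adj)

    def partners(self, snp: str) -> Mapping[str, float]:
        return self._adj.get(snp, {})

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, snp: str, r2_min: float) -> set:
        """All partners with r² >= r2_min, plus the SNP itself (self-pair)."""
        out = {snp}
        for b, r2 in self._adj.get(snp, {}).items():
            if r2 >= r2_min:
                out.add(b)
        return out

    def to_pairs(self) -> list:
        seen = set()
        out = []
        for a, nbrs in self._adj.items():
            for b, r2 in nbrs.items():
                key = (a, b) if a <= b else (b, a)
                if key in seen:
                    continue
                seen.add(key)
                out.append((key[0], key[1], r2))
        return sorted(out)


@dataclass
class TranscriptModel:
    """A refFlat-style transcript with exon structure.

    ``cds_start == cds_end`` marks a non-coding transcript.
    """

    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: Sequence[int]
    exon_ends: Sequence[int]
    transcript: str = ""

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if not self.transcript:
            self.transcript = self.gene
        es, ee = list(self.exon_starts), list(self.exon_ends)
        if len(es) != len(ee) or not es:
            raise FormatError(f"{self.gene}: exon start/end lists must be parallel, non-empty")
        if any(s >= e for s, e in zip(es, ee)):
            raise FormatError(f"{self.gene}: exon with start >= end")
        if es != sorted(es) or any(ee[i] > es[i + 1] for i in range(len(es) - 1)):
            raise FormatError(f"{self.gene}: exons must be sorted and non-overlapping")
        if es[0] < self.tx_start or ee[-1] > self.tx_end:
            raise FormatError(f"{self.gene}: exons outside transcript span")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise FormatError(f"{self.gene}: CDS outside transcript span")
        self.exon_starts, self.exon_ends = es, ee

    @property
    def coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, label=self.gene)
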