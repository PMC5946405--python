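"""SNP-to-annotation assignment and the standard GWAS filters.

Two assignment modes, mirroring positional vs LD binning of SNPs into
annotation intervals: a SNP belongs positionally to an interval iff its
(1-based) position minus one falls in the 0-based half-open interval; LD
binning additionally assigns any GWAS SNP in linkage disequilibrium
(r² >= ``r2_min``) with a SNP located inside the interval, which recovers
annotation signal when the interval's own SNPs were not genotyped.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

from intervaltree import IntervalTree

from .model import AnnotationSet, GenomicInterval, GwasTable, LDStore, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class BinningResult:
    """SNPs assigned to one annotation, with assignment provenance.

    ``per_interval`` maps each interval to its positionally assigned SNP ids
    (union equals ``positional_ids``); for LD binning, ``per_interval_ld``
    additionally holds the LD-expanded membership per interval.
    """

    annotation_name: str
    positional_ids: Set[str]
    ld_ids: Set[str]
    per_interval: Dict[GenomicInterval, Set[str]]
    params: dict = field(default_factory=dict)
    per_interval_ld: Optional[Dict[GenomicInterval, Set[str]]] = None

    @property
    def assigned_per_interval(self) -> Dict[GenomicInterval, Set[str]]:
        """LD-expanded membership when available, else positional."""
        return self.per_interval_ld if self.per_interval_ld is not None else self.per_interval


def _interval_trees(annotation: AnnotationSet) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in annotation.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def positional_bin(gwas: GwasTable, annotation: AnnotationSet) -> BinningResult:
    """Assign each GWAS SNP to every annotation interval containing it."""
    if annotation.kind != "interval":
        raise TypeError(f"positional_bin requires an interval annotation, got {annotation.kind}")
    trees = _interval_trees(annotation)
    per_interval: Dict[GenomicInterval, Set[str]] = {iv: set() for iv in annotation.intervals}
    positional: Set[str] = set()
    rec = gwas.records
    for snp_id, chrom, pos in zip(rec["snp_id"], rec["chrom"], rec["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree[pos - 1]  # the single 1-based -> 0-based seam
        if hits:
            positional.add(snp_id)
            for h in hits:
                per_interval[h.data].add(snp_id)
    return BinningResult(
        annotation_name=annotation.name,
        positional_ids=positional,
        ld_ids=set(positional),
        per_interval=per_interval,
        params={"mode": "positional"},
    )


def ld_bin(
    gwas: GwasTable,
    annotation: AnnotationSet,
    ld: LDStore,
    r2_min: float = 0.8,
    extra_positions: Optional[Mapping[str, tuple]] = None,
) -> BinningResult:
    """Positional assignment plus LD proxies at r² >= ``r2_min``.

    Seed SNPs are those located inside the intervals — GWAS SNPs, plus any
    ids in ``extra_positions`` (snp_id -> (chrom, 1-based pos)) that the GWAS
    did not genotype but the LD store knows.  For marker-kind annotations the
    markers themselves are the seed set.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError("r2_min must lie in (0, 1]")
    if annotation.kind == "interval":
        base = positional_bin(gwas, annotation)
        seeds = set(base.positional_ids)
        if extra_positions:
            for snp_id, (chrom, pos1) in extra_positions.items():
                for iv in annotation.intervals:
                    if iv.contains_pos1(chrom, pos1):
                        seeds.add(snp_id)
                        break
    else:
        seeds = set(annotation.marker_ids)
        gwas_ids = gwas.ids
        base = BinningResult(
            annotation_name=annotation.name,
            positional_ids=seeds & gwas_ids,
            ld_ids=set(),
            per_interval={},
            params={"mode": "ld", "r2_min": r2_min},
        )

    if len(ld) == 0 and not ld.snps:
        logger.warning("empty LD store: LD binning degrades to positional assignment")
        base.params = dict(base.params, mode="ld", r2_min=r2_min)
        base.ld_ids = set(base.positional_ids)
        base.per_interval_ld = {iv: set(ids) for iv, ids in base.per_interval.items()} or None
        return base

    gwas_ids = gwas.ids
    ld_assigned: Set[str] = set(base.positional_ids)
    per_interval_ld: Dict[GenomicInterval, Set[str]] = {
        iv: set(ids) for iv, ids in base.per_interval.items()
    }
    if annotation.kind == "interval":
        # per-interval seeds: positional members plus located extra ids
        for iv, members in base.per_interval.items():
            iv_seeds = set(members)
            if extra_positions:
                iv_seeds |= {
                    s for s, (chrom, pos1) in extra_positions.items()
                    if iv.contains_pos1(chrom, pos1)
                }
            expanded = set(iv_seeds)
            for seed in iv_seeds:
                expanded |= ld.neighbors(seed, r2_min)
            found = expanded & gwas_ids
            per_interval_ld[iv] |= found
            ld_assigned |= found
    else:
        for seed in seeds:
            ld_assigned |= ld.neighbors(seed, r2_min) & gwas_ids

    return BinningResult(
        annotation_name=annotation.name,
        positional_ids=base.positional_ids,
        ld_ids=ld_assigned,
        per_interval=base.per_interval,
        params={"mode": "ld", "r2_min": r2_min},
        per_interval_ld=per_interval_ld if annotation.kind == "interval" else None,
    )


def mask_region(gwas: GwasTable, chrom: str, start_bp: int, end_bp: int) -> GwasTable:
    """Remove all SNPs whose 0-based position falls in [start_bp, end_bp)."""
    from .model import normalize_chrom

    chrom = normalize_chrom(chrom)
    rec = gwas.records
    inside = (
        (rec["chrom"] == chrom)
        & (rec["pos"] - 1 >= start_bp)
        & (rec["pos"] - 1 < end_bp)
    )
    n_removed = int(inside.sum())
    logger.info("mask %s:%d-%d removed %d SNPs", chrom, start_bp, end_bp, n_removed)
    out = GwasTable(gwas.trait_name, rec[~inside], build=gwas.build)
    if len(out) == 0:
        logger.warning("mask removed every SNP from %s", gwas.trait_name)
    return out


def filter_maf(gwas: GwasTable, min_maf: float) -> GwasTable:
    """Keep SNPs with MAF >= ``min_maf``; missing MAF fails the filter."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    rec = gwas.records
    missing = rec["maf"].isna()
    if missing.any():
        logger.warning(
            "%d SNPs without MAF dropped by the MAF filter (conservative)",
            int(missing.sum()),
        )
    keep = ~missing & (rec["maf"] >= min_maf)
    return GwasTable(gwas.trait_name, rec[keep], build=gwas.build)


def filter_nss_negative(annotation: AnnotationSet) -> AnnotationSet:
    """Keep markers with strictly negative scores (positive selection in humans)."""
    if annotation.kind != "marker":
        raise TypeError("filter_nss_negative requires a marker annotation")
    kept = [(m, s) for m, s in annotation.markers if s is not None and s < 0]
    if not kept:
        from .model import EmptyInputError

        raise EmptyInputError(
            f"annotation {annotation.name!r}: no markers with negative scores"
        )
    return AnnotationSet(annotation.name, "marker", markers=kept)


def intersect_common_snps(tables: List[GwasTable]) -> Set[str]:
    """SNP ids present in every table (the cross-study common-marker set)."""
    if len(tables) < 2:
        raise ValueError("need at least two GWAS tables to intersect")
    common = tables[0].ids
    for t in tables[1:]:
        common &= t.ids
    if not common:
        logger.warning("common-SNP intersection is empty")
    return common


SnpProportion = namedtuple("SnpProportion", ["positional", "ld"])


def snp_proportion(binning: BinningResult, gwas: GwasTable) -> SnpProportion:
    """Annotation SNP counts normalised by the GWAS marker count."""
    n = len(gwas)
    if n == 0:
        raise ValueError("empty GWAS table")
    return SnpProportion(len(binning.positional_ids) / n, len(binning.ld_ids) / n)


_PRECEDENCE = {"5'UTR": 0, "3'UTR": 1, "exon": 2, "intron": 3}


def _classify_in_transcript(pos0: int, t: TranscriptModel) -> Optional[str]:
    if not (t.tx_start <= pos0 < t.tx_end):
        return None
    exonic = any(s <= pos0 < e for s, e in zip(t.exon_starts, t.exon_ends))
    if not exonic:
        return "intron"
    if not t.coding:
        return "exon"
    if pos0 < t.cds_start:
        return "5'UTR" if t.strand == "+" else "3'UTR"
    if pos0 >= t.cds_end:
        return "3'UTR" if t.strand == "+" else "5'UTR"
    return "exon"


def genic_context(
    gwas: GwasTable, transcripts: Iterable[TranscriptModel]
) -> Dict[str, str]:
    """Classify each SNP as 5'UTR / 3'UTR / exon / intron / intergenic.

    UTRs are exonic sequence outside the CDS, oriented by strand; when
    transcripts disagree the most specific call wins
    (5'UTR > 3'UTR > exon > intron).
    """
    trees: Dict[str, IntervalTree] = {}
    for t in transcripts:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.tx_start, t.tx_end, t)
    out: Dict[str, str] = {}
    rec = gwas.records
    for snp_id, chrom, pos in zip(rec["snp_id"], rec["chrom"], rec["pos"]):
        pos0 = pos - 1
        best = None
        tree = trees.get(chrom)
        if tree is not None:
            for hit in tree[pos0]:
                call = _classify_in_transcript(pos0, hit.data)
                if call is not None and (best is None or _PRECEDENCE[call] < _PRECEDENCE[best]):
                    best = call
        out[snp_id] = best if best is not None else "intergenic"
    return out
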