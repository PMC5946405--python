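"""Enriched-region identification and region-to-gene mapping.

Turns a binning result plus GC-corrected association p-values into the set
of annotation regions carrying signal, then maps those regions to gene
lists: genes directly overlapping an enriched region, and genes linked
through linkage disequilibrium with an enriched SNP (an r²-threshold
approximation to LD-block gene assignment).  These lists are what a
downstream pathway analysis would consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .binning import BinningResult
from .model import GENOME_WIDE_SIG, GenomicInterval, GwasTable, LDStore, TranscriptModel

logger = logging.getLogger(__name__)


def gene_spans(transcripts: Sequence[TranscriptModel]) -> List[GenomicInterval]:
    """One genomic span per gene name (min tx_start to max tx_end)."""
    acc: Dict[str, list] = {}
    for t in transcripts:
        if t.gene in acc:
            g = acc[t.gene]
            if g[0] != t.chrom:
                raise ValueError(f"gene {t.gene!r} spans multiple chromosomes")
            g[1] = min(g[1], t.tx_start)
            g[2] = max(g[2], t.tx_end)
        else:
            acc[t.gene] = [t.chrom, t.tx_start, t.tx_end]
    return [GenomicInterval(c, s, e, label=name) for name, (c, s, e) in acc.items()]


@dataclass
class EnrichedRegionSet:
    annotation_name: str
    regions: List[GenomicInterval]
    enriched_snp_ids: Set[str]
    p_cutoff: float


@dataclass
class GeneLists:
    direct_genes: Set[str]
    ld_genes: Set[str]

    @property
    def counts(self) -> Tuple[int, int]:
        return len(self.direct_genes), len(self.ld_genes)


def enriched_regions(
    binning: BinningResult,
    gwas_corrected: GwasTable,
    p_cutoff: float = GENOME_WIDE_SIG,
    exclude_region: Optional[Tuple[str, int, int]] = None,
) -> EnrichedRegionSet:
    """Annotation regions with >= 1 assigned SNP at corrected p <= cutoff.

    Assignment follows the binning result (LD-expanded membership when the
    binning carried it).  ``exclude_region`` drops regions overlapping the
    given (chrom, start, end) span, e.g. the extended MHC.
    """
    pmap = dict(zip(gwas_corrected.records["snp_id"], gwas_corrected.records["pvalue"]))
    mask_iv = None
    if exclude_region is not None:
        mask_iv = GenomicInterval(*exclude_region, label="mask")
    regions: List[GenomicInterval] = []
    snp_ids: Set[str] = set()
    for iv, members in binning.assigned_per_interval.items():
        if mask_iv is not None and iv.overlaps(mask_iv):
            continue
        hits = {m for m in members if m in pmap and pmap[m] <= p_cutoff}
        if hits:
            regions.append(iv)
            snp_ids |= hits
    regions.sort(key=lambda iv: (iv.chrom, iv.start))
    return EnrichedRegionSet(
        annotation_name=binning.annotation_name,
        regions=regions,
        enriched_snp_ids=snp_ids,
        p_cutoff=p_cutoff,
    )


def map_to_genes(
    regions: EnrichedRegionSet,
    transcripts: Sequence[TranscriptModel],
    ld: LDStore,
    gwas: GwasTable,
    flank_bp: int = 0,
    r2_min: float = 0.8,
) -> GeneLists:
    """Map enriched regions to direct-overlap and LD-linked gene lists.

    ``direct_genes``: genes whose span (+- ``flank_bp``) overlaps an enriched
    region.  ``ld_genes``: genes whose span contains a SNP in LD
    (r² >= ``r2_min``) with an enriched SNP; positions of LD partners come
    from the GWAS table.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    spans = gene_spans(transcripts)
    direct: Set[str] = set()
    for g in spans:
        gs, ge = max(g.start - flank_bp, 0), g.end + flank_bp
        for iv in regions.regions:
            if iv.chrom == g.chrom and gs < iv.end and iv.start < ge:
                direct.add(g.label)
                break

    pos_of = gwas.positions()
    ld_linked: Set[str] = set()
    partner_pos = []
    for snp in regions.enriched_snp_ids:
        for partner in ld.neighbors(snp, r2_min):
            loc = pos_of.get(partner)
            if loc is not None:
                partner_pos.append(loc)
    for g in spans:
        for chrom, pos1 in partner_pos:
            if chrom == g.chrom and g.start <= pos1 - 1 < g.end:
                ld_linked.add(g.label)
                break
    return GeneLists(direct_genes=direct, ld_genes=ld_linked)
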