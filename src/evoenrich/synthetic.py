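"""Synthetic GWAS / LD / annotation generator with planted enrichment.

The generator emulates the statistical structure the enrichment analysis
consumes: a genome of SNPs with block-structured LD (constant r² within
blocks of consecutive SNPs), near-uniform null p-values with a controllable
genomic inflation, a "target" interval annotation in which a chosen fraction
of intervals carries association signal (z-scores with mean ``noncentrality``,
hence mean χ² of 1 + δ²), a signal-free "control" annotation, and transcript
models so that every interval lies inside a gene.  All randomness flows from
one seed; the same config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.special import erfc

from .model import AnnotationSet, GenomicInterval, GwasTable, LDStore, TranscriptModel
from . import io as eio


class ConfigError(ValueError):
    """Raised when a synthetic config cannot be realised."""


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale genome: 10,000 SNPs on 4 chromosomes at
    ~1 kb spacing, LD blocks of 10 SNPs at r² = 0.9, and two disjoint
    20-interval annotations of 16 SNPs each (the per-region SNP count of the
    enriched differentially methylated regions in the motivating analysis,
    ≈ 5338 SNPs / 329 regions).
    """

    n_chrom: int = 4
    snps_per_chrom: int = 2500
    block_size: int = 10
    within_block_r2: float = 0.9
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_annotation_intervals: int = 20
    interval_span_snps: int = 16
    enriched_fraction: float = 0.1
    noncentrality: float = 0.0
    background_inflation: float = 1.0
    n_background_genes: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chrom", "snps_per_chrom", "block_size",
                     "n_annotation_intervals", "interval_span_snps"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("within_block_r2", "enriched_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noncentrality < 0:
            raise ConfigError("noncentrality must be >= 0")
        if self.background_inflation < 1.0:
            raise ConfigError("background_inflation must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 <= low <= high <= 0.5")


@dataclass
class SyntheticDataset:
    gwas: GwasTable
    ld: LDStore
    annotations: Dict[str, AnnotationSet]
    genes: List[TranscriptModel]
    truth: Dict[str, bool]            # target interval label -> planted signal
    enriched_ids: set                 # SNP ids inside enriched target intervals
    config: SyntheticConfig = None


def _place_disjoint_runs(rng, n_chrom, snps_per_chrom, span, count, occupied):
    """Choose ``count`` disjoint runs of ``span`` consecutive SNP indices,
    uniform over chromosome-local index space, avoiding ``occupied``."""
    if span > snps_per_chrom:
        raise ConfigError("interval_span_snps exceeds snps_per_chrom")
    runs = []
    attempts = 0
    max_attempts = 2000 * count
    while len(runs) < count:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                "interval placement impossible: genome too small for "
                f"{count} disjoint intervals of {span} SNPs"
            )
        c = int(rng.integers(n_chrom))
        s = int(rng.integers(snps_per_chrom - span + 1))
        if occupied[c][s : s + span].any():
            continue
        occupied[c][s : s + span] = True
        runs.append((c, s))
    return runs


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_chrom, m = config.n_chrom, config.snps_per_chrom
    n_total = n_chrom * m
    span = config.interval_span_snps
    if 2 * config.n_annotation_intervals * span > 0.9 * n_total:
        raise ConfigError("interval placement impossible: annotations would cover >90% of SNPs")

    # positions: ~1 kb spacing, strictly increasing within chromosome
    spacing = rng.integers(500, 1500, size=(n_chrom, m))
    pos = 10_000 + np.cumsum(spacing, axis=1)  # 1-based
    chroms = [f"chr{c + 1}" for c in range(n_chrom)]
    chrom_col = np.repeat(chroms, m)
    pos_col = pos.reshape(-1)
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(n_total)])
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_total)

    # annotation placement over SNP index space, disjoint across both sets
    occupied = [np.zeros(m, dtype=bool) for _ in range(n_chrom)]
    target_runs = _place_disjoint_runs(
        rng, n_chrom, m, span, config.n_annotation_intervals, occupied)
    control_runs = _place_disjoint_runs(
        rng, n_chrom, m, span, config.n_annotation_intervals, occupied)

    def runs_to_intervals(runs, prefix):
        ivs, idx_lists = [], []
        for k, (c, s) in enumerate(runs):
            g0 = c * m + s
            idx = np.arange(g0, g0 + span)
            start0 = int(pos_col[idx[0]]) - 1
            end0 = int(pos_col[idx[-1]])  # half-open; covers last SNP
            ivs.append(GenomicInterval(chroms[c], start0, end0, f"{prefix}{k + 1:04d}"))
            idx_lists.append(idx)
        return ivs, idx_lists

    target_ivs, target_idx = runs_to_intervals(target_runs, "T")
    control_ivs, control_idx = runs_to_intervals(control_runs, "C")

    n_enriched = int(round(config.enriched_fraction * config.n_annotation_intervals))
    enriched_choice = rng.choice(
        config.n_annotation_intervals, size=n_enriched, replace=False)
    enriched_mask = np.zeros(config.n_annotation_intervals, dtype=bool)
    enriched_mask[enriched_choice] = True
    truth = {iv.label: bool(enriched_mask[k]) for k, iv in enumerate(target_ivs)}

    # association z-scores: null scaled by sqrt(lambda_true); signal mean delta
    z = rng.standard_normal(n_total) * np.sqrt(config.background_inflation)
    enriched_snp_idx = (
        np.concatenate([target_idx[k] for k in range(len(target_ivs)) if enriched_mask[k]])
        if n_enriched else np.array([], dtype=int)
    )
    if enriched_snp_idx.size:
        z[enriched_snp_idx] = config.noncentrality + rng.standard_normal(enriched_snp_idx.size)
    pvals = np.clip(erfc(np.abs(z) / np.sqrt(2.0)), 1e-300, 1.0)  # two-sided

    gwas = GwasTable(
        "synthetic",
        pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom_col, "pos": pos_col,
            "pvalue": pvals, "maf": maf, "allele1": "A", "allele2": "G",
        }),
        build="synthetic-1.0",
    )

    # constant-r² LD blocks over consecutive SNPs within a chromosome
    bs = config.block_size
    blocks = (
        (snp_ids[c * m + b0 : c * m + min(b0 + bs, m)], config.within_block_r2)
        for c in range(n_chrom)
        for b0 in range(0, m, bs)
    )
    ld = LDStore.from_blocks(blocks)

    genes: List[TranscriptModel] = []
    chrom_min = {chroms[c]: int(pos[c, 0]) - 1 for c in range(n_chrom)}
    chrom_max = {chroms[c]: int(pos[c, -1]) for c in range(n_chrom)}

    def make_gene(name, chrom, gs, ge, strand):
        third = max((ge - gs) // 3, 2)
        exon_starts = [gs, ge - third]
        exon_ends = [gs + third, ge]
        return TranscriptModel(
            gene=name, chrom=chrom, strand=strand, tx_start=gs, tx_end=ge,
            cds_start=gs + 50, cds_end=ge - 50,
            exon_starts=exon_starts, exon_ends=exon_ends,
        )

    for iv in target_ivs + control_ivs:
        pad_l = int(rng.integers(2000, 5001))
        pad_r = int(rng.integers(2000, 5001))
        gs = max(iv.start - pad_l, 0)
        ge = iv.end + pad_r
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(make_gene(f"G{iv.label}", iv.chrom, gs, ge, strand))
    for k in range(config.n_background_genes):
        c = int(rng.integers(n_chrom))
        chrom = chroms[c]
        length = int(rng.integers(5_000, 50_000))
        lo, hi = chrom_min[chrom], max(chrom_max[chrom] - length, chrom_min[chrom] + 1)
        gs = int(rng.integers(lo, hi))
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(make_gene(f"BG{k + 1:04d}", chrom, gs, gs + length, strand))

    enriched_ids = set(snp_ids[enriched_snp_idx]) if enriched_snp_idx.size else set()
    return SyntheticDataset(
        gwas=gwas,
        ld=ld,
        annotations={
            "target": AnnotationSet("target", "interval", intervals=target_ivs),
            "control": AnnotationSet("control", "interval", intervals=control_ivs),
        },
        genes=genes,
        truth=truth,
        enriched_ids=enriched_ids,
        config=config,
    )


def plant_missingness(dataset: SyntheticDataset, drop_fraction: float, seed: int) -> SyntheticDataset:
    """Remove a random fraction of target-interval SNPs from the GWAS table.

    The LD store is untouched, so LD binning can recover annotation signal
    that positional binning misses once its genotyped SNPs are gone.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    if drop_fraction == 0.0:
        return dataset
    rec = dataset.gwas.records
    in_interval = np.zeros(len(rec), dtype=bool)
    for iv in dataset.annotations["target"].intervals:
        in_interval |= (
            (rec["chrom"].to_numpy() == iv.chrom)
            & (rec["pos"].to_numpy() - 1 >= iv.start)
            & (rec["pos"].to_numpy() - 1 < iv.end)
        )
    rng = np.random.default_rng(seed)
    drop = in_interval & (rng.uniform(size=len(rec)) < drop_fraction)
    if drop.all():
        raise ValueError("dropping would empty the GWAS table")
    gwas = GwasTable(dataset.gwas.trait_name, rec[~drop], build=dataset.gwas.build)
    return replace(dataset, gwas=gwas)


def write_dataset(dataset: SyntheticDataset, outdir, comment_lines=()) -> Dict[str, Path]:
    """Write gwas.tsv, ld.tsv, target.bed, control.bed, genes.refflat, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": outdir / "gwas.tsv",
        "ld": outdir / "ld.tsv",
        "target": outdir / "target.bed",
        "control": outdir / "control.bed",
        "genes": outdir / "genes.refflat",
        "truth": outdir / "truth.tsv",
    }
    eio.write_gwas_summary(dataset.gwas, paths["gwas"], comment_lines)
    eio.write_ld_table(dataset.ld, paths["ld"], comment_lines)
    eio.write_bed_intervals(dataset.annotations["target"], paths["target"])
    eio.write_bed_intervals(dataset.annotations["control"], paths["control"])
    eio.write_refflat(dataset.genes, paths["genes"])
    with open(paths["truth"], "w") as fh:
        fh.write("interval\tenriched\n")
        for label, flag in dataset.truth.items():
            fh.write(f"{label}\t{int(flag)}\n")
    return paths
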