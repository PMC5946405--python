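"""Positional and LD binning, filters, genic context — against brute force."""

import numpy as np
import pandas as pd
import pytest

import evoenrich as ev
from evoenrich import AnnotationSet, EmptyInputError, GenomicInterval, LDStore, TranscriptModel
from .conftest import make_gwas


def random_fixture(seed, n_snps=2000, n_intervals=50):
    """Random GWAS + random bp intervals, independent of the generator."""
    rng = np.random.default_rng(seed)
    per_chrom = n_snps // 2
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=(2, per_chrom), replace=False), axis=1)
    gwas = make_gwas(
        [f"s{i}" for i in range(n_snps)],
        ["chr1"] * per_chrom + ["chr2"] * per_chrom,
        np.concatenate(pos),
        rng.uniform(1e-6, 1.0, size=n_snps),
        maf=rng.uniform(0, 0.5, size=n_snps),
    )
    ivs = []
    for k in range(n_intervals):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 1_990_000))
        ivs.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 40_000)), f"iv{k}"))
    return gwas, AnnotationSet("rand", "interval", intervals=ivs)


def brute_force_positional(gwas, annotation):
    """O(n*m) double loop over SNPs and intervals."""
    rec = gwas.records
    per_interval = {}
    for iv in annotation.intervals:
        mask = (
            (rec["chrom"].to_numpy() == iv.chrom)
            & (rec["pos"].to_numpy() - 1 >= iv.start)
            & (rec["pos"].to_numpy() - 1 < iv.end)
        )
        per_interval[iv] = set(rec["snp_id"].to_numpy()[mask])
    return per_interval


class TestPositionalBin:
    def test_boundary_inclusion(self):
        gwas = make_gwas(["a", "b"], ["chr1", "chr1"], [11, 21], [0.5, 0.5])
        ann = AnnotationSet("d", "interval", intervals=[GenomicInterval("chr1", 10, 20, "I")])
        res = ev.positional_bin(gwas, ann)
        assert res.positional_ids == {"a"}  # pos 11 -> 0-based 10 in [10,20); 21 excluded

    def test_marker_annotation_rejected(self, toy_gwas):
        ann = AnnotationSet("m", "marker", markers=[("rs1", None)])
        with pytest.raises(TypeError):
            ev.positional_bin(toy_gwas, ann)

    def test_overlapping_intervals_count_snp_once(self):
        gwas = make_gwas(["a"], ["chr1"], [15], [0.5])
        ann = AnnotationSet("d", "interval", intervals=[
            GenomicInterval("chr1", 10, 20, "I1"), GenomicInterval("chr1", 12, 30, "I2")])
        res = ev.positional_bin(gwas, ann)
        assert res.positional_ids == {"a"}
        assert all("a" in ids for ids in res.per_interval.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        gwas, ann = random_fixture(seed)
        res = ev.positional_bin(gwas, ann)
        expected = brute_force_positional(gwas, ann)
        assert res.per_interval == expected
        assert res.positional_ids == set().union(*expected.values())


class TestLdBin:
    def test_ungenotyped_interval_snp_recovered_via_proxy(self):
        """The motivating case: interval SNP absent from the GWAS, proxy present."""
        gwas = make_gwas(["rs6"], ["chr1"], [500], [0.01])
        ann = AnnotationSet("d", "interval", intervals=[GenomicInterval("chr1", 100, 200, "I")])
        ld = LDStore([("rs5", "rs6", 0.9)])
        res = ev.ld_bin(gwas, ann, ld, r2_min=0.8,
                        extra_positions={"rs5": ("chr1", 150)})
        assert res.positional_ids == set()
        assert res.ld_ids == {"rs6"}
        assert res.per_interval_ld[ann.intervals[0]] == {"rs6"}

    def test_r2_one_without_perfect_proxies_equals_positional(self, null_dataset):
        ann = null_dataset.annotations["target"]
        res = ev.ld_bin(null_dataset.gwas, ann, null_dataset.ld, r2_min=1.0)
        pos = ev.positional_bin(null_dataset.gwas, ann)
        assert res.ld_ids == pos.positional_ids  # blocks have r2 = 0.9 < 1

    def test_superset_and_monotonicity(self, null_dataset):
        ann = null_dataset.annotations["target"]
        pos = ev.positional_bin(null_dataset.gwas, ann).positional_ids
        prev = None
        for r2_min in (1.0, 0.95, 0.9, 0.5, 0.1):
            ids = ev.ld_bin(null_dataset.gwas, ann, null_dataset.ld, r2_min=r2_min).ld_ids
            assert ids >= pos
            if prev is not None:
                assert ids >= prev  # lowering r2_min never shrinks
            prev = ids

    def test_closure_matches_pair_list_scan(self, null_dataset):
        """LD assignment equals a brute-force scan of the raw pair list."""
        ds = ev.plant_missingness(null_dataset, 0.4, seed=9)
        ann = ds.annotations["target"]
        r2_min = 0.8
        res = ev.ld_bin(ds.gwas, ann, ds.ld, r2_min=r2_min)
        gwas_pos = dict(zip(ds.gwas.records["snp_id"],
                            zip(ds.gwas.records["chrom"], ds.gwas.records["pos"])))
        # seeds: genotyped SNPs inside intervals (generator drops only from GWAS)
        seeds = {
            s for s, (c, p) in gwas_pos.items()
            if any(iv.contains_pos1(c, p) for iv in ann.intervals)
        }
        expected = set(seeds)
        for a, b, r2 in ds.ld.to_pairs():
            if r2 >= r2_min:
                if a in seeds and b in gwas_pos:
                    expected.add(b)
                if b in seeds and a in gwas_pos:
                    expected.add(a)
        assert res.ld_ids == expected

    def test_missingness_recovery_by_ld_only(self):
        """Empty an interval's genotyped SNPs: positional finds 0, LD > 0."""
        # block of 4 SNPs; interval covers the two middle ones; both dropped
        gwas = make_gwas(["a", "d"], ["chr1", "chr1"], [100, 400], [0.5, 0.5])
        ann = AnnotationSet("d", "interval",
                            intervals=[GenomicInterval("chr1", 150, 350, "I")])
        ld = LDStore.from_blocks([(["a", "b", "c", "d"], 0.9)])
        pos = ev.positional_bin(gwas, ann)
        assert pos.positional_ids == set()
        res = ev.ld_bin(gwas, ann, ld, r2_min=0.8,
                        extra_positions={"b": ("chr1", 200), "c": ("chr1", 300)})
        assert res.ld_ids == {"a", "d"}

    def test_marker_kind_seeds(self):
        gwas = make_gwas(["rs1", "rs2"], ["chr1", "chr1"], [10, 20], [0.5, 0.5])
        ann = AnnotationSet("nss", "marker", markers=[("rs9", -1.0)])
        ld = LDStore([("rs9", "rs2", 0.85)])
        res = ev.ld_bin(gwas, ann, ld, r2_min=0.8)
        assert res.ld_ids == {"rs2"}

    def test_empty_ld_store_degrades_to_positional(self, null_dataset):
        ann = null_dataset.annotations["target"]
        res = ev.ld_bin(null_dataset.gwas, ann, LDStore(), r2_min=0.8)
        assert res.ld_ids == ev.positional_bin(null_dataset.gwas, ann).positional_ids


class TestFilters:
    def test_mask_region_boundaries(self):
        gwas = make_gwas(
            ["in1", "out1"], ["chr6", "chr6"], [30_000_000, 35_000_001], [0.5, 0.5]
        )
        out = ev.mask_region(gwas, "chr6", 25_000_000, 35_000_000)
        assert out.ids == {"out1"}  # end-exclusive: pos 35,000,001 retained

    def test_mask_count(self, null_dataset):
        rec = null_dataset.gwas.records
        window = rec[(rec["chrom"] == "chr1")].head(100)
        start0 = int(window["pos"].min()) - 1
        end0 = int(window["pos"].max())
        out = ev.mask_region(null_dataset.gwas, "chr1", start0, end0)
        assert len(null_dataset.gwas) - len(out) == 100

    def test_maf_boundary_keeps_equal(self):
        gwas = make_gwas(["a", "b", "c"], ["chr1"] * 3, [1, 2, 3],
                         [0.5] * 3, maf=[0.05, 0.0499, np.nan])
        out = ev.filter_maf(gwas, 0.05)
        assert out.ids == {"a"}  # >= keeps the boundary; missing MAF dropped

    def test_mask_and_maf_commute(self, null_dataset):
        g = null_dataset.gwas
        rec = g.records
        start0 = int(rec["pos"].median())
        a = ev.filter_maf(ev.mask_region(g, "chr2", 0, start0), 0.2)
        b = ev.mask_region(ev.filter_maf(g, 0.2), "chr2", 0, start0)
        assert a.ids == b.ids

    def test_nss_strictly_negative(self):
        ann = AnnotationSet("nss", "marker",
                            markers=[("a", -2.1), ("b", 0.0), ("c", 0.3)])
        out = ev.filter_nss_negative(ann)
        assert out.marker_ids == ["a"]  # zero excluded: strictly negative

    def test_nss_all_negative_is_membership_identity(self):
        ann = AnnotationSet("nss", "marker", markers=[("a", -1.0), ("b", -0.1)])
        assert ev.filter_nss_negative(ann).marker_ids == ann.marker_ids

    def test_nss_no_scores_errors(self):
        ann = AnnotationSet("nss", "marker", markers=[("a", None), ("b", 0.5)])
        with pytest.raises(EmptyInputError):
            ev.filter_nss_negative(ann)


class TestIntersection:
    def test_pairwise(self):
        t1 = make_gwas(["rs1", "rs2"], ["chr1"] * 2, [1, 2], [0.5] * 2)
        t2 = make_gwas(["rs2", "rs3"], ["chr1"] * 2, [2, 3], [0.5] * 2)
        assert ev.intersect_common_snps([t1, t2]) == {"rs2"}
        assert ev.intersect_common_snps([t1, t1]) == {"rs1", "rs2"}

    def test_twelve_tables_with_known_core(self):
        rng = np.random.default_rng(4)
        core = {f"core{i}" for i in range(200)}
        tables = []
        for t in range(12):
            extra = {f"t{t}_{i}" for i in range(rng.integers(10, 50))}
            ids = sorted(core | extra)
            tables.append(make_gwas(ids, ["chr1"] * len(ids),
                                    np.arange(1, len(ids) + 1), [0.5] * len(ids)))
        assert ev.intersect_common_snps(tables) == core


class TestProportionAndGenicContext:
    def test_snp_proportion(self):
        n = 1000
        gwas = make_gwas([f"s{i}" for i in range(n)], ["chr1"] * n,
                         np.arange(1, n + 1), [0.5] * n)
        ann = AnnotationSet("d", "interval", intervals=[GenomicInterval("chr1", 0, 10, "I")])
        res = ev.positional_bin(gwas, ann)
        prop = ev.snp_proportion(res, gwas)
        assert prop.positional == pytest.approx(0.01)

    def test_empty_binning_proportion_zero(self, toy_gwas):
        ann = AnnotationSet("d", "interval", intervals=[GenomicInterval("chr9", 0, 10, "I")])
        prop = ev.snp_proportion(ev.positional_bin(toy_gwas, ann), toy_gwas)
        assert prop == (0.0, 0.0)

    def test_equal_density_traits_have_similar_proportions(self):
        """Interval density fixed => proportions agree across traits (~Fig S3 logic)."""
        props = []
        for seed in (31, 32):
            ds = ev.generate(ev.SyntheticConfig(seed=seed))
            res = ev.positional_bin(ds.gwas, ds.annotations["target"])
            props.append(ev.snp_proportion(res, ds.gwas).positional)
        assert abs(props[0] - props[1]) / props[0] < 0.1

    @pytest.fixture
    def plus_transcript(self):
        # tx [100,500), exons [100,200)+[300,500), cds [150,450)
        return TranscriptModel(gene="G", chrom="chr1", strand="+",
                               tx_start=100, tx_end=500, cds_start=150, cds_end=450,
                               exon_starts=[100, 300], exon_ends=[200, 500])

    @pytest.mark.parametrize(
        "pos1,expected",
        [
            (161, "exon"),       # coding exon (0-based 160)
            (251, "intron"),     # between exons
            (121, "5'UTR"),      # exonic, upstream of cds on +
            (471, "3'UTR"),      # exonic, downstream of cds on +
            (51, "intergenic"),
        ],
    )
    def test_plus_strand_contexts(self, plus_transcript, pos1, expected):
        gwas = make_gwas(["s"], ["chr1"], [pos1], [0.5])
        assert ev.genic_context(gwas, [plus_transcript])["s"] == expected

    def test_minus_strand_flips_utrs(self):
        """Exonic sequence upstream of cds_start is the 3'UTR on '-'."""
        t = TranscriptModel(gene="G", chrom="chr1", strand="-",
                            tx_start=100, tx_end=500, cds_start=150, cds_end=450,
                            exon_starts=[100, 300], exon_ends=[200, 500])
        gwas = make_gwas(["low", "high"], ["chr1", "chr1"], [121, 471], [0.5, 0.5])
        ctx = ev.genic_context(gwas, [t])
        assert ctx == {"low": "3'UTR", "high": "5'UTR"}

    def test_precedence_across_transcripts(self):
        a = TranscriptModel(gene="A", chrom="chr1", strand="+",
                            tx_start=0, tx_end=1000, cds_start=0, cds_end=1000,
                            exon_starts=[0], exon_ends=[200])  # pos 150 -> exon
        b = TranscriptModel(gene="B", chrom="chr1", strand="+",
                            tx_start=100, tx_end=900, cds_start=400, cds_end=800,
                            exon_starts=[100, 400], exon_ends=[200, 900])  # pos 150 -> 5'UTR
        gwas = make_gwas(["s"], ["chr1"], [151], [0.5])
        assert ev.genic_context(gwas, [a, b])["s"] == "5'UTR"
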