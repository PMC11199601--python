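"""IO, filtering rules, feature maps, and LD pruning."""

import numpy as np
import pytest

from ploidsv import svio
from ploidsv.svio import (
    FeatureMap,
    Gene,
    SNPFilterRules,
    SNPRecord,
    SVFilterRules,
    build_feature_map,
    filter_pangenome_candidates,
    filter_svs,
    hard_filter_snps,
    ld_prune,
)

from conftest import make_samples, make_sv


class TestSVRecords:
    def test_del_length_invariant_enforced(self):
        with pytest.raises(ValueError, match="DEL"):
            make_sv(svtype="DEL", pos=100, end=150, svlen=100)

    def test_ins_is_point_event(self):
        sv = make_sv(svtype="INS", pos=100, svlen=500)
        assert sv.end == sv.pos
        assert sv.interval() == (99, 100)

    def test_unknown_svtype_not_analyzable(self):
        sv = make_sv(svtype="INV", pos=100, end=199, svlen=100)
        assert not sv.analyzable


class TestVcfRoundTrip:
    def test_mixed_types_read_and_flagged(self, tmp_path):
        samples = make_samples([2, 2])
        recs = [
            make_sv(n_samples=2, id="a", svtype="INS", pos=100, svlen=80),
            make_sv(n_samples=2, id="b", svtype="DEL", pos=300, svlen=60),
            make_sv(n_samples=2, id="c", svtype="INV", pos=500, end=599, svlen=100),
        ]
        path = tmp_path / "mix.vcf"
        svio.write_sv_vcf(recs, samples, path, {"chr1": 1000})
        back = svio.read_sv_vcf(path, samples)
        assert len(back) == 3
        assert sum(r.analyzable for r in back) == 2

    def test_del_end_only_reconstructs_svlen(self, tmp_path):
        samples = make_samples([2])
        path = tmp_path / "endonly.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
            "##contig=<ID=chr1,length=1000>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0",
            "chr1\t101\td1\tN\t<DEL>\t40\tPASS\tSVTYPE=DEL;END=200\tGT:AD\t0/0:10,0",
        ]
        path.write_text("\n".join(lines) + "\n")
        (rec,) = svio.read_sv_vcf(path, samples)
        assert rec.svlen == 200 - 101 + 1
        assert rec.end == 200

    def test_round_trip_preserves_analyzed_fields(self, small_cohort, tmp_path):
        samples = small_cohort["samples"]
        path = tmp_path / "rt.vcf"
        svio.write_sv_vcf(small_cohort["sv_records"], samples, path,
                          small_cohort["chrom_lengths"])
        back = svio.read_sv_vcf(path, samples)
        for a, b in zip(small_cohort["sv_records"], back):
            ok = ~a.missing
            assert a.id == b.id and a.pos == b.pos and a.end == b.end
            assert a.svlen == b.svlen and a.qual == b.qual and a.svtype == b.svtype
            assert np.array_equal(a.missing, b.missing)
            assert np.array_equal(a.alt_reads[ok], b.alt_reads[ok])
            assert np.array_equal(a.ref_reads[ok], b.ref_reads[ok])
            assert np.array_equal(a.gt[ok], b.gt[ok])

    def test_sample_mismatch_lists_difference(self, tmp_path):
        samples = make_samples([2, 2])
        path = tmp_path / "m.vcf"
        svio.write_sv_vcf([make_sv(n_samples=2)], samples, path, {"chr1": 1000})
        other = make_samples([2, 2])
        other[1] = svio.SampleInfo("zz", "pop1", 2, 0.0, 50.0)
        with pytest.raises(ValueError, match="zz"):
            svio.read_sv_vcf(path, other)


class TestSvFilters:
    @pytest.mark.parametrize(
        "svlen,qual,expect_kept",
        [
            (49, 30.0, False),   # below the 50 bp floor
            (50, 30.0, True),    # inclusive lower bound
            (100_000, 20.0, True),   # inclusive upper bound and quality floor
            (100_001, 30.0, False),
            (500, 19.9, False),
        ],
    )
    def test_length_and_quality_bounds(self, svlen, qual, expect_kept):
        samples = make_samples([2] * 4)
        rec = make_sv(svtype="DEL", pos=100, svlen=svlen, qual=qual)
        kept, _ = filter_svs([rec], samples)
        assert bool(kept) is expect_kept

    def test_missingness_threshold_after_depth_floor(self):
        # 10 diploid samples; 3 fall below the 10-read floor -> 30% > 20%
        samples = make_samples([2] * 10)
        ref = np.full(10, 20)
        alt = np.full(10, 20)
        ref[:3] = 4
        alt[:3] = 4
        rec = make_sv(n_samples=10, ref_reads=ref, alt_reads=alt,
                      gt=np.ones(10, dtype=int))
        kept, stats = filter_svs([rec], samples)
        assert not kept and stats["missingness"] == 1
        # 2 of 10 below the floor (20%) passes, and those samples are masked
        ref2, alt2 = np.full(10, 20), np.full(10, 20)
        ref2[:2] = 4
        alt2[:2] = 4
        rec2 = make_sv(n_samples=10, ref_reads=ref2, alt_reads=alt2,
                       gt=np.ones(10, dtype=int))
        kept2, _ = filter_svs([rec2], samples)
        assert kept2 and kept2[0].missing[:2].all() and not kept2[0].missing[2:].any()

    def test_depth_floor_scales_with_ploidy(self):
        # 24 reads: above the diploid floor (10) but below tetraploid (20)
        samples_2x = make_samples([2] * 5)
        samples_4x = make_samples([4] * 5)
        rec = make_sv(n_samples=5, ref_reads=np.full(5, 12), alt_reads=np.full(5, 3),
                      gt=np.zeros(5, dtype=int))
        kept2, _ = filter_svs([rec], samples_2x)
        assert kept2 and not kept2[0].missing.any()
        rec4 = make_sv(n_samples=5, ref_reads=np.full(5, 12), alt_reads=np.full(5, 3),
                       gt=np.zeros(5, dtype=int))
        kept4, _ = filter_svs([rec4], samples_4x)
        assert not kept4  # all below floor -> 100% missing

    def test_reference_sample_support_excludes(self):
        samples = make_samples([2] * 4)
        rules = SVFilterRules(reference_sample="s0")
        gt = np.array([1, 0, 0, 0])
        rec = make_sv(gt=gt)
        kept, stats = filter_svs([rec], samples, rules)
        assert not kept and stats["reference_support"] == 1

    def test_filters_idempotent(self, small_cohort):
        kept1, _ = filter_svs(small_cohort["sv_records"], small_cohort["samples"])
        kept2, _ = filter_svs(kept1, small_cohort["samples"])
        assert [r.id for r in kept1] == [r.id for r in kept2]


class TestPangenomeCandidates:
    @pytest.mark.parametrize(
        "support,total,expect",
        [(4, 40, True), (3, 40, False), (10, 200, False)],
    )
    def test_support_rules(self, support, total, expect):
        alt = np.array([support, 0])
        ref = np.array([total - support, 30])
        rec = make_sv(n_samples=2, ref_reads=ref, alt_reads=alt,
                      gt=np.array([1, 0]))
        kept = filter_pangenome_candidates([rec])
        assert bool(kept) is expect


class TestSnpFilters:
    def _snp(self, info, n=4, depth=20, gq=None):
        return SNPRecord(
            id="s", chrom="chr1", pos=100, ref="A", alt="T", qual=100.0,
            info=info,
            ref_reads=np.full(n, depth // 2), alt_reads=np.full(n, depth - depth // 2),
            missing=np.zeros(n, dtype=bool), gt=np.ones(n, dtype=int),
            gq=gq,
        )

    def test_mq_boundary(self):
        samples = make_samples([2] * 4)
        bad = self._snp({"MQ": 39.9})
        good = self._snp({"MQ": 40.0})
        kept, _ = hard_filter_snps([bad, good], samples)
        assert len(kept) == 1 and kept[0].info["MQ"] == 40.0

    def test_depth_exactly_1p6x_mean_is_masked(self):
        samples = make_samples([2] * 2)
        # sample 0 depths: 10 and 16 -> mean 13; 1.6x mean = 20.8
        a = SNPRecord("a", "chr1", 1, "A", "T", 100.0, {},
                      np.array([5, 5]), np.array([5, 5]),
                      np.zeros(2, dtype=bool), np.ones(2, dtype=int), None)
        b = SNPRecord("b", "chr1", 2, "A", "T", 100.0, {},
                      np.array([8, 5]), np.array([8, 5]),
                      np.zeros(2, dtype=bool), np.ones(2, dtype=int), None)
        kept, _ = hard_filter_snps([a, b], samples, SNPFilterRules(depth_ratio=16 / 13))
        assert kept[1].missing[0] and not kept[1].missing[1]

    def test_absent_annotations_pass(self, caplog):
        samples = make_samples([2] * 4)
        kept, stats = hard_filter_snps([self._snp({})], samples)
        assert len(kept) == 1 and stats["site_filtered"] == 0

    def test_gq_below_threshold_masked(self):
        samples = make_samples([2] * 4)
        rec = self._snp({}, gq=np.array([14, 15, 99, 99]))
        kept, _ = hard_filter_snps([rec], samples)
        assert kept[0].missing[0] and not kept[0].missing[1:].any()


class TestFeatureMap:
    def test_single_gene_interval_arithmetic(self):
        # oracle by direct interval arithmetic: gene [1001, 2000] with one
        # exon covering it, chromosome of 4000 bp, 1 kb flanks
        gene = Gene("g1", "chr1", 1001, 2000, ((1001, 2000),))
        fm = build_feature_map([gene], {"chr1": 4000}, flank_bp=1000)
        assert fm.class_bp == {"exon": 1000, "intron": 0, "flank": 2000,
                               "intergenic": 1000}
        assert fm.classify("chr1", 0, 1000) == "flank"      # [1,1000]
        assert fm.classify("chr1", 2000, 3000) == "flank"   # [2001,3000]
        assert fm.classify("chr1", 3000, 4000) == "intergenic"

    def test_whole_chromosome_single_exon_gene(self):
        gene = Gene("g1", "chr1", 1, 4000, ((1, 4000),))
        fm = build_feature_map([gene], {"chr1": 4000})
        assert fm.class_bp["intergenic"] == 0 and fm.class_bp["intron"] == 0

    def test_close_genes_merge_flanks_without_double_count(self):
        g1 = Gene("g1", "chr1", 1001, 1500, ((1001, 1500),))
        g2 = Gene("g2", "chr1", 2000, 2500, ((2000, 2500),))
        fm = build_feature_map([g1, g2], {"chr1": 10_000})
        assert sum(fm.class_bp.values()) == 10_000
        # gap of 499 bp between genes is all flank, counted once
        assert fm.classify("chr1", 1600, 1601) == "flank"

    def test_partition_property(self, small_cohort):
        fm = small_cohort["fm"]
        assert sum(fm.class_bp.values()) == fm.genome_bp

    def test_exon_outside_gene_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            Gene("g1", "chr1", 1000, 2000, ((900, 1100),))

    def test_precedence_exon_over_flank(self):
        # two genes arranged so g2's exon sits inside g1's flank zone
        g1 = Gene("g1", "chr1", 1001, 1500, ((1001, 1500),))
        g2 = Gene("g2", "chr1", 1600, 1900, ((1600, 1900),))
        fm = build_feature_map([g1, g2], {"chr1": 5000})
        assert fm.classify("chr1", 1650, 1660) == "exon"


class TestLdPrune:
    def test_duplicated_variant_removed(self):
        rng = np.random.default_rng(0)
        x = np.full(6, 2)
        d = rng.integers(0, 3, size=(3, 6)).astype(float)
        d[1] = d[0]
        kept = ld_prune(d, x, maf_min=0.0)
        assert 0 in kept and 1 not in kept

    def test_independent_variants_all_kept(self):
        x = np.full(8, 2)
        d = np.array(
            [[0, 0, 0, 0, 1, 1, 1, 1],
             [0, 1, 1, 0, 0, 1, 1, 0],
             [1, 0, 1, 0, 1, 0, 1, 0]], dtype=float
        )
        kept = ld_prune(d, x, maf_min=0.0)
        assert len(kept) == 3

    def test_three_perfectly_correlated_keep_exactly_one(self):
        x = np.full(6, 2)
        base = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        d = np.vstack([base, base, base])
        kept = ld_prune(d, x, maf_min=0.0)
        assert list(kept) == [0]

    def test_low_maf_dropped_first(self):
        x = np.full(20, 2)
        rare = np.zeros(20)
        rare[0] = 1  # maf 1/40
        common = np.tile([0.0, 2.0], 10)
        kept = ld_prune(np.vstack([rare, common]), x)
        assert list(kept) == [1]
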