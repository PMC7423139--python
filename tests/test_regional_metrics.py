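import numpy as np
import pytest

from regionscope import (
    AlignmentHit,
    DepthTable,
    GenomeInterval,
    RegionalMetrics,
    classify_region,
    collapse_hsps,
    extract_gene_regions,
    match_reference_regions,
    region_set_ratios,
    regional_depth,
    regional_heterozygosity,
    total_heterozygosity,
)
from regionscope.io_formats import SequenceSet, SnpRecord
from regionscope.regional_metrics import RegionRatio


def _hit(query, subject, pident, sstart, send):
    return AlignmentHit(query, subject, pident, send - sstart + 1, 0, 0,
                        1, send - sstart + 1, sstart, send, 0.0, 50.0)


class TestExtractGeneRegions:
    def test_min_max_span_rule(self):
        hits = [_hit("t1", "c1", 99.0, 101, 200),
                _hit("t1", "c1", 99.0, 501, 650)]
        (region,) = extract_gene_regions(hits)
        assert region.interval == GenomeInterval("c1", 100, 650)
        assert region.n_exon_hits == 2
        assert region.status == "ok"

    def test_identity_threshold_is_strict_at_92(self):
        hits = [_hit("t1", "c1", 91.9, 1, 100),
                _hit("t1", "c1", 92.0, 201, 300)]
        (region,) = extract_gene_regions(hits)
        assert region.interval == GenomeInterval("c1", 200, 300)
        assert region.n_exon_hits == 1

    def test_all_hits_below_threshold_yield_nothing(self):
        assert extract_gene_regions([_hit("t1", "c1", 80.0, 1, 100)]) == []

    def test_over_10kb_span_excluded(self):
        hits = [_hit("t1", "c1", 99.0, 1, 100),
                _hit("t1", "c1", 99.0, 10_401, 10_500)]
        (region,) = extract_gene_regions(hits)
        assert region.status == "excluded_span"
        assert len(region.interval) == 10_500

    def test_multi_contig_gene_flagged_per_contig(self):
        hits = [_hit("t1", "cA", 99.0, 1, 100),
                _hit("t1", "cB", 99.0, 51, 150)]
        regions = extract_gene_regions(hits)
        assert {r.interval.contig for r in regions} == {"cA", "cB"}
        assert all(r.status == "multi_contig" for r in regions)


class TestRegionalHetAndDepth:
    def test_simple_density(self):
        snps = [SnpRecord("c1", p, "A", ("T",)) for p in (10, 20, 30)]
        assert regional_heterozygosity(
            snps, GenomeInterval("c1", 0, 300)) == pytest.approx(0.01)

    def test_empty_region_is_zero(self):
        assert regional_heterozygosity([], GenomeInterval("c1", 0, 10)) == 0

    def test_whole_genome_equals_total_heterozygosity(self):
        rng = np.random.default_rng(5)
        length = 5000
        positions = sorted(rng.choice(np.arange(1, length + 1), size=60,
                                      replace=False).tolist())
        snps = [SnpRecord("c1", int(p), "A", ("C",)) for p in positions]
        seqs = SequenceSet({"c1": "A" * length})
        whole = GenomeInterval("c1", 0, length)
        assert regional_heterozygosity(snps, whole) \
            == total_heterozygosity(snps, seqs)

    def test_depth_zero_fill_halves_mean(self):
        table = DepthTable({"c1": (np.arange(1, 51), np.full(50, 30))})
        assert regional_depth(table, GenomeInterval("c1", 0, 50)) == 30
        assert regional_depth(table, GenomeInterval("c1", 0, 100)) == 15

    def test_depth_matches_per_base_summation_oracle(self):
        rng = np.random.default_rng(6)
        pos = rng.choice(np.arange(1, 2000), 800, replace=False)
        dep = rng.integers(0, 100, 800)
        table = DepthTable({"c1": (pos, dep)})
        lookup = dict(zip(pos.tolist(), dep.tolist()))
        for _ in range(50):
            a = int(rng.integers(0, 1900))
            b = int(rng.integers(a + 1, 2000))
            region = GenomeInterval("c1", a, b)
            oracle = sum(lookup.get(p, 0)
                         for p in range(a + 1, b + 1)) / (b - a)
            assert regional_depth(table, region) == pytest.approx(oracle)


class TestMatchReferenceRegions:
    def test_identity_boundary_is_strict_at_98(self):
        hits = [_hit("r1", "ref", 97.9, 1, 100),
                _hit("r1", "ref", 98.0, 201, 300)]
        assert match_reference_regions(hits) \
            == [GenomeInterval("ref", 200, 300)]

    def test_reversed_hit_yields_forward_interval(self):
        hit = AlignmentHit.from_fields(
            "r1 ref 99.0 100 1 0 1 100 500 401 0 90".split())
        assert match_reference_regions([hit]) \
            == [GenomeInterval("ref", 400, 500)]

    def test_no_qualifying_hit_yields_empty(self):
        assert match_reference_regions([_hit("r1", "ref", 90.0, 1, 50)]) == []


class TestCollapseHsps:
    def test_overlap_merge_worked_example(self):
        merged, bp = collapse_hsps([GenomeInterval("c", 1, 100),
                                    GenomeInterval("c", 50, 150)])
        assert merged == [GenomeInterval("c", 1, 150)]
        assert bp == 149

    def test_disjoint_untouched(self):
        ivs = [GenomeInterval("c", 0, 10), GenomeInterval("c", 20, 30),
               GenomeInterval("d", 0, 5)]
        merged, bp = collapse_hsps(ivs)
        assert merged == ivs
        assert bp == 25

    def test_abutting_intervals_merge(self):
        merged, bp = collapse_hsps([GenomeInterval("c", 0, 10),
                                    GenomeInterval("c", 10, 20)])
        assert merged == [GenomeInterval("c", 0, 20)]
        assert bp == 20

    def test_random_instances_match_bitmap_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            ivs = []
            mask = {c: np.zeros(500, dtype=bool) for c in "xy"}
            for _ in range(int(rng.integers(1, 25))):
                contig = "x" if rng.random() < 0.5 else "y"
                a = int(rng.integers(0, 480))
                b = int(rng.integers(a + 1, 500))
                ivs.append(GenomeInterval(contig, a, b))
                mask[contig][a:b] = True
            merged, bp = collapse_hsps(ivs)
            assert bp == int(sum(m.sum() for m in mask.values()))
            for left, right in zip(merged, merged[1:]):
                assert left.contig != right.contig or left.end < right.start


class TestRegionSetRatios:
    def test_identical_metrics_give_unit_ratios(self):
        m = [RegionalMetrics("a", 0.01, 60.0, 1000)]
        r = region_set_ratios(m, m, "s")
        assert (r.het_ratio, r.cov_ratio, r.len_ratio) == (1.0, 1.0, 1.0)

    def test_doubling_bp_halves_density_and_depth(self):
        test = [RegionalMetrics("t", 0.005, 30.0, 2000)]
        ref = [RegionalMetrics("r", 0.01, 60.0, 1000)]
        r = region_set_ratios(test, ref, "s")
        assert r.len_ratio == 2.0
        assert r.het_ratio == pytest.approx(0.5)
        assert r.cov_ratio == pytest.approx(0.5)

    def test_zero_reference_bp_flags_unresolved(self):
        r = region_set_ratios([RegionalMetrics("t", 0.0, 10.0, 100)], [],
                              "s")
        assert not r.defined
        assert r.classification == "unresolved"

    def test_pooling_is_length_weighted(self):
        # one huge quiet region must dominate one tiny dense region
        test = [RegionalMetrics("t1", 0.0, 60.0, 9900),
                RegionalMetrics("t2", 0.5, 60.0, 100)]
        ref = [RegionalMetrics("r", 0.005, 60.0, 10_000)]
        r = region_set_ratios(test, ref, "s")
        assert r.het_ratio == pytest.approx((50 / 10_000) / 0.005)


class TestClassifyRegion:
    @pytest.mark.parametrize("het,cov,length,expected", [
        (0.4, 0.5, 2.0, "expansion"),
        (3.5, 3.0, 0.33, "collapse"),
        (1.0, 1.0, 1.0, "normal"),
        (2.0, 0.9, 1.8, "mixed"),       # length and het both up
        (1.0, 3.0, 1.0, "unresolved"),  # coverage alone out of band
    ])
    def test_signature_labels(self, het, cov, length, expected):
        ratio = RegionRatio("s", het, cov, length)
        assert classify_region(ratio) == expected

    def test_direction_law_on_synthetic_artifacts(self, demo_ratios):
        results, _ = demo_ratios
        for set_id, res in results.items():
            if set_id in ("exp1", "col1"):
                r = res.ratio
                assert np.sign(r.len_ratio - 1) == -np.sign(r.cov_ratio - 1)

    def test_demo_artifacts_classified_as_injected(self, demo_ratios):
        results, _ = demo_ratios
        assert results["exp1"].classification == "expansion"
        assert results["col1"].classification == "collapse"
        assert results["background"].classification == "normal"
        # the bubble region is an allelic duplication signature too
        assert results["bub1"].classification == "expansion"
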