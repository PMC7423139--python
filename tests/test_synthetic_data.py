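import math

import numpy as np
import pytest

from regionscope import (
    GenomeInterval,
    bubble_artifact,
    collapse_artifact,
    expansion_artifact,
    expected_assembly_length,
    generate_diploid,
    make_test_assembly,
    simulate_mapping_profile,
)
from regionscope.synthetic_data import make_demo_dataset, write_bundle


@pytest.fixture(scope="module")
def genome():
    return generate_diploid(100_000, seed=11)


class TestGenerateDiploid:
    def test_zero_heterozygosity_gives_identical_haplotypes(self):
        g = generate_diploid(20_000, het_rate=0.0, repeat_spec={}, seed=1)
        assert g.hap_a == g.hap_b
        assert g.true_snps == []

    def test_same_seed_is_byte_identical(self):
        g1 = generate_diploid(30_000, seed=5)
        g2 = generate_diploid(30_000, seed=5)
        assert g1.hap_a == g2.hap_a and g1.hap_b == g2.hap_b
        assert g1.true_snps == g2.true_snps
        assert g1.repeat_annotations == g2.repeat_annotations

    def test_haplotypes_differ_exactly_at_true_snps(self, genome):
        a = genome.hap_a_array()
        b = genome.hap_b_array()
        diff = set(np.flatnonzero(a != b) + 1)
        assert diff == {pos for _, pos in genome.true_snps}

    def test_snp_count_within_binomial_bound(self):
        g = generate_diploid(1_000_000, het_rate=0.0115, seed=13)
        expected = 1_000_000 * 0.0115
        sd = math.sqrt(1_000_000 * 0.0115 * (1 - 0.0115))
        assert abs(len(g.true_snps) - expected) < 4 * sd

    def test_repeat_overflow_is_hard_error(self):
        with pytest.raises(ValueError, match="exceeds genome length"):
            generate_diploid(20_000, repeat_spec={
                "n_families": 2, "copies": 4, "unit_length": 4000,
                "divergence": 0.01}, seed=1)

    def test_repeat_copies_are_tandem(self, genome):
        fams = genome.repeat_families()
        for copies in fams.values():
            ivs = sorted(c.interval for c in copies)
            for left, right in zip(ivs, ivs[1:]):
                assert left.end == right.start


class TestMakeAssembly:
    def test_expansion_adds_exactly_region_length(self, genome):
        art = [expansion_artifact("e", 40_000, 10_000)]
        asm, _ = make_test_assembly(genome, art)
        assert asm.total_length == genome.length + 10_000
        assert asm.total_length == expected_assembly_length(genome, art)
        assert asm["e_hapA"] == genome.hap_a[genome.contig][40_000:50_000]
        assert asm["e_hapB"] == genome.hap_b[genome.contig][40_000:50_000]

    def test_collapse_loses_factor_minus_one_units(self, genome):
        art = [collapse_artifact(genome, "fam_0")]
        asm, _ = make_test_assembly(genome, art)
        unit = len(art[0].region) // art[0].factor
        lost = (art[0].factor - 1) * unit
        assert asm.total_length == genome.length - lost
        assert asm.total_length == expected_assembly_length(genome, art)

    def test_bubble_contig_count_bounded_by_2_to_the_n(self, genome):
        for n in (1, 2, 3):
            art = [bubble_artifact("b", 10_000, 3_000, n)]
            asm, _ = make_test_assembly(genome, art)
            paths = [c for c in asm if c.startswith("b_p")]
            assert 1 <= len(paths) <= 2 ** n
            covered = sum(len(asm[c]) for c in paths)
            assert covered == 2 * 3_000  # both haplotypes of every segment

    def test_outside_artifacts_assembly_equals_consensus(self, genome):
        art = [expansion_artifact("e", 40_000, 10_000)]
        asm, _ = make_test_assembly(genome, art)
        consensus = genome.hap_a[genome.contig]
        assert asm["backbone_1"] == consensus[:40_000]
        assert asm["backbone_2"] == consensus[50_000:]

    def test_overlapping_artifact_regions_rejected(self, genome):
        arts = [expansion_artifact("e1", 30_000, 10_000),
                expansion_artifact("e2", 35_000, 10_000)]
        with pytest.raises(ValueError, match="overlap"):
            make_test_assembly(genome, arts)


class TestMappingProfile:
    def test_no_artifacts_no_het_gives_empty_vcf_and_flat_depth(self):
        g = generate_diploid(50_000, het_rate=0.0, repeat_spec={}, seed=2)
        asm, truth = make_test_assembly(g, [])
        depth, snps = simulate_mapping_profile(asm, g, truth, 60, seed=3)
        assert snps == []
        mean = depth.mean_depth(GenomeInterval(g.contig, 0, 50_000))
        se = math.sqrt(60 / 50_000)
        assert abs(mean - 60) < 3 * se

    def test_expansion_halves_depth_and_suppresses_het(self, genome):
        art = [expansion_artifact("e", 40_000, 10_000)]
        asm, truth = make_test_assembly(genome, art)
        depth, snps = simulate_mapping_profile(asm, genome, truth, 60,
                                               seed=4)
        for contig in ("e_hapA", "e_hapB"):
            mean = depth.mean_depth(GenomeInterval(contig, 0, 10_000))
            assert abs(mean - 30) / 30 < 0.10
            assert not any(s.contig == contig for s in snps)

    def test_collapse_multiplies_depth_and_inflates_het(self, genome):
        art = [collapse_artifact(genome, "fam_1")]
        asm, truth = make_test_assembly(genome, art)
        depth, snps = simulate_mapping_profile(asm, genome, truth, 60,
                                               seed=5)
        unit = len(art[0].region) // art[0].factor
        # the merged copy sits inside the backbone; locate it via layout
        offset = art[0].region.start
        prior_loss = 0
        region = GenomeInterval("backbone_1", offset - prior_loss,
                                offset - prior_loss + unit)
        mean = depth.mean_depth(region)
        assert abs(mean - 180) / 180 < 0.10
        merged_het = sum(1 for s in snps
                         if region.contains_pos(s.contig, s.pos)) / unit
        assert merged_het > 1.5 * genome.het_rate

    def test_normal_regions_call_exactly_the_true_snps(self):
        g = generate_diploid(40_000, repeat_spec={}, seed=6)
        asm, truth = make_test_assembly(g, [])
        _, snps = simulate_mapping_profile(asm, g, truth, 60, seed=7)
        assert {(s.contig, s.pos) for s in snps} == set(g.true_snps)
        a, b = g.hap_a_array(), g.hap_b_array()
        for s in snps[:50]:
            assert s.ref_allele == chr(a[s.pos - 1])
            assert s.alt_alleles == (chr(b[s.pos - 1]),)


class TestAlignmentEmission:
    def test_hit_identities_and_shared_reference_span(self, demo):
        hits = demo.tables["regions_vs_reference"]
        exp = next(a for a in demo.artifacts if a.kind == "expansion")
        allelic = [h for h in hits
                   if h.query_id.startswith(f"gene_{exp.artifact_id}|")]
        assert len(allelic) == 2
        spans = {(h.sstart, h.send) for h in allelic}
        assert len(spans) == 1  # both alleles map onto the same span
        pids = sorted(h.pident for h in allelic)
        assert pids[1] == 100.0
        assert 97.5 < pids[0] < 99.9  # ~100 - het_rate * 100

    def test_hit_coordinates_within_sequence_bounds(self, demo):
        ref_len = demo.genome.length
        asm_lengths = demo.assembly.lengths()
        for name, hits in demo.tables.items():
            for h in hits:
                assert 1 <= h.sstart <= h.send
                assert 1 <= h.qstart <= h.qend
                if h.subject_id in asm_lengths:
                    assert h.send <= asm_lengths[h.subject_id]
                elif h.subject_id == demo.genome.contig:
                    assert h.send <= ref_len

    def test_transcript_hits_cover_every_gene(self, demo):
        queried = {h.query_id
                   for h in demo.tables["transcripts_vs_assembly"]}
        assert queried == set(demo.genes)


class TestBundleDeterminism:
    def test_identical_seeds_give_byte_identical_files(self, tmp_path):
        kwargs = dict(genome_length=60_000, n_bubble=0, seed=21,
                      repeat_spec={"n_families": 1, "copies": 3,
                                   "unit_length": 2000, "divergence": 0.015})
        out1 = write_bundle(make_demo_dataset(**kwargs), tmp_path / "b1")
        out2 = write_bundle(make_demo_dataset(**kwargs), tmp_path / "b2")
        names = sorted(p.name for p in out1.iterdir())
        assert names == sorted(p.name for p in out2.iterdir())
        for name in names:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
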