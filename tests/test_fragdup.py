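import numpy as np
import pytest

from regionscope import (
    AlignmentHit,
    classify_matches,
    dedupe_hits,
    filter_reference_queries,
    identify_paralogs,
    tally_assembly,
)
from regionscope.fragdup import default_assembly_labeler


def _match(query="ref|p1", subject="asm|x", qstart=1, qend=100,
           bitscore=50.0):
    return AlignmentHit(query, subject, 95.0, qend - qstart + 1, 0, 0,
                        qstart, qend, 1, qend - qstart + 1, 1e-30, bitscore)


class TestFilterAndDedupe:
    def test_reference_query_filter(self):
        hits = [_match("ref|a", "asm|x"), _match("asm|x", "ref|a"),
                _match("ref|b", "asm|y")]
        out = filter_reference_queries(hits, {"ref|a", "ref|b"})
        assert [h.query_id for h in out] == ["ref|a", "ref|b"]
        assert filter_reference_queries(hits, set()) == []

    def test_identical_rows_collapse(self):
        hit = _match()
        assert dedupe_hits([hit, hit, hit]) == [hit]

    def test_same_coordinates_highest_bitscore_wins(self):
        low = _match(bitscore=50.0)
        high = _match(bitscore=60.0)
        assert dedupe_hits([low, high]) == [high]
        assert dedupe_hits([high, low]) == [high]

    def test_disjoint_rows_untouched(self):
        hits = [_match(qstart=1, qend=50), _match(qstart=60, qend=100)]
        assert dedupe_hits(hits) == hits


class TestIdentifyParalogs:
    def test_self_hits_only_gives_empty_set(self):
        hits = [_match("ref|a", "ref|a"), _match("ref|b", "ref|b")]
        assert identify_paralogs(hits) == set()

    def test_non_self_hit_excludes_both_sides(self):
        assert identify_paralogs([_match("ref|a", "ref|b")]) \
            == {"ref|a", "ref|b"}

    def test_mixed_self_and_cross(self):
        hits = [_match("ref|a", "ref|a"), _match("ref|a", "ref|b")]
        assert identify_paralogs(hits) == {"ref|a", "ref|b"}


class TestClassifyMatches:
    def test_three_overlapping_is_two_duplications_one_correct(self):
        matches = [_match(qstart=1, qend=100), _match(qstart=20, qend=120),
                   _match(qstart=50, qend=90)]
        assert classify_matches(matches) == (0, 0, 2)

    def test_two_overlapping_is_one_duplication_one_correct(self):
        matches = [_match(qstart=1, qend=100), _match(qstart=50, qend=150)]
        assert classify_matches(matches) == (0, 0, 1)

    def test_single_match_is_one_to_one(self):
        assert classify_matches([_match()]) == (1, 0, 0)

    def test_two_non_overlapping_is_fragmentation(self):
        matches = [_match(qstart=1, qend=50), _match(qstart=60, qend=100)]
        assert classify_matches(matches) == (0, 1, 0)

    def test_mixed_case_clusters(self):
        # two overlapping pieces plus one distant piece: one duplication
        # within the cluster, fragmentation across clusters
        matches = [_match(qstart=1, qend=50), _match(qstart=30, qend=60),
                   _match(qstart=200, qend=260)]
        assert classify_matches(matches) == (0, 1, 1)

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            classify_matches([])

    def test_accounting_identity_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(1, 12))
            matches = []
            for _ in range(n):
                a = int(rng.integers(1, 500))
                b = a + int(rng.integers(10, 120))
                matches.append(_match(qstart=a, qend=b))
            one, frag, dups = classify_matches(matches)
            clusters = n - dups
            assert 1 <= clusters <= n
            assert frag == (1 if clusters > 1 else 0)
            assert one == (1 if n == 1 else 0)
            # conservatism: K mutually overlapping matches report K-1, not K
            assert dups <= n - 1


class TestTally:
    def test_every_protein_matched_once_is_all_one_to_one(self):
        hits = [_match(f"ref|p{i}", "asmA|x") for i in range(5)]
        tallies = tally_assembly(hits, {h.query_id for h in hits}, set())
        counts = tallies["asmA"]
        assert counts.one_to_one == 5
        assert counts.fragmentation_cases == 0
        assert counts.duplication_events == 0

    def test_paralog_queries_are_dropped(self):
        hits = [_match("ref|a", "asmA|x"), _match("ref|b", "asmA|y")]
        tallies = tally_assembly(hits, {"ref|a", "ref|b"}, {"ref|a"})
        assert tallies["asmA"].one_to_one == 1
        assert tallies["asmA"].excluded_paralogs == 1

    def test_labeler_splits_assemblies(self):
        hits = [_match("ref|p", "asmA|x", 1, 100),
                _match("ref|p", "asmB|x", 1, 100)]
        tallies = tally_assembly(hits, {"ref|p"}, set())
        assert set(tallies) == {"asmA", "asmB"}
        assert all(t.one_to_one == 1 for t in tallies.values())
        assert default_assembly_labeler("asmA|x") == "asmA"

    def test_expansion_only_synthetic_gives_pure_duplication(self):
        from regionscope import emit_protein_table, generate_diploid
        from regionscope.synthetic_data import (expansion_artifact,
                                                make_test_assembly,
                                                place_genes)

        g = generate_diploid(120_000, repeat_spec={}, seed=12)
        arts = [expansion_artifact("e1", 20_000, 12_000),
                expansion_artifact("e2", 60_000, 12_000)]
        _, truth = make_test_assembly(g, arts)
        genes = place_genes(g, truth, n_background=3, seed=13)
        hits, ref_ids = emit_protein_table(g, truth, genes)
        hits = dedupe_hits(hits)
        ref_rows = filter_reference_queries(hits, ref_ids)
        paralogs = identify_paralogs(
            [h for h in ref_rows if h.subject_id in ref_ids])
        rows = [h for h in ref_rows if h.subject_id not in ref_ids]
        tallies = tally_assembly(rows, ref_ids, paralogs)
        counts = tallies["asm"]
        assert counts.fragmentation_cases == 0
        assert counts.duplication_events == 2  # one per expanded gene
        assert counts.one_to_one == 3          # the background genes
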