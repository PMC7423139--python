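import pytest

from regionscope import make_demo_dataset


@pytest.fixture(scope="session")
def demo():
    """A 200 kb study with one expansion, one repeat collapse, one bubble
    region, and four background genes."""
    return make_demo_dataset(genome_length=200_000, seed=3)


@pytest.fixture(scope="session")
def demo_ratios(demo):
    from regionscope import compute_region_ratios

    results, exclusions = compute_region_ratios(
        demo.tables["transcripts_vs_assembly"],
        demo.tables["regions_vs_reference"],
        demo.test_snps, demo.test_depth,
        demo.ref_snps, demo.ref_depth,
        demo.genes_by_set)
    return results, exclusions
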