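# Methods

## Model

`regionscope` diagnoses two complementary misassembly modes in
heterozygous diploid datasets by comparing a test assembly *T* against a
trusted reference assembly *R* of the same reads.

**Heterozygosity** is read-based throughout: reads are mapped back onto
an assembly, variants called, and *H* = SNP sites / sequence length. A
multiallelic SNP site counts once (heterozygosity is a per-position
quantity); indels and symbolic alleles are not SNP sites and are dropped
at VCF read time.

**Regional expansion.** When the assembler emits both alleles of a
heterozygous region as separate contigs, three coupled signals appear
relative to the reference: assembled length for the region doubles
(`len_ratio → 2` for a clean biallelic split, more when bubble paths
multiply), reads split between the allelic copies (`cov_ratio → 1/2`),
and heterozygous calls vanish because every read maps to its own allele
(`het_ratio → 0`). With N clusters of nearby SNPs, the assembly graph can
hold up to 2^N alternative paths, so expansion need not stop at 2x.

**Regional collapse.** When near-identical repeat copies are merged into
one sequence: length shrinks to 1/factor, reads from all copies stack
(`cov_ratio → factor`), and inter-copy divergence is miscalled as
heterozygosity (`het_ratio ≈ (divergence-variable sites + allelic
sites) / allelic sites`, well above 1).

Because the two modes move all three ratios in opposite directions, the
pair (coverage, heterozygosity) disambiguates cases that length or
coverage alone cannot.

## Pipeline and thresholds

| parameter | default | meaning |
|---|---|---|
| `min_exon_identity` | 92% | transcript exon hits kept when locating gene regions |
| `min_ref_identity` | 98% | region-vs-reference matches kept (screens paralogous regions) |
| `max_gene_span` | 10 kb | gene footprints above this are excluded as probable mapping errors |
| `min_aln_length` | 24 bp | shortest alignment counted toward reference coverage |
| `length_cutoff` | 200 bp (alt. 1000 bp) | assembly size filter before all statistics |
| `ratio_hi` / `ratio_lo` | 1.5 / 0.67 | classification band for all three ratios |

Gene regions: per transcript, kept exon hits on one contig define the
footprint [min, max). A transcript whose qualifying hits fall on several
contigs yields one footprint per contig, flagged `multi_contig` and
reported; these are *included* in region-set metrics because in an
expanded assembly the allelic contigs both carry the gene — counting only
one would hide exactly the artifact being measured. The flagged count is
itself a fragmentation signal. `excluded_span` regions never enter
ratios.

Region-set pooling: counts are pooled before dividing (SNP sums over bp
sums; depth weighted by region length), not averaged per gene — robust to
tiny regions. Both sides are HSP-collapsed to unique bp first, so only
unique assembly sequence mapped onto unique reference sequence is
counted; an expanded query can therefore never multi-count a reference
span. A zero reference denominator leaves the ratio undefined and the
set is excluded from aggregates rather than silently zeroed.

Classification uses the band [0.67, 1.5] on all three ratios: `expansion`
(len high, cov and het low), `collapse` (len low, cov and het high),
`mixed` (len and het both high — the joint signature of expanded coding
sequence containing collapsed repeats), `normal` (all inside the band),
otherwise `unresolved`. The band is a configurable default; the signature
model itself is qualitative.

Missing/expanded accounting works on totals: percent missing *m* is
uncovered reference bp (alignments ≥ 24 bp, no identity threshold, merged
on the subject side); expanded excess is
`E = |T| − (1 − m/100)·|R|`, reported over *R* and over *T*. The two
percentages satisfy `pct_of_assembly · |T| = pct_excess · |R|` by
construction, which the tests assert. Negative excess is clamped to zero
and flagged (`net_deficit`). Per-region fold change is reference bp over
test bp, reported to two decimals.

Protein matching: exact-duplicate rows are removed (ties on coordinates
keep the highest bitscore); only reference-as-query rows are used;
reference proteins in any non-self reference-reference hit are excluded
*symmetrically* (both endpoints), since an asymmetric rule would leave
the partner's matches conflatable with duplication. Matches are clustered
by query-side overlap (single linkage, ≥ 1 shared position; a minimum
overlap fraction is available as a knob, default 0). N matches in C
clusters ⇒ N − C duplication events, one fragmentation case if C > 1,
1:1 if N = 1. This generalizes the two pure cases (all-overlapping, all
non-overlapping) and reduces to them exactly.

## Coordinate conventions

All tabular inputs (alignment tables, VCF, depth) are 1-based inclusive;
the internal `GenomeInterval` is 0-based half-open. Conversion happens
once, at read time. Alignment rows with descending subject coordinates
are flipped to ascending and flagged; re-normalization is a no-op.
Depth positions absent from the file read as 0 (the `samtools depth`
default omits zero rows); regional depth is the arithmetic mean over the
full region including those zeros.

## Synthetic data generator

The generator emulates the study conditions directly rather than
simulating reads: a single-contig diploid genome with Bernoulli(het_rate)
heterozygous substitutions (default 0.0115), GC 0.40, and tandem repeat
families (each family one block of `copies × unit_length`, copies
independently diverged from an ancestral unit). Defaults: 2 families,
3 copies of 3 kb, divergence 0.01. The divergence default is set so that
a merged repeat copy's identity to each source copy (≈ 100·(1−d) ≈ 99%)
clears the pipeline's 98% reference-matching threshold with a
multiple-sigma margin on multi-kb regions — a collapse whose copies fall
below that threshold is invisible to the method by design, and the
generator's job is to produce *detectable* instances; at 1% divergence
the spurious-heterozygosity signal (≈ 3% variable sites for 3 copies) is
still far above the 1.5x classification band.

Artifacts transform the consensus (haplotype A): an expansion replaces
its region with both haplotype copies as separate contigs (+region
length); a collapse replaces a family's tandem block with one
per-position-majority consensus copy (−(factor−1)·unit, ties broken
alphabetically); a bubble region is split into `n_snp_clusters` segments
and both haplotype versions of each segment are emitted — 2N short path
contigs, always ≤ the 2^N paths the graph model allows (path emission is
capped at 2^10 regardless). Total assembly length therefore obeys an
exact conservation identity that the tests check.

Depth and SNP calls are drawn from the artifact model: Poisson around
`base_depth` (default 60) in normal sequence, `base_depth/2` per allelic
or bubble contig, `base_depth × factor` over a merged repeat. SNP calls
appear at the true heterozygous sites of normal regions, are suppressed
entirely inside expanded/bubble contigs (the idealized limit of reads
mapping to their own allele; a `mismap_rate` knob re-admits them, default
0), and appear at every position where the 2×factor haplotype-copies of a
merged repeat disagree. Alignment tables are computed from the known
layout with exact Hamming identities of the aligned spans, so an allelic
contig pair scores ≈ 100 − 100·het_rate against its shared reference span
and a merged repeat ≈ 100 − 100·divergence against each source copy.

What this does *not* emulate: sequencing error, read-length and
insert-size effects, mapper mismapping and soft-clipping, indel
heterozygosity, GC-coverage bias, scaffolding gaps, and genuinely
ambiguous repeat structures. Passing recovery tests therefore shows the
*statistics* behave as the signature model predicts under idealized
mapping — not that any particular mapper/caller stack will produce
equally clean inputs on real data.

## Problem sizes and numerics

The recovery checks run one 1 Mb genome (≈ 11,500 heterozygous sites) for
ratio accuracy and 100 replicate 100 kb genomes (one expansion + one
collapse each) for classification accuracy; at 60x depth the regional
coverage standard error over a multi-kb gene region is below 1%, so the
5–10% recovery tolerances are comfortably resolvable at these sizes,
which keep the full suite in seconds. N50 uses the descending-scan ≥-half
convention and always returns a member of the input; length cutoffs are
inclusive (`length ≥ cutoff` kept). The heterozygosity denominator
includes N runs. Random number use is `numpy.random.default_rng`
seeded everywhere; identical seeds produce byte-identical output files.

## Known limitations

* Region sets mimic functional-category gene sets; category membership is
  an input (two-column TSV), never computed — ontology scoring and
  enrichment statistics are out of scope.
* The classifier assumes the three ratios are computed against a
  trustworthy reference; if the reference itself is regionally expanded
  or collapsed, labels invert silently. The self-comparison identity
  (reference vs itself ⇒ all ratios exactly 1) is the supported control.
* Bubble regions are reported by their dominant signature (allelic
  duplication); the fragmentation they cause surfaces in the
  `multi_contig` counts and the protein-level fragmentation tallies, not
  as a separate ratio class.
* Evidence/non-evidence protein counts for the annotation-ballooning
  warning are accepted as an optional input, not computed.
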