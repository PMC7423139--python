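# regionscope

Regional sequence expansion and collapse diagnostics for heterozygous
genome assemblies.

## The problem

De novo assemblers aim to collapse the two alleles of a diploid genome
into one haploid consensus. At moderate-to-high heterozygosity (~1% SNPs
and above), allelic differences start to resemble paralogy and de Bruijn
graph assemblers fail in two quiet, hard-to-see ways:

* **Regional expansion** — the two alleles of a heterozygous region are
  emitted as *separate contigs* (or, for N nearby SNPs, up to 2^N bubble
  paths). Assembly length goes up; read-mapping coverage and apparent
  heterozygosity in that region go down, because every read now finds a
  perfect-match target.
* **Regional collapse** — near-identical repeat copies are merged into one
  sequence. Length goes down; coverage and apparent heterozygosity go up,
  because reads from every copy pile onto the merged one and inter-copy
  divergence is miscalled as SNPs.

Neither error moves N50 much, and both distort downstream annotation and
gene-ontology enrichment. `regionscope` computes the statistics that
expose them, for anyone assembling a heterozygous (typically non-model)
genome who has a trusted reference assembly of the same data to compare
against.

## The method

For an assembly *T* (test) and reference *R*, with reads mapped back onto
each and variants called:

* **Whole-assembly metrics** — N50, total length, longest sequence at a
  length cutoff (200 bp or 1000 bp), and genome-wide heterozygosity
  *H* = SNP sites / assembly length.
* **Missing/expanded accounting** — from a whole-assembly alignment of
  *T* onto *R* (alignments ≥ 24 bp), the percent of *R* with no coverage
  is *m*; the expanded excess is
  `E = |T| − (1 − m/100)·|R|`, reported as a percent of *R* (excess) and
  of *T* (share of the assembly that is expanded sequence).
* **Regional ratios** — gene regions are located on *T* from transcript
  alignments (exons at ≥ 92% identity; gene span = min..max coordinate;
  spans > 10 kb excluded), matched back to *R* at ≥ 98% identity (to
  exclude paralogous regions), and compared per region set as three
  pooled ratios: `het_ratio`, `cov_ratio` (length-weighted mean depth)
  and `len_ratio` (unique bp, overlapping HSPs collapsed so the same
  reference sequence is never counted twice). The signature
  `len↑, cov↓, het↓` classifies a set as *expansion*; `len↓, cov↑, het↑`
  as *collapse*; `len↑, het↑` as *mixed*.
* **Protein fragmentation vs duplication** — from an all-vs-all protein
  search, each reference protein's matches from one assembly are
  clustered by query-side overlap: N matches in C clusters count as
  `N − C` duplication events (conservative: K mutually overlapping
  matches report K−1, never K) and a fragmentation case when C > 1.
  Reference proteins with a non-self reference match (paralogs) are
  screened out first.

Because the raw sequencing data behind such a study cannot ship with a
package, `regionscope` includes a fully ground-truthed synthetic
generator: a diploid genome at configurable heterozygosity with tandem
repeat families, artifact-bearing assemblies (expansion, collapse, bubble
fragmentation), and the matched VCF / per-base depth / alignment tables
those artifacts produce.

## Worked example

Simulate a 200 kb study (1.15% heterozygosity, 60x depth, one expansion,
one 3-copy repeat collapse, one bubble region) and run the full report:

```sh
regionscope simulate --out-dir demo --seed 3 --genome-length 200000
regionscope report --config demo/config.toml
cut -f1,3,4,5,9 demo/report/ratios.tsv | grep -v '^#'
```

which prints (seed 3):

```
region_set  het_ratio  cov_ratio  len_ratio  classification
background  1.0000     0.9975     1.0000     normal
bub1        0.0000     0.4989     2.0000     expansion
col1        5.6860     3.0056     0.3333     collapse
exp1        0.0000     0.4993     2.0000     expansion
```

Read: the injected 2x allelic expansion (`exp1`) doubled the assembled
length of its region while halving coverage and erasing heterozygous
calls; the 3-copy repeat collapse (`col1`) shrank its region to 1/3
length with 3x coverage and ~5.7x SNP density; unaffected background genes
sit at 1.0 on every axis. The bubble region behaves as an allelic
duplication, as the graph model predicts. `demo/report/` also contains
`summary.tsv` (N50/length/heterozygosity), `comparison.tsv` (percent
missing and expanded), `fragdup.tsv` (1:1 / fragmentation / duplication
tallies) and `exclusions.tsv` (every filtered gene, with reason).

The same stages are available individually (`regionscope metrics`,
`compare`, `regions`, `fragdup`) and as library functions
(`regionscope.compute_region_ratios`, `classify_matches`, ...).

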