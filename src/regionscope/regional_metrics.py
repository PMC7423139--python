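"""Regional heterozygosity / coverage / length ratios and the
expansion-collapse signature classifier.

The workflow: locate gene regions on a test assembly from transcript
alignments (exon hits at >= 92% identity, gene span = min..max coordinate,
spans over 10 kb excluded as probable mapping errors), match each region
back to the reference at >= 98% identity (screening paralogous regions),
and compute three pooled ratios per region set:

* ``het_ratio``  — pooled SNP density, test over reference;
* ``cov_ratio``  — length-weighted mean read depth, test over reference;
* ``len_ratio``  — unique test bp over unique reference bp, with
  overlapping HSPs collapsed so expanded queries do not multi-count the
  same reference sequence.

The signature model: a regionally *expanded* assembly (alleles split into
separate contigs) shows len_ratio up with coverage and heterozygosity
down; a regional *collapse* (repeat copies merged) shows the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import AlignmentHit, DepthTable, GenomeInterval, SnpRecord

__all__ = [
    "GeneRegion",
    "RegionalMetrics",
    "RegionRatio",
    "extract_gene_regions",
    "regional_heterozygosity",
    "regional_depth",
    "match_reference_regions",
    "collapse_hsps",
    "region_set_ratios",
    "classify_region",
    "metrics_for_region",
]

DEFAULT_MIN_EXON_IDENTITY = 92.0
DEFAULT_MIN_REF_IDENTITY = 98.0
DEFAULT_MAX_GENE_SPAN = 10_000


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic footprint on one contig of an assembly.

    ``status`` is ``ok`` for a clean single-contig gene, ``multi_contig``
    when the gene's qualifying exon hits span several contigs (each contig
    gets its own flagged region — a fragmentation/expansion signal in
    itself), or ``excluded_span`` when the footprint exceeds the span cap.
    """

    gene_id: str
    interval: GenomeInterval
    n_exon_hits: int
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.n_exon_hits < 1:
            raise ValueError("n_exon_hits must be >= 1")


@dataclass(frozen=True)
class RegionalMetrics:
    region_id: str
    heterozygosity: float     # SNP sites per bp
    mean_depth: float         # fold coverage
    unique_length: int        # bp

    def __post_init__(self) -> None:
        if min(self.heterozygosity, self.mean_depth,
               self.unique_length) < 0:
            raise ValueError("regional metrics must be non-negative")


@dataclass(frozen=True)
class RegionRatio:
    region_set_id: str
    het_ratio: float | None
    cov_ratio: float | None
    len_ratio: float | None
    classification: str = "unclassified"

    @property
    def defined(self) -> bool:
        return None not in (self.het_ratio, self.cov_ratio, self.len_ratio)


def extract_gene_regions(hits: list[AlignmentHit],
                         min_identity: float = DEFAULT_MIN_EXON_IDENTITY,
                         max_gene_span: int = DEFAULT_MAX_GENE_SPAN
                         ) -> list[GeneRegion]:
    """Gene footprints from transcript-vs-assembly exon hits.

    Per transcript, hits with identity >= ``min_identity`` are kept and the
    footprint on each hit contig is [min, max) of the kept subject
    coordinates. A transcript whose kept hits land on several contigs
    yields one region per contig, flagged ``multi_contig`` (reported, and
    still measurable — in an allelically expanded assembly both allele
    contigs carry the gene and both must be counted). Footprints over
    ``max_gene_span`` are flagged ``excluded_span`` and must not enter
    ratio computations.
    """
    by_gene: dict[str, dict[str, list[AlignmentHit]]] = {}
    for hit in hits:
        if hit.pident < min_identity:
            continue
        by_gene.setdefault(hit.query_id, {}).setdefault(
            hit.subject_id, []).append(hit)

    regions: list[GeneRegion] = []
    for gene_id in by_gene:
        per_contig = by_gene[gene_id]
        multi = len(per_contig) > 1
        for contig, contig_hits in per_contig.items():
            start = min(h.sstart for h in contig_hits) - 1   # to 0-based
            end = max(h.send for h in contig_hits)
            interval = GenomeInterval(contig, start, end)
            if len(interval) > max_gene_span:
                status = "excluded_span"
            elif multi:
                status = "multi_contig"
            else:
                status = "ok"
            regions.append(GeneRegion(gene_id, interval,
                                      len(contig_hits), status))
    return regions


def regional_heterozygosity(snps: list[SnpRecord],
                            region: GenomeInterval) -> float:
    """SNP sites inside the region divided by region length."""
    count = sum(1 for s in snps if region.contains_pos(s.contig, s.pos))
    return count / len(region)


def regional_depth(depth: DepthTable, region: GenomeInterval) -> float:
    """Arithmetic mean per-base depth over the region (absent positions
    count as depth 0)."""
    return depth.mean_depth(region)


def match_reference_regions(hits: list[AlignmentHit],
                            min_identity: float = DEFAULT_MIN_REF_IDENTITY
                            ) -> list[GenomeInterval]:
    """Reference intervals of region-vs-reference hits at qualifying
    identity (orientation already normalized at read time). An empty result
    means the query region found no non-paralogous reference match and must
    be flagged unresolved by the caller."""
    return [h.subject_interval for h in hits if h.pident >= min_identity]


def collapse_hsps(intervals: list[GenomeInterval]
                  ) -> tuple[list[GenomeInterval], int]:
    """Merge overlapping/redundant HSP intervals per contig.

    Returns the disjoint sorted merge and the unique bp total, so expanded
    queries mapping repeatedly onto one reference span count it once.
    """
    merged: list[GenomeInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].contig == iv.contig \
                and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomeInterval(last.contig, last.start, iv.end)
        else:
            merged.append(iv)
    return merged, sum(len(iv) for iv in merged)


def metrics_for_region(region_id: str, interval: GenomeInterval,
                       snps: list[SnpRecord],
                       depth: DepthTable) -> RegionalMetrics:
    return RegionalMetrics(
        region_id=region_id,
        heterozygosity=regional_heterozygosity(snps, interval),
        mean_depth=regional_depth(depth, interval),
        unique_length=len(interval),
    )


def region_set_ratios(test_metrics: list[RegionalMetrics],
                      reference_metrics: list[RegionalMetrics],
                      region_set_id: str = "") -> RegionRatio:
    """Pooled test/reference ratios for one region set.

    Counts are pooled before dividing (length-weighted), not averaged per
    gene: het_ratio compares pooled SNP densities, cov_ratio compares
    length-weighted mean depths, len_ratio compares unique bp totals. A
    zero reference denominator leaves the affected ratio undefined (None)
    and the set must be excluded from aggregates.
    """
    t_bp = sum(m.unique_length for m in test_metrics)
    r_bp = sum(m.unique_length for m in reference_metrics)
    t_snps = sum(m.heterozygosity * m.unique_length for m in test_metrics)
    r_snps = sum(m.heterozygosity * m.unique_length
                 for m in reference_metrics)
    t_cov = sum(m.mean_depth * m.unique_length for m in test_metrics)
    r_cov = sum(m.mean_depth * m.unique_length for m in reference_metrics)

    if r_bp == 0 or t_bp == 0:
        return RegionRatio(region_set_id, None, None, None, "unresolved")

    len_ratio = t_bp / r_bp
    cov_ratio = ((t_cov / t_bp) / (r_cov / r_bp)) if r_cov > 0 else None
    het_ratio = ((t_snps / t_bp) / (r_snps / r_bp)) if r_snps > 0 else None
    return RegionRatio(region_set_id, het_ratio, cov_ratio, len_ratio)


def classify_region(ratio: RegionRatio,
                    len_hi: float = 1.5, len_lo: float = 0.67,
                    het_hi: float = 1.5, het_lo: float = 0.67,
                    cov_hi: float = 1.5, cov_lo: float = 0.67) -> str:
    """Label a region set by its expansion/collapse signature.

    expansion: length up, coverage and heterozygosity down (alleles split
    into separate contigs). collapse: length down, coverage and
    heterozygosity up (repeat copies merged). mixed: length AND
    heterozygosity both up — the joint expansion-plus-repeat-collapse
    signature. normal: all three ratios inside [lo, hi]. Anything else is
    unresolved.
    """
    if not ratio.defined:
        return "unresolved"
    length, cov, het = ratio.len_ratio, ratio.cov_ratio, ratio.het_ratio
    if length >= len_hi and cov <= cov_lo and het <= het_lo:
        return "expansion"
    if length <= len_lo and cov >= cov_hi and het >= het_hi:
        return "collapse"
    if length >= len_hi and het >= het_hi:
        return "mixed"
    if (len_lo <= length <= len_hi and cov_lo <= cov <= cov_hi
            and het_lo <= het <= het_hi):
        return "normal"
    return "unresolved"
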