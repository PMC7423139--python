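"""End-to-end orchestration: summarize, compare, regional ratios, protein
fragmentation/duplication, and assembly-level warnings.

All stages are pure functions over the in-memory domain types; the file
I/O lives at the edges so the same code path serves the CLI and tests.
Every output TSV starts with header comments embedding the software
version and the configuration that produced it.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from . import __version__
from .alignment_comparison import (
    ExpansionResult,
    fold_change,
    percent_expanded,
    percent_missing,
)
from .assembly_metrics import AssemblySummary, filter_by_length, \
    summarize_assembly
from .fragdup import (
    FragDupCounts,
    dedupe_hits,
    filter_reference_queries,
    identify_paralogs,
    tally_assembly,
)
from .io_formats import (
    AlignmentHit,
    DepthTable,
    GenomeInterval,
    SequenceSet,
    SnpRecord,
    read_alignment_table,
    read_depth,
    read_fasta,
    read_vcf_snps,
)
from .regional_metrics import (
    RegionRatio,
    classify_region,
    collapse_hsps,
    extract_gene_regions,
    match_reference_regions,
    metrics_for_region,
    region_set_ratios,
)

__all__ = [
    "PipelineConfig",
    "RegionSetResult",
    "PipelineReport",
    "compute_region_ratios",
    "flag_assembly",
    "run_pipeline",
    "read_genes_by_set",
]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full report run.

    Threshold defaults are the values the method is calibrated around:
    exon extraction at >= 92% identity, reference matching at >= 98%,
    gene spans over 10 kb excluded, alignments under 24 bp ignored for
    missing-sequence accounting, and a 200 bp assembly length cutoff.
    """

    test_fasta: str = ""
    ref_fasta: str = ""
    test_vcf: str = ""
    test_depth: str = ""
    ref_vcf: str = ""
    ref_depth: str = ""
    transcript_hits: str = ""
    region_hits: str = ""
    assembly_hits: str = ""
    protein_hits: str = ""
    ref_protein_ids: str = ""
    genes_by_set: str = ""
    out_dir: str = "regionscope_out"

    min_exon_identity: float = 92.0
    min_ref_identity: float = 98.0
    max_gene_span: int = 10_000
    min_aln_length: int = 24
    length_cutoff: int = 200
    ratio_hi: float = 1.5
    ratio_lo: float = 0.67
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_exon_identity", "min_ref_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.length_cutoff <= 0:
            raise ValueError("length_cutoff must be positive")

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**data)
        for f in fields(cls):
            if f.name.endswith(("_fasta", "_vcf", "_depth", "_hits",
                                "_ids", "_by_set")) or f.name == "out_dir":
                val = getattr(cfg, f.name)
                if val and not os.path.isabs(val):
                    setattr(cfg, f.name, str(base / val))
        return cfg


@dataclass(frozen=True)
class RegionSetResult:
    ratio: RegionRatio
    classification: str
    test_bp: int
    ref_bp: int
    fold_change: float | None   # reference bp over test bp
    n_genes: int


@dataclass
class PipelineReport:
    test_summary: AssemblySummary
    ref_summary: AssemblySummary
    missing_percent: float
    expansion: ExpansionResult
    region_sets: dict[str, RegionSetResult]
    fragdup: dict[str, FragDupCounts]
    warnings: list[str]
    exclusions: dict[str, int] = field(default_factory=dict)


def read_genes_by_set(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV: gene_id -> region-set id."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, set_id = line.split("\t")[:2]
            mapping[gene] = set_id
    return mapping


def compute_region_ratios(transcript_hits: list[AlignmentHit],
                          region_hits: list[AlignmentHit],
                          test_snps: list[SnpRecord],
                          test_depth: DepthTable,
                          ref_snps: list[SnpRecord],
                          ref_depth: DepthTable,
                          genes_by_set: dict[str, str],
                          min_exon_identity: float = 92.0,
                          min_ref_identity: float = 98.0,
                          max_gene_span: int = 10_000,
                          ratio_hi: float = 1.5,
                          ratio_lo: float = 0.67,
                          ) -> tuple[dict[str, RegionSetResult],
                                     dict[str, int]]:
    """The regional het/coverage/length ratio computation per region set.

    Test-side gene footprints come from the transcript hits; reference-side
    footprints come from region-vs-reference matches at
    ``min_ref_identity``. Within a set both sides are HSP-collapsed to
    unique bp before metrics are pooled.
    """
    regions = extract_gene_regions(transcript_hits, min_exon_identity,
                                   max_gene_span)
    exclusions = {
        "low_identity_exon_hits": sum(
            1 for h in transcript_hits if h.pident < min_exon_identity),
        "excluded_span_regions": sum(
            1 for r in regions if r.status == "excluded_span"),
        "multi_contig_genes": len({r.gene_id for r in regions
                                   if r.status == "multi_contig"}),
        "unmatched_regions": 0,
    }
    usable = [r for r in regions if r.status != "excluded_span"]
    test_by_gene: dict[str, list[GenomeInterval]] = {}
    for r in usable:
        test_by_gene.setdefault(r.gene_id, []).append(r.interval)

    ref_by_gene: dict[str, list[GenomeInterval]] = {}
    by_query: dict[str, list[AlignmentHit]] = {}
    for hit in region_hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    for query, hits in by_query.items():
        gene = query.split("|", 1)[0]
        matched = match_reference_regions(hits, min_ref_identity)
        if not matched:
            exclusions["unmatched_regions"] += 1
            continue
        ref_by_gene.setdefault(gene, []).extend(matched)

    sets: dict[str, list[str]] = {}
    for gene, set_id in genes_by_set.items():
        sets.setdefault(set_id, []).append(gene)

    results: dict[str, RegionSetResult] = {}
    for set_id in sorted(sets):
        genes = sets[set_id]
        t_ivs = [iv for g in genes for iv in test_by_gene.get(g, [])]
        r_ivs = [iv for g in genes for iv in ref_by_gene.get(g, [])]
        t_merged, t_bp = collapse_hsps(t_ivs)
        r_merged, r_bp = collapse_hsps(r_ivs)
        t_metrics = [metrics_for_region(f"{set_id}:{i}", iv, test_snps,
                                        test_depth)
                     for i, iv in enumerate(t_merged)]
        r_metrics = [metrics_for_region(f"{set_id}:ref:{i}", iv, ref_snps,
                                        ref_depth)
                     for i, iv in enumerate(r_merged)]
        ratio = region_set_ratios(t_metrics, r_metrics, set_id)
        label = classify_region(ratio, len_hi=ratio_hi, len_lo=ratio_lo,
                                het_hi=ratio_hi, het_lo=ratio_lo,
                                cov_hi=ratio_hi, cov_lo=ratio_lo)
        fold = fold_change(r_bp, t_bp) if (t_bp and r_bp) else None
        results[set_id] = RegionSetResult(ratio, label, t_bp, r_bp, fold,
                                          len(genes))
    return results, exclusions


def flag_assembly(summary: AssemblySummary,
                  reference_summary: AssemblySummary,
                  nonevidence_ratio: float | None = None,
                  het_warning_factor: float = 0.5,
                  length_excess_warning: float = 0.2,
                  nonevidence_warning: float = 0.5) -> list[str]:
    """Heuristic allelic-splitting warnings from whole-assembly numbers.

    Heterozygosity far below reference signals alleles split into separate
    contigs; total length well above reference at a short cutoff signals
    expanded sequence; an excess of gene predictions lacking transcript or
    protein evidence signals annotation of spurious short fragments.
    """
    warnings: list[str] = []
    ref_het = reference_summary.total_heterozygosity
    if ref_het > 0 and summary.total_heterozygosity \
            < het_warning_factor * ref_het:
        warnings.append(
            f"heterozygosity {summary.total_heterozygosity:.4%} is below "
            f"{het_warning_factor:g}x the reference value ({ref_het:.4%}): "
            "possible allelic splitting (regional expansion)")
    excess = (summary.total_length - reference_summary.total_length) \
        / reference_summary.total_length
    if excess > length_excess_warning:
        warnings.append(
            f"total length exceeds reference by {excess:.1%} at cutoff "
            f"{summary.length_cutoff} bp: possible expanded sequence")
    if nonevidence_ratio is not None \
            and nonevidence_ratio > nonevidence_warning:
        warnings.append(
            f"{nonevidence_ratio:.1%} of gene predictions lack evidentiary "
            "support: possible annotation of spurious fragments")
    return warnings


def _header(cfg: PipelineConfig, stage: str) -> str:
    lines = [f"# regionscope {__version__} :: {stage}"]
    for key, value in asdict(cfg).items():
        lines.append(f"# {key} = {value}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage from files and write the report bundle.

    Writes ``summary.tsv``, ``comparison.tsv``, ``fragdup.tsv``,
    ``ratios.tsv``, ``exclusions.tsv`` and ``warnings.txt`` under
    ``config.out_dir``. Deterministic for fixed inputs and config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                from exc

    test_seqs = stage("read", lambda: read_fasta(config.test_fasta, "test"))
    ref_seqs = stage("read", lambda: read_fasta(config.ref_fasta,
                                                "reference"))
    test_snps = stage("read", lambda: read_vcf_snps(config.test_vcf))
    ref_snps = stage("read", lambda: read_vcf_snps(config.ref_vcf))
    test_depth = stage("read", lambda: read_depth(config.test_depth))
    ref_depth = stage("read", lambda: read_depth(config.ref_depth))

    cutoff = config.length_cutoff
    test_summary = stage("summarize", lambda: summarize_assembly(
        test_seqs, test_snps, cutoff, "test"))
    ref_summary = stage("summarize", lambda: summarize_assembly(
        ref_seqs, ref_snps, cutoff, "reference"))

    asm_hits = stage("compare", lambda: read_alignment_table(
        config.assembly_hits))
    missing = stage("compare", lambda: percent_missing(
        asm_hits, ref_seqs, config.min_aln_length))
    test_total = filter_by_length(test_seqs, cutoff).total_length
    ref_total = filter_by_length(ref_seqs, cutoff).total_length
    expansion = percent_expanded(test_total, ref_total, missing / 100.0)

    transcript_hits = stage("regions", lambda: read_alignment_table(
        config.transcript_hits))
    region_hits = stage("regions", lambda: read_alignment_table(
        config.region_hits))
    genes_by_set = stage("regions", lambda: read_genes_by_set(
        config.genes_by_set))
    region_sets, exclusions = stage("regions", lambda: compute_region_ratios(
        transcript_hits, region_hits, test_snps, test_depth,
        ref_snps, ref_depth, genes_by_set,
        config.min_exon_identity, config.min_ref_identity,
        config.max_gene_span, config.ratio_hi, config.ratio_lo))

    tallies: dict[str, FragDupCounts] = {}
    if config.protein_hits:
        def _fragdup():
            hits = read_alignment_table(config.protein_hits)
            with open(config.ref_protein_ids) as handle:
                ref_ids = {line.strip() for line in handle if line.strip()}
            hits = dedupe_hits(hits)
            ref_rows = filter_reference_queries(hits, ref_ids)
            self_rows = [h for h in ref_rows if h.subject_id in ref_ids]
            paralogs = identify_paralogs(self_rows)
            assembly_rows = [h for h in ref_rows
                             if h.subject_id not in ref_ids]
            return tally_assembly(assembly_rows, ref_ids, paralogs)
        tallies = stage("fragdup", _fragdup)
    exclusions["excluded_paralogs"] = max(
        (t.excluded_paralogs for t in tallies.values()), default=0)

    warnings = flag_assembly(test_summary, ref_summary)

    _write_report(config, out, test_summary, ref_summary, missing,
                  expansion, region_sets, tallies, exclusions, warnings)
    return PipelineReport(test_summary, ref_summary, missing, expansion,
                          region_sets, tallies, warnings, exclusions)


def _write_report(cfg: PipelineConfig, out: Path,
                  test_summary: AssemblySummary,
                  ref_summary: AssemblySummary,
                  missing: float, expansion: ExpansionResult,
                  region_sets: dict[str, RegionSetResult],
                  tallies: dict[str, FragDupCounts],
                  exclusions: dict[str, int],
                  warnings: list[str]) -> None:
    with open(out / "summary.tsv", "w") as fh:
        fh.write(_header(cfg, "summary"))
        fh.write("assembly\tlength_cutoff\tn_sequences\ttotal_length\t"
                 "longest\tn50\ttotal_heterozygosity\n")
        for s in (test_summary, ref_summary):
            fh.write(f"{s.label}\t{s.length_cutoff}\t{s.n_sequences}\t"
                     f"{s.total_length}\t{s.longest}\t{s.n50}\t"
                     f"{s.total_heterozygosity:.6f}\n")

    with open(out / "comparison.tsv", "w") as fh:
        fh.write(_header(cfg, "comparison"))
        fh.write("percent_missing\tpercent_expanded_of_assembly\t"
                 "percent_excess_over_reference\tnet_deficit\n")
        fh.write(f"{missing:.4f}\t{expansion.percent_of_assembly:.4f}\t"
                 f"{expansion.percent_excess_over_reference:.4f}\t"
                 f"{int(expansion.net_deficit)}\n")

    with open(out / "ratios.tsv", "w") as fh:
        fh.write(_header(cfg, "ratios"))
        fh.write("region_set\tn_genes\thet_ratio\tcov_ratio\tlen_ratio\t"
                 "test_bp\tref_bp\tfold_change\tclassification\n")
        for set_id, res in region_sets.items():
            r = res.ratio

            def fmt(x, spec=".4f"):
                return "NA" if x is None else format(x, spec)
            fh.write(f"{set_id}\t{res.n_genes}\t{fmt(r.het_ratio)}\t"
                     f"{fmt(r.cov_ratio)}\t{fmt(r.len_ratio)}\t"
                     f"{res.test_bp}\t{res.ref_bp}\t"
                     f"{fmt(res.fold_change, '.2f')}\t"
                     f"{res.classification}\n")

    with open(out / "fragdup.tsv", "w") as fh:
        fh.write(_header(cfg, "fragdup"))
        fh.write("assembly\tone_to_one\tfragmentation_cases\t"
                 "duplication_events\texcluded_paralogs\n")
        for label in sorted(tallies):
            t = tallies[label]
            fh.write(f"{label}\t{t.one_to_one}\t{t.fragmentation_cases}\t"
                     f"{t.duplication_events}\t{t.excluded_paralogs}\n")

    with open(out / "exclusions.tsv", "w") as fh:
        fh.write(_header(cfg, "exclusions"))
        fh.write("reason\tcount\n")
        for reason, count in exclusions.items():
            fh.write(f"{reason}\t{count}\n")

    with open(out / "warnings.txt", "w") as fh:
        fh.write(_header(cfg, "warnings"))
        for w in warnings:
            fh.write(w + "\n")
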