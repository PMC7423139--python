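"""Synthetic diploid genomes and assembly artifacts, with ground truth.

This module emulates the inputs of a heterozygous-genome assembly QC study:
a diploid genome (~1% SNP heterozygosity, tandem repeat families), derived
"test assemblies" carrying injected artifacts, and the matched variant
calls, per-base depth, and pairwise-alignment tables such artifacts would
produce under an idealized read-mapping model.

Artifact model
--------------
* **expansion** — the two alleles of a heterozygous region are output as
  separate contigs (allelic duplication). Length doubles over the region,
  reads split between the alleles (depth halves), and heterozygous calls
  vanish because each read now has a perfect-match target.
* **collapse** — the copies of a near-identical tandem repeat family are
  merged into one consensus copy. Length shrinks by (factor-1) units,
  reads from every copy pile onto the merged one (depth multiplies by
  factor), and inter-copy divergence surfaces as spurious heterozygous
  calls.
* **bubble_fragmentation** — a heterozygous region with N clusters of
  nearby SNPs resolves into short partial haplotype paths (the de Bruijn
  "bubbles on bubbles" picture, up to 2^N paths). Emitted here as both
  haplotype versions of each cluster segment: 2N short contigs (always
  <= 2^N), which fragments genes and duplicates sequence at once.

Read-level simulation is deliberately bypassed: depth and SNP calls are
drawn directly from the artifact model (Poisson depth around the modelled
mean), which keeps the generator deterministic, seconds-fast, and exactly
ground-truthed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AlignmentHit,
    DepthTable,
    GenomeInterval,
    SequenceSet,
    SnpRecord,
)

REF_CONTIG = "ref_1"

DEFAULT_HET_RATE = 0.0115     # overall SNP heterozygosity of the study taxon
DEFAULT_BASE_DEPTH = 60.0     # mean fold-coverage
DEFAULT_GC = 0.40
DEFAULT_REPEAT_SPEC = {
    "n_families": 2,
    "copies": 3,
    "unit_length": 3000,
    "divergence": 0.01,       # copy-vs-consensus identity ~99%, safely
                              # above the 98% reference-matching threshold
}

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TO_IDX = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(_BASE_CODES):
    _CODE_TO_IDX[_c] = _i

__all__ = [
    "RepeatAnnotation",
    "DiploidGenome",
    "ArtifactTruth",
    "generate_diploid",
    "expansion_artifact",
    "collapse_artifact",
    "bubble_artifact",
    "make_test_assembly",
    "expected_assembly_length",
    "simulate_mapping_profile",
    "reference_mapping_profile",
    "place_genes",
    "emit_alignment_tables",
    "emit_protein_table",
    "DemoDataset",
    "make_demo_dataset",
    "write_bundle",
    "write_truth_table",
]


@dataclass(frozen=True)
class RepeatAnnotation:
    family_id: str
    interval: GenomeInterval
    divergence: float


@dataclass
class DiploidGenome:
    """Two haplotypes differing only by substitutions at ``true_snps``."""

    hap_a: SequenceSet
    hap_b: SequenceSet
    true_snps: list[tuple[str, int]]          # (contig, 1-based pos)
    het_rate: float
    repeat_annotations: list[RepeatAnnotation] = field(default_factory=list)

    @property
    def consensus(self) -> SequenceSet:
        """The haploid reference view of the genome (haplotype A)."""
        return self.hap_a

    @property
    def contig(self) -> str:
        return next(iter(self.hap_a))

    @property
    def length(self) -> int:
        return self.hap_a.total_length

    def hap_a_array(self) -> np.ndarray:
        return _as_array(self.hap_a[self.contig])

    def hap_b_array(self) -> np.ndarray:
        return _as_array(self.hap_b[self.contig])

    def repeat_families(self) -> dict[str, list[RepeatAnnotation]]:
        fams: dict[str, list[RepeatAnnotation]] = {}
        for ann in self.repeat_annotations:
            fams.setdefault(ann.family_id, []).append(ann)
        return fams


@dataclass(frozen=True)
class ArtifactTruth:
    """Ground truth for one injected assembly artifact."""

    artifact_id: str
    kind: str                     # expansion | collapse | bubble_fragmentation | none
    region: GenomeInterval        # on the consensus
    factor: int = 2               # copies emitted (expansion) or merged (collapse)
    n_snp_clusters: int = 0       # bubble case only

    def __post_init__(self) -> None:
        if self.kind not in {"expansion", "collapse",
                             "bubble_fragmentation", "none"}:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.kind in {"expansion", "collapse"} and self.factor < 2:
            raise ValueError(f"{self.kind} artifact requires factor >= 2")
        if self.kind == "bubble_fragmentation" and self.n_snp_clusters < 1:
            raise ValueError("bubble artifact requires n_snp_clusters >= 1")


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _substitute(arr: np.ndarray, positions: np.ndarray,
                rng: np.random.Generator) -> None:
    """In-place substitution at 0-based positions, never to the same base."""
    if len(positions) == 0:
        return
    idx = _CODE_TO_IDX[arr[positions]]
    offset = rng.integers(1, 4, size=len(positions))
    arr[positions] = _BASE_CODES[(idx + offset) % 4]


# ---------------------------------------------------------------------------
# Genome generation


def generate_diploid(genome_length: int,
                     het_rate: float = DEFAULT_HET_RATE,
                     repeat_spec: dict | None = None,
                     gc: float = DEFAULT_GC,
                     seed: int = 0) -> DiploidGenome:
    """Generate a single-contig diploid genome.

    Repeat families are tandem arrays: each family occupies one block of
    ``copies * unit_length`` bp, with each copy independently diverged from
    the family's ancestral unit at the per-base ``divergence`` rate.
    Heterozygous sites are Bernoulli(het_rate) per position; haplotype B is
    haplotype A with substitutions at exactly those sites.
    """
    if not 0.0 <= het_rate <= 0.05:
        raise ValueError(f"het_rate {het_rate} outside [0, 0.05]")
    if genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    if repeat_spec is None:
        repeat_spec = dict(DEFAULT_REPEAT_SPEC)

    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    hap_a = rng.choice(_BASE_CODES, size=genome_length, p=probs)

    annotations: list[RepeatAnnotation] = []
    n_fam = int(repeat_spec.get("n_families", 0))
    if n_fam > 0:
        copies = int(repeat_spec["copies"])
        unit = int(repeat_spec["unit_length"])
        div = float(repeat_spec["divergence"])
        block = copies * unit
        if n_fam * block > genome_length:
            raise ValueError(
                f"repeat total {n_fam * block} bp exceeds genome length "
                f"{genome_length} bp")
        chunk = genome_length // n_fam
        if block + 200 > chunk:
            raise ValueError("repeat blocks too large for genome partition")
        for f in range(n_fam):
            lo, hi = f * chunk + 100, (f + 1) * chunk - block - 100
            start = int(rng.integers(lo, hi))
            ancestral = rng.choice(_BASE_CODES, size=unit, p=probs)
            for c in range(copies):
                copy = ancestral.copy()
                muts = np.flatnonzero(rng.random(unit) < div)
                _substitute(copy, muts, rng)
                s = start + c * unit
                hap_a[s:s + unit] = copy
                annotations.append(RepeatAnnotation(
                    f"fam_{f}", GenomeInterval(REF_CONTIG, s, s + unit), div))

    snp_pos = np.flatnonzero(rng.random(genome_length) < het_rate)
    hap_b = hap_a.copy()
    _substitute(hap_b, snp_pos, rng)

    return DiploidGenome(
        hap_a=SequenceSet({REF_CONTIG: _to_str(hap_a)}, "hap_a"),
        hap_b=SequenceSet({REF_CONTIG: _to_str(hap_b)}, "hap_b"),
        true_snps=[(REF_CONTIG, int(p) + 1) for p in snp_pos],
        het_rate=het_rate,
        repeat_annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Artifact construction helpers


def expansion_artifact(artifact_id: str, start: int, length: int,
                       contig: str = REF_CONTIG) -> ArtifactTruth:
    return ArtifactTruth(artifact_id, "expansion",
                         GenomeInterval(contig, start, start + length),
                         factor=2)


def collapse_artifact(genome: DiploidGenome, family_id: str,
                      artifact_id: str | None = None) -> ArtifactTruth:
    """Collapse an entire tandem repeat family into one consensus copy."""
    copies = genome.repeat_families().get(family_id)
    if not copies:
        raise ValueError(f"unknown repeat family {family_id!r}")
    start = min(c.interval.start for c in copies)
    end = max(c.interval.end for c in copies)
    return ArtifactTruth(artifact_id or f"collapse_{family_id}", "collapse",
                         GenomeInterval(copies[0].interval.contig, start, end),
                         factor=len(copies))


def bubble_artifact(artifact_id: str, start: int, length: int,
                    n_snp_clusters: int,
                    contig: str = REF_CONTIG) -> ArtifactTruth:
    return ArtifactTruth(artifact_id, "bubble_fragmentation",
                         GenomeInterval(contig, start, start + length),
                         factor=2, n_snp_clusters=n_snp_clusters)


# ---------------------------------------------------------------------------
# Assembly layout: the shared provenance map between assembly construction,
# the mapping-profile simulator, and the alignment emitter.


@dataclass(frozen=True)
class _Segment:
    asm_start: int
    asm_end: int
    src: GenomeInterval           # consensus span this segment derives from
    kind: str                     # normal | expansion | collapse | bubble
    hap: str                      # "a" | "b" | "consensus"
    artifact: ArtifactTruth | None = None

    @property
    def length(self) -> int:
        return self.asm_end - self.asm_start


@dataclass(frozen=True)
class _ContigPlan:
    name: str
    segments: tuple[_Segment, ...]

    @property
    def length(self) -> int:
        return self.segments[-1].asm_end


def _validate_artifacts(genome: DiploidGenome,
                        artifacts: list[ArtifactTruth]
                        ) -> list[ArtifactTruth]:
    arts = sorted(artifacts, key=lambda a: (a.region.contig, a.region.start))
    length = genome.length
    for a in arts:
        if a.region.contig != genome.contig or a.region.end > length:
            raise ValueError(f"artifact {a.artifact_id} region outside genome")
        if a.kind == "collapse" and len(a.region) % a.factor != 0:
            raise ValueError(
                f"collapse {a.artifact_id}: region length {len(a.region)} "
                f"not divisible by factor {a.factor}")
    for x, y in zip(arts, arts[1:]):
        if x.region.overlaps(y.region):
            raise ValueError(
                f"artifact regions overlap: {x.artifact_id}, {y.artifact_id}")
    return arts


def _build_layout(genome: DiploidGenome,
                  artifacts: list[ArtifactTruth]) -> list[_ContigPlan]:
    arts = _validate_artifacts(genome, artifacts)
    contig = genome.contig
    if not any(a.kind != "none" for a in arts):
        # artifact-free assembly IS the consensus, under its own contig name
        return [_ContigPlan(contig, (_Segment(
            0, genome.length, GenomeInterval(contig, 0, genome.length),
            "normal", "a"),))]
    plans: list[_ContigPlan] = []
    backbone: list[_Segment] = []
    backbone_n = 0

    def flush() -> None:
        nonlocal backbone, backbone_n
        if backbone:
            backbone_n += 1
            plans.append(_ContigPlan(f"backbone_{backbone_n}",
                                     tuple(backbone)))
            backbone = []

    def push_backbone(src: GenomeInterval, kind: str,
                      art: ArtifactTruth | None = None,
                      asm_len: int | None = None) -> None:
        asm_len = asm_len if asm_len is not None else len(src)
        off = backbone[-1].asm_end if backbone else 0
        backbone.append(_Segment(off, off + asm_len, src, kind,
                                 "consensus" if kind == "collapse" else "a",
                                 art))

    cursor = 0
    for art in [a for a in arts if a.kind != "none"]:
        if art.region.start > cursor:
            push_backbone(GenomeInterval(contig, cursor, art.region.start),
                          "normal")
        if art.kind == "collapse":
            unit = len(art.region) // art.factor
            push_backbone(art.region, "collapse", art, asm_len=unit)
        elif art.kind == "expansion":
            flush()
            for hap, tag in (("a", "hapA"), ("b", "hapB")):
                plans.append(_ContigPlan(
                    f"{art.artifact_id}_{tag}",
                    (_Segment(0, len(art.region), art.region,
                              "expansion", hap, art),)))
        elif art.kind == "bubble_fragmentation":
            flush()
            bounds = np.linspace(art.region.start, art.region.end,
                                 art.n_snp_clusters + 1).astype(int)
            for i in range(art.n_snp_clusters):
                seg = GenomeInterval(contig, int(bounds[i]),
                                     int(bounds[i + 1]))
                for hap, tag in (("a", "a"), ("b", "b")):
                    plans.append(_ContigPlan(
                        f"{art.artifact_id}_p{i + 1}{tag}",
                        (_Segment(0, len(seg), seg, "bubble", hap, art),)))
        cursor = art.region.end
    if cursor < genome.length:
        push_backbone(GenomeInterval(contig, cursor, genome.length), "normal")
    flush()
    return plans


def _collapse_consensus(genome: DiploidGenome,
                        art: ArtifactTruth) -> np.ndarray:
    """Per-position majority base across the merged repeat copies
    (ties broken alphabetically)."""
    arr = genome.hap_a_array()
    unit = len(art.region) // art.factor
    block = arr[art.region.start:art.region.end].reshape(art.factor, unit)
    idx = _CODE_TO_IDX[block]
    counts = np.zeros((4, unit), dtype=np.int32)
    for b in range(4):
        counts[b] = (idx == b).sum(axis=0)
    return _BASE_CODES[np.argmax(counts, axis=0)]


def _segment_sequence(genome: DiploidGenome, seg: _Segment) -> np.ndarray:
    if seg.kind == "collapse":
        return _collapse_consensus(genome, seg.artifact)
    arr = genome.hap_b_array() if seg.hap == "b" else genome.hap_a_array()
    return arr[seg.src.start:seg.src.end]


def make_test_assembly(genome: DiploidGenome,
                       artifacts: list[ArtifactTruth],
                       seed: int = 0
                       ) -> tuple[SequenceSet, list[ArtifactTruth]]:
    """Materialize an artifact-bearing assembly from the consensus.

    Outside artifact regions the assembly equals the consensus (haplotype
    A). Deterministic: the construction is a pure function of the genome
    and the artifact list (the seed is accepted for interface symmetry).
    """
    arts = _validate_artifacts(genome, artifacts)
    plans = _build_layout(genome, arts)
    assembly = SequenceSet(source_label="synthetic_assembly")
    for plan in plans:
        parts = [_segment_sequence(genome, seg) for seg in plan.segments]
        assembly.add(plan.name, _to_str(np.concatenate(parts)))
    return assembly, arts


def expected_assembly_length(genome: DiploidGenome,
                             artifacts: list[ArtifactTruth]) -> int:
    """Conservation bookkeeping: consensus length plus per-artifact deltas
    (expansion/bubble gain one region length; collapse loses
    (factor-1) units)."""
    total = genome.length
    for a in artifacts:
        if a.kind in {"expansion", "bubble_fragmentation"}:
            total += len(a.region)
        elif a.kind == "collapse":
            unit = len(a.region) // a.factor
            total -= (a.factor - 1) * unit
    return total


# ---------------------------------------------------------------------------
# Mapping-profile simulation (depth + SNP calls on the test assembly)


def _collapse_variant_sites(genome: DiploidGenome, art: ArtifactTruth
                            ) -> list[tuple[int, str, tuple[str, ...]]]:
    """Variant sites surfacing in a merged repeat copy: positions where the
    2*factor haplotype-copies disagree. Returns (unit offset, ref, alts)."""
    unit = len(art.region) // art.factor
    a = genome.hap_a_array()[art.region.start:art.region.end]
    b = genome.hap_b_array()[art.region.start:art.region.end]
    stack = np.concatenate([a.reshape(art.factor, unit),
                            b.reshape(art.factor, unit)], axis=0)
    cons = _collapse_consensus(genome, art)
    variable = np.flatnonzero((stack != stack[0]).any(axis=0))
    sites = []
    for j in variable:
        alleles = {chr(c) for c in stack[:, j]}
        ref = chr(cons[j])
        alts = tuple(sorted(alleles - {ref}))
        if alts:
            sites.append((int(j), ref, alts))
    return sites


def simulate_mapping_profile(assembly: SequenceSet,
                             genome: DiploidGenome,
                             truth: list[ArtifactTruth],
                             base_depth: float = DEFAULT_BASE_DEPTH,
                             seed: int = 0,
                             mismap_rate: float = 0.0
                             ) -> tuple[DepthTable, list[SnpRecord]]:
    """Depth and SNP calls that read-mapping onto the assembly would yield.

    Per-base depth is Poisson around ``base_depth`` in normal regions,
    ``base_depth/2`` in each contig of an expanded allele pair (and in
    bubble path contigs), and ``base_depth * factor`` over a collapsed
    repeat. Heterozygous calls appear at the true SNPs of normal regions,
    are suppressed inside expanded/bubble contigs (each allele maps to its
    own contig; ``mismap_rate`` > 0 re-admits them at that rate), and
    appear at inter-copy divergence and allelic sites inside collapsed
    regions.
    """
    if base_depth < 10:
        raise ValueError("base_depth must be >= 10")
    plans = _build_layout(genome, truth)
    rng = np.random.default_rng(seed)
    hap_a = genome.hap_a_array()
    hap_b = genome.hap_b_array()
    snp_by_contig = np.array([p for _, p in genome.true_snps], dtype=np.int64)

    depth_arrays: dict[str, np.ndarray] = {}
    snps: list[SnpRecord] = []
    for plan in plans:
        lam = np.empty(plan.length, dtype=float)
        for seg in plan.segments:
            if seg.kind == "normal":
                lam[seg.asm_start:seg.asm_end] = base_depth
            elif seg.kind == "collapse":
                lam[seg.asm_start:seg.asm_end] = base_depth * seg.artifact.factor
            else:  # expansion or bubble: reads split between the two alleles
                lam[seg.asm_start:seg.asm_end] = base_depth / 2.0
        depth_arrays[plan.name] = rng.poisson(lam).astype(np.int64)

        for seg in plan.segments:
            if seg.kind == "collapse":
                for off, ref, alts in _collapse_variant_sites(
                        genome, seg.artifact):
                    snps.append(SnpRecord(plan.name,
                                          seg.asm_start + off + 1, ref, alts))
                continue
            # true heterozygous sites falling in this consensus span
            lo = np.searchsorted(snp_by_contig, seg.src.start + 1)
            hi = np.searchsorted(snp_by_contig, seg.src.end, side="right")
            span_snps = snp_by_contig[lo:hi]
            if seg.kind in {"expansion", "bubble"}:
                if mismap_rate <= 0.0:
                    continue
                keep = rng.random(len(span_snps)) < mismap_rate
                span_snps = span_snps[keep]
            for pos in span_snps:
                i = int(pos) - 1
                ref, alt = chr(hap_a[i]), chr(hap_b[i])
                if seg.hap == "b":
                    ref, alt = alt, ref
                asm_pos = seg.asm_start + (i - seg.src.start) + 1
                snps.append(SnpRecord(plan.name, asm_pos, ref, (alt,)))

    snps.sort(key=lambda s: (s.contig, s.pos))
    return DepthTable.from_dense(depth_arrays), snps


def reference_mapping_profile(genome: DiploidGenome,
                              base_depth: float = DEFAULT_BASE_DEPTH,
                              seed: int = 0
                              ) -> tuple[DepthTable, list[SnpRecord]]:
    """Depth and SNP calls for reads mapped onto the (artifact-free)
    reference itself: Poisson depth around ``base_depth`` everywhere and a
    heterozygous call at every true SNP, on the reference contig name."""
    rng = np.random.default_rng(seed)
    hap_a, hap_b = genome.hap_a_array(), genome.hap_b_array()
    depth = rng.poisson(base_depth, genome.length).astype(np.int64)
    snps = [SnpRecord(contig, pos, chr(hap_a[pos - 1]),
                      (chr(hap_b[pos - 1]),))
            for contig, pos in genome.true_snps]
    return DepthTable.from_dense({genome.contig: depth}), snps


# ---------------------------------------------------------------------------
# Gene placement and alignment-table emission


def place_genes(genome: DiploidGenome,
                artifacts: list[ArtifactTruth],
                n_background: int = 4,
                gene_length: int = 1500,
                seed: int = 0) -> dict[str, GenomeInterval]:
    """Place one gene inside each artifact region plus background genes.

    Collapse genes sit within the first repeat copy of the merged family;
    expansion/bubble genes sit at the region center; background genes land
    in normal sequence away from every artifact and repeat block.
    """
    rng = np.random.default_rng(seed)
    contig = genome.contig
    genes: dict[str, GenomeInterval] = {}
    blocked: list[GenomeInterval] = [a.region for a in artifacts]
    blocked += [r.interval for r in genome.repeat_annotations]

    for art in artifacts:
        if art.kind == "none":
            continue
        region = art.region
        if art.kind == "collapse":
            unit = len(region) // art.factor
            g_len = min(gene_length, unit - 20)
            start = region.start + (unit - g_len) // 2
        else:
            g_len = min(gene_length, len(region) - 20)
            start = region.start + (len(region) - g_len) // 2
        genes[f"gene_{art.artifact_id}"] = GenomeInterval(
            contig, start, start + g_len)

    placed = 0
    attempts = 0
    while placed < n_background and attempts < 10_000:
        attempts += 1
        start = int(rng.integers(0, genome.length - gene_length))
        cand = GenomeInterval(contig, start, start + gene_length)
        if any(cand.overlaps(b) for b in blocked):
            continue
        if any(cand.overlaps(g) for g in genes.values()):
            continue
        genes[f"gene_bg_{placed + 1}"] = cand
        placed += 1
    if placed < n_background:
        raise ValueError("could not place background genes without overlap")
    return genes


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * float(np.mean(a == b))


def _hit(query: str, subject: str, pident: float, qstart0: int, qend0: int,
         sstart0: int, send0: int) -> AlignmentHit:
    length = qend0 - qstart0
    mism = int(round(length * (100.0 - pident) / 100.0))
    return AlignmentHit(query, subject, round(pident, 2), length, mism, 0,
                        qstart0 + 1, qend0, sstart0 + 1, send0,
                        evalue=0.0, bitscore=float(2 * length))


def _gene_placements(genome: DiploidGenome, plans: list[_ContigPlan],
                     gene: GenomeInterval):
    """Yield (contig, asm_start0, src_overlap, sequence, pident) placements
    of a consensus gene interval across the assembly layout."""
    hap_a, hap_b = genome.hap_a_array(), genome.hap_b_array()
    for plan in plans:
        for seg in plan.segments:
            if not seg.src.overlaps(gene):
                continue
            ov = GenomeInterval(gene.contig, max(gene.start, seg.src.start),
                                min(gene.end, seg.src.end))
            ref_seq = hap_a[ov.start:ov.end]
            if seg.kind == "collapse":
                unit = len(seg.src) // seg.artifact.factor
                # map consensus coordinates into the merged unit
                off0 = ov.start - seg.src.start
                copy_i, unit_off = divmod(off0, unit)
                end_off = (ov.end - seg.src.start - 1) % unit + 1
                if ov.end - seg.src.start > (copy_i + 1) * unit:
                    # gene spans a copy boundary: clip to the first copy
                    end_off = unit
                    ov = GenomeInterval(ov.contig, ov.start,
                                        seg.src.start + (copy_i + 1) * unit)
                    ref_seq = hap_a[ov.start:ov.end]
                cons = _collapse_consensus(genome, seg.artifact)
                asm_seq = cons[unit_off:end_off]
                asm_start = seg.asm_start + unit_off
            else:
                asm_seq = (hap_b if seg.hap == "b" else hap_a)[ov.start:ov.end]
                asm_start = seg.asm_start + (ov.start - seg.src.start)
            yield (plan.name, asm_start, ov, asm_seq,
                   _identity(ref_seq, asm_seq))


def emit_alignment_tables(genome: DiploidGenome,
                          artifacts: list[ArtifactTruth],
                          genes: dict[str, GenomeInterval],
                          seed: int = 0,
                          min_exon_split: int = 400
                          ) -> dict[str, list[AlignmentHit]]:
    """Alignment tables the artifact layout implies, with true identities.

    Returns three 12-column hit lists:

    * ``transcripts_vs_assembly`` — each gene's consensus transcript against
      the test assembly (split into two exon-like hits when long enough);
    * ``regions_vs_reference`` — each extracted assembly gene region back
      against the consensus (queries named ``gene|contig``);
    * ``assembly_vs_reference`` — every assembly contig against its source
      span(s) on the consensus.

    Identities are exact Hamming identities of the aligned spans, so an
    allelic contig pair scores ~``100 - 100*het_rate`` against the shared
    reference span and a merged repeat scores ~``100 - 100*divergence``
    against each of its source copies.
    """
    arts = _validate_artifacts(genome, artifacts)
    plans = _build_layout(genome, arts)
    rng = np.random.default_rng(seed)
    hap_a = genome.hap_a_array()
    contig = genome.contig

    transcripts: list[AlignmentHit] = []
    region_hits: list[AlignmentHit] = []
    # per (gene, assembly contig): span and sequence of the extracted region
    placements: dict[tuple[str, str], list] = {}

    for gene_id, gene in genes.items():
        for name, asm_start, ov, asm_seq, pident in _gene_placements(
                genome, plans, gene):
            q0, q1 = ov.start - gene.start, ov.end - gene.start
            n = len(asm_seq)
            if n >= min_exon_split:
                cut = int(rng.integers(n // 3, 2 * n // 3))
                pieces = [(0, cut), (cut, n)]
            else:
                pieces = [(0, n)]
            for a, b in pieces:
                ref_piece = hap_a[ov.start + a:ov.start + b]
                transcripts.append(_hit(
                    gene_id, name, _identity(ref_piece, asm_seq[a:b]),
                    q0 + a, q0 + b, asm_start + a, asm_start + b))
            placements.setdefault((gene_id, name), []).append(
                (asm_start, ov, asm_seq, pident))

    for (gene_id, name), spans in placements.items():
        qname = f"{gene_id}|{name}"
        q_off = min(s[0] for s in spans)
        for asm_start, ov, asm_seq, pident in spans:
            seg_kind = _segment_kind_at(plans, name, asm_start)
            if seg_kind == "collapse":
                art = next(a for a in arts if a.kind == "collapse"
                           and a.region.overlaps(ov))
                unit = len(art.region) // art.factor
                u0 = ov.start - art.region.start
                for c in range(art.factor):
                    s0 = art.region.start + c * unit + (u0 % unit)
                    s1 = s0 + len(asm_seq)
                    pid = _identity(asm_seq, hap_a[s0:s1])
                    region_hits.append(_hit(
                        qname, contig, pid,
                        asm_start - q_off, asm_start - q_off + len(asm_seq),
                        s0, s1))
            else:
                region_hits.append(_hit(
                    qname, contig, pident,
                    asm_start - q_off, asm_start - q_off + len(asm_seq),
                    ov.start, ov.end))

    asm_hits: list[AlignmentHit] = []
    hap_b = genome.hap_b_array()
    for plan in plans:
        for seg in plan.segments:
            if seg.kind == "collapse":
                art = seg.artifact
                unit = len(seg.src) // art.factor
                cons = _collapse_consensus(genome, art)
                for c in range(art.factor):
                    s0 = seg.src.start + c * unit
                    pid = _identity(cons, hap_a[s0:s0 + unit])
                    asm_hits.append(_hit(plan.name, contig, pid,
                                         seg.asm_start, seg.asm_end,
                                         s0, s0 + unit))
            else:
                asm_seq = (hap_b if seg.hap == "b"
                           else hap_a)[seg.src.start:seg.src.end]
                pid = _identity(hap_a[seg.src.start:seg.src.end], asm_seq)
                asm_hits.append(_hit(plan.name, contig, pid,
                                     seg.asm_start, seg.asm_end,
                                     seg.src.start, seg.src.end))

    return {
        "transcripts_vs_assembly": transcripts,
        "regions_vs_reference": region_hits,
        "assembly_vs_reference": asm_hits,
    }


def _segment_kind_at(plans: list[_ContigPlan], name: str,
                     asm_start: int) -> str:
    for plan in plans:
        if plan.name != name:
            continue
        for seg in plan.segments:
            if seg.asm_start <= asm_start < seg.asm_end:
                return seg.kind
    return "normal"


def emit_protein_table(genome: DiploidGenome,
                       artifacts: list[ArtifactTruth],
                       genes: dict[str, GenomeInterval],
                       seed: int = 0
                       ) -> tuple[list[AlignmentHit], set[str]]:
    """All-vs-all style protein hit table plus the reference protein ids.

    One reference protein per gene (length = gene length / 3 aa). Each
    placement of the gene in the test assembly yields one match whose
    query-side span is the covered fraction of the protein, so an expanded
    gene produces two overlapping matches (an allelic duplication) and a
    bubble-fragmented gene produces overlapping and non-overlapping pieces.
    Reference self-hits are included; assembly-as-query reciprocal rows are
    included so reference-query filtering is exercised.
    """
    arts = _validate_artifacts(genome, artifacts)
    plans = _build_layout(genome, arts)
    hits: list[AlignmentHit] = []
    ref_ids: set[str] = set()
    for gene_id, gene in genes.items():
        ref = f"ref|{gene_id}"
        ref_ids.add(ref)
        aa_len = max(len(gene) // 3, 1)
        hits.append(_hit(ref, ref, 100.0, 0, aa_len, 0, aa_len))
        seen: set[str] = set()
        for name, asm_start, ov, asm_seq, pident in _gene_placements(
                genome, plans, gene):
            if name in seen and _segment_kind_at(
                    plans, name, asm_start) == "collapse":
                continue  # merged copies give one protein, not several
            seen.add(name)
            subject = f"asm|{gene_id}@{name}"
            a0 = (ov.start - gene.start) // 3
            a1 = max(a0 + 1, (ov.end - gene.start) // 3)
            a1 = min(a1, aa_len)
            hits.append(_hit(ref, subject, pident, a0, a1, 0, a1 - a0))
            hits.append(_hit(subject, ref, pident, 0, a1 - a0, a0, a1))
    return hits, ref_ids


# ---------------------------------------------------------------------------
# Demo dataset + on-disk bundle


@dataclass
class DemoDataset:
    """A complete in-memory study: genome, artifact assembly, mapping
    profiles for both assemblies, alignment tables, and ground truth."""

    genome: DiploidGenome
    artifacts: list[ArtifactTruth]
    assembly: SequenceSet
    test_depth: DepthTable
    test_snps: list[SnpRecord]
    ref_depth: DepthTable
    ref_snps: list[SnpRecord]
    tables: dict[str, list[AlignmentHit]]
    protein_hits: list[AlignmentHit]
    ref_protein_ids: set[str]
    genes: dict[str, GenomeInterval]
    genes_by_set: dict[str, str]


def make_demo_dataset(genome_length: int = 300_000,
                      het_rate: float = DEFAULT_HET_RATE,
                      base_depth: float = DEFAULT_BASE_DEPTH,
                      n_expansion: int = 1,
                      expansion_size: int = 15_000,
                      n_collapse: int = 1,
                      n_bubble: int = 1,
                      bubble_size: int = 4_000,
                      bubble_clusters: int = 3,
                      n_background_genes: int = 4,
                      gene_length: int = 3_000,
                      repeat_spec: dict | None = None,
                      mismap_rate: float = 0.0,
                      seed: int = 0) -> DemoDataset:
    """Generate a genome, inject one study's worth of artifacts, and derive
    every downstream file the pipeline consumes.

    Collapse artifacts consume the genome's repeat families (one family
    each); expansion and bubble regions are placed in non-repeat sequence.
    Each artifact carries one gene; region sets are named after their
    artifact (background genes pool into the ``background`` set).
    """
    if repeat_spec is None:
        repeat_spec = dict(DEFAULT_REPEAT_SPEC)
        repeat_spec["n_families"] = max(n_collapse, 1)
    genome = generate_diploid(genome_length, het_rate, repeat_spec,
                              seed=seed)
    rng = np.random.default_rng(seed + 1)
    blocked = [r.interval for r in genome.repeat_annotations]

    def place(size: int) -> GenomeInterval:
        for _ in range(10_000):
            start = int(rng.integers(500, genome_length - size - 500))
            cand = GenomeInterval(genome.contig, start - 500,
                                  start + size + 500)
            if not any(cand.overlaps(b) for b in blocked):
                blocked.append(cand)
                return GenomeInterval(genome.contig, start, start + size)
        raise ValueError("could not place artifact region")

    artifacts: list[ArtifactTruth] = []
    for i in range(n_expansion):
        iv = place(expansion_size)
        artifacts.append(ArtifactTruth(f"exp{i + 1}", "expansion", iv,
                                       factor=2))
    families = sorted(genome.repeat_families())
    if n_collapse > len(families):
        raise ValueError("not enough repeat families for collapse artifacts")
    for i in range(n_collapse):
        artifacts.append(collapse_artifact(genome, families[i],
                                           f"col{i + 1}"))
    for i in range(n_bubble):
        iv = place(bubble_size)
        artifacts.append(bubble_artifact(f"bub{i + 1}", iv.start, len(iv),
                                         bubble_clusters))

    assembly, truth = make_test_assembly(genome, artifacts, seed)
    test_depth, test_snps = simulate_mapping_profile(
        assembly, genome, truth, base_depth, seed + 2, mismap_rate)
    ref_depth, ref_snps = reference_mapping_profile(genome, base_depth,
                                                    seed + 3)
    genes = place_genes(genome, truth, n_background_genes, gene_length,
                        seed + 4)
    genes_by_set = {}
    for gene_id in genes:
        if gene_id.startswith("gene_bg_"):
            genes_by_set[gene_id] = "background"
        else:
            genes_by_set[gene_id] = gene_id.removeprefix("gene_")
    tables = emit_alignment_tables(genome, truth, genes, seed + 5)
    protein_hits, ref_ids = emit_protein_table(genome, truth, genes,
                                               seed + 6)
    return DemoDataset(genome, truth, assembly, test_depth, test_snps,
                       ref_depth, ref_snps, tables, protein_hits, ref_ids,
                       genes, genes_by_set)


def write_bundle(dataset: DemoDataset, out_dir,
                 self_comparison: bool = False) -> "Path":
    """Write a demo dataset as the file bundle the report pipeline reads,
    plus a ready-to-run ``config.toml``.

    With ``self_comparison=True`` the test-side paths in the config point
    at the reference's own files (the reference compared against itself).
    """
    from pathlib import Path

    from .io_formats import (write_alignment_table, write_depth,
                             write_fasta, write_vcf_snps)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = dataset
    ref_lengths = ds.genome.consensus.lengths()
    asm_lengths = ds.assembly.lengths()

    write_fasta(ds.genome.consensus, out / "ref.fa")
    write_fasta(ds.assembly, out / "asm.fa")
    write_vcf_snps(ds.test_snps, out / "test.vcf", asm_lengths)
    write_vcf_snps(ds.ref_snps, out / "ref.vcf", ref_lengths)
    write_depth(ds.test_depth, out / "test.depth")
    write_depth(ds.ref_depth, out / "ref.depth")
    for name, hits in ds.tables.items():
        write_alignment_table(hits, out / f"{name}.tsv")
    write_alignment_table(ds.protein_hits, out / "proteins_allvsall.tsv")
    with open(out / "ref_protein_ids.txt", "w") as fh:
        for pid in sorted(ds.ref_protein_ids):
            fh.write(pid + "\n")
    with open(out / "genes_by_set.tsv", "w") as fh:
        fh.write("#gene_id\tregion_set\n")
        for gene, set_id in ds.genes_by_set.items():
            fh.write(f"{gene}\t{set_id}\n")
    write_truth_table(ds.artifacts, out / "truth.tsv")

    test_prefix = "ref" if self_comparison else "test"
    test_fa = "ref.fa" if self_comparison else "asm.fa"
    with open(out / "config.toml", "w") as fh:
        fh.write(
            f'test_fasta = "{test_fa}"\n'
            'ref_fasta = "ref.fa"\n'
            f'test_vcf = "{test_prefix}.vcf"\n'
            f'test_depth = "{test_prefix}.depth"\n'
            'ref_vcf = "ref.vcf"\n'
            'ref_depth = "ref.depth"\n'
            'transcript_hits = "transcripts_vs_assembly.tsv"\n'
            'region_hits = "regions_vs_reference.tsv"\n'
            'assembly_hits = "assembly_vs_reference.tsv"\n'
            'protein_hits = "proteins_allvsall.tsv"\n'
            'ref_protein_ids = "ref_protein_ids.txt"\n'
            'genes_by_set = "genes_by_set.tsv"\n'
            'out_dir = "report"\n')
    return out


def write_truth_table(truth: list[ArtifactTruth], path) -> None:
    """Tab-separated ground truth: artifact_id, kind, contig, start, end,
    factor, n_snp_clusters."""
    with open(path, "w") as out:
        out.write("#artifact_id\tkind\tcontig\tstart\tend\tfactor"
                  "\tn_snp_clusters\n")
        for a in truth:
            out.write(f"{a.artifact_id}\t{a.kind}\t{a.region.contig}\t"
                      f"{a.region.start}\t{a.region.end}\t{a.factor}\t"
                      f"{a.n_snp_clusters}\n")
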