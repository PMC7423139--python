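"""Missing- and expanded-sequence accounting from pairwise alignments.

Given an alignment of a test assembly onto a reference, quantify how much
reference sequence has no qualifying alignment at all (percent missing) and
how much of the test assembly is attributable to regional expansion. The
expansion figures come from the totals arithmetic:

    excess = assembly_total - (1 - missing_fraction) * reference_total

reported both as a percent of the reference (excess over reference) and as
a percent of the assembly itself (share of the assembly that is expanded
sequence).
"""

from __future__ import annotations

from typing import NamedTuple

from .io_formats import AlignmentHit, GenomeInterval, SequenceSet
from .regional_metrics import collapse_hsps

__all__ = [
    "ExpansionResult",
    "percent_missing",
    "percent_expanded",
    "fold_change",
]


class ExpansionResult(NamedTuple):
    percent_of_assembly: float
    percent_excess_over_reference: float
    net_deficit: bool  # excess clamped to zero (assembly smaller than mapped reference)


def percent_missing(hits: list[AlignmentHit], reference: SequenceSet,
                    min_aln_length: int = 24) -> float:
    """Percent of reference bp not covered by any hit of qualifying length.

    Subject-side intervals of all hits with ``aln_length >= min_aln_length``
    are merged (coverage is a property of the reference, regardless of which
    query contig provided it); no identity threshold is applied.
    """
    intervals: list[GenomeInterval] = []
    contig_lengths = reference.lengths()
    for hit in hits:
        if hit.aln_length < min_aln_length:
            continue
        if hit.subject_id not in contig_lengths:
            raise ValueError(f"hit subject {hit.subject_id!r} "
                             "not in reference")
        iv = hit.subject_interval
        end = min(iv.end, contig_lengths[hit.subject_id])
        intervals.append(GenomeInterval(iv.contig, iv.start, end))
    _, covered = collapse_hsps(intervals)
    total = reference.total_length
    return 100.0 * (total - covered) / total


def percent_expanded(assembly_total: int, reference_total: int,
                     missing_fraction: float) -> ExpansionResult:
    """Expansion accounting from assembly/reference totals and the missing
    fraction of the reference."""
    if assembly_total <= 0 or reference_total <= 0:
        raise ValueError("totals must be positive")
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValueError("missing_fraction must be in [0, 1]")
    excess = assembly_total - (1.0 - missing_fraction) * reference_total
    if excess < 0:
        return ExpansionResult(0.0, 0.0, True)
    return ExpansionResult(
        100.0 * excess / assembly_total,
        100.0 * excess / reference_total,
        False,
    )


def fold_change(reference_bp: int, assembly_bp: int) -> float:
    """Fold contraction (reference bp over assembly bp); >1 means the test
    assembly holds less sequence than the reference for the region set."""
    if assembly_bp == 0:
        raise ValueError("assembly_bp must be non-zero")
    if reference_bp <= 0 or assembly_bp < 0:
        raise ValueError("base-pair totals must be positive")
    return reference_bp / assembly_bp
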