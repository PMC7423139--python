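"""Whole-assembly summary statistics.

Length filtering, N50, total length, longest sequence, and genome-wide SNP
heterozygosity (SNP sites per bp, from reads mapped back onto the assembly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import SequenceSet, SnpRecord

__all__ = [
    "AssemblySummary",
    "filter_by_length",
    "compute_n50",
    "total_heterozygosity",
    "summarize_assembly",
]


@dataclass(frozen=True)
class AssemblySummary:
    label: str
    length_cutoff: int
    n_sequences: int
    total_length: int
    longest: int
    n50: int
    total_heterozygosity: float

    def __post_init__(self) -> None:
        if not (self.n50 <= self.longest <= self.total_length):
            raise ValueError("inconsistent summary: require "
                             "n50 <= longest <= total_length")
        if self.total_heterozygosity < 0:
            raise ValueError("negative heterozygosity")


def filter_by_length(seqs: SequenceSet, cutoff: int) -> SequenceSet:
    """Keep sequences of length >= cutoff (inclusive), preserving order."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    out = SequenceSet(source_label=seqs.source_label)
    for name, seq in seqs.items():
        if len(seq) >= cutoff:
            out.add(name, seq)
    return out


def compute_n50(lengths: Iterable[int]) -> int:
    """N50: the input length L at which the descending cumulative sum first
    reaches half the total (>= convention)."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("compute_n50 requires a non-empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("all lengths must be positive")
    half = sum(lengths) / 2.0
    running = 0
    for length in lengths:
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def total_heterozygosity(snps: list[SnpRecord], seqs: SequenceSet) -> float:
    """SNP sites divided by total assembly length (N runs included)."""
    for snp in snps:
        if snp.contig not in seqs:
            raise ValueError(f"SNP on unknown contig {snp.contig!r}")
    total = seqs.total_length
    return len(snps) / total


def summarize_assembly(seqs: SequenceSet, snps: list[SnpRecord],
                       cutoff: int, label: str | None = None
                       ) -> AssemblySummary:
    """Apply the length cutoff, then summarize the filtered assembly.

    SNPs on contigs removed by the cutoff are dropped with them, so the
    heterozygosity numerator and denominator always refer to the same
    sequence set.
    """
    filtered = filter_by_length(seqs, cutoff)
    if len(filtered) == 0:
        raise ValueError(f"length cutoff {cutoff} removed every sequence")
    kept_snps = [s for s in snps if s.contig in filtered]
    lengths = list(filtered.lengths().values())
    return AssemblySummary(
        label=label or seqs.source_label,
        length_cutoff=cutoff,
        n_sequences=len(filtered),
        total_length=sum(lengths),
        longest=max(lengths),
        n50=compute_n50(lengths),
        total_heterozygosity=total_heterozygosity(kept_snps, filtered),
    )
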