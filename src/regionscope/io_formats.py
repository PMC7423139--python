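"""Readers and writers for the file dialects the pipeline consumes.

Four external formats are handled: FASTA assemblies, VCF 4.x variant calls,
3-column per-base depth tables (``samtools depth`` output), and 12-column
tabular pairwise alignments (BLAST ``-outfmt 6`` dialect, also produced by
LAST's tabular converters).

Coordinate conventions: every tabular input is 1-based inclusive (the
BLAST/VCF/samtools convention). Conversion to the internal 0-based
half-open :class:`GenomeInterval` happens exactly once, at read time, so no
downstream code ever converts coordinates again.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "GenomeInterval",
    "SequenceSet",
    "AlignmentHit",
    "SnpRecord",
    "DepthTable",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "read_vcf_snps",
    "write_vcf_snps",
    "read_depth",
    "write_depth",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A span on one contig: 0-based start, exclusive end."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, contig: str, pos_1based: int) -> bool:
        """True if the 1-based position falls inside this interval."""
        return contig == self.contig and self.start < pos_1based <= self.end


class SequenceSet:
    """Named nucleotide sequences of one assembly, insertion-ordered.

    Sequences are upper-cased on entry and restricted to A/C/G/T/N.
    """

    def __init__(self, records: dict[str, str] | None = None,
                 source_label: str = ""):
        self.source_label = source_label
        self.records: dict[str, str] = {}
        if records:
            for name, seq in records.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self.records:
            raise ValueError(f"duplicate sequence id: {name!r}")
        if not seq:
            raise ValueError(f"empty sequence for id {name!r}")
        seq = seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {name!r} contains invalid characters {sorted(bad)}"
            )
        self.records[name] = seq

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __iter__(self):
        return iter(self.records)

    def items(self):
        return self.records.items()

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def slice(self, iv: GenomeInterval) -> str:
        seq = self.records[iv.contig]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv} exceeds contig length {len(seq)}")
        return seq[iv.start:iv.end]

    def __eq__(self, other) -> bool:
        return isinstance(other, SequenceSet) and self.records == other.records


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output, orientation-normalized.

    After normalization ``qstart <= qend`` and ``sstart <= send`` always hold
    (1-based inclusive, as printed); ``subject_reversed`` records whether the
    original row had a descending subject span (a reverse-strand match).
    """

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_reversed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")

    @classmethod
    def from_fields(cls, fields: list[str]) -> "AlignmentHit":
        q, s = fields[0], fields[1]
        pident = float(fields[2])
        aln_length = int(fields[3])
        mism, gaps = int(fields[4]), int(fields[5])
        qstart, qend = int(fields[6]), int(fields[7])
        sstart, send = int(fields[8]), int(fields[9])
        evalue, bits = float(fields[10]), float(fields[11])
        reversed_ = sstart > send
        if reversed_:
            sstart, send = send, sstart
        if qstart > qend:
            qstart, qend = qend, qstart
        return cls(q, s, pident, aln_length, mism, gaps,
                   qstart, qend, sstart, send, evalue, bits, reversed_)

    def normalized(self) -> "AlignmentHit":
        """Canonical form; a no-op on an already-normalized hit."""
        if self.sstart <= self.send and self.qstart <= self.qend:
            return self
        new = replace(
            self,
            sstart=min(self.sstart, self.send),
            send=max(self.sstart, self.send),
            qstart=min(self.qstart, self.qend),
            qend=max(self.qstart, self.qend),
            subject_reversed=self.subject_reversed or self.sstart > self.send,
        )
        return new

    @property
    def subject_interval(self) -> GenomeInterval:
        return GenomeInterval(self.subject_id, self.sstart - 1, self.send)

    @property
    def query_interval(self) -> GenomeInterval:
        return GenomeInterval(self.query_id, self.qstart - 1, self.qend)

    def to_row(self) -> str:
        sstart, send = self.sstart, self.send
        if self.subject_reversed:
            sstart, send = send, sstart
        return "\t".join(str(x) for x in (
            self.query_id, self.subject_id, f"{self.pident:.2f}",
            self.aln_length, self.mismatches, self.gap_opens,
            self.qstart, self.qend, sstart, send,
            f"{self.evalue:.2g}", f"{self.bitscore:.1f}"))


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic or multiallelic SNP site (single-base alleles only)."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position {self.pos} < 1")


class DepthTable:
    """Per-base read depth, zero-filled at positions absent from the input.

    Internally each contig holds sorted position/depth arrays plus a prefix
    sum, so regional mean depth is O(log n) per query.
    """

    def __init__(self, per_contig: dict[str, tuple[np.ndarray, np.ndarray]]):
        # per_contig: contig -> (positions 1-based sorted, depths)
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for contig, (pos, depth) in per_contig.items():
            pos = np.asarray(pos, dtype=np.int64)
            depth = np.asarray(depth, dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            pos, depth = pos[order], depth[order]
            if np.any(depth < 0):
                raise ValueError(f"negative depth on contig {contig!r}")
            csum = np.concatenate([[0], np.cumsum(depth)])
            self._data[contig] = (pos, depth, csum)

    @classmethod
    def from_dense(cls, arrays: dict[str, np.ndarray]) -> "DepthTable":
        """Build from dense per-contig arrays (index 0 = position 1)."""
        per = {}
        for contig, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.int64)
            per[contig] = (np.arange(1, len(arr) + 1), arr)
        return cls(per)

    @property
    def contigs(self) -> list[str]:
        return list(self._data)

    def depth_at(self, contig: str, pos: int) -> int:
        """Depth at a 1-based position; 0 if absent."""
        if contig not in self._data:
            return 0
        positions, depths, _ = self._data[contig]
        i = np.searchsorted(positions, pos)
        if i < len(positions) and positions[i] == pos:
            return int(depths[i])
        return 0

    def region_sum(self, region: GenomeInterval) -> int:
        if region.contig not in self._data:
            return 0
        positions, _, csum = self._data[region.contig]
        lo = np.searchsorted(positions, region.start + 1)   # first 1-based pos
        hi = np.searchsorted(positions, region.end, side="right")
        return int(csum[hi] - csum[lo])

    def mean_depth(self, region: GenomeInterval) -> float:
        return self.region_sum(region) / len(region)

    def items(self):
        for contig, (pos, depth, _) in self._data.items():
            yield contig, pos, depth


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike, source_label: str | None = None
               ) -> SequenceSet:
    """Read a FASTA file; record id is the first whitespace token."""
    seqs = SequenceSet(source_label=source_label or os.fspath(path))
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0] if title.split() else ""
            if not name:
                raise ValueError(f"{path}: FASTA record with empty id")
            seqs.add(name, seq.replace(" ", ""))
    if len(seqs) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: SequenceSet, path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignments


def read_alignment_table(path: str | os.PathLike) -> list[AlignmentHit]:
    """Parse a tab-separated 12+ column alignment table.

    Rows with descending subject coordinates are flipped to ascending and
    flagged ``subject_reversed``. Errors carry the 1-based line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                hits.append(AlignmentHit.from_fields(fields))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_alignment_table(hits: list[AlignmentHit],
                          path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for hit in hits:
            out.write(hit.to_row() + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf_snps(path: str | os.PathLike) -> list[SnpRecord]:
    """Extract SNP sites from a VCF 4.x file.

    Indels and symbolic alleles are dropped; a multiallelic SNP site yields
    one :class:`SnpRecord` (one segregating site). Only CHROM/POS/REF/ALT
    are consumed.
    """
    from cyvcf2 import VCF

    records: list[SnpRecord] = []
    vcf = VCF(os.fspath(path))
    try:
        for var in vcf:
            ref = var.REF
            alts = var.ALT
            if len(ref) != 1 or ref not in VALID_BASES:
                continue
            if not alts:
                continue
            snp_alts = tuple(a for a in alts
                             if len(a) == 1 and a in VALID_BASES)
            if len(snp_alts) != len(alts):
                continue  # any indel/symbolic allele disqualifies the site
            records.append(SnpRecord(var.CHROM, var.POS, ref, snp_alts))
    finally:
        vcf.close()
    return records


def write_vcf_snps(snps: list[SnpRecord], path: str | os.PathLike,
                   contig_lengths: dict[str, int] | None = None) -> None:
    """Write SNP records as a minimal sites-only VCF 4.2 file."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=regionscope-synthetic\n")
        for contig, length in (contig_lengths or {}).items():
            out.write(f"##contig=<ID={contig},length={length}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda r: (r.contig, r.pos)):
            out.write(f"{s.contig}\t{s.pos}\t.\t{s.ref_allele}\t"
                      f"{','.join(s.alt_alleles)}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Depth tables


def read_depth(path: str | os.PathLike) -> DepthTable:
    """Read a ``samtools depth``-style 3-column table (contig, pos, depth)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "pos", "depth"],
                     dtype={"contig": str, "pos": np.int64,
                            "depth": np.int64})
    if len(df) and (df["depth"] < 0).any():
        bad = df.index[df["depth"] < 0][0] + 1
        raise ValueError(f"{path}: negative depth at line {bad}")
    per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, sub in df.groupby("contig", sort=False):
        per[str(contig)] = (sub["pos"].to_numpy(), sub["depth"].to_numpy())
    return DepthTable(per)


def write_depth(table: DepthTable, path: str | os.PathLike,
                omit_zero: bool = True) -> None:
    """Write the 3-column depth table (zero rows omitted by default,
    matching samtools depth without ``-a``)."""
    with open(path, "w") as out:
        for contig, positions, depths in table.items():
            buf = io.StringIO()
            for pos, depth in zip(positions.tolist(), depths.tolist()):
                if omit_zero and depth == 0:
                    continue
                buf.write(f"{contig}\t{pos}\t{depth}\n")
            out.write(buf.getvalue())
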