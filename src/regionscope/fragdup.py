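"""Fragmentation-vs-duplication classification of protein matches.

Each reference protein's matches from one test assembly are clustered by
query-side overlap (single linkage, >= 1 shared position by default). With
N matches falling into C clusters:

* ``duplication_events = N - C`` — overlapping matches count as N-1
  duplications plus 1 correct match, a deliberately conservative tally;
* ``fragmentation_case = 1`` if C > 1 — the protein is recovered in
  non-overlapping pieces;
* ``one_to_one = 1`` if N == 1.

Reference proteins with a non-self match inside the reference itself
(paralogs) are screened out first, so within-genome gene families are not
misread as assembly duplications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

from .io_formats import AlignmentHit

__all__ = [
    "FragDupCounts",
    "filter_reference_queries",
    "dedupe_hits",
    "identify_paralogs",
    "classify_matches",
    "tally_assembly",
    "default_assembly_labeler",
]


@dataclass
class FragDupCounts:
    assembly_label: str
    one_to_one: int = 0
    fragmentation_cases: int = 0
    duplication_events: int = 0
    excluded_paralogs: int = 0
    n_proteins_matched: int = 0

    def __post_init__(self) -> None:
        for field_name in ("one_to_one", "fragmentation_cases",
                           "duplication_events", "excluded_paralogs"):
            if getattr(self, field_name) < 0:
                raise ValueError(f"negative {field_name}")


def filter_reference_queries(hits: Iterable[AlignmentHit],
                             reference_ids: set[str]) -> list[AlignmentHit]:
    """Keep only rows whose query is a reference protein, order preserved."""
    return [h for h in hits if h.query_id in reference_ids]


def dedupe_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse duplicate rows.

    Byte-identical rows collapse to one; among rows sharing
    (query, subject, qstart, qend, sstart, send) the highest bitscore
    survives. First-seen order is preserved.
    """
    best: dict[tuple, AlignmentHit] = {}
    order: list[tuple] = []
    for hit in hits:
        key = (hit.query_id, hit.subject_id, hit.qstart, hit.qend,
               hit.sstart, hit.send)
        cur = best.get(key)
        if cur is None:
            best[key] = hit
            order.append(key)
        elif hit.bitscore > cur.bitscore:
            best[key] = hit
    return [best[k] for k in order]


def identify_paralogs(reference_self_hits: Iterable[AlignmentHit]
                      ) -> set[str]:
    """Reference ids appearing on either side of a non-self reference hit.

    Exclusion is symmetric: both endpoints of a paralogous pair are
    discounted, otherwise the partner's assembly matches would still be
    conflatable with duplications.
    """
    paralogs: set[str] = set()
    for hit in reference_self_hits:
        if hit.query_id != hit.subject_id:
            paralogs.add(hit.query_id)
            paralogs.add(hit.subject_id)
    return paralogs


def _cluster_by_overlap(spans: list[tuple[int, int]],
                        min_overlap_frac: float = 0.0) -> list[int]:
    """Single-linkage cluster index per span; spans are 1-based inclusive."""
    order = sorted(range(len(spans)), key=lambda i: spans[i])
    labels = [0] * len(spans)
    cluster = -1
    cur_end = -1
    cur_start = -1
    for i in order:
        start, end = spans[i]
        shared = min(cur_end, end) - max(cur_start, start) + 1
        needed = 1
        if min_overlap_frac > 0 and cluster >= 0:
            shortest = min(end - start + 1, cur_end - cur_start + 1)
            needed = max(1, int(min_overlap_frac * shortest))
        if cluster >= 0 and shared >= needed:
            labels[i] = cluster
            cur_end = max(cur_end, end)
        else:
            cluster += 1
            labels[i] = cluster
            cur_start, cur_end = start, end
    return labels


def classify_matches(matches: list[AlignmentHit],
                     min_overlap_frac: float = 0.0
                     ) -> tuple[int, int, int]:
    """Classify all matches to ONE reference protein from ONE assembly.

    Returns ``(one_to_one, fragmentation_case, duplication_events)``.
    Overlap is evaluated on the query (reference protein) side.
    """
    if not matches:
        raise ValueError("classify_matches requires at least one match")
    spans = [(h.qstart, h.qend) for h in matches]
    labels = _cluster_by_overlap(spans, min_overlap_frac)
    n = len(matches)
    clusters = len(set(labels))
    return (1 if n == 1 else 0,
            1 if clusters > 1 else 0,
            n - clusters)


def default_assembly_labeler(subject_id: str) -> str:
    """Assembly label = id prefix before the first '|' (the OrthoMCL-style
    'assembly|protein' naming), else the whole id."""
    return subject_id.split("|", 1)[0]


def tally_assembly(hits: list[AlignmentHit], reference_ids: set[str],
                   paralogs: set[str],
                   assembly_labeler: Callable[[str], str]
                   = default_assembly_labeler,
                   min_overlap_frac: float = 0.0
                   ) -> dict[str, FragDupCounts]:
    """Tally 1:1 / fragmentation / duplication per test assembly.

    ``hits`` must already be deduped and reference-query filtered. Hits
    whose query is a screened paralog, and reference self-matches, are
    dropped; the rest are grouped by (reference protein, test assembly)
    and classified.
    """
    excluded = {h.query_id for h in hits if h.query_id in paralogs}
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for hit in hits:
        if hit.query_id in paralogs:
            continue
        if hit.subject_id == hit.query_id:
            continue
        label = assembly_labeler(hit.subject_id)
        groups.setdefault((label, hit.query_id), []).append(hit)

    tallies: dict[str, FragDupCounts] = {}
    for (label, _protein), matches in groups.items():
        counts = tallies.setdefault(
            label, FragDupCounts(label, excluded_paralogs=len(excluded)))
        one, frag, dups = classify_matches(matches, min_overlap_frac)
        counts.one_to_one += one
        counts.fragmentation_cases += frag
        counts.duplication_events += dups
        counts.n_proteins_matched += 1
    return tallies
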