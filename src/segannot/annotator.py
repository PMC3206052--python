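"""Classify coordinates and intervals against transcripts; cluster by gene.

A query is classified once per overlapping transcript.  Records for one
query are then clustered by gene symbol; the best record per gene and the
best record overall are chosen by a fixed priority (exon hits outrank
intron hits, which outrank upstream/downstream), with ties broken by
smaller distance, then gene name, then transcript id, so output is fully
deterministic.  Upstream/downstream is defined by the transcript's strand;
the query's own strand is ignored.

The per-category tally counts one category per query (the overall-best
record), so tallies always sum to the number of input queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from .gene_model import GenericFeature, Transcript
from .interval_index import IntervalIndex

log = logging.getLogger(__name__)

__all__ = [
    "LocusCategory",
    "AnnotationRecord",
    "CoordinateQuery",
    "IntervalQuery",
    "Tally",
    "AnnotationResult",
    "classify_coordinate",
    "classify_interval",
    "annotate",
    "DEFAULT_RANGE_BP",
    "INTERVAL_CAP",
]

DEFAULT_RANGE_BP = 10_000  # up/downstream window on either side of a gene
INTERVAL_CAP = 2_000       # intervals longer than this are processed with a warning


class LocusCategory(str, Enum):
    EXON = "EXON"
    INTRON = "INTRON"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"
    # interval refinements
    CONTAINED_IN_EXON = "CONTAINED_IN_EXON"
    SPANS_EXON_INTRON = "SPANS_EXON_INTRON"
    CONTAINED_IN_INTRON = "CONTAINED_IN_INTRON"
    SPANS_MULTIPLE = "SPANS_MULTIPLE"
    OVERLAPS_GENE_BOUNDARY = "OVERLAPS_GENE_BOUNDARY"


# lower value = higher priority when picking the most relevant transcript
LOCUS_PRIORITY: dict[LocusCategory, int] = {
    LocusCategory.EXON: 0,
    LocusCategory.CONTAINED_IN_EXON: 0,
    LocusCategory.SPANS_EXON_INTRON: 1,
    LocusCategory.SPANS_MULTIPLE: 1,
    LocusCategory.OVERLAPS_GENE_BOUNDARY: 2,
    LocusCategory.INTRON: 3,
    LocusCategory.CONTAINED_IN_INTRON: 3,
    LocusCategory.UPSTREAM: 4,
    LocusCategory.DOWNSTREAM: 5,
    LocusCategory.INTERGENIC: 99,
}


@dataclass
class CoordinateQuery:
    id: str
    chrom: str
    pos: int  # 0-based internal


@dataclass
class IntervalQuery:
    id: str
    chrom: str
    start: int  # 0-based half-open internal
    end: int


Query = Union[CoordinateQuery, IntervalQuery]


@dataclass
class AnnotationRecord:
    """One (query, transcript) classification."""

    query_id: str
    transcript_id: str
    gene: str
    category: LocusCategory
    exon_index: Optional[int] = None    # 1-based, strand-aware
    intron_index: Optional[int] = None  # 1-based, strand-aware
    distance: int = 0                   # bp to tx boundary for UP/DOWNSTREAM

    @property
    def rank(self) -> int:
        return LOCUS_PRIORITY[self.category]

    def sort_key(self) -> tuple:
        return (self.rank, self.distance, self.gene, self.transcript_id)


class Tally:
    """Per-category query counts (one count per query, from its best record)."""

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}

    def add(self, category) -> None:
        key = category.value if isinstance(category, Enum) else str(category)
        self.counts[key] = self.counts.get(key, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_lines(self) -> list[str]:
        lines = ["category\tcount"]
        lines.extend(f"{cat}\t{n}" for cat, n in sorted(self.counts.items()))
        return lines


@dataclass
class AnnotationResult:
    all_records: list[AnnotationRecord]
    per_gene_best: list[AnnotationRecord]
    overall_best: list[AnnotationRecord]
    tally: Tally


# ---------------------------------------------------------------------------
# classification


def _gene_view(t) -> tuple[str, int, int, tuple[tuple[int, int], ...], str, str]:
    """(strand, start, end, exons, gene, id) for transcripts or BED/PSL features.

    Features without blocks are treated as single-exon; a '.' strand is
    treated as '+' for upstream/downstream purposes.
    """
    if isinstance(t, Transcript):
        return t.strand, t.tx_start, t.tx_end, t.exons, t.gene, t.id
    strand = t.strand if t.strand in ("+", "-") else "+"
    exons = t.blocks if t.blocks else ((t.start, t.end),)
    return strand, t.start, t.end, exons, t.id, t.id


def _ordinals(strand: str, n: int, genomic_index: int, of_introns: bool) -> int:
    total = n - 1 if of_introns else n
    return genomic_index + 1 if strand == "+" else total - genomic_index


def classify_coordinate(pos: int, t, range_bp: int = DEFAULT_RANGE_BP,
                        query_id: str = "") -> Optional[AnnotationRecord]:
    """Classify a single coordinate against one transcript/feature.

    Returns EXON/INTRON records with 1-based strand-aware ordinals, an
    UPSTREAM/DOWNSTREAM record when the position lies within ``range_bp``
    of the transcript on the appropriate side, or None.
    """
    strand, start, end, exons, gene, tid = _gene_view(t)
    if start <= pos < end:
        for i, (s, e) in enumerate(exons):
            if s <= pos < e:
                return AnnotationRecord(
                    query_id, tid, gene, LocusCategory.EXON,
                    exon_index=_ordinals(strand, len(exons), i, False),
                )
        for i in range(len(exons) - 1):
            if exons[i][1] <= pos < exons[i + 1][0]:
                return AnnotationRecord(
                    query_id, tid, gene, LocusCategory.INTRON,
                    intron_index=_ordinals(strand, len(exons), i, True),
                )
        return None  # unreachable for well-formed transcripts
    if pos < start:
        dist = start - pos
        if dist <= range_bp:
            cat = LocusCategory.UPSTREAM if strand == "+" else LocusCategory.DOWNSTREAM
            return AnnotationRecord(query_id, tid, gene, cat, distance=dist)
        return None
    dist = pos - end + 1
    if dist <= range_bp:
        cat = LocusCategory.DOWNSTREAM if strand == "+" else LocusCategory.UPSTREAM
        return AnnotationRecord(query_id, tid, gene, cat, distance=dist)
    return None


def classify_interval(start: int, end: int, t, range_bp: int = DEFAULT_RANGE_BP,
                      query_id: str = "") -> Optional[AnnotationRecord]:
    """Classify an interval [start, end) against one transcript/feature."""
    if start >= end:
        raise ValueError("interval needs start < end")
    strand, tx_start, tx_end, exons, gene, tid = _gene_view(t)
    if start < tx_end and tx_start < end:
        if start < tx_start or end > tx_end:
            return AnnotationRecord(query_id, tid, gene, LocusCategory.OVERLAPS_GENE_BOUNDARY)
        touched_exons = [i for i, (s, e) in enumerate(exons) if s < end and start < e]
        n_introns = len(exons) - 1
        touched_introns = [
            i for i in range(n_introns)
            if exons[i][1] < end and start < exons[i + 1][0]
        ]
        if touched_exons and touched_introns:
            first = min(touched_exons)
            return AnnotationRecord(
                query_id, tid, gene, LocusCategory.SPANS_EXON_INTRON,
                exon_index=_ordinals(strand, len(exons), first, False),
            )
        if touched_exons:
            return AnnotationRecord(
                query_id, tid, gene, LocusCategory.CONTAINED_IN_EXON,
                exon_index=_ordinals(strand, len(exons), touched_exons[0], False),
            )
        return AnnotationRecord(
            query_id, tid, gene, LocusCategory.CONTAINED_IN_INTRON,
            intron_index=_ordinals(strand, len(exons), touched_introns[0], True),
        )
    if end <= tx_start:
        dist = tx_start - end + 1  # from the interval's nearest covered base
        if dist <= range_bp:
            cat = LocusCategory.UPSTREAM if strand == "+" else LocusCategory.DOWNSTREAM
            return AnnotationRecord(query_id, tid, gene, cat, distance=dist)
        return None
    dist = start - tx_end + 1
    if dist <= range_bp:
        cat = LocusCategory.DOWNSTREAM if strand == "+" else LocusCategory.UPSTREAM
        return AnnotationRecord(query_id, tid, gene, cat, distance=dist)
    return None


# ---------------------------------------------------------------------------
# the annotation driver


def _best(records: Sequence[AnnotationRecord]) -> AnnotationRecord:
    return min(records, key=AnnotationRecord.sort_key)


def annotate(
    queries: Iterable[Query],
    index: IntervalIndex,
    range_bp: int = DEFAULT_RANGE_BP,
    mode: str = "coordinates",
) -> AnnotationResult:
    """Annotate coordinate or interval queries against an indexed gene set.

    For each query the index is range-queried with the query span widened by
    ``range_bp`` on both sides; every hit is classified; records are
    clustered by gene; the per-gene best and the overall best are selected by
    priority.  Queries with no record at all count as INTERGENIC in the tally
    and are absent from the record lists.
    """
    if mode not in ("coordinates", "intervals"):
        raise ValueError(f"unknown annotate mode {mode!r}")
    all_records: list[AnnotationRecord] = []
    per_gene_best: list[AnnotationRecord] = []
    overall_best: list[AnnotationRecord] = []
    tally = Tally()
    for q in queries:
        if isinstance(q, CoordinateQuery):
            span = (q.pos, q.pos + 1)
        else:
            span = (q.start, q.end)
            if q.end - q.start > INTERVAL_CAP:
                log.warning(
                    "interval %s is %d bp (> %d); processed anyway",
                    q.id, q.end - q.start, INTERVAL_CAP,
                )
        qs, qe = max(0, span[0] - range_bp), span[1] + range_bp
        records: list[AnnotationRecord] = []
        for hit in index.range_query(q.chrom, qs, qe):
            if isinstance(q, CoordinateQuery):
                rec = classify_coordinate(q.pos, hit, range_bp, query_id=q.id)
            else:
                rec = classify_interval(q.start, q.end, hit, range_bp, query_id=q.id)
            if rec is not None:
                records.append(rec)
        if not records:
            tally.add(LocusCategory.INTERGENIC)
            continue
        records.sort(key=AnnotationRecord.sort_key)
        all_records.extend(records)
        by_gene: dict[str, list[AnnotationRecord]] = {}
        for rec in records:
            by_gene.setdefault(rec.gene, []).append(rec)
        gene_best = sorted(
            (_best(recs) for recs in by_gene.values()),
            key=AnnotationRecord.sort_key,
        )
        per_gene_best.extend(gene_best)
        best = gene_best[0]
        overall_best.append(best)
        tally.add(best.category)
    return AnnotationResult(all_records, per_gene_best, overall_best, tally)
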