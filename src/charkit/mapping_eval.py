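"""Genome-mapping evaluation of assembled unigenes from PSL alignments.

Assembled unigenes realigned onto a reference genome (e.g. with blat)
yield one or more PSL records per query.  Evaluation keeps only the
longest alignment per unigene, then summarizes the mapped fraction,
the split between single-block (putative single-exon) and multi-block
alignments, and the distribution of query coverage, defined as the
ratio of matching bases to query length.  "More than 90% coverage" is
a strict inequality.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .seq_core import CharkitError, ParseError, SequenceRecord, _open_text

PSL_COLUMNS = 21


@dataclass(frozen=True)
class AlignmentRecord:
    """One PSL alignment row (coordinates 0-based half-open)."""

    query_id: str
    query_length: int
    matches: int
    block_count: int
    target_id: str
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.query_length):
            raise ValueError(
                f"{self.query_id}: matches {self.matches} outside "
                f"[0, {self.query_length}]"
            )
        if self.block_count < 1:
            raise ValueError(f"{self.query_id}: block_count must be >= 1")
        if self.target_span[0] >= self.target_span[1]:
            raise ValueError(f"{self.query_id}: empty target span")


@dataclass(frozen=True)
class MappingSummary:
    n_queries: int
    n_mapped: int
    mapped_fraction: float
    n_single_block: int
    n_multi_block: int
    n_cov_ge_090: int
    block_histogram: dict[int, int]
    coverage_histogram: tuple[int, ...]  # 10 bins: [0,.1) .. [.9,1.0]


def parse_psl(path) -> list[AlignmentRecord]:
    """Parse a 21-column PSL file; the 5-line psLayout header is
    auto-detected and skipped.  A row with the wrong column count
    raises :class:`ParseError` naming the line."""
    records: list[AlignmentRecord] = []
    with _open_text(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5  # psLayout header: title, blank, 2 column rows, dashes
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_COLUMNS:
            raise ParseError(
                f"{path}: line {lineno}: expected {PSL_COLUMNS} columns, "
                f"got {len(fields)}"
            )
        try:
            records.append(
                AlignmentRecord(
                    query_id=fields[9],
                    query_length=int(fields[10]),
                    matches=int(fields[0]),
                    block_count=int(fields[17]),
                    target_id=fields[13],
                    target_span=(int(fields[15]), int(fields[16])),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def dedup_longest(alignments: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep, per query, the alignment maximizing matching bases; ties
    go to the larger target span, then to input order.  Output follows
    first appearance of each query."""
    best: dict[str, AlignmentRecord] = {}
    order: list[str] = []
    for rec in alignments:
        cur = best.get(rec.query_id)
        if cur is None:
            best[rec.query_id] = rec
            order.append(rec.query_id)
            continue
        span = rec.target_span[1] - rec.target_span[0]
        cur_span = cur.target_span[1] - cur.target_span[0]
        if rec.matches > cur.matches or (
            rec.matches == cur.matches and span > cur_span
        ):
            best[rec.query_id] = rec
    return [best[q] for q in order]


def coverage(a: AlignmentRecord) -> float:
    """Match-to-length ratio for one alignment, in [0, 1]."""
    if a.query_length <= 0:
        raise CharkitError(f"{a.query_id}: zero query length")
    return a.matches / a.query_length


def mapping_summary(
    queries: Sequence[SequenceRecord], alignments: Sequence[AlignmentRecord]
) -> MappingSummary:
    """Summarize mapping of ``queries`` given their alignments.

    Alignments are deduplicated to the longest per query first.
    Coverage bins are 0.1-wide deciles with the top bin closed at 1.0;
    ``n_cov_ge_090`` counts coverage strictly greater than 0.90.
    """
    known = {q.id for q in queries}
    deduped = dedup_longest(alignments)
    for a in deduped:
        if a.query_id not in known:
            raise CharkitError(f"alignment references unknown query {a.query_id!r}")
    n_mapped = len(deduped)
    block_hist: Counter[int] = Counter()
    cov_hist = [0] * 10
    n_single = 0
    n_cov = 0
    for a in deduped:
        block_hist[a.block_count] += 1
        if a.block_count == 1:
            n_single += 1
        c = coverage(a)
        cov_hist[min(int(c * 10), 9)] += 1
        if c > 0.90:
            n_cov += 1
    return MappingSummary(
        n_queries=len(queries),
        n_mapped=n_mapped,
        mapped_fraction=(n_mapped / len(queries)) if queries else 0.0,
        n_single_block=n_single,
        n_multi_block=n_mapped - n_single,
        n_cov_ge_090=n_cov,
        block_histogram=dict(block_hist),
        coverage_histogram=tuple(cov_hist),
    )
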