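"""Annotation merging, orientation calling and CDS extraction.

Unigenes are annotated from tabular protein-database similarity
searches (12-column BLAST tabular).  Hits with E-value <= 1e-5
(inclusive) qualify; per query the best hit maximizes bit score, with
ties broken by lower E-value then input order.  When several protein
databases annotate the same unigene, a fixed priority order
(Nr, SwissProt, KEGG, COG by default) decides which hit sets the
sequence orientation and coding region.  The coding region is the
aligned query interval on the oriented strand, trimmed to full codons
in the hit's reading frame — no extension to external start/stop
codons.  Unigenes without any qualifying protein hit fall back to a
deterministic longest-ORF call across all six frames
(``source_db="fallback"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .codon_usage import STOP_CODONS
from .seq_core import CharkitError, ParseError, SequenceRecord, _open_text

DEFAULT_PRIORITY: tuple[str, ...] = ("Nr", "SwissProt", "KEGG", "COG")
E_VALUE_MAX = 1e-5


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular similarity search.

    Query coordinates are 1-based inclusive; ``q_start > q_end``
    signals a minus-orientation (translated) hit.  ``frame`` is the
    reading frame in {-3..-1, 1..3}, derived from the aligned interval
    when absent.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    evalue: float
    bit_score: float
    q_start: int
    q_end: int
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative E-value")
        if self.q_start < 1 or self.q_end < 1:
            raise ValueError(f"{self.query_id}: query coordinates are 1-based")
        if self.frame is not None and self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"{self.query_id}: frame {self.frame} invalid")

    @property
    def orientation(self) -> str:
        return "-" if self.q_start > self.q_end else "+"


@dataclass(frozen=True)
class AnnotationRecord:
    """Orientation and coding region decided for one unigene.

    ``cds_start``/``cds_end`` are 1-based inclusive coordinates on the
    oriented strand; ``cds_seq`` has length divisible by 3.
    """

    query_id: str
    source_db: str
    orientation: str
    cds_start: int
    cds_end: int
    cds_seq: str

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        n = self.cds_end - self.cds_start + 1
        if n < 3 or n % 3 != 0:
            raise ValueError(
                f"{self.query_id}: CDS length {n} not a positive multiple of 3"
            )
        if len(self.cds_seq) != n:
            raise ValueError(f"{self.query_id}: cds_seq length mismatch")


def parse_blast_tab(path) -> list[HitRecord]:
    """Parse 12-column tab-separated similarity results
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore); '#' comment lines are skipped."""
    hits: list[HitRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        align_length=int(fields[3]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def best_hit(
    hits: Iterable[HitRecord], e_max: float = E_VALUE_MAX
) -> dict[str, HitRecord]:
    """Best qualifying hit per query: E-value <= ``e_max`` (inclusive),
    then maximal bit score; ties by lower E-value, then input order."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > e_max:
            continue
        cur = best.get(h.query_id)
        if cur is None or h.bit_score > cur.bit_score or (
            h.bit_score == cur.bit_score and h.evalue < cur.evalue
        ):
            best[h.query_id] = h
    return best


def merge_priority(
    per_db: Mapping[str, Mapping[str, HitRecord]],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[str, tuple[str, HitRecord]]:
    """Annotate each query with the first database in ``priority``
    holding a best hit for it."""
    for db in priority:
        if db not in per_db:
            raise CharkitError(f"unknown database {db!r} in priority order")
    merged: dict[str, tuple[str, HitRecord]] = {}
    for db in priority:
        for qid, hit in per_db[db].items():
            if qid not in merged:
                merged[qid] = (db, hit)
    return merged


def _oriented(seq: str, orientation: str) -> str:
    return seq if orientation == "+" else str(Seq(seq).reverse_complement())


def extract_cds(
    unigene: SequenceRecord, hit: HitRecord, source_db: str = "Nr"
) -> AnnotationRecord:
    """Extract the coding region implied by a translated best hit.

    The aligned query interval is mapped onto the oriented strand
    (reverse complement for minus hits) and trimmed at both ends to
    full codons in the hit's reading frame.  With no explicit frame the
    alignment start is taken to sit on a codon boundary.
    """
    if hit.query_id != unigene.id:
        raise CharkitError(
            f"hit query {hit.query_id!r} does not belong to unigene {unigene.id!r}"
        )
    L = len(unigene)
    if not (1 <= hit.q_start <= L and 1 <= hit.q_end <= L):
        raise CharkitError(f"{unigene.id}: hit coordinates outside sequence")
    orientation = hit.orientation
    if orientation == "+":
        s, e = hit.q_start, hit.q_end
    else:
        s, e = L - hit.q_start + 1, L - hit.q_end + 1
    oriented = _oriented(unigene.seq, orientation)

    frame = abs(hit.frame) if hit.frame is not None else ((s - 1) % 3) + 1
    # first codon-aligned position >= s in the given frame
    s2 = s + ((frame - s) % 3)
    n_codons = (e - s2 + 1) // 3
    if n_codons < 1:
        raise CharkitError(
            f"{unigene.id}: aligned interval too short for one codon"
        )
    e2 = s2 + 3 * n_codons - 1
    return AnnotationRecord(
        query_id=unigene.id,
        source_db=source_db,
        orientation=orientation,
        cds_start=s2,
        cds_end=e2,
        cds_seq=oriented[s2 - 1 : e2],
    )


def longest_orf(
    unigene: SequenceRecord, min_nt: int = 150
) -> Optional[AnnotationRecord]:
    """Deterministic longest-ORF fallback across all six frames.

    An ORF is a maximal stop-free run of codons in one frame, bounded
    by stop codons or the sequence ends.  The longest one is reported
    if strictly longer than ``min_nt``; ties prefer the plus strand,
    then the lower frame, then the leftmost start.  Orientation is set
    by the winning frame and ``source_db`` is "fallback".
    """
    best: Optional[tuple[int, int, int, int, str]] = None  # (-len, strand, frame, start, ori)
    for strand_rank, orientation in ((0, "+"), (1, "-")):
        oriented = _oriented(unigene.seq, orientation)
        L = len(oriented)
        for f in range(3):
            n = (L - f) // 3
            seg_start = 0  # in codon units within this frame
            for ci in range(n + 1):
                at_end = ci == n
                if at_end or oriented[f + 3 * ci : f + 3 * ci + 3] in STOP_CODONS:
                    seg_codons = ci - seg_start
                    if seg_codons >= 1:
                        key = (-3 * seg_codons, strand_rank, f, f + 3 * seg_start)
                        if best is None or key < best[:4]:
                            best = (*key, orientation)
                    seg_start = ci + 1
    if best is None:
        return None
    neg_len, _, f, start, orientation = best
    length = -neg_len
    if length <= min_nt:
        return None
    oriented = _oriented(unigene.seq, orientation)
    return AnnotationRecord(
        query_id=unigene.id,
        source_db="fallback",
        orientation=orientation,
        cds_start=start + 1,
        cds_end=start + length,
        cds_seq=oriented[start : start + length],
    )


def annotation_summary(
    per_db: Mapping[str, Iterable[str]]
) -> tuple[dict[str, int], int]:
    """Per-database annotated counts plus the size of their union."""
    sets = {db: set(ids) for db, ids in per_db.items()}
    counts = {db: len(s) for db, s in sets.items()}
    union: set[str] = set()
    for s in sets.values():
        union |= s
    return counts, len(union)


def annotate(
    unigenes: Sequence[SequenceRecord],
    per_db_hits: Mapping[str, Iterable[HitRecord]],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    e_max: float = E_VALUE_MAX,
    min_orf_nt: int = 150,
) -> dict[str, AnnotationRecord]:
    """Full annotation pass: per-database best hits, priority merge,
    CDS extraction, and the longest-ORF fallback for unannotated
    unigenes.  Protein databases only decide orientation/CDS."""
    per_db_best = {db: best_hit(hits, e_max) for db, hits in per_db_hits.items()}
    merged = merge_priority(per_db_best, priority)
    out: dict[str, AnnotationRecord] = {}
    for u in unigenes:
        if u.id in merged:
            db, hit = merged[u.id]
            try:
                out[u.id] = extract_cds(u, hit, source_db=db)
                continue
            except CharkitError:
                pass  # degenerate hit interval: fall through to the ORF call
        ann = longest_orf(u, min_nt=min_orf_nt)
        if ann is not None:
            out[u.id] = ann
    return out
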