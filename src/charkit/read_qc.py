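"""Raw-read cleaning and clean-read summary statistics.

HiSeq-era paired-end reads are cleaned with three rules: adapter
trimming, discarding reads whose fraction of ambiguous N bases exceeds
5%, and discarding reads with more than 10% of bases below Phred 20.
Both composition thresholds are strict ("larger than" / "more than"),
so a 90-nt read with exactly 9 bases under Q20 (10%) survives while
one with 10 such bases (11.1%) is dropped.  In paired-end mode a pair
is dropped whenever either mate fails, keeping the two files in sync.

Quality encoding defaults to Phred+33 (Sanger / Illumina 1.8+); the
FASTQ I/O helpers accept ``encoding="phred64"`` for legacy data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq_core import CharkitError, ParseError, _open_text


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.id}: {len(self.quals)} qualities for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QcReport:
    n_raw: int
    n_clean: int
    clean_nt: int
    q20_pct: float
    gc_pct: float
    n_pct: float


_FORMATS = {"phred33": "fastq", "phred64": "fastq-illumina"}


def read_fastq(path, encoding: str = "phred33") -> list[ReadRecord]:
    """Parse a FASTQ file (gzip transparently handled)."""
    if encoding not in _FORMATS:
        raise ValueError(f"unknown quality encoding {encoding!r}")
    reads: list[ReadRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, _FORMATS[encoding]):
                reads.append(
                    ReadRecord(
                        id=rec.id,
                        bases=str(rec.seq).upper(),
                        quals=tuple(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path, encoding: str = "phred33") -> None:
    bio = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        bio.append(rec)
    with _open_text(path, "wt") as fh:
        SeqIO.write(bio, fh, _FORMATS[encoding])


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 5) -> ReadRecord:
    """Remove a 3' adapter by exact prefix/suffix match.

    The leftmost position where a prefix of the adapter matches the
    read out to the read's end (or where the full adapter occurs) is
    trimmed together with everything 3' of it, provided the match is at
    least ``min_overlap`` long.  No match leaves the read unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    adapter = adapter.upper()
    la = len(adapter)
    n = len(read.bases)
    for i in range(n):
        k = min(la, n - i)
        if k < min_overlap:
            break
        if read.bases[i : i + k] == adapter[:k]:
            return ReadRecord(id=read.id, bases=read.bases[:i], quals=read.quals[:i])
    return read


def n_fraction(read: ReadRecord) -> float:
    """Fraction of ambiguous N bases."""
    if len(read) == 0:
        raise CharkitError(f"{read.id}: empty read")
    return read.bases.count("N") / len(read)


def low_qual_fraction(read: ReadRecord, q_threshold: int = 20) -> float:
    """Fraction of bases with quality strictly below ``q_threshold``."""
    if len(read) == 0:
        raise CharkitError(f"{read.id}: empty read")
    return sum(1 for q in read.quals if q < q_threshold) / len(read)


def _fails(read: ReadRecord, n_max: float, lowq_max: float) -> bool:
    return n_fraction(read) > n_max or low_qual_fraction(read) > lowq_max


def clean_reads(
    reads: Sequence[ReadRecord],
    n_max: float = 0.05,
    lowq_max: float = 0.10,
    adapter: Optional[str] = None,
) -> tuple[list[ReadRecord], QcReport]:
    """Single-end cleaning: optional adapter trim, then discard reads
    with N fraction > ``n_max`` or low-quality fraction > ``lowq_max``
    (both strict).  Returns survivors and a report computed on them."""
    for name, v in (("n_max", n_max), ("lowq_max", lowq_max)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    n_raw = len(reads)
    if adapter is not None:
        reads = [trim_adapter(r, adapter) for r in reads]
    kept = [r for r in reads if len(r) > 0 and not _fails(r, n_max, lowq_max)]
    return kept, _report(kept, n_raw)


def clean_read_pairs(
    reads1: Sequence[ReadRecord],
    reads2: Sequence[ReadRecord],
    n_max: float = 0.05,
    lowq_max: float = 0.10,
    adapter: Optional[str] = None,
) -> tuple[list[ReadRecord], list[ReadRecord], QcReport]:
    """Paired-end cleaning: a pair is discarded if either mate fails."""
    if len(reads1) != len(reads2):
        raise CharkitError(
            f"mismatched pair files: {len(reads1)} vs {len(reads2)} reads"
        )
    if adapter is not None:
        reads1 = [trim_adapter(r, adapter) for r in reads1]
        reads2 = [trim_adapter(r, adapter) for r in reads2]
    kept1: list[ReadRecord] = []
    kept2: list[ReadRecord] = []
    for r1, r2 in zip(reads1, reads2):
        if len(r1) == 0 or len(r2) == 0:
            continue
        if _fails(r1, n_max, lowq_max) or _fails(r2, n_max, lowq_max):
            continue
        kept1.append(r1)
        kept2.append(r2)
    report = _report(kept1 + kept2, len(reads1) + len(reads2))
    return kept1, kept2, report


def _report(reads: Sequence[ReadRecord], n_raw: int) -> QcReport:
    total = sum(len(r) for r in reads)
    if total == 0:
        return QcReport(n_raw, len(reads), 0, 0.0, 0.0, 0.0)
    q20 = sum(sum(1 for q in r.quals if q >= 20) for r in reads)
    gc = sum(r.bases.count("G") + r.bases.count("C") for r in reads)
    nn = sum(r.bases.count("N") for r in reads)
    return QcReport(
        n_raw=n_raw,
        n_clean=len(reads),
        clean_nt=total,
        q20_pct=100.0 * q20 / total,
        gc_pct=100.0 * gc / total,
        n_pct=100.0 * nn / total,
    )


def qc_summary(reads: Sequence[ReadRecord]) -> QcReport:
    """Summary statistics (Q20%, GC%, N%) over a read set."""
    if not reads:
        raise CharkitError("qc_summary requires a non-empty read set")
    return _report(reads, len(reads))
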