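"""Perfect microsatellite (SSR) detection and summaries.

SSRIT-style scan for perfect di- to hexa-nucleotide tandem repeats
with class-specific minimum repeat numbers (default 6/5/4/4/4 for
motif lengths 2–6).  Mononucleotide runs are never reported (Illumina
homopolymer artifacts), motifs that are powers of a shorter motif
collapse to the shortest period (ATATAT x 3 is reported as AT x 6 at
most once), and overlapping candidates are suppressed greedily from
the left.  Transcriptome-level scans screen only sequences strictly
longer than 1 kb and report Table-style summaries including the
one-SSR-per-X-kb frequency and a motif-length x repeat-number matrix
binned at 4,5,...,10,>10 repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .seq_core import SequenceRecord

DEFAULT_THRESHOLDS: dict[int, int] = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}
REPEAT_BINS: tuple[str, ...] = ("4", "5", "6", "7", "8", "9", "10", ">10")
MOTIF_CLASS_NAMES: dict[int, str] = {2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta", 6: "Hexa"}

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SSRHit:
    """One detected perfect microsatellite (1-based inclusive coords)."""

    seq_id: str
    motif: str
    repeat_count: int
    start: int
    end: int
    canonical_motif: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeat_count:
            raise ValueError(
                f"{self.seq_id}:{self.start}: span does not equal "
                "motif length x repeat count"
            )


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest cyclic rotation (no reverse-complement
    folding)."""
    if not (2 <= len(motif) <= 6):
        raise ValueError("motif length must be 2-6")
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(
    seq: SequenceRecord | str,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    seq_id: Optional[str] = None,
) -> list[SSRHit]:
    """Scan one sequence for perfect SSRs.

    Maximal tandem runs are reported left to right; at a given start
    the shortest qualifying (primitive) motif wins, and the scan jumps
    past each reported run so hits never overlap.
    """
    if isinstance(seq, SequenceRecord):
        s, sid = seq.seq, seq.id
    else:
        s, sid = seq.upper(), (seq_id or "seq")
    lengths = sorted(thresholds)
    if lengths != [2, 3, 4, 5, 6]:
        raise ValueError("thresholds must cover motif lengths 2-6")
    n = len(s)
    hits: list[SSRHit] = []
    i = 0
    while i < n - 3:  # shortest reportable run is 2*2... loop guard only
        emitted = False
        for m in (2, 3, 4, 5, 6):
            motif = s[i : i + m]
            if len(motif) < m or not set(motif) <= _ACGT:
                continue
            if not _is_primitive(motif):
                continue
            r = 1
            while s[i + r * m : i + (r + 1) * m] == motif:
                r += 1
            if r >= thresholds[m]:
                hits.append(
                    SSRHit(
                        seq_id=sid,
                        motif=motif,
                        repeat_count=r,
                        start=i + 1,
                        end=i + m * r,
                        canonical_motif=canonical_motif(motif),
                    )
                )
                i += m * r
                emitted = True
                break
        if not emitted:
            i += 1
    return hits


@dataclass(frozen=True)
class SsrSummary:
    n_sequences_screened: int
    n_sequences_with_ssr: int
    n_ssrs: int
    n_kinds: int  # distinct raw motif strings
    n_kinds_canonical: int  # distinct canonical rotations
    n_kinds_motif_repeat: int  # distinct (motif, repeat-count) pairs
    n_sequences_multi: int
    frequency_kb: Optional[float]  # one SSR per this many kb
    class_by_repeat_matrix: pd.DataFrame


def _repeat_bin(r: int) -> str:
    return str(r) if r <= 10 else ">10"


def ssr_scan(
    records: Sequence[SequenceRecord],
    min_seq_nt: int = 1000,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    freq_denominator: str = "all",
) -> tuple[list[SSRHit], SsrSummary]:
    """Scan a transcriptome for SSRs and summarize.

    Only sequences strictly longer than ``min_seq_nt`` are screened.
    ``frequency_kb`` divides a nucleotide denominator by the SSR count:
    by default the full input's total nt (``freq_denominator="all"``),
    optionally only the screened sequences' nt (``"screened"``).
    """
    if freq_denominator not in ("all", "screened"):
        raise ValueError("freq_denominator must be 'all' or 'screened'")
    screened = [r for r in records if len(r) > min_seq_nt]
    all_hits: list[SSRHit] = []
    n_with = 0
    n_multi = 0
    for rec in screened:
        hits = find_ssrs(rec, thresholds)
        if hits:
            n_with += 1
            if len(hits) >= 2:
                n_multi += 1
        all_hits.extend(hits)

    matrix = pd.DataFrame(
        0,
        index=[MOTIF_CLASS_NAMES[m] for m in (2, 3, 4, 5, 6)],
        columns=list(REPEAT_BINS),
    )
    for h in all_hits:
        matrix.loc[MOTIF_CLASS_NAMES[len(h.motif)], _repeat_bin(h.repeat_count)] += 1

    denom_nt = sum(
        len(r) for r in (records if freq_denominator == "all" else screened)
    )
    freq = (denom_nt / 1000.0) / len(all_hits) if all_hits else None
    summary = SsrSummary(
        n_sequences_screened=len(screened),
        n_sequences_with_ssr=n_with,
        n_ssrs=len(all_hits),
        n_kinds=len({h.motif for h in all_hits}),
        n_kinds_canonical=len({h.canonical_motif for h in all_hits}),
        n_kinds_motif_repeat=len({(h.motif, h.repeat_count) for h in all_hits}),
        n_sequences_multi=n_multi,
        frequency_kb=freq,
        class_by_repeat_matrix=matrix,
    )
    return all_hits, summary
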