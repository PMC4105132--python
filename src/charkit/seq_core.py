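"""Sequence I/O, unigene bookkeeping, and assembly-level statistics.

A *unigene* is a non-redundant assembled transcript (a cluster
representative or a singleton) from a de novo transcriptome assembly.
This module holds the basic sequence container, FASTA round-tripping,
the minimum-length filter applied to assembled sequences, the
CL/Unigene cluster labeling scheme, and whole-assembly statistics
(N50, mean length, GC content).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class CharkitError(Exception):
    """Base error for the package."""


class ParseError(CharkitError):
    """A malformed input file; the message names the offending line."""


_VALID_NT = frozenset("ACGTN")


def _normalize_nt(seq: str) -> str:
    """Uppercase and map RNA U to T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide (or amino-acid) sequence.

    Nucleotide sequences are normalized to uppercase {A,C,G,T,N}.
    Peptide records (used by the orthology module) skip the alphabet
    check via ``alphabet="protein"``.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: sequence must be nonempty")
        if self.alphabet == "nucleotide":
            bad = set(self.seq) - _VALID_NT
            if bad:
                raise ValueError(
                    f"{self.id}: invalid nucleotide characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        """G+C over non-N bases (0.0 if the sequence is all N)."""
        non_n = len(self.seq) - self.seq.count("N")
        if non_n == 0:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / non_n


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Parse a FASTA file into an ordered list of records.

    Sequences are uppercased and U is mapped to T.  An empty file or a
    first line that is not a header raises :class:`ParseError` naming
    the line.  Duplicate ids are rejected.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: line 1: empty file")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header '>'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: record with empty id")
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if alphabet == "nucleotide":
                seq = _normalize_nt(seq)
            else:
                seq = seq.upper()
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(
                SequenceRecord(id=rec.id, seq=seq, description=desc, alphabet=alphabet)
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(bio, fh, "fasta")


def filter_min_length(
    records: Sequence[SequenceRecord], min_nt: int = 200
) -> list[SequenceRecord]:
    """Keep records of length >= ``min_nt`` (assembled sequences shorter
    than the threshold are deleted; the boundary itself is kept)."""
    if min_nt < 1:
        raise ValueError("min_nt must be >= 1")
    return [r for r in records if len(r) >= min_nt]


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_nt: int
    mean_length: float
    n50: int
    gc_fraction: float


def n50(lengths: Sequence[int]) -> int:
    """N50: the length L at which the cumulative sum of lengths in
    descending order first reaches >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    total = sum(lengths)
    half = total / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    """Whole-assembly summary: count, total nt, mean, N50 and pooled GC.

    GC is G+C over all non-N bases pooled across sequences.
    """
    if not records:
        raise CharkitError("assembly_stats requires a non-empty collection")
    lengths = [len(r) for r in records]
    total = sum(lengths)
    gc = sum(r.seq.count("G") + r.seq.count("C") for r in records)
    non_n = total - sum(r.seq.count("N") for r in records)
    return AssemblyStats(
        n_sequences=len(records),
        total_nt=total,
        mean_length=total / len(records),
        n50=n50(lengths),
        gc_fraction=(gc / non_n) if non_n else 0.0,
    )


@dataclass(frozen=True)
class ClusterLabel:
    kind: str  # "cluster" | "singleton"
    label: str  # "CL<i>" | "Unigene<j>"

    def __post_init__(self) -> None:
        if self.kind == "cluster" and not self.label.startswith("CL"):
            raise ValueError("cluster labels must use the CL prefix")
        if self.kind == "singleton" and not self.label.startswith("Unigene"):
            raise ValueError("singleton labels must use the Unigene prefix")


def cluster_label(
    records: Sequence[SequenceRecord],
    similarity_pairs: Iterable[tuple[str, str, float]],
    threshold: float = 0.70,
) -> dict[str, ClusterLabel]:
    """Group unigenes whose pairwise similarity exceeds ``threshold``
    (strictly) into clusters labeled CL1..CLk; everything else is a
    singleton labeled Unigene1..Unigenem.

    Components are connected components (union-find) over qualifying
    pairs; cluster numbering follows the first appearance of any member
    in the record order.
    """
    ids = [r.id for r in records]
    known = set(ids)
    parent: dict[str, str] = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, ident in similarity_pairs:
        if a not in known or b not in known:
            raise CharkitError(f"similarity pair references unknown id: ({a}, {b})")
        if not (0.0 <= ident <= 1.0):
            raise ValueError(f"identity {ident} outside [0, 1]")
        if ident > threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    members: dict[str, list[str]] = {}
    for i in ids:
        members.setdefault(find(i), []).append(i)

    labels: dict[str, ClusterLabel] = {}
    n_cl = 0
    n_single = 0
    for i in ids:
        if i in labels:
            continue
        comp = members[find(i)]
        if len(comp) >= 2:
            n_cl += 1
            lab = f"CL{n_cl}"
            for m in comp:
                labels[m] = ClusterLabel(kind="cluster", label=lab)
        else:
            n_single += 1
            labels[i] = ClusterLabel(kind="singleton", label=f"Unigene{n_single}")
    return labels
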