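"""Reciprocal-best-hit orthology between two sequence sets.

One-directional analysis counts queries with at least one significant
hit (E-value <= 1e-5).  Bi-directional analysis pairs sequences that
are each other's best hit in both search directions — the classic
reciprocal-best-hit (RBH) proxy for 1:1 orthology between closely
related species.  Best-hit resolution (bit score, then E-value, then
input order) is shared with the annotation module so both directions
break ties consistently.  Peptide inputs are pre-filtered to >= 50
residues (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import E_VALUE_MAX, HitRecord, best_hit
from .seq_core import SequenceRecord


@dataclass(frozen=True)
class OrthologPair:
    """A putative 1:1 ortholog pair; each id appears in one pair only."""

    id_a: str
    id_b: str


def filter_peptides(
    peptides: Sequence[SequenceRecord], min_aa: int = 50
) -> list[SequenceRecord]:
    """Keep peptides equal to or longer than ``min_aa`` residues."""
    return [p for p in peptides if len(p) >= min_aa]


def one_directional(
    hits_ab: Iterable[HitRecord], e_max: float = E_VALUE_MAX
) -> set[str]:
    """Query ids with at least one hit at E-value <= ``e_max``."""
    return {h.query_id for h in hits_ab if h.evalue <= e_max}


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    e_max: float = E_VALUE_MAX,
) -> list[OrthologPair]:
    """Pairs (a, b) such that b is a's best hit in A→B and a is b's
    best hit in B→A.  Output is sorted by ``id_a``."""
    best_ab = best_hit(hits_ab, e_max)
    best_ba = best_hit(hits_ba, e_max)
    pairs = [
        OrthologPair(id_a=a, id_b=h.subject_id)
        for a, h in best_ab.items()
        if (back := best_ba.get(h.subject_id)) is not None and back.subject_id == a
    ]
    pairs.sort(key=lambda p: p.id_a)
    return pairs
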