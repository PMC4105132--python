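"""Codon-usage-bias statistics for predicted coding sequences.

Implements the classical gene-level codon bias toolkit:

* codon counting (frame 0, skipping N-containing and trailing partial
  codons; stop codons tallied separately and excluded from all bias
  statistics),
* RSCU — relative synonymous codon usage, a codon's count divided by
  its expected count under uniform usage within its synonymous family,
* GC and GC3 (GC fraction at third codon positions),
* Wright's effective number of codons Nc, ranging from 20 (one codon
  per amino acid) to 61 (uniform synonymous usage), plus the expected
  Nc-vs-GC3 curve under pure compositional (mutational) pressure,
* the Bennetzen–Hall codon bias index CBI against a set of "optimal"
  codons, derived here from the most-expressed genes,
* FPKM and the Pearson correlation used to relate CBI to expression.

The standard nuclear genetic code is the default; six-fold families
(Leu, Ser, Arg) are treated as single 6-fold classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats as _scipy_stats

from .seq_core import CharkitError, SequenceRecord

# ---------------------------------------------------------------------------
# Genetic code tables (standard code, id 1)
# ---------------------------------------------------------------------------

_STD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)  # 61 sense codons
STOP_CODONS: frozenset[str] = frozenset(_STD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in FAMILIES
}
#: amino acids with >= 2 synonymous codons
DEGENERATE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in FAMILIES.items() if len(codons) >= 2
}
#: number of amino-acid families per degeneracy class in the standard code
CLASS_SIZES: dict[int, int] = {2: 9, 3: 1, 4: 5, 6: 3}

NC_MIN, NC_MAX = 20.0, 61.0


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------

@dataclass
class CodonCountTable:
    """64-codon counts for one (or a pool of) coding sequence(s).

    ``counts`` holds sense codons only; stop codons are tracked in
    ``stop_counts`` and excluded from every bias statistic.  ``skipped``
    counts N-containing triplets and a trailing partial codon.
    """

    counts: dict[str, int] = field(default_factory=dict)
    stop_counts: dict[str, int] = field(default_factory=dict)
    skipped: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def family_count(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in FAMILIES[aa])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        out = CodonCountTable(
            counts=dict(self.counts),
            stop_counts=dict(self.stop_counts),
            skipped=self.skipped + other.skipped,
        )
        for c, n in other.counts.items():
            out.counts[c] = out.counts.get(c, 0) + n
        for c, n in other.stop_counts.items():
            out.stop_counts[c] = out.stop_counts.get(c, 0) + n
        return out


def count_codons(cds: str) -> CodonCountTable:
    """Count frame-0 triplets of ``cds``.

    Tolerates lengths not divisible by 3 (the trailing partial codon is
    skipped) and N-containing codons (skipped).
    """
    cds = cds.upper().replace("U", "T")
    table = CodonCountTable()
    n_full = len(cds) // 3
    for i in range(n_full):
        codon = cds[3 * i : 3 * i + 3]
        if codon in CODON_TO_AA:
            table.counts[codon] = table.counts.get(codon, 0) + 1
        elif codon in STOP_CODONS:
            table.stop_counts[codon] = table.stop_counts.get(codon, 0) + 1
        else:
            table.skipped += 1
    if len(cds) % 3:
        table.skipped += 1
    return table


# ---------------------------------------------------------------------------
# RSCU, GC3
# ---------------------------------------------------------------------------

def rscu(counts: CodonCountTable) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    RSCU_i = X_i / ((1/k) * sum_j X_j) within each k-fold family.
    Families with zero total are undefined and omitted from the result.
    """
    if counts.n_codons == 0:
        raise CharkitError("rscu requires a non-empty codon count table")
    out: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c] = counts.counts.get(c, 0) / (total / k)
    return out


def gc3(cds: str) -> float:
    """Fraction of complete codons with G or C at the third position;
    codons containing N are excluded from numerator and denominator."""
    cds = cds.upper().replace("U", "T")
    n_full = len(cds) // 3
    total = 0
    gc = 0
    for i in range(n_full):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        total += 1
        if codon[2] in "GC":
            gc += 1
    if total == 0:
        raise CharkitError("gc3 requires at least one complete codon")
    return gc / total


def gc_content(cds: str) -> float:
    """Overall G+C fraction over non-N bases."""
    cds = cds.upper().replace("U", "T")
    non_n = len(cds) - cds.count("N")
    if non_n == 0:
        raise CharkitError("gc_content of an all-N sequence is undefined")
    return (cds.count("G") + cds.count("C")) / non_n


# ---------------------------------------------------------------------------
# Wright's effective number of codons
# ---------------------------------------------------------------------------

def _family_homozygosity(
    counts: CodonCountTable, aa: str, estimator: str
) -> Optional[float]:
    """Homozygosity F for one amino-acid family, or None if not
    computable from the available counts."""
    xs = [counts.counts.get(c, 0) for c in FAMILIES[aa]]
    n = sum(xs)
    if estimator == "wright":
        if n < 2:
            return None
        s = sum((x / n) ** 2 for x in xs)
        f = (n * s - 1.0) / (n - 1.0)
    elif estimator == "population":
        if n < 1:
            return None
        f = sum((x / n) ** 2 for x in xs)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return f


def effective_number_of_codons(
    counts: CodonCountTable, estimator: str = "wright"
) -> float:
    """Wright's effective number of codons.

    Per k-fold degenerate amino acid with n observed codons and usage
    proportions p_i, the homozygosity is estimated as
    F = (n * sum(p_i^2) - 1) / (n - 1) (``estimator="wright"``, the
    small-sample form; requires n >= 2) or as the population value
    F = sum(p_i^2) (``estimator="population"``).  Class means F̄_k are
    unweighted means over the amino acids of each degeneracy class and

        Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6

    with six-fold families (Leu, Ser, Arg) as their own class.  Amino
    acids with too few counts (or F = 0) are omitted from their class
    mean; a class with no computable member falls back to the
    codon-count-weighted mean of the other classes' F̄.  Estimates
    above 61 (possible with the finite-sample estimator) are clamped
    to 61.
    """
    per_class_f: dict[int, list[float]] = {k: [] for k in CLASS_SIZES}
    per_class_n: dict[int, int] = {k: 0 for k in CLASS_SIZES}
    for aa, codons in DEGENERATE_FAMILIES.items():
        k = len(codons)
        f = _family_homozygosity(counts, aa, estimator)
        if f is None or f <= 0.0:
            continue
        per_class_f[k].append(f)
        per_class_n[k] += counts.family_count(aa)

    means: dict[int, float] = {}
    for k, fs in per_class_f.items():
        if fs:
            means[k] = sum(fs) / len(fs)
    if not means:
        raise CharkitError("no degenerate family has enough counts to estimate Nc")
    for k in CLASS_SIZES:
        if k not in means:
            # count-weighted mean of the computable classes
            w = sum(per_class_n[j] for j in means)
            if w == 0:
                raise CharkitError(f"no fallback available for {k}-fold class")
            means[k] = sum(means[j] * per_class_n[j] for j in means) / w

    nc = 2.0 + sum(CLASS_SIZES[k] / means[k] for k in CLASS_SIZES)
    return min(nc, NC_MAX)


def expected_nc(s: float) -> float:
    """Expected Nc at third-position GC content ``s`` under purely
    compositional codon usage: Nc(s) = 2 + s + 29 / (s^2 + (1-s)^2)."""
    if not (0.0 < s < 1.0):
        raise CharkitError(f"GC3 value {s} outside the open interval (0, 1)")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


# ---------------------------------------------------------------------------
# CBI and optimal codons
# ---------------------------------------------------------------------------

def _validate_optimal(optimal_codons: Iterable[str]) -> dict[str, str]:
    by_aa: dict[str, str] = {}
    for c in optimal_codons:
        c = c.upper().replace("U", "T")
        aa = CODON_TO_AA.get(c)
        if aa is None:
            raise CharkitError(f"{c!r} is not a sense codon")
        if aa not in DEGENERATE_FAMILIES:
            raise CharkitError(f"{c} encodes a non-degenerate amino acid")
        if aa in by_aa:
            raise CharkitError(f"two optimal codons given for amino acid {aa}")
        by_aa[aa] = c
    missing = set(DEGENERATE_FAMILIES) - set(by_aa)
    if missing:
        raise CharkitError(
            f"optimal set missing amino acids: {sorted(missing)}"
        )
    return by_aa


def codon_bias_index(
    counts: CodonCountTable, optimal_codons: Iterable[str]
) -> Optional[float]:
    """Bennetzen–Hall codon bias index.

    CBI = (N_opt - N_ran) / (N_tot - N_ran), where N_opt is the number
    of codons drawn from the optimal set, N_tot the number of codons of
    degenerate families, and N_ran = sum over families of n_family / k,
    the expected optimal count under uniform usage.  Returns None when
    the denominator vanishes (undefined).
    """
    by_aa = _validate_optimal(optimal_codons)
    n_opt = 0
    n_tot = 0
    n_ran = 0.0
    for aa, codons in DEGENERATE_FAMILIES.items():
        fam = counts.family_count(aa)
        if fam == 0:
            continue
        n_tot += fam
        n_ran += fam / len(codons)
        n_opt += counts.counts.get(by_aa[aa], 0)
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        return None
    return (n_opt - n_ran) / (n_tot - n_ran)


def select_optimal_codons(
    tables: Mapping[str, CodonCountTable],
    expression: Sequence["ExpressionRecord"],
    top_fraction: float = 0.10,
) -> frozenset[str]:
    """Derive an optimal-codon set from the most-expressed genes.

    Codon counts are pooled over the ``top_fraction`` highest-FPKM
    genes shared between the two inputs; within each degenerate family
    the most frequent codon is optimal (ties alphabetical).
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    expr_by_id = {e.id: e for e in expression}
    shared = [i for i in tables if i in expr_by_id]
    if not shared:
        raise CharkitError("no ids shared between codon tables and expression")
    shared.sort(key=lambda i: (-expr_by_id[i].fpkm, i))
    n_top = max(1, math.ceil(top_fraction * len(shared)))
    pooled = CodonCountTable()
    for i in shared[:n_top]:
        pooled = pooled + tables[i]
    optimal: set[str] = set()
    for aa, codons in DEGENERATE_FAMILIES.items():
        best = min(codons, key=lambda c: (-pooled.counts.get(c, 0), c))
        optimal.add(best)
    return frozenset(optimal)


# ---------------------------------------------------------------------------
# Expression (FPKM) and correlation
# ---------------------------------------------------------------------------

def fpkm(fragment_count: int, length: int, total_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped
    fragments: 1e9 * count / (length * total)."""
    if length <= 0:
        raise CharkitError("fpkm requires length > 0")
    if total_fragments <= 0:
        raise CharkitError("fpkm requires total_fragments > 0")
    return 1.0e9 * fragment_count / (length * total_fragments)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression: fragment count, length, FPKM and its log10
    (None for zero-count genes; no pseudocount by default)."""

    id: str
    fragment_count: int
    length: int
    fpkm: float
    log10_fpkm: Optional[float]

    @classmethod
    def from_counts(
        cls, id: str, fragment_count: int, length: int, total_fragments: int
    ) -> "ExpressionRecord":
        value = fpkm(fragment_count, length, total_fragments)
        return cls(
            id=id,
            fragment_count=fragment_count,
            length=length,
            fpkm=value,
            log10_fpkm=math.log10(value) if value > 0 else None,
        )


def read_expression_table(path) -> list[tuple[str, int]]:
    """Read a two-column (id, fragment_count) TSV."""
    out: list[tuple[str, int]] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise CharkitError(f"{path}: expected two columns (id, count)")
    for _, row in df.iterrows():
        out.append((str(row.iloc[0]), int(row.iloc[1])))
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-test
    p-value (t = r * sqrt((n-2)/(1-r^2)), n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CharkitError("pearson requires two equal-length vectors")
    if len(x) < 3:
        raise CharkitError("pearson requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CharkitError("pearson is undefined for a constant vector")
    r, p = _scipy_stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Per-gene bias table and bias-vs-expression analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonBiasStats:
    """Derived statistics for one coding sequence."""

    rscu: dict[str, float]
    gc: float
    gc3: float
    nc: float
    cbi: Optional[float]


def codon_bias_stats(
    cds: str, optimal_codons: Optional[Iterable[str]] = None
) -> CodonBiasStats:
    counts = count_codons(cds)
    return CodonBiasStats(
        rscu=rscu(counts),
        gc=gc_content(cds),
        gc3=gc3(cds),
        nc=effective_number_of_codons(counts),
        cbi=(
            codon_bias_index(counts, optimal_codons)
            if optimal_codons is not None
            else None
        ),
    )


def bias_expression_analysis(
    cds_set: Sequence[SequenceRecord],
    expression: Sequence[ExpressionRecord],
    min_orf_nt: int = 150,
    optimal_codons: Optional[Iterable[str]] = None,
    top_fraction: float = 0.10,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-gene bias table plus the CBI-vs-log10(FPKM) correlation.

    ORFs are filtered to length strictly greater than ``min_orf_nt``.
    When no optimal-codon set is supplied, one is derived from the
    ``top_fraction`` most-expressed genes.  Genes with undefined
    statistics (zero FPKM, undefined CBI/Nc) stay in the table with a
    ``flag`` and are excluded from the correlation only.
    """
    kept = [r for r in cds_set if len(r) > min_orf_nt]
    if not kept:
        raise CharkitError(f"no ORF longer than {min_orf_nt} nt")
    expr_by_id = {e.id: e for e in expression}
    tables = {r.id: count_codons(r.seq) for r in kept}
    if optimal_codons is None:
        optimal_codons = select_optimal_codons(tables, expression, top_fraction)

    rows = []
    for r in kept:
        counts = tables[r.id]
        e = expr_by_id.get(r.id)
        flag = []
        try:
            nc = effective_number_of_codons(counts)
        except CharkitError:
            nc = None
            flag.append("nc_undefined")
        cbi = codon_bias_index(counts, optimal_codons)
        if cbi is None:
            flag.append("cbi_undefined")
        if e is None:
            flag.append("no_expression")
        elif e.log10_fpkm is None:
            flag.append("zero_fpkm")
        rows.append(
            {
                "id": r.id,
                "n_codons": counts.n_codons,
                "gc": gc_content(r.seq),
                "gc3": gc3(r.seq),
                "nc": nc,
                "cbi": cbi,
                "fpkm": e.fpkm if e else None,
                "log10_fpkm": e.log10_fpkm if e else None,
                "flag": ";".join(flag),
            }
        )
    df = pd.DataFrame(rows)
    clean = df[(df["flag"] == "") & df["cbi"].notna() & df["log10_fpkm"].notna()]
    r_p = pearson(clean["cbi"].to_numpy(), clean["log10_fpkm"].to_numpy())
    return df, r_p


def nc_plot(df: pd.DataFrame, path=None):
    """Nc-vs-GC3 scatter with the expected curve overlaid (requires
    matplotlib; saved to ``path`` if given, else the figure returns)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(df["gc3"], df["nc"], s=6, alpha=0.5, label="genes")
    s = np.linspace(0.01, 0.99, 200)
    ax.plot(s, [expected_nc(v) for v in s], "r--", label="expected (GC3 only)")
    ax.set_xlabel("GC3")
    ax.set_ylabel("Nc")
    ax.set_ylim(15, 63)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
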