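"""Seeded synthetic-data generators with machine-readable ground truth.

Every input format the pipeline consumes can be fabricated here with a
known truth table: transcriptomes with a realistic unigene length
distribution (log-normal, mean ~571 nt) and GC content (~51%), coding
sequences whose synonymous-codon usage interpolates between uniform
usage at a target GC3 and complete single-codon bias, planted perfect
microsatellites with guard bases so the planted repeat count is exact,
paired 90-nt reads with labelled quality/ambiguity failures, reciprocal
best-hit tables with planted 1:1 orthologs plus decoys, and expression
counts whose log-mean is coupled to the planted codon-bias strength.

Each generator takes its own integer seed and builds a private
``numpy.random.Generator``; identical arguments and seed give
byte-identical outputs.  Truth tables are plain dicts / DataFrames and
round-trip through TSV via :func:`truth_to_tsv` / :func:`truth_from_tsv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import HitRecord
from .codon_usage import DEGENERATE_FAMILIES, ExpressionRecord
from .read_qc import ReadRecord
from .seq_core import CharkitError, SequenceRecord
from .ssr_miner import DEFAULT_THRESHOLDS, find_ssrs

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic transcriptome.

    Defaults emulate a mosquito de novo assembly: mean unigene length
    571 nt (log-normal), GC 51.26%, minimum assembled length 200 nt.
    """

    seed: int
    n_sequences: int = 1000
    mean_length: float = 571.0
    sigma_log: float = 0.7
    gc: float = 0.5126
    min_length: int = 200

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.mean_length <= 0:
            raise CharkitError("invalid generator size parameters")
        if not (0.0 < self.gc < 1.0):
            raise CharkitError("gc target must be in (0, 1)")


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def gen_transcriptome(config: GeneratorConfig) -> list[SequenceRecord]:
    """Draw unigene-like sequences: log-normal lengths tuned to the
    requested mean (clipped at ``min_length``), iid bases at the
    requested GC."""
    rng = np.random.default_rng(config.seed)
    mu = math.log(config.mean_length) - config.sigma_log**2 / 2
    lengths = np.maximum(
        rng.lognormal(mu, config.sigma_log, size=config.n_sequences).astype(int),
        config.min_length,
    )
    return [
        SequenceRecord(id=f"unigene_{i + 1:05d}", seq=_random_nt(rng, int(L), config.gc))
        for i, L in enumerate(lengths)
    ]


# ---------------------------------------------------------------------------
# SSR planting
# ---------------------------------------------------------------------------

_RELAXED = {m: t - 1 for m, t in DEFAULT_THRESHOLDS.items()}


def _scrub_ssrs(seq: str, rng: np.random.Generator, max_rounds: int = 25) -> str:
    """Disrupt incidental near-threshold repeats so later planting is
    the only source of reportable SSRs (scrubbed at thresholds one
    repeat below the defaults, leaving a safety margin)."""
    s = list(seq)
    for _ in range(max_rounds):
        hits = find_ssrs("".join(s), _RELAXED)
        if not hits:
            return "".join(s)
        for h in hits:
            mid = (h.start - 1 + h.end) // 2
            old = s[mid]
            s[mid] = rng.choice([b for b in "ACGT" if b != old])
    raise CharkitError("could not scrub incidental SSRs")


def plant_ssrs(
    records: Sequence[SequenceRecord],
    spec: Sequence[tuple[str, int, int]],
    seed: int,
    scrub: bool = True,
    placements: Optional[Sequence[tuple[str, str, int]]] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Insert perfect SSR runs into host sequences.

    ``spec`` lists (motif, repeats, count) to plant at random positions
    in randomly chosen hosts; alternatively ``placements`` pins every
    run to a host id as (seq_id, motif, repeats).  One guard base on
    each side (chosen to differ from the adjacent motif base) stops the
    planted run from extending into its flanks, so the planted repeat
    count is exact.  Returns the modified records and a truth table
    (seq_id, motif, repeats, start, end; 1-based inclusive).
    """
    rng = np.random.default_rng(seed)
    seqs = {r.id: list(r.seq) for r in records}
    if scrub:
        seqs = {rid: list(_scrub_ssrs("".join(s), rng)) for rid, s in seqs.items()}
    used: dict[str, list[tuple[int, int]]] = {r.id: [] for r in records}
    ids = [r.id for r in records]

    jobs: list[tuple[str, str, int]] = []
    if placements is not None:
        jobs = [(sid, motif.upper(), reps) for sid, motif, reps in placements]
    else:
        for motif, reps, count in spec:
            for _ in range(count):
                jobs.append((ids[int(rng.integers(len(ids)))], motif.upper(), reps))

    truth_rows = []
    for sid, motif, reps in jobs:
        if sid not in seqs:
            raise CharkitError(f"unknown host sequence {sid!r}")
        m = len(motif)
        window = m * reps + 2  # run plus two guard bases
        L = len(seqs[sid])
        if L < window:
            raise CharkitError(f"{sid}: too short ({L} nt) for a {window}-nt insert")
        for _attempt in range(200):
            pos = int(rng.integers(0, L - window + 1))
            if all(pos + window <= a or pos >= b for a, b in used[sid]):
                break
        else:
            raise CharkitError(f"{sid}: no free window for planting")
        left_guard = rng.choice([b for b in "ACGT" if b != motif[-1]])
        right_guard = rng.choice([b for b in "ACGT" if b != motif[0]])
        seqs[sid][pos : pos + window] = left_guard + motif * reps + right_guard
        used[sid].append((pos, pos + window))
        truth_rows.append(
            {
                "seq_id": sid,
                "motif": motif,
                "repeats": reps,
                "start": pos + 2,  # 1-based, after the guard base
                "end": pos + 1 + m * reps,
            }
        )

    out = [
        SequenceRecord(id=r.id, seq="".join(seqs[r.id]), description=r.description)
        for r in records
    ]
    return out, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Coding sequences with controlled GC3 and bias
# ---------------------------------------------------------------------------

# degenerate amino acids only: keeps every drawn codon informative for Nc
_AA_POOL = tuple(sorted(DEGENERATE_FAMILIES))


def _family_probs(codons: tuple[str, ...], gc3_target: float, bias: float) -> np.ndarray:
    """Within-family codon probabilities: compositional weights by the
    third base (GC-ending codons get weight s), linearly interpolated
    toward a point mass on the preferred codon as bias goes to 1."""
    w = np.array(
        [gc3_target if c[2] in "GC" else 1.0 - gc3_target for c in codons]
    )
    w = w / w.sum()
    pref = int(np.argmax(w))  # ties resolve to the alphabetically first codon
    point = np.zeros(len(codons))
    point[pref] = 1.0
    return (1.0 - bias) * w + bias * point


def gen_cds_set(
    n_genes: int,
    codons_per_gene: int,
    gc3_target: float,
    bias_strength: float | tuple[float, float],
    seed: int,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate coding sequences with known GC3 and bias strength.

    Amino acids are drawn uniformly from the 18 degenerate families;
    synonymous codons come from a family-level distribution that is
    compositional at bias 0 (third-base GC probability ~ ``gc3_target``)
    and a single codon per family at bias 1.  ``bias_strength`` may be
    a scalar or a (lo, hi) range sampled per gene.  No stop codons are
    emitted.  Truth records each gene's planted bias and GC3 target.
    """
    if not (0.0 < gc3_target < 1.0):
        raise CharkitError("gc3_target must be in (0, 1)")
    lo, hi = (
        (bias_strength, bias_strength)
        if isinstance(bias_strength, (int, float))
        else bias_strength
    )
    if not (0.0 <= lo <= hi <= 1.0):
        raise CharkitError("bias_strength must lie in [0, 1]")
    if n_genes < 1 or codons_per_gene < 2:
        raise CharkitError("need n_genes >= 1 and codons_per_gene >= 2")
    rng = np.random.default_rng(seed)

    records: list[SequenceRecord] = []
    truth_rows = []
    fam_codons = {aa: DEGENERATE_FAMILIES[aa] for aa in _AA_POOL}
    for g in range(n_genes):
        bias = float(lo if lo == hi else rng.uniform(lo, hi))
        probs = {
            aa: _family_probs(codons, gc3_target, bias)
            for aa, codons in fam_codons.items()
        }
        aas = rng.choice(len(_AA_POOL), size=codons_per_gene)
        codons = []
        for ai in aas:
            aa = _AA_POOL[ai]
            fam = fam_codons[aa]
            codons.append(fam[int(rng.choice(len(fam), p=probs[aa]))])
        gid = f"gene_{g + 1:04d}"
        records.append(SequenceRecord(id=gid, seq="".join(codons)))
        truth_rows.append(
            {
                "id": gid,
                "bias_strength": bias,
                "gc3_target": gc3_target,
                "n_codons": codons_per_gene,
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Reads with labelled failures
# ---------------------------------------------------------------------------

def gen_reads(
    records: Sequence[SequenceRecord],
    n_pairs: int,
    read_length: int = 90,
    fail_n_fraction: float = 0.05,
    fail_lowq_fraction: float = 0.05,
    seed: int = 0,
    base_q: tuple[int, int] = (30, 40),
    low_q: int = 10,
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """Sample paired reads from transcripts and plant labelled failures.

    A ``fail_n_fraction`` of pairs gets one mate with >5% ambiguous N
    bases; a disjoint ``fail_lowq_fraction`` gets one mate with >10% of
    bases below Q20.  All other reads are strictly clean (no N, all
    qualities >= 20).  Truth labels each pair id pass/fail with the
    planted failure mode.
    """
    if not records:
        raise CharkitError("gen_reads requires a non-empty transcript set")
    eligible = [r for r in records if len(r) >= read_length]
    if not eligible:
        raise CharkitError("no transcript is as long as one read")
    if fail_n_fraction + fail_lowq_fraction > 1.0:
        raise CharkitError("failure fractions exceed 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r) for r in eligible], dtype=float)
    weights = lengths / lengths.sum()

    n_fail_n = int(round(fail_n_fraction * n_pairs))
    n_fail_q = int(round(fail_lowq_fraction * n_pairs))
    modes = ["fail_n"] * n_fail_n + ["fail_lowq"] * n_fail_q
    modes += ["pass"] * (n_pairs - len(modes))
    modes = list(rng.permutation(modes))

    # enough planted bases to clear the strict thresholds with margin
    n_planted_n = max(2, math.ceil(0.05 * read_length) + 2)
    n_planted_q = max(2, math.ceil(0.10 * read_length) + 2)

    from Bio.Seq import Seq  # local import keeps module load light

    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    truth_rows = []
    for i in range(n_pairs):
        t = eligible[int(rng.choice(len(eligible), p=weights))]
        frag_len = int(min(len(t), max(read_length, 2 * read_length + 20)))
        start = int(rng.integers(0, len(t) - frag_len + 1))
        frag = t.seq[start : start + frag_len]
        b1 = frag[:read_length].replace("N", "A")
        b2 = str(Seq(frag[-read_length:]).reverse_complement()).replace("N", "A")
        q1 = rng.integers(base_q[0], base_q[1] + 1, size=read_length)
        q2 = rng.integers(base_q[0], base_q[1] + 1, size=read_length)

        mode = modes[i]
        if mode == "fail_n":
            idx = rng.choice(read_length, size=n_planted_n, replace=False)
            b1 = "".join(
                "N" if j in set(int(x) for x in idx) else c for j, c in enumerate(b1)
            )
        elif mode == "fail_lowq":
            idx = rng.choice(read_length, size=n_planted_q, replace=False)
            q1 = q1.copy()
            q1[idx] = low_q
        pid = f"pair_{i + 1:06d}"
        reads1.append(ReadRecord(id=f"{pid}/1", bases=b1, quals=tuple(int(q) for q in q1)))
        reads2.append(ReadRecord(id=f"{pid}/2", bases=b2, quals=tuple(int(q) for q in q2)))
        truth_rows.append(
            {"pair_id": pid, "label": "pass" if mode == "pass" else "fail", "mode": mode}
        )
    return reads1, reads2, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Ortholog hit tables
# ---------------------------------------------------------------------------

def gen_ortholog_tables(
    n_a: int,
    n_b: int,
    n_orthologs: int,
    score_noise: float = 0.0,
    decoy_rate: float = 0.2,
    seed: int = 0,
) -> tuple[list[HitRecord], list[HitRecord], pd.DataFrame]:
    """Fabricate reciprocal hit tables with planted 1:1 orthologs.

    The first ``n_orthologs`` (a_i, b_i) pairs receive high-scoring
    reciprocal hits (bit ~300 + noise); decoy hits at ~half the score
    are injected at ``decoy_rate`` per query in each direction.  Decoy
    targets are chosen so decoys alone can never form a reciprocal
    pair.  Truth lists the planted pairs.
    """
    if n_orthologs > min(n_a, n_b):
        raise CharkitError("n_orthologs exceeds a set size")
    if not (0.0 <= decoy_rate <= 1.0) or score_noise < 0:
        raise CharkitError("invalid rate parameters")
    rng = np.random.default_rng(seed)
    a_ids = [f"a{i + 1:05d}" for i in range(n_a)]
    b_ids = [f"b{i + 1:05d}" for i in range(n_b)]

    def _hit(q: str, s: str, bit: float, evalue: float) -> HitRecord:
        return HitRecord(
            query_id=q,
            subject_id=s,
            pct_identity=80.0,
            align_length=200,
            evalue=evalue,
            bit_score=round(max(bit, 30.0), 1),
            q_start=1,
            q_end=600,
        )

    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    for i in range(n_orthologs):
        bit = 300.0 + score_noise * rng.normal(0.0, 30.0)
        hits_ab.append(_hit(a_ids[i], b_ids[i], bit, 1e-80))
        bit = 300.0 + score_noise * rng.normal(0.0, 30.0)
        hits_ba.append(_hit(b_ids[i], a_ids[i], bit, 1e-80))

    # A->B decoys
    ab_target: dict[str, str] = {}
    for i, a in enumerate(a_ids):
        if rng.random() < decoy_rate:
            j = int(rng.integers(n_b))
            if i < n_orthologs and j == i:
                j = (j + 1) % n_b
            bit = 150.0 + score_noise * rng.normal(0.0, 30.0)
            hits_ab.append(_hit(a, b_ids[j], bit, 1e-20))
            ab_target[a] = b_ids[j]
    # B->A decoys, never reciprocating an A->B decoy
    for j, b in enumerate(b_ids):
        if rng.random() < decoy_rate:
            for _ in range(50):
                i = int(rng.integers(n_a))
                if j < n_orthologs and i == j:
                    continue
                if ab_target.get(a_ids[i]) != b:
                    break
            else:
                continue
            bit = 150.0 + score_noise * rng.normal(0.0, 30.0)
            hits_ba.append(_hit(b, a_ids[i], bit, 1e-20))

    truth = pd.DataFrame(
        {"id_a": a_ids[:n_orthologs], "id_b": b_ids[:n_orthologs]}
    )
    return hits_ab, hits_ba, truth


# ---------------------------------------------------------------------------
# Expression coupled to bias
# ---------------------------------------------------------------------------

def gen_expression(
    cds_truth: pd.DataFrame,
    coupling: float,
    seed: int,
    mean_log10: float = 1.0,
    coupling_scale: float = 0.8,
    noise_sd: float = 0.25,
) -> list[ExpressionRecord]:
    """Draw per-gene fragment counts whose log10 mean is linearly
    coupled to the planted bias strength (standardized across genes);
    ``coupling`` = 0 gives independence.  Needs the truth table from
    :func:`gen_cds_set` (columns id, bias_strength, n_codons).
    """
    if not (-1.0 <= coupling <= 1.0):
        raise CharkitError("coupling must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    bias = cds_truth["bias_strength"].to_numpy(dtype=float)
    z = np.zeros_like(bias) if bias.std() == 0 else (bias - bias.mean()) / bias.std()
    log_mu = mean_log10 + coupling * coupling_scale * z + rng.normal(0, noise_sd, len(bias))
    counts = rng.poisson(np.power(10.0, log_mu))
    lengths = (cds_truth["n_codons"].to_numpy(dtype=int)) * 3
    total = int(counts.sum())
    if total == 0:
        total = 1
    return [
        ExpressionRecord.from_counts(
            id=str(cds_truth["id"].iloc[i]),
            fragment_count=int(counts[i]),
            length=int(lengths[i]),
            total_fragments=total,
        )
        for i in range(len(bias))
    ]


# ---------------------------------------------------------------------------
# Truth-table serialization
# ---------------------------------------------------------------------------

def truth_to_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def truth_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# An end-to-end study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Every artifact of a small synthetic study plus its ground truth."""

    transcripts: list[SequenceRecord]
    cds_truth: pd.DataFrame  # per-gene bias/gc3 plus transcript placement
    per_db_hits: dict[str, list[HitRecord]]
    ssr_hosts: list[SequenceRecord]
    ssr_truth: pd.DataFrame
    reads1: list[ReadRecord]
    reads2: list[ReadRecord]
    read_truth: pd.DataFrame
    expression: list[ExpressionRecord]
    cds_records: list[SequenceRecord]


def gen_study_bundle(
    seed: int,
    n_genes: int = 40,
    n_ssr_hosts: int = 10,
    n_read_pairs: int = 1500,
) -> StudyBundle:
    """Fabricate a miniature end-to-end study.

    Coding genes are embedded in transcripts with random UTR flanks
    (half on the minus strand), database hits are synthesized from the
    true CDS placements across the four protein databases in rotation
    (one gene in four gets no hit and must go through the ORF
    fallback), SSR hosts carry 14 planted runs in 8 of 10 sequences
    (3 hosts with several), and reads carry 5% + 5% labelled failures.
    """
    rng = np.random.default_rng(seed)

    # per-gene codon counts vary, so build genes one by one
    genes: list[SequenceRecord] = []
    truth_rows = []
    for g in range(n_genes):
        n_codons = int(rng.integers(120, 401))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        recs, tr = gen_cds_set(1, n_codons, 0.654, (0.0, 0.6), sub_seed)
        gid = f"gene_{g + 1:04d}"
        genes.append(SequenceRecord(id=gid, seq=recs[0].seq))
        row = tr.iloc[0].to_dict()
        row["id"] = gid
        truth_rows.append(row)
    cds_truth = pd.DataFrame(truth_rows)

    from Bio.Seq import Seq

    dbs = ("Nr", "SwissProt", "KEGG", "COG")
    transcripts: list[SequenceRecord] = []
    per_db_hits: dict[str, list[HitRecord]] = {db: [] for db in dbs}
    placements = []
    for g, gene in enumerate(genes):
        utr5 = _random_nt(rng, int(rng.integers(30, 300)), 0.5126)
        utr3 = _random_nt(rng, int(rng.integers(30, 300)), 0.5126)
        plus = utr5 + gene.seq + utr3
        cds_start = len(utr5) + 1  # 1-based on plus strand
        cds_end = len(utr5) + len(gene.seq)
        minus = bool(rng.random() < 0.5)
        tseq = str(Seq(plus).reverse_complement()) if minus else plus
        tid = f"unigene_{g + 1:05d}"
        transcripts.append(SequenceRecord(id=tid, seq=tseq))
        placements.append(
            {
                "id": gene.id,
                "transcript_id": tid,
                "orientation": "-" if minus else "+",
                "cds_start": cds_start,  # on the oriented (plus) strand
                "cds_end": cds_end,
            }
        )
        if g % 4 == 3:
            continue  # no database hit: exercised via the ORF fallback
        db = dbs[g % 4]
        if minus:
            L = len(tseq)
            q_start = L - cds_start + 1
            q_end = L - cds_end + 1
        else:
            q_start, q_end = cds_start, cds_end
        per_db_hits[db].append(
            HitRecord(
                query_id=tid,
                subject_id=f"prot_{g + 1:04d}",
                pct_identity=85.0,
                align_length=(cds_end - cds_start + 1) // 3,
                evalue=1e-30,
                bit_score=200.0,
                q_start=q_start,
                q_end=q_end,
            )
        )
    cds_truth = cds_truth.merge(pd.DataFrame(placements), on="id")

    # SSR hosts: 14 planted runs across 8 of n_ssr_hosts, 3 hosts multi
    host_cfg = GeneratorConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_sequences=n_ssr_hosts,
        mean_length=2000.0,
        sigma_log=0.1,
        min_length=1500,
    )
    hosts = gen_transcriptome(host_cfg)
    hosts = [
        SequenceRecord(id=f"ssrhost_{i + 1:03d}", seq=h.seq)
        for i, h in enumerate(hosts)
    ]
    motifs = ["AT", "AC", "ATG", "AAG", "ACGT", "AAGT", "ACGTC", "ACGTAG"]
    counts_per_host = [3, 3, 3, 1, 1, 1, 1, 1]  # 14 runs, 8 hosts, 3 multi
    placements_ssr = []
    mi = 0
    for hi, c in enumerate(counts_per_host):
        for _ in range(c):
            motif = motifs[mi % len(motifs)]
            reps = DEFAULT_THRESHOLDS[len(motif)] + int(rng.integers(0, 4))
            placements_ssr.append((hosts[hi].id, motif, reps))
            mi += 1
    ssr_hosts, ssr_truth = plant_ssrs(
        hosts, [], seed=int(rng.integers(0, 2**31 - 1)), placements=placements_ssr
    )

    reads1, reads2, read_truth = gen_reads(
        transcripts,
        n_pairs=n_read_pairs,
        fail_n_fraction=0.05,
        fail_lowq_fraction=0.05,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    expression = gen_expression(cds_truth, coupling=0.6, seed=int(rng.integers(0, 2**31 - 1)))

    return StudyBundle(
        transcripts=transcripts,
        cds_truth=cds_truth,
        per_db_hits=per_db_hits,
        ssr_hosts=ssr_hosts,
        ssr_truth=ssr_truth,
        reads1=reads1,
        reads2=reads2,
        read_truth=read_truth,
        expression=expression,
        cds_records=genes,
    )
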