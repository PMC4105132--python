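"""Independent brute-force oracles, kept deliberately naive and
separate from the library implementations they cross-check."""

from __future__ import annotations

import math

from Bio.Data import CodonTable

# --- N50 ------------------------------------------------------------------

def n50_brute(lengths):
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= total / 2:
            return L


# --- Wright's Nc, straight from the definition ----------------------------

_fw = CodonTable.unambiguous_dna_by_id[1].forward_table
_aa_to_codons = {}
for _c, _a in _fw.items():
    _aa_to_codons.setdefault(_a, []).append(_c)


def nc_direct(cds: str) -> float:
    """Direct-from-definition Wright estimator on a CDS string."""
    counts = {}
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _fw and "N" not in codon:
            counts[codon] = counts.get(codon, 0) + 1
    class_fs = {2: [], 3: [], 4: [], 6: []}
    class_counts = {2: 0, 3: 0, 4: 0, 6: 0}
    for aa, codons in _aa_to_codons.items():
        k = len(codons)
        if k < 2:
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f <= 0:
            continue
        class_fs[k].append(f)
        class_counts[k] += n
    sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    means = {k: sum(v) / len(v) for k, v in class_fs.items() if v}
    for k in sizes:
        if k not in means:
            w = sum(class_counts[j] for j in means)
            means[k] = sum(means[j] * class_counts[j] for j in means) / w
    nc = 2 + sum(sizes[k] / means[k] for k in sizes)
    return min(nc, 61.0)


# --- SSR enumeration ------------------------------------------------------

def _primitive(motif):
    m = len(motif)
    return not any(
        m % d == 0 and motif == motif[:d] * (m // d) for d in range(1, m)
    )


def ssr_brute(seq: str, thresholds=None):
    """Enumerate, at every substring position and motif length, the
    tandem repeat count of the primitive motif starting there; keep the
    qualifying runs and pick non-overlapping ones greedily from the
    left (smallest motif first at equal starts).

    Returns (motif, repeats, start, end) tuples, 1-based inclusive.
    """
    if thresholds is None:
        thresholds = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}
    n = len(seq)
    candidates = []
    for i in range(n):
        for m in range(2, 7):
            motif = seq[i : i + m]
            if len(motif) < m or set(motif) - set("ACGT"):
                continue
            if not _primitive(motif):
                continue
            r = 1
            while seq[i + r * m : i + (r + 1) * m] == motif:
                r += 1
            if r >= thresholds[m]:
                candidates.append((i, m, motif, r))
    candidates.sort(key=lambda t: (t[0], t[1]))
    chosen = []
    occupied_until = -1
    for i, m, motif, r in candidates:
        if i > occupied_until:
            chosen.append((motif, r, i + 1, i + m * r))
            occupied_until = i + m * r - 1
    return chosen


# --- Reciprocal best hits by exhaustive pair search -----------------------

def rbh_brute(hits_ab, hits_ba, e_max=1e-5):
    """All (a, b) with b = argmax-bit hit of a and a = argmax-bit hit
    of b (ties: lower evalue, then earlier input order)."""

    def best_map(hits):
        order = {}
        for idx, h in enumerate(hits):
            if h.evalue > e_max:
                continue
            order.setdefault(h.query_id, []).append((idx, h))
        out = {}
        for q, items in order.items():
            best = min(items, key=lambda t: (-t[1].bit_score, t[1].evalue, t[0]))
            out[q] = best[1].subject_id
        return out

    fwd = best_map(hits_ab)
    rev = best_map(hits_ba)
    pairs = set()
    for a, b in fwd.items():
        if rev.get(b) == a:
            pairs.add((a, b))
    return pairs


# --- Longest ORF by exhaustive 6-frame enumeration ------------------------

_STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
_COMP = str.maketrans("ACGTN", "TGCAN")


def longest_orf_brute(seq: str):
    """(length_nt, orientation, frame0, start0) of the longest
    stop-free codon run over 6 frames; ties prefer plus strand, lower
    frame, leftmost.  None if no codon exists."""
    best = None
    for rank, (ori, s) in enumerate(
        (("+", seq), ("-", seq.translate(_COMP)[::-1]))
    ):
        for f in range(3):
            run = 0
            run_start = f
            pos = f
            while pos + 3 <= len(s):
                if s[pos : pos + 3] in _STOPS:
                    if run:
                        cand = (-3 * run, rank, f, run_start)
                        if best is None or cand < best:
                            best = cand
                    run = 0
                    run_start = pos + 3
                else:
                    run += 1
                pos += 3
            if run:
                cand = (-3 * run, rank, f, run_start)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return (-best[0], "+" if best[1] == 0 else "-", best[2], best[3])


# --- Pearson from the textbook formula ------------------------------------

def pearson_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


# --- Naive k-mer identity estimator (cluster-input helper) -----------------

def kmer_identity(a: str, b: str, k: int = 8) -> float:
    """Exact k-mer containment of the smaller set in the larger."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 0.0
    small, big = (ka, kb) if len(ka) <= len(kb) else (kb, ka)
    return len(small & big) / len(small)
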