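# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and
the limitations a user should keep in mind.

## Read cleaning

Reads are dropped when the fraction of `N` bases exceeds 0.05 or the
fraction of bases with Phred quality below 20 exceeds 0.10. Both
comparisons are **strict**: a 90-nt read with exactly 9 bases under
Q20 (10.0%) survives; 10 such bases (11.1%) removes it. Q20% counts
bases with Q ≥ 20 (Q20 conventionally means "error ≤ 1%"). In
paired-end mode a pair is dropped when either mate fails, keeping the
two files synchronized; single-end mode is also supported. Quality
encoding is Phred+33 by default with a `phred64` option for legacy
Illumina data. Adapter removal is exact-match trimming: the leftmost
position where a prefix of the adapter (≥ 5 nt by default) matches the
read out to its end — or where the full adapter occurs — is removed
together with everything 3′ of it. No mismatch-tolerant alignment and
no quality-based or sliding-window trimming is attempted; the stage is
deliberately simple and fully testable, and the adapter sequence is a
user-supplied parameter.

## Assembly statistics and clustering

N50 is the conventional definition: sort lengths descending and report
the first length at which the cumulative sum reaches at least half of
the total. When the half-total falls exactly on a cumulative boundary,
that boundary length is reported. The GC denominator excludes `N`
bases (inert on clean data, which carries 0% N). The minimum-length
filter keeps sequences of exactly 200 nt ("shorter than 200 are
deleted" read literally), and clustering joins unigenes whose supplied
pairwise similarity is **strictly** greater than 0.70 into connected
components; components of size ≥ 2 are labeled `CL1…`, the rest
`Unigene1…`. How the similarities are computed is out of scope — the
function consumes precomputed pairs (a naive k-mer containment
estimator lives in the test helpers only).

## Mapping evaluation

PSL records are parsed with 0-based half-open coordinates (the PSL
standard); the 5-line `psLayout` header is auto-detected. Per query
only the alignment with the most matching bases is kept; ties prefer
the larger target span, then input order. Coverage is matches divided
by query length; "more than 90% coverage" is strict. The coverage
histogram uses decile bins `[0, 0.1) … [0.9, 1.0]` with the top bin
closed.

## Annotation and CDS extraction

Hits qualify at E-value ≤ 1e-5 (inclusive). The best hit per query
maximizes bit score, with ties resolved by lower E-value and then
stable input order — documented because tabular search output order is
itself deterministic. Database priority (default Nr, SwissProt, KEGG,
COG) only decides attribution and which hit orients the unigene; the
annotated *set* is priority-invariant. Orientation comes from the
query coordinates (`q_start > q_end` ⇒ minus). The coding region is
the aligned interval on the oriented strand trimmed at both ends to
full codons in the hit's reading frame; when no frame is given the
alignment start is assumed to sit on a codon boundary. The interval is
**not** extended to external start/stop codons — the minimal
interpretation, chosen for reproducibility. An interval containing no
complete codon after trimming is an error. Unigenes with no qualifying
protein hit fall back to a deterministic longest-ORF call: the longest
stop-free codon run over all six frames (bounded by stop codons or
sequence ends), reported when strictly longer than 150 nt, labelled
`source_db="fallback"`. This replaces a trained gene predictor with a
self-contained, exactly testable rule; ties prefer the plus strand,
lower frame, then the leftmost start. Nucleotide-database (BLASTN)
results may be counted as an annotation set but never orient a
sequence.

## Orthology

Peptides shorter than 50 residues are removed (inclusive boundary: 50
is kept). Reciprocal best hits use the same best-hit tie-breaking in
both directions. Identifier namespaces of the two sets are assumed
disjoint; no paralog handling or orthology-graph clustering is done.

## Codon usage

The standard nuclear genetic code is fixed (Biopython table 1). Stop
codons are tallied separately and excluded from every bias statistic.
Counting is frame-0; a trailing partial codon and codons containing
`N` are recorded as skipped.

* **RSCU**: per k-fold family, count divided by family mean. Families
  with zero counts are reported as missing rather than zero.
* **Nc**: Wright's estimator with the (n−1) small-sample correction
  per family, unweighted class means over the 2-, 3-, 4- and 6-fold
  classes (Leu/Ser/Arg kept as single 6-fold families, the CodonW
  convention), and `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`. Families
  with fewer than 2 codons (or F̂ = 0, possible at tiny n) are omitted
  from their class mean; a class left empty takes the
  codon-count-weighted mean of the computable classes — a fallback
  needed for short ORFs. Estimates above 61 clamp to 61. A
  `population` estimator option (F = Σp̂², no correction) exposes the
  exact asymptotic limits: uniform usage gives 61 and single-codon
  usage gives 20, to machine precision.
* **Expected Nc–GC3 curve**: `Nc(s) = 2 + s + 29/(s² + (1−s)²)`,
  Wright's published closed form, adopted explicitly (the curve is
  asymmetric in s because of the linear term). Defined on the open
  interval (0, 1).
* **CBI**: Bennetzen–Hall, `(N_opt − N_ran)/(N_tot − N_ran)` over
  degenerate families only, undefined (None) when the denominator
  vanishes. The optimal-codon set defaults to the per-family most
  frequent codon pooled over the top 10% of genes by FPKM (ties
  alphabetical), since no organism-specific preset is assumed.
* **FPKM** is `1e9·c/(L·N)`; log₁₀(FPKM) is left undefined for
  zero-count genes (no pseudocount by default) and such genes are
  flagged and excluded from the CBI–expression correlation rather than
  silently dropped from the per-gene table.
* **Pearson correlation** uses the product-moment formula with the
  two-sided t-test p-value (n−2 df), via scipy.

## SSR mining

Only perfect (uninterrupted) di- to hexa-nucleotide repeats are
reported, at minimum repeat numbers 6/5/4/4/4; mononucleotide runs are
ignored (homopolymer sequencing artifacts). Motifs that are powers of
a shorter motif collapse to the shortest period. The scan is greedy
left-to-right: at each position the shortest qualifying primitive
motif is reported and the scan resumes after the run, so hits never
overlap. A consequence worth knowing: when two planted runs share a
rotational junction (e.g. `(ATG)₅` directly followed by `(AT)₆`), the
maximal run crossing the junction (`(GAT)₆`) is the one reported —
the detector and the brute-force enumeration oracle agree on this.
Transcriptome scans screen only sequences strictly longer than 1 kb.
The per-kb frequency divides a nucleotide denominator by the SSR
count; the default denominator is the *full* input's total nt (the
convention matching published per-transcriptome frequencies), with a
`screened` option restricted to the sequences actually scanned. "Kinds
of SSRs" is ambiguous in the field, so three counts are exposed:
distinct raw motif strings (default), distinct canonical rotations,
and distinct (motif, repeat-count) pairs. The repeat-number matrix is
binned at 4, 5, …, 10, >10.

## Synthetic data

Each generator takes an explicit integer seed and builds a private
`numpy.random.Generator`; identical arguments give byte-identical
output. Defaults emulate the structure of a mosquito de novo
transcriptome: log-normal unigene lengths with mean 571 nt (σ_log =
0.7, floor 200 nt), iid bases at GC 51.26%, paired 90-nt reads.

* **CDS generator**: amino acids drawn uniformly from the 18
  degenerate families (Met/Trp excluded so every codon is informative
  for Nc and the GC3 target is attainable); within a family, codon
  probabilities weight third-position G/C by the GC3 target and
  interpolate linearly toward a single preferred codon as the bias
  parameter goes from 0 to 1. At bias 1 every family is single-codon,
  so Nc = 20 exactly. At bias 0 the usage matches the compositional
  model underlying the expected Nc–GC3 curve up to the curve's own
  approximation (≈ 1 unit at extreme GC3), which the parameter-recovery
  tests bound at 1.5 Nc units for 200 genes × 500 codons.
* **SSR planting** first scrubs hosts of incidental repeats at
  thresholds one repeat *below* the reporting thresholds (so a planted
  run plus one guard base can never be pushed over a reporting
  threshold by its flanks), then writes each run with one guard base
  per side chosen to differ from the adjacent motif base, making the
  planted repeat count exact.
* **Read generator** plants disjoint failure sets: >5% N in one mate,
  or >10% of bases at Q10; passing reads are strictly clean. Truth
  labels are per pair.
* **Ortholog tables** give planted pairs reciprocal top hits (bit
  ~300) and inject lower-scoring decoys (~150) whose targets are
  chosen so that decoys alone can never form a reciprocal pair;
  score noise scales a Gaussian perturbation on all bit scores.
* **Expression** draws Poisson counts around a log-normal mean whose
  log10 is linearly coupled to the standardized planted bias strength.

What the generators do **not** emulate: realistic Illumina error
profiles, duplication and optical artifacts, isoform structure,
compound/interrupted SSRs, alignment score distributions of real
search tools, or UTR composition differences. Passing tests therefore
demonstrate algorithmic correctness against known truth, not
robustness to every artifact of real libraries.

## Problem sizes and numerical conventions

The test suite runs the oracle equivalences at 200 random 5-kb
sequences (SSR), 100 random CDSs (Nc, agreement to 1e-9), 1,000 random
length multisets (N50), and the parameter recovery at 200 genes × 500
codons — sizes chosen so the whole suite completes in well under a
minute per criterion while keeping the stochastic checks comfortably
away from their tolerances. Correlation checks that depend on sampling
use fixed seeds. Floating-point equality is asserted only where the
arithmetic is exact (FPKM scaling identities, the analytic Nc
endpoints); everything stochastic carries an explicit tolerance.

## Known limitations

* The 70% clustering similarity is consumed, not computed; results
  depend on how the caller measured similarity.
* CDS extraction trusts the best hit's interval; chimeric unigenes or
  frameshifted alignments yield the trimmed interval as-is.
* The optimal-codon set (and hence CBI) depends on the expression
  table supplied; with no expression data CBI requires an explicit
  codon set.
* Nc on very short ORFs leans on the sparse-class fallback and is
  noisy, as with any Wright-style estimator.
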