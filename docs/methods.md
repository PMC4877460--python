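# Methods

This note documents the models, defaults and design choices behind
`mirgrad`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design emulated

The package targets the common exploratory design for tissue miRNA
profiling: one pooled small-RNA library per tissue class (normal,
tumor-adjacent, tumor), sense-strand, adapter-trimmed reads of 18–25 nt,
followed by qPCR validation of selected miRNAs in individual samples
with U6 as reference gene. There are no sequencing replicates, which
dictates the choice of an exact two-count test over dispersion-based
models (edgeR/DESeq-style fits need replicates; their use here is a
non-goal).

## Quantification and isomiR classification

A mature miRNA is an annotated interval on its precursor (0-based
half-open internally; the GFF3 boundary is 1-based inclusive and is
converted at parse time). A read matches a mature arm when it equals,
with at most one substitution, the precursor window obtained by shifting
the annotated 5′ end by `offset5` and the 3′ end by `offset3`, both in
−4..+4 (positive = extension beyond the canonical end). Indels are not
isomiR events. Because the window length must equal the read length,
only 2·4+1 windows exist per arm per read; ties are broken by fewest
mismatches, then smallest |offset5|+|offset3|, then smallest |offset5|,
then deterministically by the signed offsets.

Two policies are deliberate and configurable nowhere (they define the
method):

* Both ends may vary simultaneously (5′ and 3′ isomiRs co-occur on real
  loci).
* A read matching several mature miRNAs equally well is assigned once,
  to the lexicographically smallest `mature_id`; every such event is
  logged (`multi_assignments`) for audit. Fractional assignment is not
  used.
* Reads are not reverse-complement searched: directional small-RNA
  libraries yield sense-strand reads.

`quantify_sample` accelerates matching with a k-mer anchor index: for a
fixed 5′ offset, a window's first k bases are a fixed precursor
substring (symmetrically for 3′ offsets and suffixes), and a read with
at most one mismatch must agree exactly with at least one of its two
k-base halves (k ≤ read length/2, k = 10 for reads ≥ 20 nt). Index
candidates are then verified by the exhaustive per-arm matcher, so
results are provably identical to brute force over every arm (also
asserted by a test).

## Differential expression

Counts per million: `cpm = count × 10⁶ / library_size`, where a
sample's library size is its total assigned read count, so a column
normalized by its own total sums to exactly 10⁶.

Three-step calling between libraries A and B:

1. **Reliability filter.** Remove a miRNA only when BOTH raw counts are
   ≤ `min_count` (default 10; strictly more than 10 on either side
   keeps it). This is the pair-wise reading of "low copy number in both
   samples at the same time"; a stricter per-sample rule can be
   obtained by pre-filtering the matrix.
2. **Exact test.** Under independent Poisson sampling the count in B
   given the count in A follows the Audic–Claverie negative binomial
   `Y | x ~ NegBin(x+1, N_A/(N_A+N_B))`; equivalently, given the total
   `s = x + y`, `y ~ Binomial(s, N_B/(N_A+N_B))`. The two-sided p-value
   doubles the smaller of the two inclusive "as extreme" tails,
   `P(Y ≥ y | x)` and `P(X ≥ x | y)`, capped at 1. The two formulations
   give identical tails (regularized-incomplete-beta identity), and the
   doubled-binomial form makes the statistic exactly symmetric in the
   two libraries; a one-directional doubling of `min(P(Y≤y|x), P(Y≥y|x))`
   is *not* symmetric (the inclusive point mass sits on different sides)
   and was rejected for that reason. Tails are computed by scipy in log
   space; a direct log-gamma summation oracle in the test suite agrees
   to 1e-10 for all counts ≤ 50 and both equal and unequal library
   sizes.
3. **Gates.** Benjamini–Hochberg q-values are computed across the
   filtered miRNAs of the comparison at hand (per comparison, never
   pooled across comparisons); a call requires `q < 0.01` and a CPM
   fold change ≥ 2 in either direction. The fold change is
   `(cpm_B + 1)/(cpm_A + 1)`: the 1-CPM pseudocount only guards the
   zero-count edge that the asymmetric filter permits and is negligible
   for retained miRNAs.

Defaults (`DEConfig`): `min_count=10`, `q_threshold=0.01`,
`fc_threshold=2.0`, `pseudocount_cpm=1.0` — the thresholds of the
three-step procedure the pipeline implements.

The test's null hypothesis is equal *concentration* (CPM), not equal
raw counts. When strongly induced miRNAs inflate one library's total,
miRNAs with constant raw expression genuinely lose relative abundance
and are correctly reported as differential — the compositional bias
inherent to all library-size normalization. The synthetic generator
reproduces this effect (see below); the gradient caller is robust to it
because a composition-driven shift in one comparison is generally not
confirmed by the other.

## Gradient calling

A miRNA is `up_gradient` iff (a) it is a called DE versus normal in
BOTH the tumor and the adjacent comparison, (b) both directions are up,
and (c) its CPM is strictly increasing across normal → adjacent →
tumor; `down_gradient` is symmetric. "Gradually changed" is thus
operationalized as significance against the common (normal) reference
plus strict monotonicity; ties break monotonicity (a gradient implies
change at every step). The tumor-vs-adjacent comparison is not required
by default — requiring it (`strict=True`) additionally demands a called
DE in the same direction between adjacent and tumor, which suppresses
shallow gradients whose second step is under 2-fold. The call is
invariant to rescaling all three CPM values by a positive constant.

## qPCR analysis

Per sample and target, ΔCt = mean(triplicate Ct of target) −
mean(triplicate Ct of reference). Group contrasts use ΔΔCt =
mean ΔCt(case) − mean ΔCt(control) and fold change 2^(−ΔΔCt). Group
tests are computed on ΔCt values (the scale on which normality is most
defensible): Welch's t-test by default — the paper-standard "t-test"
leaves the variance assumption open, and unequal variances across
tissue states are the safer default — with pooled-variance and paired
variants available (`equal_var=True`, `paired=True`; samples are
paired per patient in the emulated design, but group-level summaries
are the default presentation). The degenerate zero-variance case
returns p = 1 for equal means and p = 0 otherwise rather than NaN.

## Hairpin plausibility

`fold_maxpairs` maximizes the number of nested base pairs (Nussinov
recurrence) with Watson–Crick plus G·U wobble pairing and a minimum
hairpin loop of 3 unpaired bases. Two deviations from the textbook
algorithm matter:

* **No lonely pairs (default).** Pure pair maximization decorates loops
  with isolated single-pair "helices" that no thermodynamic model would
  form, splitting one terminal loop into several. By default every
  helix must stack at least two pairs (the `--noLP` convention of
  thermodynamic folders); plain maximization is available via
  `allow_lonely_pairs=True`. The test-suite oracle enumerates all
  nested structures under the same rules for sequences ≤ 14 nt.
* **Traceback preference.** Among co-optimal structures the traceback
  prefers the longest stack and the outermost pairing, which recovers a
  single long stem from hairpin-shaped inputs.

Note that the G·U wobble pair is not closed under reverse complement
(G·T maps to A·C), so the pair count is strand-symmetric only under
Watson–Crick-only folding (`wobble=False`); the property test asserts
symmetry in that mode.

`stemloop_check` passes a candidate when the fold has exactly one
terminal loop (a pair whose interior is entirely unpaired), the mature
region does not overlap that loop, and ≥ 60% of mature bases are paired
(`min_paired_fraction`, exposed). The single-loop and 60% thresholds
are operationalizations of "the mature miRNA lies in the stem, away
from loops and bulges"; base-pair maximization is a qualitative stand-in
for free-energy folding — adequate for a plausibility gate,
insufficient for ΔG-based novel-miRNA scoring, which is out of scope.

## Over-representation analysis

One-sided hypergeometric test of a target-gene list against each set of
a GMT collection: p = P(X ≥ k) for X ~ Hypergeom(N, K, n), BH-corrected
across sets. The background universe is a required argument — no
default is guessed, because enrichment p-values are meaningless without
a stated background. The exact test is conservative when the overlap
distribution has coarse support (small sets or small target lists); the
uniformity property test therefore uses sizes with near-continuous
support. A set-intersection utility covers the usual
"consensus of several target-prediction tools" step that precedes
enrichment.

## Synthetic data generator

The generator defines the study conditions under which the pipeline's
guarantees are tested.

* **Precursors** are built as `arm + loop + revcomp(arm)` with ≤ 2
  planted point changes on the far arm (arm 28–38 nt, loop 8–12 nt,
  total 60–90 nt), so folding recovers a stem-loop. The mature region
  (20–23 nt) sits inside one arm with a ≥ 4 nt margin from the
  molecule's outer end, leaving room for every ±4 isomiR window. Mature
  lengths are drawn from the 20–23 nt slice of `read_length_weights`
  (renormalized).
* **Reads**: per read, a mature arm is chosen uniformly, end offsets
  are drawn independently per end from `isomir_offset_probs` (a single
  mapping for both ends, or a `(five_prime, three_prime)` pair), and
  the read is the corresponding precursor window, with one substitution
  planted at `mismatch_rate`. The read length therefore *emerges* as
  mature length + offsets; with the default length weights (peak 0.38
  at 22 nt) and offset mass 0.55 at 0 per end, the modal read length is
  22 nt, matching the canonical small-RNA length peak. Offsets are
  drawn first (rather than read length first) so that a degenerate
  offset distribution yields exactly canonical reads — the two
  parameterizations cannot both be primary. Ground truth (precursor,
  mature id, offsets, mismatches) is written into the FASTQ comment, so
  quantification can be scored with no side files. Quality strings are
  constant `'I'`; quality is never used downstream.
* **Counts**: `counts[i, s] ~ Poisson(mean_i,tissue(s))` — Poisson, not
  negative binomial, matching the exact test's sampling model for
  pooled (replicate-free) libraries; overdispersion is deliberately not
  simulated. Gradient miRNAs multiply (up) or divide (down) the
  baseline mean by `gradient_step` at each tissue step; the defaults
  are `baseline_mean=100`, `gradient_step=2` (the minimum change the
  calling thresholds target; recovery benchmarks use step 4). Library
  sizes are the realized column totals, so normalization is exact; an
  optional per-tissue `depth_factors` mapping tilts sequencing depth to
  exercise unequal-library normalization. Note the generator reproduces
  compositional bias: planted gradients change the library totals, so
  constant-count miRNAs shift in CPM — a property of real pooled
  designs, not an artifact.
* **qPCR**: expected Ct = `base_ct − log2(expected expression)` (one
  cycle per doubling; `base_ct=30`), U6 constant at Ct 18, independent
  Gaussian noise of `noise_sd` cycles per replicate well (default 0.1,
  a typical triplicate SD for strong signals).

What the generator does **not** emulate — and hence what passing tests
do not certify on real data: sequencing error beyond uniform
substitutions, adapter artifacts, quality-score structure, biological
overdispersion between patients, multi-mapping across paralogous miRNA
families, and cross-mapping between miRNAs and other ncRNA classes.

## Determinism and numerics

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical FASTQ,
TSV and JSON outputs (asserted by tests). The exact-test tails are
computed via scipy's binomial cdf/sf in log space (no overflow at large
counts); BH uses `scipy.stats.false_discovery_control` and is checked
against a literal step-up implementation. Degenerate inputs resolve
explicitly: zero library sizes, empty reads, empty profiles, empty
gene-set universes and out-of-range Ct values raise `ValueError`;
all-zero count columns get library size 1 in the generator so
downstream normalization stays defined.

## Problem sizes used by the checks

The FDR-control check runs 50 replicates of 2,000 miRNAs (two
equal-size libraries, Poisson mean 100); gradient recovery runs 50
replicates of 200 miRNAs (10 up, 10 down, step 4, baseline 100); the
generator/quantifier round trip uses 100 precursors × 5,000 reads; the
oracle-equivalence grids cover all count pairs ≤ 50, sequences ≤ 14 nt,
1,000 random read/window pairs, and hypergeometric parameters with
N ≤ 30. These sizes make the whole suite run in well under a minute
while keeping every binomial confidence interval far from the asserted
thresholds.
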