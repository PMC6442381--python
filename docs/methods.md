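# Methods

This note documents the models, conventions and design choices behind
`cpgmpra`, in the spirit of the methods documentation of packages like
statsmodels or msprime: enough detail to know exactly what is computed,
what the defaults mean, and where the simulator stops being realistic.

## Sequence statistics

Normalized CpG density is the observed/expected ratio
`OE = (n_CpG / (n_C · n_G)) · L` over the full given region; CpG sites
are counted on the forward strand (the site is strand-symmetric), and
coordinates are 0-based half-open throughout. When a sequence contains
no C or no G the expected count degenerates; we return OE = 0, reading
"no CpG structure possible" rather than raising. The CGI call combines
three gates: length ≥ 200 bp, G+C strictly > 0.5 (the definition says
"more than 50 %"), OE ≥ 0.6 (inclusive, "at least"). Sequences are
uppercased on ingest and restricted to A/C/G/T — designed reporter
constructs never contain ambiguity codes, so N is rejected rather than
silently skipped.

## Library design

All five strategies are substitution-only: a construct always has its
parent's length, so downstream distance matching needs no alignment. A
CpG is *mutable* when its 2-bp interval does not intersect any motif
annotation flagged as ChIP-supported (`bound=True`); unsupported motif
predictions do not protect their CpGs. Design conventions:

* **Window combinations** enumerate all 2^k WT/mutant window states;
  the all-WT state reproduces the parent byte-for-byte.
* **Density series** retain `round(p · n_mutable)` CpGs per retention
  fraction `p`, rounding half away from zero so that the intent of
  "75 / 50 / 25 %" series is preserved at small n (e.g. 65.7 % of 35
  mutable CpGs keeps 23 and mutates 12). The retained subset is
  re-randomized per density level.
* **Random CpG-free replacements** (motif mutations, tiling, add-back
  baselines) are sampled base-by-base, excluding G after any C and
  excluding C before a junction G. This guarantees CG-freeness at any
  length, including across both junctions, at the cost of a slight
  compositional bias (G is mildly under-represented after C); each
  construct exposes its achieved GC so composition drift is auditable.
* **Motif mutations** draw their replacement from an RNG stream keyed
  by the motif interval, so the same motif receives the same scramble
  in its single-motif and all-motifs constructs (and a TF with one
  motif yields two identical sequences, as expected). An optional
  scoring callback resamples until the replacement's motif log-odds is
  negative, guaranteeing destruction.
* **Add-back** pins `CA` at every WT CpG position inside the replaced
  blocks, so re-introducing a CpG is the single substitution A→G at
  the G position. Add-back subsets are nested across increasing
  counts. Together these make the OE of the series strictly increasing
  in the add-back count (the CpG numerator rises by one per site while
  n_C stays constant), turning a statistically-likely property into a
  guaranteed one.

Barcodes follow the degenerate pattern `NNNNWNNNNWNNNNN`
(W ∈ {A, T}; space 4^13 · 2^2 ≈ 2.7 × 10^8) with a default minimum
pairwise Hamming distance of 3, so a single sequencing error cannot
convert one barcode into another.

## Read assignment

Reads are matched to references by total mismatch (Hamming) count over
the pair — the substitution-only library design makes indel-aware
alignment unnecessary, and a distance matcher has no mismatch ceiling,
which matters for long reads with degraded ends. Assignment requires,
with best/second-best distances d1 ≤ d2:

1. d1 ≤ 0.20 × (total sequenced bases) — the error budget;
2. d2 ≥ 3 — the second-closest reference must be at least the margin
   away (read as an absolute distance; the alternative gap reading
   d2 − d1 ≥ margin is available via `margin_is_gap`);
3. d1 < d2 — exact ties are ambiguous and rejected.

Failing reads become `UNASSIGNED`, a value rather than an error, so
ambiguity can never create phantom counts. An edit-distance mode
(edlib) exists for inputs with indels but is off by default. Barcode
purity: after tallying (barcode, reference) associations over reads, a
barcode is kept only if it has a single association or the second-most
frequent one is below 0.3 of the top (computed on read counts); a kept
barcode always maps to its modal reference.

## Activity quantification

Per replicate, DNA and RNA libraries are scaled to the smaller total
(replicates are treated as independent sequencing runs and scaled
pairwise). Barcodes need a scaled DNA count strictly above 20 reads; a
DNA-passing barcode absent from RNA is transcriptionally silent and
enters with RNA count 0, not as missing data. Barcode enrichment is
`n_r/n_d + α` with α = 0.05, and a promoter's log2 activity is the
mean of its barcodes' log2 enrichments, requiring ≥ 3 barcodes by
default (configurable down to 1 for low-coverage libraries). The
pseudocount floors every activity at log2 α ≈ −4.32; a fully silent
promoter sits exactly on the floor. α is configurable, and
`alpha_variance_profile` reports the mean within-promoter variance of
barcode log2 enrichments across candidate α so users can repeat the
selection procedure (smallest α that roughly stabilizes the variance).
If the entire RNA library is empty, scaling is skipped and every
barcode lands on the floor. Replicates aggregate as unweighted mean
with sample SD (n − 1); relative activities subtract the reference
construct per replicate before aggregating.

## Permutation statistics

Spearman's ρ is the Pearson correlation of mid-ranks (average ranks on
ties), computed by composing rank transformation with a normalized dot
product; scipy's independent implementation serves as a cross-check in
the test suite, not as the implementation. The approximate test
permutes y (permuting one margin suffices under exchangeability) and
uses the +1-corrected two-sided p-value
`(1 + #{|ρ*| ≥ |ρ|}) / (1 + n_perm)`, which is valid at any n_perm and
never 0. The exact test enumerates all n! permutations (bound n ≤ 9 by
default) and reports the raw proportion, which includes the identity
permutation and is therefore also never 0. Two-sidedness on |ρ| is the
default; `greater`/`less` are available. For replicated experiments,
ρ is computed per replicate and reported as mean ± SD; significance
pools the per-replicate permutation distributions by averaging ρ
across replicates within each permutation index.

## Binding prediction

Motif scores are log2 log-odds against a uniform background,
`Σ_i log2(p_i(base)/0.25)`, maximized over all offsets and both
strands (motifs are directional; both-strand max is the standard
window summary). PWM cells are floored at 1e-3 and renormalized so
scores are finite. Windows are non-overlapping 600-nt tiles with the
trailing remainder dropped; a window is bound when its ChIP log2
enrichment over input strictly exceeds 2.5. Subset summaries use best
score ≥ 12 for "contains a motif" and OE ≥ 0.6 for the density gate.
The additive logistic model `P(bound) = σ(a + b·score + c·OE)` is fit
by maximum likelihood (convex, hence deterministic) in natural units —
no feature scaling, so coefficients read directly as log-odds per
score unit and per OE unit. Complete separation triggers a warning and
a lightly L2-regularized fallback. PR curves evaluate 100 equally
spaced cutoffs from min to max of the score, with
precision = bound-and-above / above and recall = bound-and-above /
all-bound; at the minimum cutoff recall is 1 and precision equals the
prevalence. PR area integrates precision over recall by trapezoid.

## Methylation

Promoter methylation is the unweighted mean of per-CpG methylation
fractions over CpGs meeting the coverage threshold (default 1 read):
each CpG contributes equally regardless of depth. Bisulfite alignment
is upstream of this package; the input is a per-CpG call table.

## The synthetic-data generators

Each generator is a pure function of (config, seed) on numpy PCG64
streams — fixed seed, identical bytes — and returns its ground truth
alongside the data. The defaults describe a small single-locus
reporter study: 20 promoters of 600 bp (400 up / 200 down of the TSS)
spanning OE 0.15–1.1 at GC 0.55, 8 barcodes per construct, 3
replicates, DNA depth 200 reads per barcode, 2 × 300-like read
structure.

* **Promoters**: random sequence at the target GC, steered to the
  target OE by inserting CG at random interior positions or breaking
  random CpGs until within ±0.05, with a bounded iteration count.
* **Activities**: log2 activity = β0 + β_OE·OE + motif effects +
  N(0, σ), defaults β0 = −2, β_OE = 4, σ = 0.25 — a gradual density
  effect spanning ~4 log2 units over the OE range.
* **Counts**: DNA ~ negative binomial (size 5) around depth ×
  barcode abundance (lognormal, σ = 0.25), capturing
  library-bottleneck overdispersion; RNA ~ Poisson with mean
  proportional to 2^activity × the realized DNA count. This is the
  simplest structure under which the α-pseudocount estimator behaves
  as designed.
* **Reads**: i.i.d. substitutions at rate ε ≤ 0.1 over both reads; no
  indels, no quality-dependent error profile, no PCR chimeras.
* **Binding windows**: motif scores from a two-component mixture (75 %
  exponential background, 25 % motif class at 14 ± 3), OE from the
  bimodal promoter-density mixture, bound ~ Bernoulli of the additive
  logistic with defaults (a, b, c) = (−6, 0.4, 4); ChIP enrichments
  from bound/unbound normals (4.0 ± 0.7 vs 0.5 ± 0.7) so the 2.5 gate
  reproduces labels ≈ 99 % of the time (the realized consistency is
  reported per data set).
* **Methylation**: per-CpG probability σ(2 − 5·OE), binomial counts at
  Poisson coverage 30 — dense-CpG constructs unmethylated, sparse ones
  methylated.

What passing tests on these data do **not** show: robustness to
quality-correlated or indel errors, to GC-dependent amplification
bias, to barcode bottlenecking between DNA and RNA, or to the genomic
context effects a real integration locus adds. The generators verify
the estimators' correctness under their stated models, not the models'
fidelity to any particular instrument.

## Problem sizes and numerical conventions

The test and acceptance workloads use 20 promoters × 8 barcodes × 3
replicates for quantification recovery, 10,000 read pairs for
assignment, 20,000 windows for the logistic fit and PR comparisons,
and 1,000 null data sets (n = 30, 999 permutations each) for
type-I-error calibration — sizes at which the Monte-Carlo error of
each check is comfortably below its tolerance. Permutation machinery
is vectorized (ranks computed once; permuted rank matrices hit a
matrix product), which keeps the calibration run in seconds.
Tie-breaks: exact distance ties in assignment reject the read;
rank ties use mid-ranks; PR cutoffs include both endpoints of the
score range. Degenerate inputs (empty sequences, constant vectors,
zero-total libraries, windows shorter than the motif) raise early with
specific messages, except where the field convention is a defined
value (OE of a C-free sequence is 0; a motif that does not fit scores
−∞; an all-silent RNA library floors at log2 α).
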