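# Methods

## Scope and data model

The package operates on three objects: a gene × sample matrix of raw
integer counts with a group label per sample (strain × age × cell
population), per-animal behavioral battery tables for one age cohort, and
plain-text gene lists over a stated background universe. All gene
identifiers are compared case-insensitively (mouse symbol capitalization is
inconsistent across sources, e.g. ApoE/Apoe) with the first-seen spelling
preserved for output; duplicates after normalization are dropped with a
logged count rather than an error.

## Expression processing

CPM normalization divides each count by its sample's library size and
multiplies by 10⁶, so every retained-gene column sums to one million. The
highly-expressed filter computes within-group mean CPM per gene, takes the
maximum over groups, and keeps genes with log₂(max + 1) strictly greater
than the threshold (default 4, the microglia convention; 5 for macrophages).
"Group" here means every distinct sample label present, so the filter's
universe depends on the grouping supplied. Genes with zero counts in all
samples are rejected at container construction.

Differential calling is a deliberately transparent stand-in for a
negative-binomial GLM tool: per gene, a Welch (unequal-variance) t-test on
log₂(CPM+1) across the two groups, BH step-up adjustment within the supplied
universe, and a fold-change gate computed on group-mean CPM with a
pseudocount of 1 on both numerator and denominator (avoids division by zero;
the choice of pseudocount only matters for very low-expressed genes, which
the filter removes). A gene is flagged only if it passes the fold gate
(strictly, in either direction) and every supplied significance gate (raw p
and/or BH q, strict). Genes constant in both groups get p = 1. With n = 4
vs 4 samples the Welch test is conservative relative to a count-model test;
calibration under a simulated global null is part of the acceptance suite,
but published gene counts obtained with other tools are not reproducible by
this stand-in and are not targets. Externally produced DE tables (gene,
direction, significance) can be substituted wherever a DE table is consumed.

## Overlap statistics

Overlap of two gene sets of sizes K and n on a background of size N with
observed intersection k is summarized by expected = K·n/N, enrichment =
k/expected, and exact hypergeometric tails. The upper tail includes the
observed value, P(X ≥ k), the standard over-representation convention; the
lower tail is P(X ≤ k), so P(X ≥ k) + P(X ≤ k−1) = 1. The pmf is evaluated
in log-space through log-gamma binomial coefficients and summed with
logsumexp — naive factorials overflow at N ≈ 7,000-gene backgrounds. The
implementation is verified against exhaustive enumeration of all C(N, n)
draws for every parameter combination with N ≤ 15 and against an
independent distribution implementation at study scale.

At the study-scale configuration N = 7076, K = 256, n = 214, k = 18 the
exact upper tail is 7.07 × 10⁻⁴. Published analyses of this configuration
have quoted smaller bounds; since the overlap count and tail convention
behind such bounds are not always stated, the package reports its exact
value and makes no attempt to match quoted bounds.

Sets whose members fall outside the common background are restricted to it
with a logged count. The 2×2 enrichment panel (up/down × reference
over/under) refuses inputs where a gene is simultaneously up- and
down-regulated. The combined DAM signature is the union over models of
reference genes differential in that model, annotated with each model's
direction; identifiers unresolvable in any DE table are logged, not fatal.

## Behavior and expression scoring

Within one age cohort, each subtest is ranked with 1 = most normal given the
subtest's abnormality direction; ties receive midranks so the rank sum is
always n(n+1)/2, and missing measurements are excluded from the ranking and
propagate as missing. Default directions: water-maze escape latency higher =
abnormal; fear-conditioning freezing (context and cue) lower = abnormal;
%PPI higher = abnormal (an elevated prepulse-inhibition ratio reflects
failure to adapt to the stimulus); rotarod time before drop lower =
abnormal. All directions are configurable. Per test, subtest ranks are
averaged — weighting each test equally regardless of its subtest count — and
the four per-test averages are summed, giving [T, T·n] bounds ([4, 32] for
T = 4 tests, n = 8 animals). An animal missing an entire test gets a missing
score rather than a biased partial sum. Because the score is rank-based, it
is invariant under any strictly monotone transform of a subtest's raw
measurements.

The expression score min-max-normalizes each signature gene to [0, 1] across
the cohort's samples and sums over genes, giving [0, G]. Min-max
normalization is computed within each age cohort separately (cohorts are
scored and ranked independently). A gene constant across the cohort has no
ordering information; it contributes 0 and is counted in `genes_dropped`
so the effective G is visible. The score is invariant under per-gene affine
rescaling of expression, hence insensitive to gene-level scale differences.

Scores are correlated by Pearson product-moment R with a two-sided p from
the t-distribution on n − 2 degrees of freedom, requiring ≥ 3 complete pairs
and nonzero variance in both scores. Group comparisons use the Mann-Whitney
test: for combined n ≤ 20 the two-sided p is computed by full enumeration of
all C(n, n_a) labelings of the pooled midranks — exact under ties — with
p = P(|ranksum − mean| ≥ |observed − mean|); larger samples fall back to the
tie-corrected normal approximation. The fully separated 4 vs 4 case yields
2/70 ≈ 0.0286, the smallest attainable two-sided value at that size.

## Synthetic cohort generator

The generator emulates one age cohort of a two-strain study arm: 4 control
and 4 case animals (the size of the RNA-seq arm the pipeline is designed
around), each with a latent severity s ∈ [0, 1]. Controls draw |N(0, 0.05)|
(near-healthy but not exactly 0, avoiding degenerate all-tied ranks); cases
draw Beta(5, 2) (mean ≈ 0.71, realistic spread of disease burden).

Behavioral subtests are Gaussian around baseline + effect·s, truncated to
the subtest's physical range (water-maze latency capped at the 60 s search
limit, percentages at [0, 100], gait symmetry near 1). Defaults mirror the
phenotype of lupus-prone strains: latency effects of +20…30 s, context
freezing −25%, %PPI at 12 kHz +30% with 4/20 kHz unaffected, rotarod −60 s;
fear-conditioning cue, Y-maze alternation, zero-maze open time, open-field
distance and gait symmetry have zero effect (deficits absent in the
emulated phenotype) but remain in the battery as realistic null subtests.
Noise SDs are set to roughly a quarter to a half of the effect at full
severity, so group differences are detectable but not trivial at n = 4.

Counts follow a gamma-Poisson (negative binomial) model: per-gene relative
abundances are log-normal(0, 1.5) normalized to sum to 1, library sizes
log-normal with mean 10⁶ and CV 0.2 (a 3'-tag–scale library), and variance
μ + φμ² with dispersion φ = 0.1. The planted signature (default 18 genes,
named `sig###` so recovery is checkable) is multiplied by 2^(coupling·s),
coupling defaulting to 1.5 log₂-fold per unit severity — an effect at the
upper end of what a 4 vs 4 design detects, so with default settings only
part of the signature is recovered, as in real data. The Y-maze is modeled
at the arm-entry level: the mouse never re-enters its current arm, making a
uniformly random choice between the two remaining arms a 50% alternation
null exactly (the probability that the third arm differs from both previous
is 1/2); forced policies give 0% and 100%.

What the generator does not emulate: gene-gene correlation structure,
compositional shifts from the signature genes (18 of 2000 genes is
negligible), batch effects, sample dropout/QC exclusions, repeated-measure
time courses within a test, and any per-gene parameters of real datasets.
Passing tests therefore demonstrate the pipeline's statistical machinery and
its recovery behavior under a faithful-but-idealized generative model, not
agreement with any particular real dataset.

## Pipeline and numerical choices

The end-to-end runner derives the second model cohort from the single
config seed by a fixed offset, so one seed determines the whole run;
artifacts (counts, behavior, DE tables, signature list, scores, run report)
are written per stage, and a stage failure leaves a FAILED marker naming the
stage. The run report reconciles stage counts (background ≥ upregulated ≥
signature size = overlap k).

Problem sizes used in the validation suite — 2,000 genes for FDR
calibration, 200–500 replicate cohorts of 300–400 genes for recovery and
null-uniformity checks, 10,000 Monte-Carlo draws for the alternation and
chance-enrichment nulls — were chosen so each property is measured with
comfortable Monte-Carlo margins while the whole suite stays quick on a
laptop. Monte-Carlo assertions use three standard errors of the simulated
estimate.

## Known limitations

- The Welch-on-log-CPM stand-in has lower power than count-model tests at
  n = 4 and ignores mean-variance shrinkage; it is calibrated, not powerful.
- Exact Mann-Whitney enumeration grows as C(n, n_a); the cutoff of 20 keeps
  it under ~2·10⁵ labelings.
- The behavior score assumes one cohort per battery table; cross-cohort
  pooling must be done by scoring cohorts separately.
- Min-max expression scores depend on cohort extremes and are not comparable
  across cohorts in absolute terms; only their within-cohort correlation
  with behavior is meaningful.
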