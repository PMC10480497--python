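# Methods

This note records the models, conventions and numerical choices behind
`cellrep`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Normalization to nTPM

The pipeline starts from gene-level TPM (or counts). `to_ptpm` restricts to
a protein-coding gene list and rescales each sample to sum 10⁶; a sample
with zero coding expression is a hard error naming the sample.

TMM factors are computed against a reference sample. "Median column" is
interpreted as: compute each sample's upper quartile over its positive
values and take the sample whose statistic is the (lower) median across
samples, ties to the lexicographically smallest ID. The concept admits more
than one formalization; this one is deterministic and matches the common
implementation family.

For sample *k* vs reference *r*, genes positive in both contribute
`M = log2(x_k/x_r)` and `A = ½·log2(x_k·x_r/10¹²)` (the pTPM unit implies a
pseudo-library of 10⁶). Trimming is rank-based and two-sided: with *n*
genes and trim fraction *t*, ranks outside `[floor(nt)+1, n−floor(nt)]` are
discarded, on M (default 0.30) and A (default 0.05) independently; a gene
must survive both. Fewer than 10 survivors triggers a logged fallback to
the untrimmed set. Weights are the inverse delta-method binomial variance
`1/[(N−x_k)/(N x_k) + (N−x_r)/(N x_r)]` with `N = 10⁶` when weighting is on
(default), else uniform. Factors are rescaled to geometric mean 1, so the
reference choice only fixes a global constant; this rescaling convention is
recorded in the matrix metadata contract rather than assumed.

Two properties worth knowing:

* With **uniform weights and a pinned reference**, re-running TMM on the
  normalized output returns factors of exactly 1 (the uniform shift of M and
  A preserves the trim sets). With inverse-variance weighting the weights
  change after rescaling and the fixed point is only approximate (within a
  few percent on near-proportional data); the test suite pins both
  behaviors.
* A single strongly shifted gene among many is trimmed away entirely at the
  default 30% trim; composition shifts only move the factor when they carry
  enough rank mass to reach the trimmed middle.

For activity scoring, counts are normalized by median-of-ratios size
factors (per gene positive in all samples: geometric mean across samples;
per sample: median count/geomean ratio, unrescaled), then transformed as
`log2(count/sf + 1)` and centered per gene. The log2(x+1) transform stands
in for a variance-stabilizing transformation; it preserves the centered
linear-model contract (every row sums to zero) which is all the downstream
scorers require.

## Gene classification

Detection means nTPM ≥ 1 — the boundary counts as detected, the only
assignment that covers "above cut-off" and "less than 1" consistently.

Distribution categories per gene across individual samples, with *n*
samples and *k* detected: 0 → not-detected; 1 → single; *k* = *n* → all;
1 < *k* < *n*/3 → some; *n*/3 ≤ *k* < *n* → many. The *n*/3 comparisons are
on real numbers, counts are exact.

Specificity categories are evaluated over CLD (per-disease mean) profiles
in strict precedence order — enriched, group-enriched, enhanced,
low-specificity, not-detected — because the lower categories are defined by
not qualifying for the higher ones. Conventions fixed here:

* Fold boundary is inclusive (≥ 4).
* Every defining group must itself be detected (≥ 1 nTPM); a gene is never
  called elevated on sub-cutoff expression.
* Ratio denominators are clamped below at 0.01 nTPM, so zero outside
  expression gives a large finite fold.
* The group-enriched search sorts groups by descending expression and grows
  the candidate set from the top, accepting the smallest set (2–10 groups,
  at least one group outside) whose **mean** is ≥ 4× the outside maximum.
  For a fixed set size the top-expression prefix simultaneously maximizes
  the mean and minimizes the outside maximum, so the greedy verdict equals
  the exhaustive-subset verdict; the test suite checks this equivalence
  against a brute-force oracle on random matrices.
* The group-mean reading is the default; a stricter per-member reading
  (weakest member ≥ 4× outside) is available via `require_each_member`.
  Note the readings genuinely differ: `[10, 4, 1]` is group-enriched under
  the group-mean rule (mean 7 ≥ 4×1) even though the weaker member sits
  exactly at the boundary.

Stage signatures reuse the same machinery at the cohort level: a gene
belongs to a stage's signature iff its stage mean is ≥ 4× every other stage
mean (clamped) and ≥ 1 nTPM; at least two stages are required.

## Comparison machinery

Tumor samples are kept only when purity strictly exceeds 0.7 — the boundary
sample counts as infiltrated and is removed; the threshold is configurable.

Overlap tests use the one-sided hypergeometric tail P(X ≥ overlap) with the
universe supplied by the caller (default: the shared protein-coding list);
multiple tests are corrected by Benjamini-Hochberg step-up. BH is monotone
and bounded by 1 but **not** idempotent on arbitrary adjusted vectors (the
step-up multipliers re-inflate small leading entries); only constant
adjusted vectors are fixed points.

Spearman correlations average tied ranks. The matched-vs-unmatched cohort
test is a one-sided Wilcoxon signed-rank of (unmatched ρ − matched ρ)
against zero: exact distribution for n ≤ 25 without ties, normal
approximation with continuity correction otherwise. With *u* unmatched
cohorts the exact one-sided p is floor-limited at 2⁻ᵘ, so panels with fewer
than five cohorts cannot reach 0.05 no matter how clean the separation —
the tests assert attainment of the floor instead.

CLD clustering is complete-linkage agglomeration on D = 1 − ρ; constant
columns are rejected (undefined correlation), and dendrograms serialize to
Newick. The cross-panel identity check z-scores genes, takes the smallest
number of principal components reaching 80% cumulative variance, and asks
whether each left-panel sample's Euclidean first neighbor among the
right-panel samples is its declared counterpart.

## Prioritization

The disease baseline is the unweighted mean over CLD mean profiles — not
over cell lines — so small diseases are not swamped. Fold changes use a
pseudocount of 1 on both numerator and denominator (conventional on the
nTPM scale and configurable); the ranking sorts descending with gene-ID
tie-breaks for determinism.

Preranked GSEA: hit increments proportional to |stat|^w (default w = 1,
normalized to sum 1 over hits; an all-zero hit set falls back to uniform
increments), miss decrement 1/(n − m), ES the signed maximal deviation. The
null permutes gene labels — random same-size gene sets, the only
permutation a single ranked list admits. NES = ES / mean(|null ES| of the
matching sign); p = (1 + #{same-sign nulls ≥ |ES|})/(1 + #same-sign nulls).
The +1 smoothing and sign conditioning make the p-values slightly
conservative (stochastically a little larger than uniform), which the null
self-consistency test accounts for. Default 1,000 permutations for pipeline
runs; the oracle tests use more.

Rank integration: descending ranks on ρ and on NES (average ranks for
ties), combined score the mean of the two, final order ascending by
combined score with ties broken by higher ρ then lexicographic ID; the top
5 plus exact combined-score ties with the fifth are selected. The whole
integration depends only on ranks, so any strictly monotone transform of
either metric leaves the result unchanged.

Stage/subtype prioritization repeats the same per label with the label's
mean profile and fourfold signature; a label with an empty signature falls
back to a correlation-only ranking with a warning.

## Activity inference

All scorers consume per-gene-centered log2 expression and a
gene-by-signature weight matrix (zero = not in signature, at least 3
nonzero weights per signature).

* **ulm** — per (sample, signature) simple regression of the sample's
  expression on the signature's weights; score = slope t (df = genes − 2).
  Numerically perfect fits cap |t| at 10⁶.
* **mlm** — one regression per sample with all signatures plus intercept;
  scores = partial t (df = genes − signatures − 1); rank-deficient weight
  matrices are rejected with the collinear pairs named.
* **wsum** — raw weighted sum with a gene-label permutation z-score (one
  shared gene permutation per iteration; per-sample marginals are
  unaffected by the sharing). Zero null sd yields z = 0 with a warning.

Consensus: each method standardized per signature across samples (methods
contributing zero variance are dropped for that signature, logged), then
averaged; |z| > 1 is significant. This is the simplest construction
honoring the z-scale contract; other aggregations would be monotone
rearrangements of the same information.

The cytokine-style scorer solves (WᵀW + λI)b = Wᵀx per sample with
λ = 10⁴ by default; the permutation null re-solves under gene-label
permutations; z = (b − null mean)/null sd and a two-sided permutation p
with +1 smoothing; p < 0.05 significant. Because λ rescales all
coefficients nearly uniformly at these dimensions, rankings are stable over
at least a 10× λ range (tested) — the specific default matters less than
its order of magnitude.

MSE matching averages squared activity differences over shared signatures
per sample pair; prioritization by MSE ranks ascending on pathway and
cytokine MSE separately, averages the ranks, and breaks ties by lower
pathway MSE then ID.

## The synthetic-data generator

The generator emulates a multi-disease cell-line panel with the structure
the classifier is meant to find, at desk scale: 8 diseases × 6 lines,
2,000 genes, baseline 20 nTPM, planted fold 8 (twice the classification
threshold), NB dispersion 0.1, library size 10⁷ expected counts.

* **Planted categories.** Enriched genes: fold × baseline in one disease.
  Group-enriched: fold × baseline across a small disease group (cyclic
  pairs by default). Enhanced genes need care: the elevated disease sits at
  `a = 4.6×` the mean of the others while one partner disease is raised to
  `b = a/3.5`, which keeps the gene below the enriched rule (a/b < 4),
  below the group-enriched rule (top-2 mean < 4× the rest) and above the
  enhanced rule with ≥ 10% margin on every check. These margins only close
  for panels of at least four diseases, so enhanced planting requires
  `n_diseases ≥ 4`.
* **Mass budget.** Housekeeping genes (10% of the panel) are drawn at
  50–500× baseline so columns carry roughly the 10⁶ mass the pTPM unit
  implies; without that, the pTPM rescale would inflate sub-cutoff genes
  past the detection boundary and the planted "not-detected" class would
  dissolve. Background genes are either clearly detected (5–200 nTPM) or
  clearly below cutoff (≤ 0.2 nTPM); margins on both sides of the
  detection boundary are what make exact recovery possible at all.
* **Best-line structure.** Each disease's first line is the designated best
  line: expected profile equal to the disease mean. Every other line gets
  (i) log2-normal jitter (sd 0.4) on detected background genes — degrading
  its rank correlation to the cohort, (ii) a mild uniform attenuation of
  its planted folds, and (iii) a small line-specific fraction (5–15%) of
  its elevated genes dropped back to baseline — degrading its enrichment
  score. The dropout is the mechanism that separates lines for GSEA: a
  uniform attenuation cancels in the hit-weight normalization and barely
  moves ES. Dropouts per gene are capped at ⌊(L−1)/2⌋ lines so the
  worst-case disease mean stays above 4.3× baseline at fold 8, preserving
  exact classification recovery at dispersion 0. Sub-cutoff genes are never
  jittered, for the same reason.
* **Counts.** Negative binomial via gamma-Poisson with var = μ + φμ²;
  φ = 0 degenerates to Poisson. At the default library size, Poisson noise
  on disease means is ~1–3%, far inside the planted margins — this is why
  "dispersion 0" recovery is exact rather than merely likely.
* **Cohorts.** One per disease, sharing the disease mean profile (hence its
  elevated genes); one stage per cohort carries an extra 5× signature on
  background genes (recoverable exactly at dispersion 0 by the fourfold
  rule). Purity is drawn uniformly in the configured range and is
  annotation-only — the generator does not emulate stromal/immune
  contamination of the expression itself, so the purity filter is exercised
  as bookkeeping, not as a signal-recovery step.
* **Signatures.** Random gene subsets with Gaussian weights, Gaussian
  planted activities, expression = W·Aᵀ + noise, centered per gene.

What passing on this generator shows — and what it does not: recovery
results demonstrate that the implementation of each rule is correct and
that the pipeline composes correctly end to end (normalization preserves
the planted folds, the classifier finds them, the prioritizer finds the
planted best line). They do not demonstrate robustness to batch effects,
annotation errors, compositional shifts from a few extreme genes, or
contamination — real-data phenomena the generator deliberately omits.

All randomness flows from one integer seed with deterministically derived
per-matrix sub-streams; identical configs serialize byte-identically.

## Problem sizes

The test suite and the acceptance script run at deliberately small scale:
panels of 4–8 diseases with 700–2,000 genes, cohorts of 9–20 samples,
1,000 GSEA permutations in pipeline runs (10,000 where the permutation null
itself is under test), 40 seeded panels for the rank-recovery rate. These
sizes put every Monte-Carlo estimate well inside its tolerance while
keeping a full run in minutes on one CPU.

## Known limitations

* The TMM reference rule and the factor rescaling convention are documented
  choices among several in circulation; factors from other implementations
  can differ by a global constant or by tie handling.
* The variance-stabilizing transform is approximated by log2(x/sf + 1).
* GSEA p-values are permutation-based and conservative by construction; no
  multilevel/analytic refinement is attempted.
* The consensus aggregation (standardize per signature, average) is one of
  several defensible conventions; significance calls at |z| > 1 inherit it.
* Whether cytokine z-scores should be additionally centered across samples
  before MSE comparison is left to the caller; `activity_mse` compares the
  tables as given.
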