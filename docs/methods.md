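# Methods

This note documents the models, estimators, and numerical choices behind
`cgsig`, and what the synthetic cohorts do and do not establish about real
data.

## Segmentation (CBS)

Each chromosome's ordered marker log ratios are treated as a circular
sequence. For every contiguous arc `x[i:j]` (minimum 2 markers on each
side), a two-sample t statistic with pooled variance compares the arc mean
with the complement mean; wrap-around arcs are complements of contiguous
ones and share the same |t|, so contiguous enumeration covers the circle.
The maximizing arc is tested by permuting marker order within the tested
stretch and recomputing the max-|t|; the p-value uses the `(b+1)/(B+1)`
estimator and a split is accepted at `p ≤ α` (defaults `α = 0.01`,
`B = 1000`). Accepted change points are recursed on both sides.

Numerical choices:

* Ties in max-|t| (the complement pair always ties exactly) are broken
  toward the lexicographically smallest `(i, j)` under a relative tolerance
  of 1e-9, so the search is deterministic and matches an exhaustive oracle.
* Permutations are drawn in chunks with early termination as soon as the
  exceedance count makes `p ≤ α` unreachable; the reported p-value is then a
  conservative estimate from the permutations drawn. This leaves
  accept/reject decisions identical to the full-B test.
* The arc search is exhaustive up to 1,000 markers per stretch; longer
  stretches are scanned on a uniformly sampled subset of arc lengths with
  local exhaustive refinement of the winning boundary (a fast hybrid).
* RNG substreams are derived per (sample, chromosome) from the root seed, so
  chromosomes can be re-segmented independently and reproducibly.
* Segments inherit exact marker means, so the marker-count-weighted segment
  means reproduce per-chromosome marker means to 1e-9 by construction.

`merge_levels` then repeatedly merges the pair of segment levels whose
member marker values are least distinguishable by a two-sided
Mann–Whitney rank-sum test, while that p-value exceeds `merge_p = 1e-4`;
merged levels take the pooled mean, and adjacent equal-mean segments
collapse into one.

## CNV calling

The per-array noise scale is the plain (unscaled) median absolute deviation
of the raw marker log ratios; no 1.4826 consistency factor is applied
because the calling thresholds are expressed directly as MAD multiples:
amplification above `+5·MAD`, homozygous deletion below `−5·MAD`
(symmetric default), gain/loss beyond `±1.1·MAD`, neutral otherwise.
Two alternatives are exposed: `mad_on="residual"` computes the MAD on
residuals from segment means (a purer noise estimate for heavily aberrant
genomes), and `homdel_mode="ratio"` places the deletion cut at
`log2(0.2) ≈ −2.32`, the literal copy-ratio reading of a "0.2 times"
threshold. A MAD of zero raises an error rather than producing degenerate
calls.

## Recurrence (G-scores)

For gains (losses analogously), each marker's G-score sums `|seg_mean|`
over the samples whose call at that marker is gain or amplification — the
frequency × amplitude form. The null preserves within-sample segmental
autocorrelation by applying an independent uniform cyclic shift to each
sample's marker-level contribution vector; when the number of shift
combinations is at most `n_resamples` the null is enumerated exhaustively,
otherwise shifts are sampled and the identity shift is pooled in so p-values
stay positive. Per-marker p is the fraction of the pooled null (markers ×
resamples) at or above the observed score; Benjamini–Hochberg q-values are
computed over markers, and significant markers are grouped into maximal runs
reported with their peak marker. Marker-level (rather than segment-level)
shifting is a modelling choice; the shift unit is the marker grid, which
keeps the null exchangeable across markers.

## Concurrency

The gene-centric table assigns each gene, per sample, the segmentation mean
of the segment with maximal base-pair overlap (a single sourced value per
cell rather than a length-weighted blend; cells without coverage are
missing). Spearman's ρ with midrank ties is computed per gene over complete
pairs; the two-sided p-value is exact by full enumeration for n ≤ 9 pairs
and uses the t approximation otherwise. A gene is *concurrent* iff it
overlaps at least one non-neutral call in at least one sample, `p < α`
(default 0.05, unadjusted — this stage is a screen, not an inference), and
`ρ > 0` (dosage and transcription move in the same direction;
negative-ρ genes are reported but not flagged). Genes with a constant
copy-number or expression row are excluded with a diagnostic.

## Random-variance t-test and permutation screen

Gene-level precisions are modelled as `1/σ² ~ Gamma(shape a, rate a·b)`, so
the pooled variance `s²` with `d = n₁+n₂−2` degrees of freedom is marginally
`b·F(d, 2a)`. `(a, b)` are fitted once across genes by maximizing the
corresponding F likelihood (Nelder–Mead on log-parameters, three starts).
The per-gene statistic uses the shrunken variance
`σ̃² = (d·s² + 2ab)/(d + 2a)` with `d + 2a` degrees of freedom; as `a → 0`
this is the plain pooled t-test (also available as `mode="plain"`). Genes
with zero variance in both classes are reported with `t = 0, p = 1` and a
`degenerate` flag.

The global multivariate permutation test counts genes with `p < α`
(`α = 10⁻³` by default) and compares that count against label permutations —
exhaustive over balanced relabelings when at most 10,000 exist, else
sampled with the `(b+1)/(B+1)` estimator. Group means and variances are
refitted per permutation; the `(a, b)` hyperparameters are fitted once on
the observed labels and reused, since refitting the hyper-likelihood per
permutation is costly and the fit is nearly label-symmetric.

## Classifiers and LOOCV

Five signature classifiers share the same selected-panel interface:
compound covariate predictor (score `Σ t_g x_g`, threshold midway between
class mean scores), diagonal LDA (per-gene pooled variances), 3-nearest
neighbors and nearest centroid (distance `1 − Pearson correlation` by
default, Euclidean by flag; distance ties break by sample order), and a
linear SVM (`C = 1`, per-gene standardized inputs, via scikit-learn).
Leave-one-out cross-validation repeats *gene selection and fitting* inside
every fold; when the stringent screen selects fewer than two genes in a
fold, the two smallest-p genes are used so every fold yields a prediction.
For pooled multi-cohort classification, per-cohort gene mean-centering
(`center_by_cohort`) serves as a fixed additive surrogate for a cross-study
random effect — the estimable desk-scale version of that adjustment.
Consensus signatures are plain intersections, preserving the first list's
order.

## Survival risk model

Univariate Cox screening (Efron tie handling, via lifelines) retains genes
with Wald `p < α` (10⁻³ for concurrent-gene candidates; 0.01 is the
conventional relaxed level when external candidate lists are evaluated with
the same machinery). The selected gene rows are centered and the first
right singular vector of the samples × genes matrix defines the supergene;
its Cox coefficient (sign fixed so higher score ⇒ higher hazard) times the
loadings gives per-gene score coefficients. The calibration constant is a
free intercept anchored so event-free training subjects average a score of
exactly zero — a Cox model has no intercept of its own, and this anchoring
reproduces the convention under which the published model's constant (3.9)
was printed; the published fixture is used verbatim with its batch
coefficient 0.079 and threshold 0.122. Dichotomization uses
linear-interpolation percentiles (50th default, 30th for sensitivity
analysis), with `high risk ⇔ score > threshold`. Evaluation reports the
2×2 relapse table with Pearson χ² (no continuity correction), the log-rank
test over the two groups, and the AUC as the Mann–Whitney probability that
an event case outscores an event-free one.

## Subtyping and receptor mixtures

Single-sample prediction mean-centers genes across the cohort (removing
per-gene systematic shifts across studies) and assigns each sample to the
subtype centroid with the highest Spearman correlation over shared genes
(≥ 20 required); a best correlation below `min_rho = 0.1` leaves the sample
unclassified — the cutoff is configurable because no canonical value
exists. Centroid matrices (e.g. intrinsic-gene centroids) are user-supplied
files, not bundled.

Receptor status is inferred from a designated marker gene by a
two-component Gaussian mixture fitted with EM: 20 restarts initialized at
jittered quartiles, tolerance 1e-8 on the log-likelihood, at most 2,000
iterations, best likelihood kept. Component standard deviations are floored
at 1e-6 of the data spread to avoid variance collapse. Components are
relabelled so `μ_low < μ_high` (calls are invariant to the relabeling) and a
sample is positive when the posterior of the high component exceeds 0.5.
A separation index `|μ_high − μ_low| / pooled sd < 2` marks low-confidence
(near-unimodal) fits. The log-likelihood trajectory is retained; it is
non-decreasing by construction of EM and asserted in tests.

## Gene set enrichment

Phenotype mode ranks genes by signal-to-noise `(μ₁−μ₂)/(σ₁+σ₂)` with each σ
floored at `0.2·|μ|` (metric 0 if the denominator still vanishes);
pre-ranked mode orders by the coefficient of variation `sd/mean` (0 for
zero-mean genes). Rank ties break stably by gene symbol. The running sum
increments at hits by `|metric|^p` normalized by the set total (weight
`p = 1` default, `p = 0` exposed; equal weights if all hit metrics vanish)
and decrements at misses by `1/(N−k)`; the enrichment score is the extremum.
Label permutations (exhaustive with a warning when fewer distinct
permutations exist than requested) give: NES = ES / mean same-sign null ES;
a one-sided nominal p within sign, floored at `1/(B+1)`; and a
sign-stratified FDR q — the ratio of null to observed tail proportions at
`|NES|`, clipped at 1, then monotonized by taking for each set the minimum
ratio over all thresholds at or below its |NES| (so q never increases with
|NES| within a sign class). Sets with `q < 0.25` are flagged enriched, the
conventional GSEA cutoff. Directional signatures are handled by splitting a
signature into up- and down-regulated gene sets before testing.

## Synthetic cohorts

`simulate_cohort` generates the paired study design end to end. Copy-number
states follow a five-state Markov chain along each chromosome's markers
(homozygous deletion, loss, neutral, gain, amplification with log-ratio
means −0.9, −0.25, 0, +0.25, +0.9) with a sticky neutral state; the
per-marker switch probability is set from the expected segments per
chromosome (default 6 over 500 markers) and the aberrant stationary mass is
0.40 — a fraction of genome altered typical of aneuploid breast tumors.
Markers add Gaussian noise (sd 0.1). Genes (default 1,000 over 2
chromosomes) take their true copy value from the state at their midpoint.
Expression is `baseline + γ·copy + effects + N(0, 0.2²)`; a 30% dosage
subset uses slope γ = 2.5 — γ and the noise were calibrated once so the
population Spearman between copy value and expression is ≈ 0.8 at 21 paired
samples (rank ties among the five discrete copy states cap the achievable
correlation, which is why the slope exceeds the physical log2 expectation
of ~1). Receptor-like labels add fixed effects to designated gene blocks;
prognostic genes form a coherent module driven by one latent
(proliferation-like) factor whose value is also the Cox linear predictor
(log hazard ratio 0.7 per SD) — the coherent-module structure is exactly
what a supervised principal component assumes, and with independent
prognostic genes PC1 would be an arbitrary direction. Survival is
exponential with administrative uniform censoring over a 10-year window
(~25% events at defaults). All randomness flows through named substreams of
one root seed; identical configs write byte-identical files.

What the simulations do **not** emulate: probe-level intensity artifacts,
GC waves, real hotspot/recurrence maps, correlated gene co-expression
beyond the planted modules, non-linear dosage response, and informative
censoring. Passing tests therefore establish the statistical correctness of
the machinery under the stated generative model, not performance on any
particular real cohort.

## Problem sizes used in tests

The default simulated cohort is 2 chromosomes × 500 markers, 1,000 genes,
60 samples (21 paired). The end-to-end concurrency check runs segmentation
with 250 permutations per split test — the `(b+1)/(B+1)` estimator still
resolves the 0.01 split level — and completes in about a minute; the
risk-recovery check uses 20 seeds of a 150-sample, 120-gene cohort. Unit
tests use smaller instances throughout. These sizes are the package's
chosen desk-scale study conditions; all thresholds (α levels, MAD
multipliers, FDR cutoffs) are the workflow's stated defaults.

## Known limitations

* CBS here implements the exhaustive arc search plus a sampled-length
  hybrid; it does not implement the sequential early-stopping boundary
  approximations of reference implementations, so very long chromosomes
  (≫10⁵ markers) are slow.
* `merge_levels` is O(L²) in the number of segment levels per array.
* The GISTIC stage scores recurrence only; it does not do peel-off peak
  refinement or broad/focal decomposition.
* Cox screening loops per gene through lifelines; screening tens of
  thousands of genes takes minutes, not seconds.
* The exact-permutation Spearman p-value enumerates n! permutations and is
  limited to n ≤ 9 pairs by design.
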