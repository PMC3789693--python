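# cgsig

Integrative copy-number / expression analysis for paired tumor cohorts:
from marker-level array-CGH log ratios to **concurrent genes** — genes whose
DNA dosage changes are mirrored in their transcription — and onward to
receptor-status signatures and a survival risk model built from them.

The package is aimed at analysts working with paired platforms (array CGH or
other segmental copy-number data alongside expression microarrays) who want a
tested, scriptable implementation of the classic integration workflow:

1. **Segmentation** — circular binary segmentation (CBS): per chromosome,
   the arc `(i, j]` of the circularized marker sequence maximizing the
   two-sample statistic
   `|t| = |x̄_arc − x̄_comp| / √(s²_pooled (1/m + 1/(n−m)))`
   is tested by permuting marker order; accepted splits (permutation
   `p ≤ α`, default `α = 0.01`, 1,000 permutations) are recursed.
   A rank-sum `mergeLevels` step pools indistinguishable segment levels.
2. **CNV calling** — segment means against multiples of the array's median
   absolute deviation: amplification/homozygous deletion beyond `±5·MAD`,
   gain/loss beyond `±1.1·MAD`.
3. **Recurrence** — GISTIC-style per-marker G-scores
   `G(m) = Σ_samples |seg_mean(m)| · 1[aberrant]`, with a null from
   independent cyclic shifts of each sample's profile and BH FDR control.
4. **Concurrency** — a gene-centric table (each gene takes the mean of its
   maximal-overlap segment) correlated with paired expression by Spearman's
   ρ; a gene is *concurrent* iff it carries a CNV, `p < 0.05`, and `ρ > 0`.
5. **Signatures** — random-variance t-test screening
   (`σ̃² = (d·s² + 2ab)/(d + 2a)`, `df = d + 2a`, with `(a, b)` fitted by
   maximum likelihood from `s² ~ b·F(d, 2a)`), a global multivariate
   permutation test, five classifiers (CCP, DLDA, 3-NN, nearest centroid,
   linear SVM) with honest leave-one-out cross-validation, and cross-cohort
   consensus (intersection) signatures.
6. **Risk model** — univariate Cox screening at `α = 10⁻³`; the first
   principal component of the selected genes enters a Cox model, giving the
   linear prognostic index
   `score = Σ_g coef_g · x_g + coef_batch · batch + c`,
   dichotomized at the 50th (or 30th) percentile and evaluated by χ²,
   log-rank, and the Mann–Whitney AUC. The published 16-gene breast cancer
   model (batch coefficient 0.079, constant 3.9, threshold 0.122) ships as a
   loadable fixture.
7. **Subtyping / receptors / enrichment** — centroid single-sample subtype
   prediction, two-component Gaussian-mixture receptor calls, and GSEA
   (phenotype-permutation and CV-pre-ranked modes).

A seeded synthetic-cohort generator (`cgsig.simulate`) emulates the paired
study design — segmental CNV profiles, dosage-coupled expression, receptor
phenotypes, two-cohort batch structure, right-censored survival — with full
ground truth, so every stage is testable end to end.

## Worked example

Find concurrent genes on a simulated paired cohort
(`examples/03_concurrent_genes.py`):

```python
from cgsig import SimulationConfig, run_concurrency_pipeline, simulate_cohort

sim = simulate_cohort(SimulationConfig(seed=2, n_samples=30, n_paired=21,
                                       n_chromosomes=1, markers_per_chromosome=300,
                                       n_genes=300))
run = run_concurrency_pipeline(sim.marker_profiles, sim.expression, sim.genes,
                               n_perm=250, seed=2)
```

prints

```
300 genes assessed over 21 paired samples
299 genes carry a CNV in >=1 sample; 94 flagged concurrent (rho > 0, p < 0.05)
against ground truth: sensitivity 0.96, false-positive rate 0.038
strongest concurrent genes:
  G0177: rho = +0.93, p = 1.51e-09, n = 21
```

94 of 300 genes pass the concurrency filter; compared with the generator's
truth table, 96% of the planted dosage-coupled genes are recovered while
3.8% of null genes slip through (the two-sided 5% test fires in the positive
direction on ≈2.5% of nulls, plus estimation noise). Building the survival
model on such genes (`examples/05_survival_risk_model.py`) then prints,
e.g.,

```
8 genes pass the Cox screen at alpha = 0.001
median threshold = 0.108
high   100      38  0.38
low    100      21  0.21
chi2 = 6.9 (p = 8.39e-03), log-rank p = 8.46e-04, AUC = 0.659
published 16-gene model at the zero-expression reference subject: 3.9
```

— the high-risk half relapses at 38% vs 21%, and the published 16-gene
fixture evaluates to its calibration constant 3.9 for a subject with all
signature genes at zero and batch indicator 0.

The other scripts in `examples/` cover segmentation and CNV calling,
recurrent-region scoring, signature derivation with LOOCV, subtype and
receptor inference, gene set enrichment, and cohort harmonization.

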