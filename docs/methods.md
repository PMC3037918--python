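# Methods

## The screening statistic

The screen operates on a compendium of independent disease-expression
studies. Each study contributes a gene × sample matrix and per-sample
annotations (disease concept, disease/normal state, tissue). Because the
studies span platforms with incomparable intensity scales, every array is
reduced to ranks: within an array measuring G genes, the value with
1-based average rank r maps to

    rho = (r − 1) / (G − 1)  ∈  [0, 1].

Average ranks handle ties; with no ties the minimum maps to 0 and the
maximum to 1. The per-gene change measure for a disease contrast in one
study is

    Δ = mean(rho | disease arrays) − mean(rho | normal arrays),

bounded in [−1, +1] with the endpoints attained exactly when a gene moves
from bottom rank in every normal array to top rank in every disease array
(or vice versa). Δ is invariant to any strictly increasing transform of an
array (hence to monotone normalization differences between platforms) and
antisymmetric under exchange of the group labels. Ranking is per array by
default; a pooled-ranking variant (all arrays of a contrast ranked
jointly) is available behind the `scope` switch but is not the default,
since per-array ranking is what makes cross-platform aggregation sound.

Across the studies annotated to a disease, per-study Δ values are combined
as a weighted mean with weight equal to the number of contributing samples
in the study (an unweighted mean is available via `weighted=False`).
Weighting limits the influence of very small studies. Genes absent from a
study's platform contribute nothing to their own aggregate; zero-imputing
them would shrink Δ toward 0 by platform coverage rather than biology.

## The filter cascade

Candidates must be (1) selectively upregulated — aggregate Δ in the target
disease at or above `up_threshold` (default 0.10) while, in every
comparator disease in which the gene is measured, Δ stays at or below
`comparator_max_delta` (default 0.0); (2) on a curated
disease-susceptibility gene list; and (3) detectable in blood or urine
per a biofluid proteome list. The defaults reflect the deltas reported for
top-ranked genes in compendium screens of this kind (≈0.12–0.19): 0.10
admits that stratum, and 0.0 encodes "not upregulated at all" in
comparators, since no published comparator cutoff exists. Genes unmeasured
in a comparator are retained but flagged; dropping them would penalize
platform gaps. List intersection normalizes identifiers (case-fold,
strip). Final candidates are the `top_n` (default 10) genes by target Δ
among those passing all stages, with ties broken by gene identifier for
reproducibility.

## Synthetic compendium generator

No real compendium of this kind is redistributable, and the per-study
sample sizes and noise levels of such compendia are unpublished, so the
generator's defaults are free parameters chosen to be unremarkable for
log-scale microarray data rather than estimates of any particular corpus:

| parameter | default | meaning |
|---|---|---|
| `n_diseases` / `n_datasets_per_disease` | 3 / 3 | compendium structure |
| `n_genes` | 500 | universe size |
| `n_samples_per_group` | 10 | arrays per state per study |
| `effect_shift` | 2.0 | planted upregulation, in units of `noise_sd` |
| `noise_sd` | 1.0 | within-gene measurement SD (log scale) |
| `missing_gene_fraction` | 0.1 | per-study probability a gene is off-platform |

Expression of gene g is `mu_g + eps` with `mu_g ~ N(8, 2²)` fixed per
compendium and `eps ~ N(0, noise_sd²)`; planted genes gain
`effect_shift · noise_sd` in the target disease's disease arrays only.
Genes drop out of each study independently, mimicking multi-platform
coverage gaps. The Gaussian baseline is a convenience: the downstream
statistic is rank-based and distribution-free, so the oracle calculations
are simplest under a model whose ranks are easy to reason about. What the
generator does **not** emulate: probe-level effects, correlated gene
modules, batch structure within a study, and non-monotone normalization
artifacts. Passing tests therefore demonstrate correctness of the
statistic and cascade under clean sampling assumptions, not robustness to
those real-data pathologies.

Two properties of the bounded rank statistic shape how simulation
experiments must be designed:

* **Ceiling effect.** A gene whose baseline sits above normalized rank
  1 − `up_threshold` can never gain Δ ≥ `up_threshold`, however large the
  planted effect: it has no rank headroom. Recovery experiments therefore
  plant effects on mid-baseline genes (`mid_baseline_genes()` exposes the
  generator's deterministic baselines for this). This mirrors the biology
  of a useful circulating marker — a protein low in normal tissue and
  induced in disease — and is a genuine blind spot of the statistic for
  constitutively high genes.
* **Baseline-dependent null variance.** Under the null, genes at the
  extremes of the baseline hierarchy are rank-pinned and have narrow Δ
  distributions, while mid-baseline genes have wide ones. Null-calibration
  experiments therefore label their "planted" genes uniformly at random;
  baseline-informed labels would bias the planted-vs-non-planted
  comparison even with no effect present.

Gene lists are drawn without replacement at exact size
`round(fraction · |universe|)` (removing binomial size variance from
tests), with a forced-overlap argument so planted candidates can be made
to survive the whole cascade.

## TMA validation statistics

Staining of a tissue-microarray core is graded 0–3 by percent cytoplasmic
staining (0 none, 1 = 1–25%, 2 = 25–75%, 3 = >75%) and binarized as
positive ⇔ score ≥ 1 (the cutoff is a parameter). Cores stratify into
normal, tumor-without-diabetes, and tumor-with-diabetes; tumor cores with
unknown diabetes status stay in two-group analyses but drop out of the
stratified ones.

Statistical conventions, each of which matters for reproducing published
values from printed counts:

* **Fisher's exact test** is two-sided by the minimum-likelihood rule
  (sum of hypergeometric probabilities ≤ that of the observed table); the
  tail-doubling rule is available behind a flag. Binary staining tables
  are sparse (expected cells < 5), so Fisher is the primary binary test;
  Pearson chi-square (no continuity correction) is emitted alongside for
  transparency. A degenerate margin yields p = 1 with a warning.
* **Rank-sum test**: z = (W − μ)/σ with average ranks and tie-corrected
  variance σ² = (n₁n₂/12)[(N+1) − Σ(t³−t)/(N(N−1))], **no continuity
  correction**. With the correction the normal-vs-tumor-diabetic contrast
  on the reference cohort gives ≈0.005; without it, ≈0.004 — the published
  value. Pairwise contrasts run on the 0–3 score, not the binary variable,
  which is what reproduces the published 0.004 / 0.07 / 0.09 triplet; both
  raw and Bonferroni-adjusted (×3, capped at 1) values are reported.
* **Kruskal–Wallis** uses the standard tie-correction divisor
  C = 1 − Σ(t³−t)/(N³−N), guarded to p = 1 when every observation is tied
  (C = 0). For k = 2 the H statistic equals z² from the rank-sum test to
  1e-9 and the p-values coincide — an internal consistency check the test
  suite enforces.
* **Odds ratio** ad/bc with the Woolf interval
  exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)); any zero cell triggers the
  Haldane–Anscombe +0.5 correction of all cells (flagged). The crude
  single-predictor logistic model is the default (its exp(coefficient)
  equals ad/bc exactly in the saturated 2×2 case, which the tests check to
  1e-6); covariate-adjusted models are fit on request only, since
  published adjusted models for this design are under-specified.
* **Logistic regression** is Newton (IRLS) maximum likelihood, tolerance
  1e-8, 100 iterations, with rank-deficient designs and complete
  separation reported as distinct statuses rather than silent numbers.
* **Missing covariates** are handled per variable by complete-case
  analysis with the analyzed denominator logged.

The normal approximation of the rank tests deserves a caveat: at very
small, heavily tied samples it tracks the exhaustive permutation
distribution closely in the significance tail (within ~0.02 at p ≈ 0.03
for two groups of four scores) but understates p badly in the body of the
distribution (deviations up to ~0.7 near p = 1). The test suite compares
against exhaustive permutation only in the tail, which is where decisions
are made; at the reference cohort's sizes (n = 21/37/10) the approximation
is accurate to the printed precision.

## Reference cohort

`reference_tma_cohort()` reconstructs, cell for cell, the marginal
staining distributions of a published FABP-1 pancreatic-adenocarcinoma
TMA cohort: 21 normal cores (scores 0/1/2/3 = 20/0/1/0, of which 3 are
from diabetic patients, all score 0) and 60 tumor cores (42/12/5/1),
splitting into 37 without diabetes (28/7/2/0), 10 with diabetes
(5/3/1/1), and 13 with unknown diabetes status (9/2/2/0) — the remainder
that reconciles the two-group and three-stratum margins. Rank tests and
exact tests depend only on these margins, so every published statistic is
recomputable from the fixture; covariates other than diabetes status are
not reconstructible from printed counts and are left missing. The
synthetic TMA generator, by contrast, draws scores from per-group
multinomials (optionally tilted by age through a proportional-odds
mechanism, for exercising confounding analyses) and fills in covariates.

## Problem sizes

Monte-Carlo checks use 50 replicates of a 100-gene, one-study compendium
with 20+20 samples; the acceptance script uses the same sizes. These are
small enough to run in seconds while leaving the Monte-Carlo standard
errors well below the margins being tested.

## Known limitations

* The screen cannot rank genes the compendium never measures, and the
  ceiling effect above blinds it to upregulation of constitutively
  high-expressed genes.
* The comparator rule treats "unmeasured in a comparator" as "not
  excluded", which is permissive by construction.
* The TMA toolkit has no matched-pair analysis and no inter-rater
  modelling; both are out of scope for single-pathologist, unmatched
  designs.
* Published score-level two-group p-values of the form "0.059" are not
  uniquely attributable to one method from printed counts; the package
  emits the 2×4 chi-square and the score rank-sum side by side rather
  than guessing.
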