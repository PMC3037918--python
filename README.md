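# rankscreen

Candidate-biomarker discovery by rank-normalized disease-expression
screening, with the tissue-microarray statistics needed to validate a
candidate by immunohistochemistry.

The motivating problem is finding a circulating marker for a disease via
public expression data — for example a tumor-derived protein upregulated
in pancreatic adenocarcinoma, on a type-II-diabetes susceptibility list,
and detectable in blood or urine (the profile that singles out FABP-1,
liver-type fatty acid binding protein). The package is for computational
biologists who want that screening logic, and the validation statistics
that go with it, as tested and reusable code rather than a one-off
analysis.

## What it computes

**Screen arm.** Within each microarray, gene values are rank-normalized,
ρ = (r − 1)/(G − 1) ∈ [0, 1]. Per gene and disease contrast,

Δ = mean(ρ | disease samples) − mean(ρ | normal samples) ∈ [−1, +1],

aggregated across studies by a sample-size-weighted mean. Candidates must
pass Δ ≥ 0.10 in the target disease, Δ ≤ 0 in every comparator disease
where measured, membership on a susceptibility gene list, and membership
on a biofluid-detectability list; the top 10 by Δ survive. Because no real
compendium of this kind is redistributable, a seeded synthetic-compendium
generator (planted upregulated genes, per-study gene dropout) makes every
stage testable end to end.

**TMA arm.** Immunohistochemistry scores 0–3 on tissue-microarray cores,
binarized at score ≥ 1, analyzed by Fisher's exact test
(minimum-likelihood two-sided rule), Pearson chi-square, tie-corrected
Wilcoxon rank-sum and Kruskal–Wallis tests (no continuity correction),
Bonferroni adjustment, Woolf odds-ratio intervals, and logistic
regression. A deterministic reference cohort reproduces the published
staining margins of an FABP-1 pancreatic TMA study (21 normal / 60 tumor
cores, stratified by diabetes), from which every published statistic is
recomputable. See `docs/methods.md` for the full conventions.

## Worked example

```python
import rankscreen as rs

# --- screen a synthetic compendium with 5 planted genes -----------------
base = rs.CompendiumConfig(
    n_diseases=1, n_datasets_per_disease=1, n_genes=100,
    n_samples_per_group=20, effect_shift=3.0,
    missing_gene_fraction=0.0, seed=0,
)
planted = rs.mid_baseline_genes(base, 5)       # genes with rank headroom
cfg = base.model_copy(update={"planted_up_genes": {"disease_00": set(planted)}})
datasets = rs.generate_compendium(cfg)
susc, biof = rs.generate_gene_lists(rs.gene_universe(100), 0.1, 0.1,
                                    planted, seed=1)
report = rs.run_screen(datasets, susc, biof,
                       rs.ScreenConfig(target_disease="disease_00"))
print(report.loc[report.final_candidate, ["gene", "target_delta"]])

# --- validate staining on the reference TMA cohort ----------------------
res = rs.analyze_staining_cohort(rs.reference_tma_cohort())
print(f"Fisher p = {res['fisher_exact']['p_value']:.4f}")
oddsr = res["odds_ratio"]
print(f"OR = {oddsr['odds_ratio']:.1f} "
      f"(95% CI {oddsr['ci_low']:.2f}-{oddsr['ci_high']:.1f})")
for pair in res["stratified"]["pairwise_rank_sum"]:
    print(f"{pair['groups'][0]} vs {pair['groups'][1]}: "
          f"p = {pair['p_raw']:.3f}")
```

Output:

```
     gene  target_delta
0  G00003      0.357576
1  G00025      0.355556
2  G00078      0.355051
3  G00070      0.330303
4  G00011      0.328788
Fisher p = 0.0183
OR = 8.6 (95% CI 1.07-68.8)
normal vs PaC no DM: p = 0.074
normal vs PaC-DM: p = 0.004
PaC no DM vs PaC-DM: p = 0.089
```

All five planted genes survive the cascade with the largest deltas. On
the reference cohort, tumor cores stain positive far more often than
normal cores (18/60 vs 1/21; Fisher p ≈ 0.02, odds ratio 8.6 with Woolf
95% CI from 1.1), staining rises across the diabetes strata, and the
tumor-with-diabetes vs normal contrast is the sharp one (p = 0.004).

The same pipeline is scriptable from the shell:

```sh
rankscreen run-all --seed 7 --out runs/demo      # simulate → screen → TMA
rankscreen tma --reference-cohort --out runs/tma # TMA arm alone
```

Every run writes a `manifest.json` from which it can be replayed exactly.

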