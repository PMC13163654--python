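# comorbidnet

A tested, reusable reimplementation of a multi-stage computational analysis
of pyoderma gangrenosum (PG) / inflammatory bowel disease (IBD) comorbidity,
driven entirely by a synthetic-data generator so every stage is runnable and
checkable without access to controlled patient data.

The pipeline covers, in the order the analysis runs:

1. **Genetics** — cross-trait LD-score regression (genetic correlation
   `rg`), two-sample Mendelian randomization (inverse-variance-weighted
   `θ̂ = Σ wⱼ βʸⱼβˣⱼ / Σ wⱼ (βˣⱼ)²` with `wⱼ = 1/se²(βʸⱼ)`, weighted median,
   MR-Egger), Cochran's Q, an MR-PRESSO-style residual global/outlier test,
   leave-one-out sensitivity, and Bayesian colocalization via Wakefield
   approximate Bayes factors
   (`log ABF = ½[ln(V/(V+W)) + z²·W/(V+W)]`, `W = 0.15²`).
2. **Expression** — per-gene location–scale batch adjustment, PCA checks,
   unpaired Wilcoxon differential expression with Benjamini–Hochberg
   correction, and single-cell per-type summaries
   (`ln(1 + 10⁴·c/total)` normalization, 10% detection floor).
3. **Co-expression** — unsigned weighted network `a_ij = |cor(x_i,x_j)|^β`,
   scale-free soft-threshold scan (β ∈ 2..20), topological overlap
   `ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)`, average-linkage
   module detection, module eigengenes, Spearman module–trait correlation,
   and permutation Zsummary module preservation across tissues.
4. **Network** — interaction-graph construction at a strict confidence
   threshold (> 0.7), degree / betweenness
   (`C_B(v) = Σ σ_st(v)/σ_st`) / closeness centralities, and
   filter-then-rank hub selection (degree ≥ 10, top 10 by mean rank).
5. **Enrichment** — running-sum enrichment scores, phenotype-permutation
   significance, single-sample pathway activity (per-sample KS statistic),
   standardized group differences (Cohen's d), and median-split
   high/low-activity stratification against hub genes, serum CRP and
   CD/UC subtype.
6. **Kinetics** — an ODE model of the JAK–STAT axis (pSTAT3, SOCS3 with
   lagged sigmoidal synthesis and pSTAT3-coupled degradation, TNF read-out)
   under JAK-subtype-selective inhibition `a_i = 1/(1 + D(t)/ki_i)` with
   single-dose exponential pharmacokinetics; ΔG→ki conversion
   `ki = exp(ΔG/RT)`; trajectory metrics and steady-state dose–response.

The synthetic generator plants the effects the estimators are asked to
recover: a causal odds ratio of 1.32 across 127 instruments, genetic
correlation 0.45, a shared causal variant (PP4 ≈ 0.92), a 325-gene "blue"
disease module whose eigengene tracks disease activity at Spearman 0.92
(skin) / 0.88 (gut) and CRP at 0.47, network hubs with degree ≥ 10, a
myeloid marker expressed in 34.7% of cells at mean log-normalized 1.52, and
drug ki tables (baricitinib 0.8/1.2/45 nM; tofacitinib 12/25/1.5 nM).

## Worked example

```python
from comorbidnet import genetics, synthdata

exposure, outcome = synthdata.gen_mr_data(synthdata.MrScenario(seed=1))
inst = genetics.instruments_from_summaries(exposure, outcome)
ivw = genetics.mr_fit(inst, method="ivw")
q = genetics.heterogeneity_q(inst)
print(f"IVW OR {ivw.odds_ratio:.2f} (95% CI {ivw.ci_low:.2f}-{ivw.ci_high:.2f})")
print(f"Cochran's Q {q['Q']:.1f} on {q['df']} df, p = {q['p']:.2f}")
```

prints

```
IVW OR 1.22 (95% CI 1.11-1.34)
Cochran's Q 104.9 on 126 df, p = 0.91
```

i.e. on this one synthetic cohort of 127 instruments the IVW estimate is
consistent with the planted odds ratio of 1.32 (inside its own confidence
interval) with no excess heterogeneity among instruments; averaged over 200
replicate cohorts, as `scripts/acceptance.py` does, the estimate centres on
1.32. The full pipeline runs end to end with

```sh
comorbidnet run --seed 1 --out run1
```

which writes per-stage TSV/CSV/GMT/MTX outputs plus `report.json`, or from
Python via `comorbidnet.pipeline.run_all(RunConfig(seed=1))`. Individual
stages are exposed as subcommands (`comorbidnet synth`, `comorbidnet mr`,
`comorbidnet coloc`, `comorbidnet coexpr`, `comorbidnet enrich`,
`comorbidnet kin simulate`, `comorbidnet kin dose-response`).

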