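# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `comorbidnet`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## What the package models

The analysis treats pyoderma gangrenosum (PG, a neutrophilic skin disease)
and inflammatory bowel disease (IBD) as a comorbid pair linked through a
shared inflammatory axis: a common genetic background (assessed by genetic
correlation, Mendelian randomization and colocalization of summary
statistics), a cross-tissue conserved co-expression module enriched for
JAK–STAT signaling, hub genes in the protein-interaction neighbourhood of
that module, elevated pathway activity in lesional tissue, and the response
of the axis to JAK-subtype-selective inhibitors. Real accession data is
access-controlled and platform-heterogeneous, so every stage here runs on
synthetic data that plants the statistical structure the estimators assume;
tests then ask whether the estimators recover what was planted.

## Synthetic-data generator

**GWAS summary statistics.** Instruments for MR are drawn as
`bx ~ N(0, 0.1²)` observed with error `se_bx = 0.005` (strong instruments:
the exposure association dwarfs its standard error, consistent with
genome-wide-significant, independently associated variants), and
`by = θ·bx + α + ε`, `ε ~ N(0, 0.05²)`, with defaults θ = ln(1.32) across
127 instruments and pleiotropy intercept α = 0. Designated outliers get a
fixed additive offset on `by`. Regression dilution from the small exposure
error biases IVW by ≈ var-ratio 0.9975, i.e. well inside Monte-Carlo noise.
For LD-score regression, per-SNP z-score pairs are drawn bivariate normal
with `E[z_i²] = 1 + N_i h²_i l_j/M` and
`E[z1 z2] = rg·sqrt(h²_1 h²_2 N1 N2)·l_j/M` (no sample overlap, hence no
cross-trait intercept); LD scores `l_j ~ 1 + Gamma(3, 30)`. Defaults:
20 000 SNPs, h² = 0.30/0.25, N = 50 000/30 000, rg = 0.45. SNPs are
independent (no LD) throughout, which makes the single-causal-variant
colocalization model exact: the causal SNP carries `beta = z·se` in both
traits (shared) or in displaced positions (distinct), all other z ~ N(0,1).

**Bulk expression.** Two tissues (skin, gut), 30 disease + 30 control
samples each, 2 000 genes, 10 planted modules of sizes
325, 200, 150, 120, 90, 70, 55, 45, 35, 30 (1 120 module genes). Each module
has a latent factor per tissue; gene loadings run linearly from 1.3 (core)
to 0.5 (periphery) within each module, which produces the intramodular
connectivity continuum and heavy-tailed degree distribution that real
co-expression networks show (a flat loading profile fails the scale-free
scan). Loadings repeat across tissues with N(0, 0.1) jitter — conserved but
not identical modules. Disease samples shift the first two module factors
by +2.2 and +1.0; residual noise sd 0.6; two balanced batches per tissue
with additive offset 1.0. The disease-activity trait and (lesional) serum
CRP are generated through a Gaussian copula on the blue factor's normal
scores, so the planted Spearman correlations (0.92 skin / 0.88 gut for
activity, 0.47 for CRP) hold regardless of the factor's bimodal
disease/control marginal. Gut disease samples split evenly into CD and UC.
The +2.2 blue-module disease shift is the single knob behind the
pathway-activity effect sizes (standardized score difference ≈ 1.8
disease vs control, and CD/UC vs control in the same range).

**Single cell.** 500 cells over four types (myeloid 0.30, T 0.35, B 0.20,
fibroblast 0.15); 60 background genes with Poisson(30) counts set each
cell's library size. The target (IL10-like) gene is expressed in a
Bernoulli(0.347) subset of myeloid cells at a per-cell count chosen so the
mean log-normalized value over all myeloid cells is 1.52
(`ln(1 + 10⁴·c/total)`), with 2% leak at count 1 elsewhere.

**Interaction network.** Erdős–Rényi background (p = 0.04) with confidences
uniform in (0.4, 0.95); each planted hub gets 12 extra edges with
confidences in the upper part of the range so hubs survive the strict 0.7
filter with degree ≥ 10. If the confidence range sits entirely below the
threshold, the filtered graph is empty by construction.

**What the generator does not emulate:** linkage disequilibrium and allele
frequencies, strand/allele harmonization, count-level RNA-seq noise and
normalization artifacts, single-cell ambient RNA or doublets, nonlinear
batch distortions, and any real gene identity. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions and
the stated noise model — not robustness to the full messiness of the real
accessions.

## Estimator details and numerical choices

- **LDSC**: unweighted OLS of z² (and z1·z2) on the LD score with
  intercept; h² = slope·M/N, rg = slope·M/(√(N1·N2)·√(h²1·h²2)); SE by
  delete-one block jackknife over 200 contiguous blocks (reduced with a
  warning when SNPs are scarce). Reported rg is clamped to [−1.25, 1.25]
  and flagged outside [−1, 1]; non-positive h² flags the result as
  undefined rather than reporting a number.
- **MR**: IVW is the closed-form weighted regression through the origin.
  The weighted median uses Bowden's centred cumulative weights with a
  seeded parametric bootstrap (1 000 draws) for its SE. Egger uses weighted
  least squares with a free intercept and a multiplicative overdispersion
  factor bounded below by 1; its intercept p-value is the pleiotropy
  read-out. All p-values are two-sided normal (t for the Egger intercept);
  odds-ratio CIs are `exp(est ± 1.96·se)`.
- **MR-PRESSO variant**: observed RSS of outcome betas around leave-one-out
  IVW predictions vs 1 000 parametric simulations; per-SNP tail
  probabilities Bonferroni-flagged. Leave-one-out estimates are computed
  from sufficient statistics, so the simulation loop is O(n_sim · n).
- **Colocalization**: per-SNP Wakefield log-ABFs with prior effect sd 0.15;
  hypothesis sums accumulated with log-sum-exp; priors p1 = p2 = 1e−4,
  p12 = 1e−5. Posteriors sum to 1 within 1e−9 by construction.
- **Batch adjustment** standardizes each gene within batch and rescales to
  the pooled per-gene moments (population variances, so pooling is exact
  and the map is idempotent). This is a deliberate simplification of
  empirical-Bayes batch correction: no shrinkage across genes, appropriate
  at 2 000 genes × 60 samples and an additive planted batch effect.
- **Wilcoxon**: exact enumeration when both groups ≤ 8 with no cross-group
  ties, otherwise normal approximation with mid-ranks and tie correction.
- **Co-expression**: unsigned adjacency `|cor|^β` (the absolute value keeps
  a_ij ∈ [0,1] for odd β). TOM excludes u ∈ {i, j} from the shared-neighbour
  sum and self-adjacency from k. The scale-free index uses 10 equal-width
  connectivity bins, empty bins dropped; powers whose network falls below
  unit mean connectivity are reported as NaN (a vacuous network fits a
  2-bin line perfectly — the guard prevents pure noise from "passing").
  Module detection is a static cut of the average-linkage dendrogram on
  1 − ω at 0.995 of the maximum merge height (min module size 30); on TOM
  dissimilarities, module merges sit at 0.90–0.99 of the between-module
  height, so meaningful static cuts live near the top of the dendrogram.
  Labels are ordered by module size (label 1 = largest = blue).
- **Preservation**: Zsummary = mean of density and connectivity permutation
  Z-scores, 200 random same-size gene sets. In this generator the whole
  network topology is conserved across tissues, so the connectivity
  component carries little contrast (random sets preserve connectivity
  too); density carries the signal. Zsummary > 10 reads as strong
  preservation, 2–10 as moderate.
- **Centralities**: unweighted shortest paths (confidence is a filter, not
  a length), betweenness unnormalized with each unordered pair counted once
  and fractional split over tied shortest paths; a normalized column
  (÷ (n−1)(n−2)/2) is also reported. Closeness is
  (component size − 1)/Σ distances. Hub rule: filter degree ≥ 10, then top
  10 by mean rank across the three centralities, ties lexicographic.
- **Enrichment**: unweighted running sum (hits +1/|S|, misses −1/(N−|S|)),
  signed extreme; a weighted variant (|metric|^p, p = 1) is available. A
  set covering the whole list returns +1 by convention. Permutation
  p-values use the +1 correction. Sample scores rank genes within each
  sample (descending, stable ties), making them invariant to within-sample
  monotone transforms. "Standardized enrichment score difference" is
  Cohen's d with pooled sd; median-split ties go to the low group.
- **Kinetics** (state equations in `kinetics.py`): STAT3 phosphorylation is
  driven by the weighted residual activity of JAK1/2/3 under competitive
  inhibition and suppressed by SOCS3 through `1/(1 + (M/K_s)^h_s)`; SOCS3
  synthesis is sigmoidal in a lagged pSTAT3 signal (STAT3 engages its
  promoter as a dimer, hence cooperatively) and its degradation is
  pSTAT3-coupled; TNF is a Hill read-out of pSTAT3. The
  sigmoidal-synthesis/coupled-degradation pair produces the transient SOCS3
  surge after dosing and differentiates the two drug regimes: a deep
  pSTAT3 crash (JAK1/2-selective baricitinib) shuts synthesis off sharply,
  giving an early SOCS3 peak, while a shallow drop (JAK3-selective
  tofacitinib) keeps synthesis saturated so the SOCS3 pool keeps growing
  and the pSTAT3 minimum lands late (the recovery onset). A purely linear
  synthesis term cannot produce a late recovery onset together with an
  early surge — the SOCS3 pool then peaks within 2–3 lag constants for
  both drugs regardless of rates.

  The frozen default parameter vector was calibrated by differential
  evolution against five simultaneous behavioural constraints (deep fast
  suppression and early SOCS3 surge under the baricitinib profile; moderate
  maximum inhibition, late recovery onset with visible recovery, under
  tofacitinib; monotone non-decreasing steady-state dose–response for both
  drugs and read-outs) and frozen at the calibrated values (the feasible
  region is narrow: coarse rounding of the vector flips the tofacitinib
  trajectory back to an early minimum, so the defaults keep four-decimal
  precision). Single-dose PK is exponential with half-lives 12 h
  (baricitinib) and 3.33 h (tofacitinib); the reference dose is 26.29 nM.
  Dose–response holds the concentration constant (maintained exposure) and
  reads the settled end-of-window value, because a single decaying dose
  shows transient feedback-rebound overshoot at low doses, which is a
  statement about washout dynamics rather than about steady-state
  inhibition. Integration uses LSODA at rtol 1e−9/atol 1e−11 on a 481-point
  grid (Radau agrees to < 1e−6); the pre-dose steady state is solved by
  bracketed root-finding on a one-dimensional reduction, and trajectories
  are reported normalized to it. ΔG→ki uses R = 1.98720425e−3 kcal/(mol·K)
  at 298.15 K on a 1 M standard state; the shipped drug profiles carry
  printed ki values directly and `dg_to_ki` serves user-supplied docking
  energies.

## Pipeline and reproducibility

Stage seeds derive from the global seed as `crc32(f"{seed}:{stage}")`
masked to 31 bits, so inserting a stage never reshuffles the others. Every
generator is a pure function of its scenario (seed included); two runs with
the same config produce byte-identical statistics. All tabular outputs are
plain-text TSV/CSV/GMT/MTX.

## Problem sizes

Defaults are desk-scale by design: 2 000 genes × 60 samples per tissue,
20 000 SNPs for LDSC, 500-SNP colocalization regions, 500 cells, 200-node
networks. Replicate counts in the acceptance script (200 MR replicates,
50 expression/single-cell replicates, 200 preservation permutations) were
chosen so Monte-Carlo error sits well inside the comparison tolerances.

## Known limitations

- LDSC omits the sample-overlap intercept and uses unweighted OLS; fine for
  the overlap-free generator, not for real overlapping cohorts.
- Colocalization assumes a single causal variant per trait and no LD.
- The static-cut module detector needs well-separated modules; it has no
  dynamic-tree-cut refinement for nested or adjacent modules.
- Connectivity preservation is nearly uninformative under this generator
  (see above); with real cross-cohort data it would carry more signal.
- The kinetic model is a four-state caricature of JAK–STAT signalling: no
  receptor trafficking, no STAT dimerization kinetics, no transcriptional
  delay distributions, one compartment, and behaviourally calibrated (not
  fitted to measured rate constants).
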