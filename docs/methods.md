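# Methods

## Overview

`comutpath` implements a pathway-level mutation biomarker workflow for
immunotherapy outcome. The premise: single-gene mutation biomarkers are
fragile across heterogeneous tumours, but mutations concentrate in pathways,
and a tumour carrying non-silent mutations in *both* members of a suitable
pathway pair ("comut+") tends to carry a high tumour mutational burden (TMB)
and neoantigen load (NAL), an inflamed microenvironment, and a better
response to immune checkpoint blockade. The package discovers such a pair
from somatic mutations and clinical data, classifies patients, profiles
immune signatures, and validates the classification with survival, response
and meta-analytic statistics.

## The discovery procedure

1. **Binary mutation matrix.** Non-silent calls (missense, nonsense,
   frameshift and in-frame indels, splice) are binarized per gene × sample;
   genes mutated in more than 1% of samples are retained (strict `>`), the
   cutoff exposed as `min_gene_freq`. Multiple hits of a gene in one sample
   collapse to a single 1. The 1% frequency is computed over the supplied
   cohort as a whole.
2. **Pathway status.** A pathway is mutated in a sample iff at least one of
   its retained genes is (OR over the gene set); pathways mutated in at
   least 1% of samples are kept (inclusive `>=`, `min_pathway_freq`).
3. **Survival screen.** Per pathway, a multivariate Cox model (pathway
   status + age + sex + cancer type) against overall survival; BH-FDR across
   the screened pathways; FDR < 0.05 retained. Efron tie handling and Wald
   95% intervals throughout; cancer type enters as indicators with the modal
   type as reference. Pathways constant across samples are skipped and
   excluded from the FDR family.
4. **Burden association.** TMB (non-silent count / coding Mb, default
   denominator 38 Mb) and NAL are each regressed by OLS on the retained
   pathways' status indicators. Pathways with positive β in *both*
   regressions are the comutation candidates. ("Both-positive" is this
   package's operationalization of a qualitative retention step; no numeric
   rule exists in the source literature.)
5. **Pair selection.** For each candidate pair, samples comutated for that
   pair are compared with samples comutated for each competing pair on TMB
   and NAL by Wilcoxon rank-sum, after removing samples comutated for both
   pairs from each comparison. A pair's score is its worst (minimum)
   standardized rank advantage over all competitors and both responses; the
   max–min pair wins, ties breaking lexicographically. The disjoint
   comparison matters: samples comutated for both pairs carry no information
   about which pair drives the burden, and leaving them in both groups makes
   the contest between overlapping pairs essentially a coin flip.
6. **Operating point.** TMB (or NAL) is dichotomized at its top quartile
   (linear-interpolation percentile; values at the cutoff go high). The
   per-sample count of comutated pathways among the retained subset is
   thresholded by the Youden index (J = sensitivity + specificity − 1) over
   a "count ≥ t" ROC; J-ties break toward the smaller, more sensitive
   threshold. AUC is the trapezoid over the full curve.

## Validation statistics

- **Response.** Responder = CR|PR vs SD|PD (objective response scheme) or
  the durable-clinical-benefit column directly; NA excluded and counted.
  Association by Fisher's exact test, two-sided by the probability method
  (sum of tables no more probable than observed), odds ratio by conditional
  MLE. Rates are stored as exact fractions; percentages are display only.
- **Survival.** Kaplan–Meier with median = smallest t with S(t) ≤ 0.5 (else
  the "NR" sentinel); log-rank (k-group form for stratified analyses).
- **Two-biomarker stratification.** Dual-positive / single-positive /
  dual-negative; a numeric second biomarker (PD-L1 percent) is
  dichotomized at ≥ 50 by default, boundary inclusive. Response association
  across three strata uses an exact 2×3 test (full enumeration over fixed
  margins, probability method) up to total 200, chi-square beyond.
- **Biomarker comparison.** Harrell's C (ties = 0.5) and response AUROC; a
  binary biomarker's one-threshold AUROC equals (sensitivity+specificity)/2,
  a numeric biomarker gets the full rank-based AUROC.
- **Confusion vs a reference label** (e.g. MSI-H): sensitivity/specificity/
  PPV/NPV kept as exact fractions with their counts.

## Immune profiling

Expression is expected on a log2(value+1) scale. CYT = mean of GZMA and
PRF1; MHC-I = mean of the class-I core list (editable fixture). The
T-cell-inflamed GEP is scored by single-sample GSEA: per sample, genes are
ranked by expression (descending, average ranks for ties); the score is the
sum over positions of the difference between the in-set ECDF weighted by
(rank-from-bottom)^α and the unweighted out-of-set ECDF, α = 0.25; an
optional normalization divides by (N − set size). A user-supplied general
immune signature can be scored the same way — the package does not
implement the ESTIMATE algorithm or ship its gene sets.

Differential testing of the shipped 47-gene immune panel (a representative,
user-replaceable curation of checkpoint, T-cell receptor, microenvironment
and IFN-γ/T-effector genes) uses per-gene Wilcoxon rank-sum with BH-FDR over
the tested panel only. Preranked GSEA ranks genes by the Welch t statistic
between groups, computes the weighted Kolmogorov–Smirnov running-sum score
(weight |t|), and calibrates it against a seeded gene-permutation null
(membership redistributed uniformly; NES = ES / mean |same-sign null|).
Gene permutation was chosen over phenotype permutation for determinism and
desk-scale cost; it tests set enrichment relative to random gene sets of
the same size, not the phenotype-association null, and its p-values should
be read accordingly.

## Meta-analysis

Effects are pooled on the log scale with inverse-variance weights.
Cochran's Q uses fixed-effect weights; τ² is DerSimonian–Laird,
max(0, (Q−df)/(Σw−Σw²/Σw)); random-effects weights 1/(SE²+τ²); the pooled
CI uses normal quantiles (not Hartung–Knapp). I² = max(0, (Q−df)/Q)·100.
The consistency flag is P_het > 0.1 and I² < 50%. Standard errors are
recovered from printed 95% CIs as (ln hi − ln lo)/(2·1.96), so forests can
be rebuilt from literature-style inputs; risk ratios from raw counts use
the standard log-SE √(1/a − 1/n₁ + 1/c − 1/n₂) with a 0.5 continuity
correction when a margin cell is zero.

## The synthetic cohort generator

The generator emulates the joint structure the analysis assumes, with the
planted truth returned for recovery tests. Defaults (units in parentheses):

| parameter | default | why |
| --- | --- | --- |
| `carrier_fraction` | 0.07 | pan-cancer comut+ prevalence scale (~7%) |
| `tmb_mean` (mut/Mb) | 1.0 | background burden; gives per-gene frequencies ~2% (above the 1% filter) and pathway frequencies ~17%, the 10–25% range typical of signaling pathways |
| `tmb_dispersion` (NB k) | 1.2 | heavy-tailed burden, CV ≈ 0.9 as in pan-cancer data |
| `tmb_shift` (mut/Mb) | +3.0 | carrier shift, ≈3 SD of background TMB |
| `nal_kappa` / `nal_noise` | 0.3 / 2 | NAL ≈ 0.3·mutation count + Poisson noise |
| `baseline_hazard` (/month) | 0.03 | median survival ~23 months |
| `hazard_ratio` | 0.5 | carrier protective effect |
| `censoring_rate` (/month) | 0.012 | ~30% censored |
| `orr_pos` / `orr_neg` | 0.60 / 0.25 | response rates by comut stratum |
| `immune_shift` (log2) | 1.5 | carrier upregulation of the immune panel |

Carriers are guaranteed ≥1 non-silent mutation in each planted pathway;
their extra burden lands on genes *outside* the pathway catalogue. This is
deliberate: spreading ~114 extra mutations uniformly would comutate nearly
every pathway in every carrier, making the planted pair unidentifiable by
any method — the restriction keeps pair-level comutation the only planted
pathway signal while background mutations still hit pathway genes at their
base rate. Cancer type is a 3-level categorical with distinct baseline
hazards (exercising the covariate-adjusted Cox path); sex and age carry
small log-hazard effects. Multi-cohort simulation derives per-cohort seeds
from a master `SeedSequence`, so a collection is reproducible from one
integer while cohorts stay independent.

What the generator does **not** emulate: mutational signatures and
trinucleotide context, copy-number events, gene-length and
expression-correlated mutation rates, cancer-type-specific pathway
frequencies, and correlated censoring. Passing recovery tests therefore
shows the statistical machinery is sound under the stated model, not that
the biomarker generalizes to real tumours.

### Recovery test conditions

The end-to-end recovery experiments run at n = 1000 with carrier HR 0.6 and
the +3/Mb shift. Carrier prevalence for these experiments is 0.25, set by an
a-priori power calculation: the screen's marginal hazard ratio for a planted
pathway is diluted by background comutation (carrier share among
status-positive samples ≈ c/(c+(1−c)·0.175)), and prevalence 0.25 puts the
per-pathway screen z near 4.3, i.e. ~95% per-pathway and ~90% joint power —
an adequately powered design for a recovery experiment, rather than one
sitting at the acceptance threshold. Null-calibration experiments use
carrier fraction 0. Meta-analysis recovery uses five cohorts of n = 300 with
a common carrier HR 0.6, Cox-fitted per cohort and pooled; problem sizes are
chosen so the full suite and the acceptance script each run in minutes on
one CPU.

## Numerical conventions and edge cases

- Wilcoxon rank-sum: exact enumeration when m+n ≤ 20 with no ties, normal
  approximation with tie and continuity correction otherwise.
- Cox: non-convergence (monotone likelihood under separation) raises a
  diagnostic error rather than returning a divergent estimate; constant
  covariates and zero-event inputs are rejected up front.
- All-censored KM stays at 1 with median "NR"; log-rank requires ≥1 event
  and ≥2 groups.
- BH-FDR validates p ∈ [0,1], is order-invariant and capped at 1.
- Quartile split requires ≥4 finite values and a non-constant vector.
- Empty strata are dropped with a warning; pairs with zero comutated
  samples are excluded from the selection contest with a warning.
- Determinism: every stochastic routine takes an explicit seed; the same
  config and seed produce byte-identical files through the CLI.

## Known limitations

- The pair-selection statistic and the "both-β-positive" candidate rule are
  this package's own concrete choices for qualitative steps; alternatives
  (e.g. AIC-based pair scoring) could rank borderline pairs differently.
- The Cox screen is covariate-adjusted, not stratified; strongly
  non-proportional cancer-type effects would argue for stratification.
- GSEA uses a gene-permutation null (see above) and preranked scoring only.
- The exact 2×3 test enumerates up to total 200; beyond that the chi-square
  approximation is used.
- No regularized regression: with many highly correlated pathways the OLS
  βs become unstable before the rank-deficiency error triggers.
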