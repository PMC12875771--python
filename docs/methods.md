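# Methods

## The measurement model

The pipeline implements the Alkire–Foster (AF) dual-cutoff counting
approach to multidimensional deprivation, applied to structural and social
determinants of health (S/SDOH) rather than income poverty. Two cutoffs
operate in sequence. First, each of 37 indicators has its own deprivation
rule mapping raw cohort measurements to 0/1. Second, a participant is
identified as multidimensionally deprived ("poor") when their weighted
deprivation score `c_i = Σ_j w_j g_ij` reaches the cutoff `d` (inclusive:
"11 indicators or more" under equal weights). The aggregate measures are
the headcount ratio `H`, the average deprivation share among the poor `A`,
and the adjusted headcount ratio `M0 = H·A`, which is the composite index.
`M0` satisfies two exact identities used as internal assertions and test
oracles: `M0 = (Σ_poor c_i)/(n·W)` and population-share decomposability
`M0 = Σ_g (n_g/n)·M0_g`.

The default cutoff is `d = 11`, chosen (as in the motivating study design)
so the headcount among the index population sits near 19.2%, the national
poverty proportion of the older Black population it mirrors.
`calibrate_cutoff` makes that choice reproducible: it returns the cutoff
whose `H` is nearest a target prevalence, ties broken toward the smaller
cutoff.

### Weights

Two schemes: **EIW** gives every indicator weight 1 (total weight 37;
cutoff expressed as a count) and **ENW** gives each of the 10 factors one
unit split equally over its member indicators (total weight 10; cutoff
expressed as a share of total weight, e.g. 0.30). Both normalise to shares
internally, so with one indicator per factor they identify identical poor
sets — a property test.

### Contributions

Indicator `j`'s contribution uses the **censored** headcount `CH_j`
(deprived *and* poor) : `w_j·CH_j/(W·M0)`. Censoring is what makes
contributions sum to one; the raw-headcount variant (which need not close)
is available behind `censored=False`. Factor and dimension rollups are
sums of member-indicator contributions.

### Burden

The regression exposure is the per-participant weighted deprivation share
`c_i/W ∈ [0,1]`, uncensored by default: everyone's burden counts, not only
the poor's. The source description of this quantity is grammatically
ambiguous about censoring, so the standard AF censored score (`0` unless
poor) is selectable via `censored=True`; the uncensored reading is the
default because the regression treats deprivation as a continuous exposure
for the whole sample.

### Inference on group differences

No standard-error formula is prescribed for the M0 gap between groups, so
`group_difference_test` uses a participant-level nonparametric bootstrap,
resampling within each group and forming a two-sided percentile p-value on
the M0 difference. Simulation checks show near-nominal type-I error under
label permutation. Normal-approximation alternatives were deliberately not
implemented; percentile bootstrap needs no variance formula for a
ratio-of-means statistic on small groups.

## Indicator rules

Scale-based indicators use *sample-referenced* cutpoints — the analytic
sample's own mean and SD (n−1 denominator) — because the index z-scores
its own cohort; external norms can be supplied per indicator by replacing
the rule. Boundaries are inclusive on both sides (`≤ mean − t·SD` for
deficits, `≥ mean + t·SD` for adverse exposures, default `t = 1`). A
zero-SD scale raises a degenerate-scale error naming the indicator.

Composites:

- **Material living standards**: deprived iff (non-homeowner AND > 2
  persons/room) OR no car access OR no internet. The overcrowding clause
  binds to non-homeownership; the fully conjunctive reading is a registry
  flag. The crowding threshold is strict (`> 2`).
- **Asset index**: two-step polychoric ML (thresholds from marginal
  category frequencies via the inverse normal; the correlation maximising
  the bivariate-normal cell likelihood, optimised on (−0.999, 0.999)),
  eigendecomposition of the polychoric matrix, first-component scores via
  normal-score category quantifications, sign oriented so more assets score
  higher; deprived at `≤ mean − 1 SD` of the scores. Non-positive-definite
  matrices are repaired by eigenvalue clipping with a logged warning.
  Two-step rather than full ML because it is standard practice, faster,
  and accurate at cohort sample sizes.
- **Education**: two separate indicators by default — no college
  attendance, and reading skill at `≤ −1 SD` — because gaps are reported
  separately for years of education and reading; the single conjunctive
  indicator is a registry variant.
- **Barriers to care**: 17 binary difficulty items collapse onto 9
  components; a component is deprived when at least one member item is
  endorsed (the per-component thresholds of the original instrument are
  not public, so ≥ 1 is the declared default, overridable per component).

Missing data are handled by complete-case filtering at the participant
level before cutpoints are formed, with the drop count logged.

## Cognitive outcomes

PCI (possible cognitive impairment) is MoCA total ≤ 23. PCP (poor
cognitive performance) comes from the PACC composite: z-score each of four
components — combined free/cued recall, Trail Making A and B
(reverse-coded so higher is better), animal naming — against the analytic
sample, average them, and flag `≤ mean − 1 SD`. The boundary is inclusive
for consistency with the index's other rules (a strict-mode flag exists,
since the source phrases the cut both ways). Whether recall enters as one
or two components is configurable; one combined component is the default.

## The synthetic cohort generator

The cohort data this pipeline targets are available only on request, so
the generator is a first-class module that emulates the statistical
structure the analysis assumes — not the true joint distribution of any
real cohort.

- **Dependence**: one latent propensity `θ ~ N(0,1)`; indicator `j` fires
  with probability `expit(α_j + λ_j θ)`. The intercepts are root-found
  (Gauss–Hermite quadrature + Brent) so marginals hit the configured
  targets exactly in expectation. A single loading `λ = 0.6` for all
  indicators yields pairwise phi correlations around 0.05–0.15 — positive
  but weak, matching the reported absence of strong indicator overlap. One
  latent factor (not one per dimension) keeps the model tractable;
  per-indicator loadings are configurable.
- **Prevalence profile**: material-hardship indicators highest (~0.3–0.4),
  barrier components lowest (~0.13), scale-tail indicators near the ~16%
  a one-SD cut implies. The profile is scaled by a single frozen factor
  (1.09) so the equal-weight headcount at `d = 11` is 0.192 in the
  large-sample limit — this calibration defines the study condition and is
  part of the package defaults, not a tuning knob.
- **Outcome**: Bernoulli with `expit(β₀ + β_burden·burden + β_age·1{65+} +
  β_sex·female)`; defaults `β_burden = log 11.48`, `β_age = log 1.90`,
  `β_sex = log 0.90`. β₀ is root-found against the realised covariates so
  the marginal outcome rate matches its target (0.337). Demographics are
  drawn independently of `θ` (the analysis adjusts for, but does not
  quantify, demographic–deprivation dependence); fractions follow the
  cohort table (65+: 0.795, female: 0.776).
- **Raw-column emission**: every registry source column is generated so
  that re-applying the rules reproduces the generating binary matrix
  *exactly*. For scale columns this uses a two-cluster construction: the
  deprived cluster is shifted away from the rest until the realised sample
  `mean − SD` cut separates the groups (feasible whenever the deprived
  fraction is below `1/(1+t²)` — one-sided Chebyshev; 50% deprivation on a
  1-SD rule is mathematically unrealisable, and the generator raises).
  Presentation scales/offsets are cosmetic since the rules are
  affine-equivariant. Asset items put the deprived at the lowest category
  and others in upper categories so the polychoric first component
  separates; barrier and living-standards sources trigger their rules
  directly. MoCA totals are drawn on the impaired (≤ 23) or normal side
  according to the outcome; PACC components derive from a latent ability
  correlated with outcome and burden, so PCP emerges (~15%) rather than
  being directly imposed.

What passing tests therefore show: the pipeline's algebra, rules, and
inference behave correctly under a cohort with calibrated marginals, weak
positive dependence, and a logistic burden→outcome link. What they do not
show: robustness to real-data features the generator omits — item
missingness patterns, measurement error in scales, demographic–deprivation
confounding (available but off by default), spatial structure, or
heavy-tailed scale distributions.

## Statistical conventions

- Logistic fits: maximum likelihood (IRLS via statsmodels GLM/binomial);
  Wald intervals `exp(β ± 1.96·SE)`, matching symmetric-on-log-scale
  reporting. Perfect separation is flagged (`converged=False`), not
  raised. Tjur R² = mean fitted probability among cases minus non-cases.
- Chi-square tests are continuity-corrected (Yates) by default; this
  variant is pinned by reproducing the published p = 0.577 on the
  sex-by-status counts (the uncorrected statistic gives 0.483). Two-sample
  t-tests are Welch with Satterthwaite df (pooled by flag).
- ANOVA post-hocs default to Tukey HSD, with Bonferroni selectable — the
  adjustment method behind the source analysis is unstated.
- Marital status is collapsed to married/partnered vs single for the
  regression stage; the 6-level coding is kept for descriptives. The age
  covariate is dichotomised at 65 with under-65 as the reference level
  (configurable; the source table's reference annotation is ambiguous).
- Sample SDs use the n−1 denominator throughout. Identification and share
  cutoffs compare with a 1e-12 tolerance so ENW's 1/3-weights sum exactly
  at factor boundaries.
- Neighborhood-level comparator indices (ADI/SVI) are consumed as optional
  precomputed columns through the same logistic stage; their derivation
  from geographic codes is out of scope.

## Problem sizes

Defaults keep every check fast while leaving Monte-Carlo error well inside
the asserted tolerances: identity/oracle suites use 200 random matrices
(n ≤ 30, k ≤ 12); parameter recovery uses 100 replicates at the cohort's
n = 312; calibration checks use one n = 50,000 cohort; polychoric recovery
uses n = 20,000 with a ±0.05 band; large-sample tail checks use n = 2·10⁵
draws. The full test suite runs in well under a minute on one CPU.

## Known limitations

- The generator cannot emit raw scale scores when a binary column's
  prevalence makes the sample-referenced cut infeasible (≥ 1/(1+t²)); such
  configurations fail loudly rather than approximately.
- Polychoric estimation assumes an underlying bivariate normal per pair;
  no polyserial or mixed continuous/ordinal path is provided.
- The bootstrap M0 test resamples participants only; no survey weights or
  clustered designs.
- No M1/M2 (gap/severity) members of the AF family — deprivations here are
  binary by construction.
- Printed-count acceptance checks take the published table's stratum
  counts at face value; the source's own prose/table discrepancies (e.g.
  207 vs 208 cognitively normal) are not reconciled, and the pipeline
  simply reports its own counts on its own inputs.
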