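# Methods

This note documents the statistical models the package implements, the
synthetic cohort generator that stands in for patient data, the numerical
choices behind both, and the limits of what the test-suite can show.

## Data model

The central object is a samples × proteins matrix of relative abundance on
the log2 scale (NPX-like units), with a per-protein lower detection limit
(LOD) and a missingness mask. Masked cells are excluded from every
statistic; below-LOD values are masked, never imputed (no LOD/√2
substitution). Sample timing is reduced to integer days relative to the
first treatment dose at ingestion. The clinical table carries centre, sex,
age, BMI, ordered metastatic stage (III-unresectable < IV-M1a < M1b < M1c
< M1d, coded 1–5), ECOG, LDH and BRAF status, treatment, the binary
response label, and right-censored PFS/OS endpoints with the invariant
PFS ≤ OS.

## Quality control

Proteins whose fraction of below-LOD values strictly exceeds 25%
(computed over unmasked cells only, so assay failures do not count as
below-LOD) are discarded; below-LOD values in retained proteins are
masked. Extreme values beyond 4 SD of the protein mean are masked in a
**single pass** using the pre-masking mean and SD — one pass preserves the
Chebyshev argument that at most 1/16 ≈ 6.25% of any distribution can be
removed, and makes the filter idempotent in practice. QC runs once on the
pooled baseline + follow-up matrix so a single retained-protein set feeds
all stages. The PCA stratification check standardises each protein (mean
imputation is used for the decomposition only) and reports Kruskal–Wallis
p-values of PC1/PC2 scores across batch-factor levels.

## Two-centre random-effects meta-analysis

Per centre c, a protein's effect is y_c = x̄_NR − x̄_R (log2 units;
positive = higher in non-responders) with Welch SE
se_c = √(s²_NR/n_NR + s²_R/n_R). The group-SD-vs-difference-SE ambiguity
is resolved in favour of the Welch SE of the difference. Centres are
pooled under y_c ~ N(μ, se_c² + τ²); τ² is the REML estimate obtained by
Fisher scoring (score and expected information in τ², DerSimonian–Laird
start, τ² floored at 0, tolerance 1e-8, 100-iteration cap with the trace
carried on failure), verified in the tests against a brute-force
restricted-likelihood grid search and against metafor's REML. CIs and
p-values are z-based; Cochran's Q uses fixed-effect weights. With two
centres the τ² estimate is intrinsically unstable: chance divergence of
the centre estimates inflates the pooled SE, which is visible in the
pipeline's power (see "Generator noise" below).

Multiplicity uses the Li–Ji effective number of tests on the Pearson
correlation matrix of pairwise-complete baseline values:
M_eff = Σ_i [1(|λ_i| ≥ 1) + (|λ_i| − ⌊|λ_i|⌋)], rounded to the nearest
integer before forming the threshold α/M_eff (a printed threshold like
0.05/42 implies an integer count).

## Response prediction

Design matrix: the three marker proteins plus sex (male indicator), age,
BMI, and the ordered stage code. Predictors are standardised on the
training centre (test data transformed with training parameters); missing
values are mean-imputed from the training set with a logged count. The
L1-logistic penalty λ is selected by leave-one-out cross-validated
binomial deviance over a glmnet-style grid (λ_max down to 10⁻³λ_max, 20
points; ties go to the larger penalty); misclassification loss is a
config option. The null model is an independently tuned LASSO on the
covariates alone (two nested models, each trained), not the full model
with markers zeroed. AUC is the Mann–Whitney rank statistic with
half-credit for ties.

The permutation test of marker contribution permutes the rows of the
marker block of the **test** design matrix jointly — one row permutation
applied to all markers simultaneously, covariates untouched — so the
markers' mutual correlation survives under the null. The empirical
p-value uses the add-one convention (1 + #{null ≥ observed})/(B + 1) to
avoid zero p-values; the strict-greater variant is available. Validity of
the permutation p is conditional on the trained model; if the model
assigns all markers zero weight the statistic is permutation-invariant
and p = 1 by construction, which is why the calibration test fixes a
small penalty rather than re-tuning per dataset.

## Longitudinal analysis

Within each patient, baseline is the latest sample with day ≤ 0; the
early window is days 14–34 and late is 35–84 (day 35, exactly five weeks,
belongs to the late window, resolving the 2–5/5–12-week overlap by a
half-open convention), keeping the sample closest to the 21- or 63-day
midpoint with ties to the earlier day. Change scores are follow-up minus
baseline so positive Δ means an on-treatment increase and the mean fold
change is 2^(mean Δ). Per-protein inference is the two-sided Wilcoxon
signed-rank test (exact for n ≤ 25, normal approximation with continuity
correction above; zeros dropped).

The multivariate permutation test is a max-T construction: each protein's
statistic is standardised (signed-rank for paired pre/post, rank-sum for
change-vs-response) so the maximum is comparable across proteins with
different missingness; patients missing a protein are dropped
protein-wise. Per permutation the maximum absolute statistic across the
panel is recorded and protein j's FWER-adjusted p is
(1 + #{max* ≥ |t_j|})/(B + 1). The exchangeable operations — flipping the
sign of a patient's whole delta vector, or permuting responder labels
across patients — leave the protein columns intact, so the adjustment
adapts to the panel's correlation (a duplicated protein incurs no extra
penalty). The max-T reading of "family-wise control" is an assumption of
this implementation.

## Outcome models

Survival curves are Kaplan–Meier (via lifelines); the log-rank test is a
hand-vectorised 1-df statistic (cross-checked against lifelines) because
the survival permutation test calls it thousands of times: proteins are
dichotomised at their median (strictly above = high; ties go low), the
observed signed log-rank z is computed per protein, and permutations
shuffle the (time, event) pairs across patients jointly while the protein
matrix stays fixed — again max-T across proteins. The displayed hazard
ratio is the O/E summary (O₁/E₁)/(O₂/E₂); inference comes from Cox
models. Cox fits use Efron tie handling with Wald CIs; the global
proportional-hazards check is the Grambsch–Therneau χ² built from
unscaled Schoenfeld residuals with a rank transform of event time:
u = Σ(g_k − ḡ)s_k, χ² = uᵀ[Σ(g−ḡ)²/d · V(β̂)⁻¹]⁻¹u on p df, and the
model is flagged when p ≤ 0.05.

Logistic response models (markers on the absolute pg/mL scale, adjusted
for sex, age, BMI and stage) report percentile-bootstrap CIs over 1000
patient-level resamples; single-class resamples are redrawn and counted.
On perfect separation the unpenalised fit raises an error advising a
penalised refit; the penalised path (ridge logistic) reports bootstrap
CIs and a bootstrap sign-test p. Percentile-bootstrap coverage is
asymptotic — at n ≈ 80 the logistic coefficient distribution is
heavy-tailed and coverage dips a few points below nominal, which the
test-suite checks at larger n.

Stratification counts each patient's elevated markers (0–3), tabulates
per-stratum response rates, compares the extreme strata by Fisher's exact
test (probability-mass two-sided p, conditional-MLE odds ratio), and
estimates the additive OR per additional elevated marker by logistic
regression on the integer count plus covariates. Dual-assay concordance
is the per-protein Spearman correlation of paired samples.

## Synthetic cohort generator

The generator draws, per cohort: clinical covariates with marginals
patterned on the emulated study's descriptive table; a response label
from a logistic model (male log-OR ln 0.27, BMI ln 0.91 per kg/m², stage
ln 0.62 per level) whose intercept is calibrated by root-finding so the
cohort-average response probability equals the target ORR (0.53); a
92-protein baseline panel as a block-correlated Gaussian on the log2
scale; marker shifts added to non-responders (0.90/0.41/0.48 log2 units);
per-protein LODs placed at the 40% quantile for the 15 designated
low-detectability proteins and the 1% quantile elsewhere (left-censoring
by quantile directly controls the below-LOD fraction); follow-up samples
for 46 (early) and 35 (late) randomly retained patients at uniform days
within each window, equal to the patient's baseline value plus the
treatment log2-shift (FC 1.43 and 2.41 for the two designated proteins,
applied to all patients) plus within-patient noise; exponential survival
whose log-hazard is linear in the primary marker's absolute level
(ln 1.90 per pg/mL) plus a non-responder effect, with independent
exponential + administrative censoring and PFS = min(progression, death);
and an absolute (pg/mL) assay for the markers obtained by a per-marker
affine map on the log scale (anchored to the study's printed medians:
1.57, 188.98, 50.99 pg/mL) plus noise tuned through the Gaussian-copula
relation ρ_S ≈ (6/π)·asin(r/2) to hit the configured Spearman concordance
band (0.69–0.89). All injected parameters are recorded in a truth record
for recovery tests.

**Generator noise.** The study conditions fix the sample sizes, effect
sizes, retention and concordance, but not the within-group protein SD.
The default (0.25 NPX log2 units) was set by a power analysis of the
two-centre design: detection at the 0.05/M_eff threshold requires the
weakest marker's base z-score (effect / pooled Welch SE) to exceed
3.24·|d| where d is the standardised chance divergence of the two centre
estimates (the k = 2 REML instability), which demands base-z ≈ 8 and
hence SD ≈ 0.25 for an 0.41 log2-unit effect at n = 87. This is an
idealisation: the study's own interval estimates imply protein-specific
SDs of roughly 0.5–1.2, at which the weaker markers would be detected in
only about half of replicate cohorts. Passing pipeline tests on this
generator therefore demonstrate correctness of the machinery, not that
effects of this size are reliably discoverable at n = 87 in real data.
Within-patient longitudinal noise (SD 0.30) is likewise a free parameter;
the study reports no repeat-measurement variance.

What the generator does **not** emulate: non-Gaussian protein
distributions, plate/batch effects, informative dropout (retention is
random), assay drift between visits, correlation between marker levels
and clinical covariates, and RECIST measurement error in the response
label.

## Simulation sizes and numerical choices

Tolerances: REML convergence 1e-8 on τ²; the grid-search REML oracle uses
step 1e-4 on [0, 10]. Empirical p-values use the add-one convention
throughout, so p ∈ [1/(B+1), 1]. Defaults: 1000 permutations for the AUC
test, 5000 for MPTs, 1000 bootstrap resamples. The test-suite runs
scaled-down designs chosen as the package's own verification sizes: 500
cohorts for meta-analysis recovery/coverage, 400 global-null cohorts ×
200 permutations for MPT FWER calibration, 200 datasets × 199
permutations for permutation-AUC uniformity, 40 seeds at 1000 patients
per group for Cox recovery, and 100 seeds for the end-to-end discovery
check. Degenerate inputs are handled explicitly: zero-SD proteins are
excluded from effects (and never masked by the outlier filter), all-zero
delta vectors give p = 1, zero-margin contingency tables give p = 1 with
an undefined OR, and one-class test sets make the AUC undefined (error).

## Known limitations

- With two centres, τ² is weakly identified; z-based intervals are used
  by design and their far-tail behaviour is slightly anti-conservative
  (normal vs ~t₄₀ tails), which matters at multiplicity-corrected
  thresholds near 10⁻³.
- The max-T permutation scheme is one reading of multivariate FWER
  control; step-down refinements would be strictly more powerful.
- The O/E hazard ratio is a display summary, not an estimator with good
  small-sample properties; Cox estimates carry the inference.
- The absolute-assay map is monotone-affine on the log scale; real
  immunoassay calibration curves can be nonlinear near their own limits
  of quantification.
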