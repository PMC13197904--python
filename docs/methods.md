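# Methods

## The measurement problem

DXA partitions body mass into fat mass (FM), lean soft tissue (LST) and
bone mineral content (BMC). These are molecular compartments, not tissues:
adipose tissue is roughly 85% lipid (counted as FM) and 15% fat-free mass —
water, protein, minerals — which DXA books under LST. A person losing
adipose tissue therefore appears to lose lean tissue at ~0.176 kg per kg of
FM even if muscle is untouched. The package's accounting layer works on
three corrections of raw LST:

* **aLST = LST − c·FM** with c = 0.176 by default (exposed as a parameter;
  the exact adipose-composition ratio would be 0.15/0.85 = 0.17647…, and
  0.176 is the conventional rounded operator). Because the map is linear,
  group mean changes transform the same way as individual changes — this is
  what makes the adjustment applicable to published summary statistics.
* **Appendicular restriction**: arms + legs only, ~70% skeletal muscle,
  the usual muscle surrogate. `regional_totals` treats "total" as the sum
  of all six regions including the head.
* **Percentage predicted LST** = 100·observed/predicted. Predicted total
  LST comes from NHANES linear anthropometric equations (height in **cm**,
  weight in kg); predicted appendicular LST from allometric log-log models.
  The shipped allometric equations are only numerically sensible with
  height in **meters** (with cm the predictions are ~100× too large), so
  their model files declare `units.height = "m"`; unit declarations live in
  the model JSON so either convention is expressible. Percentage predicted
  at follow-up recomputes predicted LST from follow-up mass — the metric is
  "relative to body size at that visit" by construction.

## Statistics

Paired changes (6 mo − baseline) are summarized by mean difference with a
Student-t 95% CI and two-sided p. Composition-of-loss proportions
(100·Δcompartment/Δtotal mass) are skewed, so they are reported as median
and IQR with linearly interpolated (type-7) quartiles; subjects with zero
total-mass change are excluded from proportions with the count logged.
Percent-predicted changes are tested on the log scale (positive ratio
data), with the mean difference also reported on the raw percent scale.
Between-diet comparisons use Welch's t for absolute changes (conservative
default; pooled-variance available) and the Wilcoxon rank-sum for
proportions (exact enumeration up to n = 25 per group, normal approximation
with continuity correction beyond). The TEE sensitivity model is OLS of
ΔLST on mean(TEE 3-mo, 6-mo) and a diet indicator.

Analyses are sex-stratified throughout, and the two diet arms are pooled by
default (both are pipeline-level switches).

## NPX quality control

NPX is a log2-scale relative abundance with a per-assay limit of detection.
The QC pipeline runs in a fixed, logged order:

1. drop assays with strictly more than 50% of non-missing values below LOD
   (exactly 50% is retained);
2. replace remaining below-LOD values with that assay's LOD, keeping the
   censoring flags for downstream sensitivity checks;
3. resolve proteins measured on more than one panel to a single copy. The
   published rule "higher LOD and fewer missing values" is internally tense
   (a higher LOD generally means *more* censoring), so the default policy
   prioritizes fewer below-LOD/missing values and uses higher LOD only as
   the tie-break; a `higher_lod` policy swaps the priority;
4. remove sample×panel observations carrying a vendor QC flag (the flag is
   consumed as given — the internal-control deviation behind it is computed
   upstream by the vendor);
5. remove samples whose PC1 score lies more than 3 SD from the mean, in a
   single pass. The PCA pools all samples across timepoints, centers per
   protein, is unscaled, and mean-imputes missing cells for score
   computation only. Only flagged samples are removed, not their partner
   timepoint.

Every removal is appended to an exclusion log from which the clean table
can be reconstructed (tested).

## Residual screen

ΔLST is regressed on ΔFM (OLS with intercept); the residuals isolate LST
change not explained by fat change. Total-body LST is the outcome
(appendicular LST changes too little to residualize usefully). Baseline
protein levels and Δprotein values are then screened one protein at a time:
univariate OLS, and multivariable OLS adjusted for diet, age, height, and
race/ethnicity indicators (Black, Asian, Other, Hispanic; White
non-Hispanic reference; indicator levels with no observations in a stratum
are dropped). The multivariable fit uses Frisch–Waugh–Lovell partialling,
which reproduces the full per-protein regression exactly (cross-checked
against statsmodels) while staying vectorizable. Benjamini–Hochberg
q-values are computed within each of the four model families (baseline/Δ ×
univariate/multivariable), separately per sex; two-sided p from the t
distribution with residual degrees of freedom. Complete-case per protein:
subjects missing an assay (or the 6-mo draw) drop out of that protein's
model only.

## Stability selection

The elastic net mixes an L1 and L2 penalty with weight α (1 = lasso). Both
α (11-point grid by default) and λ (glmnet-style log-spaced path from
λ_max, floor 10⁻² of λ_max for the tuner) are chosen by 10-fold CV
minimizing MSE, with the fold assignment shared across the α grid. The
tuned pair is then fixed and the model refit on B bootstrap resamples of
subjects (standardization recomputed inside each replicate; coefficients
back-transformed to the original scale). A feature is "selected" in a
replicate iff its coefficient is nonzero; features selected in more than
the 60% threshold are reported with the median/IQR of their coefficients —
over all B replicates including zeros by default (conservative), with a
nonzero-only switch. Covariates are always candidates and are tagged in the
output if they pass the threshold.

**Caveat of the min-MSE rule.** Under a global null, CV noise regularly
places the MSE minimum a few path steps below λ_max, which admits the
feature most spuriously correlated in the full data — and that same feature
then stays selected in most bootstrap resamples *of that same data*. The
60% rule is therefore not a null-calibrated error control; it measures
selection consistency, not significance. The one-SE rule would restore
sparsity under the null but changes the procedure; we keep the min rule and
note the caveat. Agreement with the FDR screen (reported features being a
subset of FDR-significant proteins) holds in planted-signal simulations and
is tested.

## Structure discovery

* **Preranked GSEA.** Proteins map to gene symbols via a user-supplied
  two-column table; duplicates collapse to the max-|t| entry, unmapped
  proteins are dropped with a logged count. Gene sets come from GMT files.
  The enrichment score is the weighted Kolmogorov–Smirnov running sum
  (weight exponent 1 on |t|): hits add |t|/Σ_set|t|, misses subtract
  1/(N−s), and ES is the running-sum value of largest magnitude. The null
  is gene-label permutation — random same-size sets (10 000 by default) —
  giving a two-tailed p with the +1 correction (p ≥ 1/(n_perm+1)), BH
  across sets. This plain permutation replaces adaptive multilevel p-value
  machinery: the enrichment question here is a negative-result check, and
  permutation precision of ~10⁻⁴ is ample.
* **Rotated PC regression.** Δprotein columns are standardized
  (correlation-scale PCA). A scree elbow is subjective, so retention uses a
  deterministic rule: the smallest k reaching 60% cumulative explained
  variance, capped at 10 (both configurable). The retained loadings
  (variable–component correlations) are varimax-rotated; rotated scores =
  standardized unrotated scores × rotation matrix; each component is
  oriented so its largest-|loading| protein loads positively. Residuals are
  regressed on the rotated scores jointly; components with p < 0.05 are
  reported with their top-10 loading proteins. Rotation preserves
  communalities (row sums of squared loadings) to 1e-8 — tested.

## The synthetic cohort generator

No subject-level data ship with the package; the generator emulates the
structure of a two-arm diet trial so every stage runs against known ground
truth.

* **Demographics.** Sex Bernoulli(0.607 female); age truncated-normal
  39.4 ± 6.7 y on [18, 50]; BMI truncated-normal per sex (32.1/32.5 ± 3.2/3.3)
  on [28, 40] — the eligibility windows of such trials. Truncation shifts
  the realized mean (≈ −0.8 y for age); calibration tests compare against
  the analytic truncated-normal moments. Heights are normal per sex
  (164.4/176.8 ± 6.4/6.9 cm, chosen so BMI·height² reproduces the cohort
  mean masses); body-fat% truncated-normal per sex (40.6/30.1 ± 4.0/4.8);
  BMC ≈ 4% of weight; LST is the remainder. Race/ethnicity and diet-arm
  frequencies follow the cohort margins.
* **Changes.** A core mass change is drawn per sex (−5.9 ± 4.7 kg female,
  −7.18 ± 6.3 male; SDs back-calculated from the published CIs), ΔFM =
  f·core + η with f = 0.725/0.685 and η ~ N(0, 0.4 kg), ΔBMC ~ N(0,
  0.05 kg) (bone change is never reported and is near zero). The
  protein-driven deviation u = Σ_p γ_p·ΔProtein_p + ε (ε ~ N(0, 0.7 kg))
  is added to ΔLST, and Δtotal mass is defined as the exact sum, so mass
  conservation holds to machine precision. The residual SD around the
  ΔLST~ΔFM line is a free parameter of the design (the source tables give
  only marginal CIs); 0.7 kg plus the FM-noise leak-through gives the
  screen moderate power at n ≈ 350, with a single dominant planted effect
  (γ = 1.2 kg per NPX unit by default, the "DLK1-like" marker) explaining
  ~13% of residual variance. Compartment positivity is enforced by
  resampling, with a degenerate-config error after 1000 rounds.
* **Regions.** Appendicular fractions per sex at the cohort ratios
  (female LST 21.1/49.0, FM 17.1/35.4; male 30.6/67.8, 12.1/30.8) plus
  N(0, 0.02) noise; arms carry 27% of limb mass; fixed head shares of the
  non-appendicular remainder. Appendicular change fractions follow the
  published change ratios.
* **NPX.** Baseline NPX ~ N(μ_p, 1) with μ_p ~ U(1, 9); ΔProtein ~
  N(0, 0.3) except planted columns, which are shared verbatim with the
  cohort truth. Per-assay LOD at the 5% empirical quantile (70% for the
  heavy-censored block, guaranteeing the >50% rule fires); 10 proteins
  duplicated on a second panel with N(0, 0.15) copy noise; sample×panel QC
  flags at 1.3%; 20 subjects lack the 6-mo draw (354 paired of 374, the
  708-sample shape); 2 follow-up samples shifted +2.5 NPX on every protein,
  which puts them far outside 3 SD on PC1.
* **What it does not emulate:** DXA measurement error structure,
  plate/batch effects and bridging normalization, protein–protein
  correlation beyond the planted signal and panel duplicates, diet-specific
  effect modification beyond a configurable mean shift, and any real
  biology behind the gene sets (the pipeline's GMT for simulated data is
  random). Passing tests therefore demonstrate procedure correctness and
  calibration under the stated generative model, not performance on real
  cohorts.

## Calibration experiments (`leansift.experiments`)

Sizes quoted are the package's defaults. FDR control: 200 global-null
screens (242 proteins, n = 200) keep the mean false-discovery proportion at
nominal 5% below 0.07. Plant-and-recover: the single planted marker is the
smallest-p protein in ≥95% of 200 cohorts at n = 227 and exceeds the 60%
bootstrap selection frequency (B = 200, α fixed at 0.5 for the tuning loop
of the experiment) in ≥90% of 50 cohorts. Allometric recovery: with
NHANES-like height spread (SD 7.1 cm) and multiplicative noise SD 0.02, the
penalized fit on a full cohort of 466 recovers both exponents of the known
law within ±0.05 in ≥95% of 100 cohorts; the recovery experiment fits on
the full cohort because it probes the estimator, while `fit_allometric_model`
keeps the 80/20 split for honest test-set R². The LassoCV path floor is
10⁻⁴·λ_max (the glmnet default for n > p); a higher floor leaves visible
shrinkage bias on the small-variance log-height predictor.

## Numerical conventions and edge cases

* Quartiles: linear interpolation (type-7) everywhere.
* Zero-variance paired differences: mean reported, CI degenerate, p = NaN,
  `degenerate` flag set.
* Constant ΔFM: residualization refuses (slope undefined).
* Singular multivariable designs raise naming the aliased columns; a
  protein collinear with the covariates raises naming the protein.
* Degenerate bootstrap replicates (constant resampled outcome) are skipped
  and counted.
* Gene sets smaller than 3 after intersection, or spanning the whole
  ranked list, are skipped with a reason.
* All randomness flows through explicit integer seeds; identical seeds give
  byte-identical outputs (tested), and the pipeline manifest hashes every
  stage's inputs and outputs so a changed seed is attributable to its
  stage.

## Known limitations

Whether DXA "total mass" should include the head is convention; we include
it. The appendicular-mass predictor includes limb BMC. The FFAT coefficient
is a population constant applied uniformly; true adipose hydration varies.
The bootstrap elastic net reports consistency, not calibrated error (see
caveat above). The percent-predicted paired test reports the raw-scale mean
difference alongside a log-scale p, which mixes scales deliberately to
match how such tables are conventionally presented. PC labels refer to
rotated components; significance testing uses rotated scores.
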