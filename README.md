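# leansift

Does diet-based weight loss cost you muscle? DXA, the workhorse of body
composition studies, cannot answer that directly: it splits the body into
fat mass (FM), lean soft tissue (LST) and bone mineral content, and its LST
compartment silently includes the fat-free part of adipose tissue (FFAT —
the ~15% of adipose tissue that is water, protein and mineral). When
someone loses a lot of fat, measured LST drops even if no muscle was lost.

`leansift` is an analysis pipeline for paired-DXA weight-loss cohorts with
Olink-style plasma proteomics. It quantifies LST change three ways and then
screens proteins for association with LST *retention*:

1. **By region.** Appendicular (arms + legs) LST is ~70% skeletal muscle and
   the preferred muscle surrogate; totals and appendicular sums come from
   regional scans.
2. **FFAT-corrected.** The adjusted measure `aLST = LST − 0.176·FM` removes
   the adipose-tissue contamination (adipose tissue = FM/0.85, so FFAT ≈
   0.176·FM). The correction is linear, so it applies to changes as well as
   levels.
3. **Relative to body size.** Percentage predicted LST =
   100 · observed / predicted, with predicted LST from shipped NHANES
   anthropometric equations (total LST) or allometric log-log models
   (appendicular LST), e.g. for females

   ln(appLST) = 0.33 + 0.60·ln(appendicular mass) + 1.03·ln(height) + …

   New allometric models can be re-derived on any cohort by LASSO with a
   10-fold cross-validated penalty and an 80/20 train/test split.

For the proteomics, ΔLST is regressed on ΔFM and the residuals — LST change
not explained by fat change — become the outcome. Per-protein linear models
(univariate and covariate-adjusted, sex-stratified) are screened at 5%
Benjamini–Hochberg FDR; a bootstrapped elastic net (features reported if
selected in >60% of resampled refits) finds a minimal predictive set; and
preranked permutation GSEA plus varimax-rotated PC regression look for
higher-order structure. NPX quality control (LOD filtering and imputation,
redundant-panel resolution, vendor QC flags, PC1 outlier removal) is built
in, as is a synthetic-cohort generator with known ground truth so every
stage is testable end to end.

## Worked example

Run the full pipeline on the default simulated cohort (374 subjects, 61%
female, 266 unique proteins on three panels):

```bash
leansift run --out-dir demo_run
```

`demo_run/table_total.tsv` (values from this run, rounded):

| region | sex    | measure | n   | mean_diff | ci_lo | ci_hi | median_prop |
|--------|--------|---------|-----|-----------|-------|-------|-------------|
| total  | female | mass    | 215 | −6.01     | −6.63 | −5.39 | —           |
| total  | female | fm      | 215 | −4.37     | −4.82 | −3.92 | 71.2        |
| total  | female | lst     | 215 | −1.64     | −1.85 | −1.43 | 28.8        |
| total  | female | alst    | 215 | −0.87     | −1.03 | −0.71 | 16.3        |

Reading it: the simulated women lost ~6 kg over six months, most of it fat.
Raw LST change (−1.64 kg) looks like a 29% lean contribution to weight
loss, but after removing the FFAT artifact the adjusted change is only
−0.87 kg (16% of the loss). The appendicular table shrinks it further
(−0.44 kg, 8%), and `table_percent_predicted.tsv` shows percentage
predicted appendicular LST *rising* from 99.5% to 100.3% (mean difference
+0.77, 95% CI 0.51–1.04, p < 0.001): relative to their smaller bodies,
participants end with proportionally more lean tissue than they started
with.

On the proteomic side the generator plants a dominant protein-change
effect on the LST residuals (a stand-in for the DLK1 adipogenesis-inhibitor
signal). In this run `screen_results.tsv` puts that protein at the top in
both sexes (female β = 1.39 kg per NPX unit, q = 5.7 × 10⁻⁵), the
bootstrap elastic net selects it in 100% (female) and 96% (male) of 200
resamples — far above the 60% reporting threshold — and none of the 50
random gene sets is enriched at 5% FDR, as expected when the signal sits in
a single protein.

Library use mirrors scikit-learn:

```python
from leansift import CohortConfig, simulate_cohort, ffat_adjust, ProteinScreen

adj = ffat_adjust(lst=49.0, fm=35.4)      # aLST = 42.77 kg
est = ProteinScreen(family="delta:multivariable").fit(delta_npx, residuals,
                                                      covariates=covs)
est.significant_                           # proteins at 5% FDR
```

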