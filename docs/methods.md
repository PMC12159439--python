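# Methods

## Generative model

Cohorts are simulated under a multi-trait liability-threshold model. Every
liability is constructed with unit variance, so prevalences map to
thresholds through the standard-normal quantile: trait j with prevalence
K_j is diagnosed iff its liability exceeds Φ⁻¹(1 − K_j).

For individual i:

- polygenic score g_i ~ N(0,1); latent shared factor C_i ~ N(0,1); all
  noise terms independent N(0,1);
- index-disease liability
  L_i = √r²·g_i + b·C_i + √(1 − r² − b²)·e_i, case iff L_i > Φ⁻¹(1 − K);
- comorbidity j liability
  L_ij = α_j·g_i + β_j·C_i + √(1 − α_j² − β_j²)·ε_ij.

α_j is the pleiotropic loading of the index-disease PRS on comorbidity j;
β_j the loading of the shared non-genetic factor. Parameter validation
rejects any decomposition with negative residual variance (r² + b² > 1 or
α² + β² > 1).

Diagnosis streams are ICD-10-style. Each diagnosed comorbidity contributes
its 4-character code; in addition each person receives Poisson(λ)
background codes drawn uniformly from per-chapter pools of synthetic but
chapter-valid codes (pools never contain N80* or configured comorbidity
codes). Background diagnoses are status-independent by default; an optional
log-linear, mean-preserving coupling of the Poisson rate to C emulates
healthcare-exposure confounding and is off in every documented study so the
collider mechanism can be isolated. Ages are uniform on the configured
range and independent of all liabilities: the analyses are designed for
age-matched cohorts, so simulating age effects would add nothing testable.
There is a single diagnosis stream (no self-report vs hospital split).

The PRS exposed to the analyses is, by default, the true standardized
genetic score g, so r² is exactly the liability variance it explains.
Genotype mode exists to exercise file-based scoring: dosages are
binomial(2, f) with f ~ U(0.05, 0.5), weights standard normal, and the
standardized weighted dosage score replaces g. Discrimination (AUC) is an
emergent property of r² and prevalence, never an input.

All randomness flows from one root seed through named substreams
(liabilities, ages, background codes, genotypes), so adding a stage never
perturbs earlier stages' draws and cohorts are byte-identical across runs.

### Default parameters

| parameter | default | notes |
|---|---|---|
| n_individuals | 200,000 | biobank scale; smaller sizes used where noted |
| endo_prevalence K | 0.05 | cohort-level case fraction, matching a ~17:1 control:case design |
| prs_r2 (r²) | 0.26 | liability variance explained by common SNPs for endometriosis |
| shared_factor_loading b | 0.45 | ~20% of liability variance from the shared factor |
| comorbidity α, β | 0.1, 0.5 | weak pleiotropy, strong shared non-genetic factor |
| comorbidity prevalence | 0.04–0.12 | female biobank-scale rates for the six index conditions (asthma, diverticular disease, IBS, uterine fibroids, dysmenorrhea, heavy menstrual bleeding) |
| background_rate λ | 4.0 | mean background diagnoses per person |
| chapter pools | 10 codes × chapters 1–21 | ~200 distinct background codes |
| age_range | 25–70 years | uniform |

The collider reference simulation (`collider_default_params`) replaces the
six named comorbidities with twenty conditions (prevalence 0.10 each,
α = 0.1, β = 0.5, distinct 3-character stems) so that comorbid burden is a
genuine count rather than a near-binary variable.

## ICD-10 handling

Codes are stored dot-less and uppercase (`[A-Z][0-9]{2,4}`); "3/4/5
character" counts exclude the dot, so N80.1 is 4-character. Chapter
assignment follows the WHO chapter boundaries on the 3-character prefix,
with gap prefixes (e.g. D49) rejected loudly rather than silently mapped —
this surfaces coding-dialect mismatches in real inputs; the simulator never
generates them. Burden counts deduplicate *after* truncation, so K570 and
K571 are one 3-character condition. Comorbid membership is decided at
4-character resolution (where the scan runs) and then reduced; a native
3-character code is a valid member of a 4-character set. Default
exclusions: chapters 19–21 and N80.1–N80.9. Bare N80/N80.0 is retained by
default (the documented exclusion range starts at .1) with a flag to drop
all N80*.

## Statistical choices

- **Per-code test**: Pearson chi-squared without continuity correction;
  Fisher's exact (two-sided, point-probability method) whenever any
  expected cell count is below 5. Both choices are isolated behind one
  function for sensitivity analysis. Odds ratios use +inf/0 sentinels on
  zero cells; no Haldane–Anscombe correction by default since direction
  filtering needs only the OR's side of 1.
- **Multiplicity**: Benjamini–Hochberg over *all* tested codes; exclusions
  are applied to the significant set afterwards. "Significant decreased
  risk" codes (FDR-significant, OR < 1) are removed from the comorbid set.
- **Chapter-composition comparison**: two-proportion chi-squared with Yates
  continuity correction, matching R `prop.test` defaults.
- **PRS scoring**: plink `--score` average-per-allele convention,
  sum(w·dosage)/(2·n_snps); missing dosages imputed to 2f when frequencies
  are available, else dropped with the divisor adjusted. Irrelevant after
  z-scoring but fixed for reproducibility. Standardization uses the
  combined case-control cohort with the n−1 SD.
- **Quantiles**: rank-based with stable tie-breaking by input order, so bin
  sizes always differ by at most one; a warning is emitted when ties
  actually cross a bin boundary. Centile ORs use unconditional 2×2 tables
  against the median bin with Woolf (log-OR normal) 95% CIs.
- **OLS**: classical homoskedastic SEs (the burden response is a count, but
  the documented analyses report a plain linear model); rank deficiency is
  detected and the collinear columns named.
- **Logistic MLE**: Newton iterations via statsmodels; (quasi-)separation
  or non-convergence is flagged and coefficients are withheld rather than
  reported as spuriously large numbers.
- **Additive-scale interaction**: per-decile prevalence difference in
  percentage points with Wilson CIs per arm; deciles with an empty arm are
  flagged and excluded from the top/bottom ratio, which is reported to one
  decimal place (the convention when quoting "x times greater").
- **Age matching**: greedy without replacement, processing cases in age
  order and taking the youngest available control in each ±tolerance
  window (the standard greedy that maximizes total matches). A case errors
  only if the pool contains *no* control within tolerance; windows emptied
  by earlier cases yield partial or zero matches, since the contract is "up
  to ratio controls". The matching algorithm and tolerance are exposed as
  parameters rather than fixed.

## Cross-cohort contract

Comorbid code sets are discovered by scanning one cohort and consumed by
burden counting in the *other*; the pipeline refuses same-cohort
scan-and-count unless explicitly overridden. This prevents the circularity
of selecting codes and measuring their burden in the same individuals.

## Reference experiments and problem sizes

The experiments module fixes the study conditions used by both the test
suite and `scripts/acceptance.py`:

- **Collider signature**: ten replicate cohorts of 200,000 under the
  collider defaults; expectation is a negative PRS × status interaction on
  comorbid burden and a nonnegative control-arm PRS-burden correlation in
  at least 9 of 10 seeds.
- **Null scan FDR**: 100 replicates of 50,000 individuals carrying only
  background codes (~200 codes, all null). The cohort size keeps expected
  2×2 cell counts near 50: the quantity BH thresholds is the extreme tail
  (p ≈ q/m ≈ 2.5e-4), where the chi-squared approximation is accurate only
  when expected counts are well above the Fisher-switch threshold of 5. At
  10,000 individuals (expected counts ≈ 10) the realized false-positive
  rate exceeds the nominal level through test-statistic tail error, not
  through any failure of the step-up procedure — a practical caveat for
  phenome scans of rare codes generally.
- **CI calibration**: 1,000 replicates of 4,000 individuals drawn from a
  logistic model with zero interaction; the fitted interaction's 95% CI
  should cover zero in at least 93% of replicates (1,000 replicates keep
  the Monte-Carlo SE of the coverage estimate near 0.7 points).
- **AUC limits**: single 200,000 cohorts at r² ∈ {0, 0.05, 0.26} with all
  other loadings zero; chance-level discrimination at r² = 0 and strictly
  increasing AUC thereafter.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* — threshold disease liability,
pleiotropy, shared non-genetic factors, status-independent background
coding — not the messiness of real biobank data: no diagnostic censoring
windows, no coding-practice drift, no self-report/EHR disagreement, no age
or ascertainment structure, no linkage disequilibrium (genotypes are
independent SNPs), and one diagnosis stream per person. Passing tests
demonstrate that the analysis stack is correct and that the collider
signature follows from the stated model; they do not certify effect sizes
in any real cohort, where realized AUCs and interaction magnitudes depend
on data-specific PRS accuracy and confounding.

## Known limitations

- Realized PRS discrimination at r² = 0.26 (AUC ≈ 0.80) exceeds what
  current endometriosis PRSs achieve (AUC ≈ 0.6), because real scores
  capture only part of the SNP heritability; r² here is the *score's* own
  variance explained, so emulating a weaker PRS means lowering r², not
  reinterpreting it.
- The additive-scale difference ratio is reported descriptively without a
  formal test; a bootstrap CI is a straightforward extension.
- Fisher's exact p-values use the point-probability two-sided rule; other
  two-sided conventions (central, mid-p) differ on sparse tables.
- Burden regressions use no covariates, assuming age-matched inputs.
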