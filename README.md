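# endoprs

Analyses of the interplay between polygenic risk and diagnosed comorbidities
in endometriosis-style case-control biobank cohorts, driven entirely by a
liability-threshold cohort simulator — no access-controlled biobank data
required.

The package is aimed at statistical geneticists and genetic epidemiologists
who want to study (or teach) a recurring puzzle in biobank analyses: a
disease's polygenic risk score (PRS) correlates *positively* with
comorbidity burden in unaffected individuals but *negatively* in cases.
Under a liability-threshold model this sign flip needs no biological
antagonism — it is index-event (collider) bias, induced by conditioning on
case status when genetic and non-genetic causes combine additively in the
liability. `endoprs` implements the full analysis stack on synthetic
cohorts where the generative truth is known, so every stage and the
qualitative signatures can be verified end to end.

## Model

Each individual draws a standardized polygenic score g ~ N(0,1), a latent
shared factor C ~ N(0,1) (non-genetic risk shared between the index disease
and its comorbidities), and independent noise. Index-disease liability is

    L = sqrt(r²)·g + b·C + sqrt(1 − r² − b²)·e,   e ~ N(0,1)

and an individual is a case iff L > Φ⁻¹(1 − K), where K is the disease
prevalence and r² the liability variance explained by the PRS. Each
comorbidity j has its own unit-variance liability α_j·g + β_j·C + noise and
its own prevalence threshold; diagnosed comorbidities contribute their
ICD-10-style code to the individual's diagnosis stream, alongside a Poisson
number of status-independent background codes drawn from per-chapter pools.

On top of the simulator the package implements:

- **Phenome-wide comorbidity scan** — per-code 2×2 tests against case
  status (Pearson chi-squared, Fisher's exact when any expected cell
  count < 5) with Benjamini–Hochberg FDR, direction filtering, and
  chapter/code exclusions (injury/external-cause/contact chapters 19–21
  and the disease's own N80.1–N80.9 codes).
- **Comorbidity-burden metrics** — unique diagnosis counts at 3- and
  4-character ICD-10 resolution, total and comorbid-restricted, chapter-wise
  and leave-one-chapter-out, with a cross-cohort contract: the comorbid code
  set discovered in cohort A is counted in cohort B and vice versa.
- **PRS stratification** — plink-convention scoring from a weight table,
  z-scoring, decile/centile assignment, per-centile odds ratios vs the
  median bin (Woolf CIs), ROC AUC, and prevalence-by-burden tables.
- **Interaction models** — linear burden ~ PRS × status (the collider
  signature), logistic status ~ PRS × comorbidity (multiplicative scale),
  and decile-stratified absolute prevalence differences (additive scale)
  summarized by the top-vs-bottom-decile ratio.

## Worked example

```python
from endoprs import (SimulationParams, simulate_cohort, default_index_comorbidities,
                     phenome_scan, build_comorbid_set, burden_table,
                     burden_prs_interaction, roc_auc, assign_quantiles,
                     additive_interaction, welch_t)

common = dict(n_individuals=50_000,
              comorbidities=tuple(default_index_comorbidities()))
cohort_a = simulate_cohort(SimulationParams(seed=1, **common), label="A")
cohort_b = simulate_cohort(SimulationParams(seed=2, **common), label="B")

# discover comorbid codes in B, count burden in A (cross-cohort contract)
scan_b = phenome_scan(cohort_b, q=0.05)
comorbid_from_b = build_comorbid_set(scan_b)
burden_a = burden_table(cohort_a.diagnoses, cohort_a.ids, comorbid_from_b)

case = cohort_a.status
b3 = burden_a["comorbid_3char"].to_numpy()
t, df, p, mean_case, mean_ctrl = welch_t(b3[case], b3[~case])
fit = burden_prs_interaction(cohort_a, burden_a, metric="comorbid")
deciles = assign_quantiles(cohort_a.phenotypes.set_index("id")["prs_z"], k=10)
fib = additive_interaction(cohort_a, "uterine_fibroids", deciles)
```

With the default parameters (prevalence 5%, r² = 0.26, b = 0.45, six index
comorbidities with α = 0.1, β = 0.5) this prints:

```
cohort B scan: 6/216 codes FDR-significant; 6 retained after exclusions
comorbid burden: case mean 1.23, control mean 0.46, Welch p 1.37e-183
PRS AUC in cohort A: 0.803
burden ~ PRS x status interaction: -0.128 +/- 0.019, p = 4.76e-12
fibroids decile-1 difference 1.09 pp, decile-10 14.27 pp, ratio 13.1
```

Reading the output: the scan recovers exactly the six truly loaded
comorbidity codes out of ~216 tested; cases carry about 2.7× the comorbid
burden of controls; and although every pairwise relationship (PRS-disease,
burden-disease, PRS-burden in controls) is positive, the PRS × status
interaction on burden is significantly *negative* — the collider signature.
The additive-scale table shows the absolute prevalence increase conferred
by a fibroids diagnosis growing steeply across PRS deciles, while (not
shown) the same cohort's multiplicative interaction term is negative: an
artifact of the log-odds scale's dependence on baseline risk.

A command-line interface mirrors the library
(`endoprs run-all --out out/ --seed 0`, plus `simulate`, `scan`, `burden`,
`prs`, `interact` subcommands that compose to the same outputs).

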