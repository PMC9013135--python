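# wealthgap

Quantifying and decomposing household-wealth inequality in under-five deaths
on clustered, weighted survey microdata.

The package provides, end to end:

* **`wealthgap.synthetic`** — a seeded generator of multi-country, clustered
  child-level survey data (log-normal sampling weights, within-country wealth
  quintiles cut at weighted 20% points, categorical covariates whose
  distributions differ between poor and non-poor households, a logistic death
  outcome with cluster random intercepts and per-country effect
  heterogeneity), plus Monte-Carlo ground-truth oracles
  (`true_contributions`, `marginal_rates`) for parameter-recovery testing.
* **`wealthgap.harmonize`** — poor/non-poor dichotomy (quintiles 1–2 vs 3–5),
  a cluster-level socioeconomic disadvantage composite (first principal
  component of cluster rates of no-education / no-media-access / unemployment,
  oriented so higher = more disadvantaged, cut into weighted quintiles), and
  iterative VIF screening (threshold 2.5) of the dummy-coded design.
* **`wealthgap.heat`** — weighted subgroup prevalences and the summary
  measures D, R, PAR, PAF with 95% CIs, including the adverse-indicator
  conventions (reference = highest quintile, PAR/PAF truncated to 0 when the
  reference subgroup does worse than the national average, PAF = PAR/μ·100).
* **`wealthgap.meta`** — per-country poor-vs-non-poor risk differences with
  pro-poor / pro-non-poor / insignificant classification, inverse-variance
  fixed effects and DerSimonian–Laird random effects (Q, τ², I², weights),
  Mantel–Haenszel pooled odds ratios with Robins–Breslow–Greenland CIs and a
  Woolf-weighted homogeneity test, and the prevalence × inequality country
  typology.
* **`wealthgap.fairlie`** — a from-scratch nonlinear decomposition of the
  poor/non-poor gap in death probability: pooled weighted logit (group
  indicator dropped at prediction time), subsample-and-rank matching,
  sequential substitution of covariate blocks, and averaging over seeded
  random covariate orderings and subsample draws. Per replication the
  per-covariate contributions telescope exactly to the explained gap.
* **`wealthgap.pipeline` / CLI** — a reproducible generate → harmonize →
  measures → meta → decompose run with CSV/JSON stage outputs and a manifest.

## CLI

```sh
wealthgap simulate --seed 7 --out results            # synthetic survey CSV
wealthgap harmonize --input results/data.csv --out results
wealthgap heat      --input results/data.csv --out results
wealthgap meta      --input results/data.csv --out results
wealthgap decompose --input results/data.csv --seed 7 --out results
```

or run everything from a config:

```sh
wealthgap all --config run.yaml
```

with `run.yaml` like

```yaml
seed: 7
synthesis:            # or: input_path: path/to/data.csv
  n_countries: 10
  clusters_per_country: 30
  births_per_cluster: 40
  covariates:
    - {name: residence, categories: [rural, urban], p_poor: [0.8, 0.2], p_non_poor: [0.45, 0.55]}
  outcome:
    intercept: -3.2
    poor_effect: 0.25
    covariate_effects: {residence: {rural: 0.3}}
  cluster_re_sd: 0.2
  country_effect_sd: 0.15
n_orderings: 20
n_subsamples: 5
output_dir: results
```

Input CSVs need columns `country_id, cluster_id, weight, wealth_quintile,
died` plus one column per categorical covariate.

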