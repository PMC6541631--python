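# cytoscreen

Prognostic survival screening of tumor expression programs — the kind of
question a cancer biologist asks of a TCGA cohort: *which cytokines,
receptors, or regulator-controlled genes predict poor patient survival, and
do ligand–receptor programs act together?*

The package implements the full screening stack from first principles:

* **Kaplan–Meier** product-limit estimation of S(t) under right censoring,
  with at-risk/event bookkeeping and median survival;
* the **logrank test** (hypergeometric expected events and variance at each
  distinct event time, χ² with 1 df);
* **Cox proportional hazards** for a binary group covariate, maximizing the
  partial likelihood by Newton–Raphson with Efron (default) or Breslow tie
  handling — the per-gene screening engine;
* the **combined prognostic rank**: each gene's cohort-mean-dichotomized
  high/low expressor groups yield a survival p-value; p-values are ranked,
  and a ligand's and its receptor's ranks are aggregated (mean by default)
  into one score per cytokine signaling program;
* **iterative Kaplan–Meier** screening of gene lists with poor/good
  direction calls, Z-score stratification (> 0.25 / < −0.25 with an excluded
  middle band), concordant dual-marker groups, GISTIC copy-number zygosity
  groups, and two-gene cross stratification;
* **genome-wide Pearson ranking** against an index gene, a Welch two-group
  expression test with Benjamini–Hochberg q-values, and exact one-sided
  **hypergeometric gene-set enrichment** over GMT libraries;
* a **synthetic cohort generator** with planted, recoverable ground truth
  (correlated ligand–receptor blocks, proportional-hazards gene effects,
  copy-number states with their own hazards), so every stage is testable
  without any download.

Data flows through plain TSV/GMT text files in the cBioPortal-export
dialects (a second Entrez-id column and `0:LIVING`/`1:DECEASED` status
strings are understood), with `NA` for missing values.

## Model

For gene *g*, patients are split at the cohort mean of the Z-scored
expression: x_i = 1 if z_gi exceeds the mean, else 0. The hazard of patient
*i* is modeled as

    h_i(t) = h0(t) · exp(β · x_i)

and β̂ (log hazard ratio of high expressors) is the maximizer of the Cox
partial likelihood; the per-gene p-value is the two-sided Wald test (the
logrank p is always computed alongside and may drive ranking instead).
Genes are ranked by ascending p (average-rank ties). For a ligand L with
receptors R₁…R_k, the combined score is

    score(L) = agg( rank(L), agg(rank(R₁) … rank(R_k)) ),  agg ∈ {mean, sum, best}

and programs are ordered by ascending score. Enrichment of a target list T
in a gene set S within universe U is the exact hypergeometric tail
P(X ≥ |S∩T|) with X ~ Hypergeom(|U|, |S∩U|, |T|).

## Worked example

Simulate a 208-patient cohort with one planted IL1B–IL1R1-style pair
(expression correlation 0.77, per-gene log hazard ratio 0.9 for above-mean
expressors) among null genes, then screen and rank:

```python
import cytoscreen as cs

cfg = cs.SyntheticCohortConfig(
    n_samples=208, n_genes=60,
    planted_pairs=(cs.PlantedPair("IL1B", "IL1R1", rho=0.77, beta=0.9),),
    rng_seed=42)
cohort = cs.simulate_cohort(cfg)
expr = cs.zscore_normalize(cohort.expression)
screen = cs.screen_genes(expr, cohort.clinical)
print(screen.summary(top=5))
```

```
Survival screen: 60 genes tested (0 untestable), endpoint OS, ranking test cox
significant at alpha=0.05: 4
  gene  n_high  n_low  hazard_ratio     cox_p  logrank_p   p_value   q_value  rank direction  converged
  IL1B     102    106         3.802 2.653e-14  8.067e-16 2.653e-14 1.592e-12     1      poor       True
 IL1R1     103    105         3.263 1.866e-13  1.585e-14 1.866e-13 5.597e-12     2      poor       True
G00030      91    117        0.7079   0.02225    0.02167   0.02225    0.3818     3      good       True
G00010     105    103         1.391   0.02545    0.02483   0.02545    0.3818     4      poor       True
```

Both planted genes take ranks 1–2 while the null genes' p-values scatter
uniformly. The marginal hazard ratios (≈ 3.3–3.8) exceed the per-gene
exp(0.9) ≈ 2.46 because the ρ = 0.77 correlation makes each gene's high
group co-expose the partner's effect. Combining ranks puts the planted pair first:

```python
pairing = cs.PairingMap(entries=(("IL1B", ("IL1R1",)),
                                 ("G00000", ("G00001",)),
                                 ("G00002", ("G00003",))))
print(cs.combined_rank(screen, pairing).table.to_string(index=False))
```

```
ligand  ligand_rank  receptor_rank  combined_score  order
  IL1B          1.0            2.0             1.5      1
G00000         42.0            7.0            24.5      2
G00002         55.0           20.0            37.5      3
```

Patients concordantly high for both markers fare dramatically worse than
concordantly low patients (discordant patients are excluded):

```python
labels = cs.dual_marker_groups(expr, "IL1B", "IL1R1")
surv = cohort.clinical.endpoint("OS").loc[labels.index]
lr = cs.logrank_test(surv["time"], surv["event"], labels)
# logrank chi2 = 78.610, p = 7.57e-19
# both_high: n = 82, median survival = 2.7 months
# both_low:  n = 85, median survival = 15.4 months
```

The same flows are scriptable from the shell (`cytoscreen simulate`,
`cytoscreen cyto-screen`, `cytoscreen iterative-km`, `cytoscreen gene-rank`,
`cytoscreen enrich`, …); see `cytoscreen --help`.

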