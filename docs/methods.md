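# Methods

This note records the statistical model, the defaults and why they were
chosen, the numerical decisions, and the limits of what the synthetic-cohort
tests demonstrate.

## Survival machinery

**Kaplan–Meier.** S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event
times, with the standard convention that subjects censored at t leave the
risk set after the events at t. The median is the smallest event time with
S(t) ≤ 0.5; a curve that never reaches 0.5 (heavy censoring) has an
undefined median rather than a sentinel value. All-censored input is a flat
curve at 1, not an error.

**Logrank.** Two groups only. At each distinct event time with d events, n
at risk and n₁ at risk in group 1, the group-1 expectation is d·n₁/n and the
variance is the hypergeometric variance d·(n₁/n)(1−n₁/n)(n−d)/(n−1); the
statistic (O−E)²/V is referred to χ² with 1 df. Zero total events yields
p = 1 with an explicit flag instead of an error, because null fixtures can
legitimately produce it.

**Cox (binary covariate).** The partial likelihood is maximized by
Newton–Raphson from β = 0, with steps damped to |Δβ| ≤ 2 to prevent early
overshoot, convergence declared at |score| < 1e−9, and a cap of 50
iterations. Ties use Efron's correction by default — month-resolution
survival data is heavily tied, and Efron is the materially better
approximation there — with Breslow available because it makes the score
test at β = 0 exactly the logrank statistic (a cross-check the test suite
exploits). The SE comes from the observed information at β̂; p-values are
two-sided Wald. Monotone partial likelihoods (one group's events wholly
precede the other's) are detected by β escaping to the ±20 cap; the fit is
returned with `converged=False` and downstream code treats such genes as
having no direction call. Significance thresholds (the conventional
p < 0.05) are downstream filters, never baked into the estimators.

## The screen and the combined rank

Each gene is dichotomized at the cohort mean of its (Z-scored) expression;
values exactly at the mean go to the low group so the split is
deterministic even on constructed fixtures. The per-gene ranking p-value is
the Cox Wald p by default; the logrank p is always computed and reported,
and a switch lets it drive ranking instead — the two tests answer the same
question and agree asymptotically, so exposing both costs nothing and
removes an arbitrary choice. Ranks use average-rank tie handling.
Benjamini–Hochberg q-values are emitted alongside every screen; the default
screen ranks on raw p (with q as modern hygiene clearly separated) because
the screening procedure itself is defined by the per-gene ranking, not by an
FDR cut.

The combined ligand–receptor score aggregates the ligand's rank with the
(first aggregated) receptor ranks. The aggregation rule is configurable —
`mean` (default), `sum`, `best` — because "combined" under-determines the
arithmetic; mean is the default since it is scale-stable across panels of
different size and identical in ordering to sum for single-receptor
ligands. Ties in the final ordering break deterministically on ligand id.

Stratification by Z-score uses > 0.25 for high and < −0.25 for low, the
conventional thresholds for calling expressors in Z-scored cohort data; the
middle band is excluded, so the two thresholds must differ (use the mean
dichotomizer when no excluded band is wanted). The iterative KM screen is
the plain screen filtered to p < α with each survivor labeled poor
(high-expressor HR > 1) or good.

Z-scores are computed within-cohort with the n−1 sample standard deviation.
Public cohort exports sometimes Z-score tumors against a reference
population instead; within-cohort normalization is self-contained and
reproducible from the expression matrix alone, and the dichotomization at
the cohort mean is unaffected by the choice.

Missing values are excluded pairwise per computation and never imputed;
every operation reports the effective n it used. Sample intersection across
expression/clinical/copy-number tables is automatic but logged with counts.

## Association stages

Pearson correlation against an index gene is computed over
pairwise-complete samples with two-pass centered sums (the one-pass
raw-sums formula loses ~8 digits under translation and is avoided);
p-values come from t = r·√((n−2)/(1−r²)) on n−2 df. Ranking is by
descending r, matching the genome-wide-rank presentation, not by p.

The two-group expression test is Welch's t (unequal variances,
Satterthwaite df) with BH q-values. A moderated-variance (empirical-Bayes)
test would borrow strength across genes and is the field's standard for
small groups; it is deliberately out of scope here, and at the ~80-patient
strata this package targets the Welch test is adequately powered. The
"upregulated in high" call is difference > 0 with q < 0.05 by default —
a configuration choice, flagged as such.

Gene-set enrichment is the exact one-sided hypergeometric tail over sets
intersected with the universe, BH-corrected across the library. The
universe is the expression matrix's gene complement after QC, not the whole
genome — enrichment against genes that could never have been called is
anticonservative. Composite enrichment scores that mix the p-value with a
rank deviation against background ensembles are not reproduced; ranking is
by p then q.

## Synthetic cohorts

The generator emulates a TCGA-style GBM cohort: 208 patients by default
(206 for the copy-number fixture, matching the slightly smaller
stratification subset of such cohorts), standard-normal per-gene
expression, planted ligand–receptor pairs drawn bivariate-normal with
correlation ρ (default 0.77, the magnitude of a strongly co-expressed
cytokine pair), and right-censored survival.

The hazard is λ·exp(Σ β_g·1[z_g > cohort mean] + copy-number terms) with
exponential baseline λ = 0.05 events/month (median OS ≈ 14 months,
typical of glioblastoma). The effect acts on the **dichotomized indicator,
not the continuous Z** — deliberately, so exp(β) is exactly the estimand of
the binary-covariate Cox fit and parameter recovery is a sharp test rather
than an approximation. Censoring is the minimum of administrative follow-up
(60 months) and exponential dropout (0.01/month), giving ≈ 10–15% censoring
under the defaults. DFS is drawn from the same linear predictor with a
1.5× hazard multiplier (progression precedes death). A Weibull shape
parameter is exposed (default 1, i.e. exponential) for closed-form medians;
optional month rounding exercises the tie-handling paths deliberately.

Copy-number states are drawn i.i.d. per gene from configurable state
probabilities over the GISTIC codes −2…2, each state carrying its own
additive log-hazard; the `hetloss80` fixture plants heterozygous loss of a
tumor suppressor in 80% of patients with a 0.8 log-hazard penalty,
mirroring the near-universal single-allele loss reported for SIRT1-like
suppressors in GBM.

What the generator does **not** emulate: batch effects, expression subtype
structure, realistic genome-wide correlation beyond the planted blocks,
informative censoring, or copy-number/expression coupling. Passing tests
therefore demonstrate the *procedures* are correct and calibrated under a
clean proportional-hazards world; they do not certify behavior under the
dependence structures of real tumor data.

## Problem sizes and determinism

Calibration checks use 2,000 logrank replicates at n = 100 (~30%
censoring) and a 2,000-gene null screen at n = 208; parameter recovery uses
n = 5,000 for the Cox hazard ratio (10% tolerance) and 100 seeded
replicates of the 51-pair combined-rank recovery (the top-1 pass threshold,
90/100, was frozen after a pilot run against a brute-force recomputation of
the ranking from the per-gene rank table; the pilot scored 100/100). These
sizes give comfortable statistical resolution while keeping the full suite
fast on a single CPU.

All randomness flows from `numpy.random.default_rng` seeded per
configuration; identical config + seed reproduces cohorts and pipeline
outputs byte for byte (float serialization uses `%.17g`, which round-trips
every finite double, and config hashes exclude the output directory so the
same analysis written to two places is identical).

## Known limitations

* Only two-group comparisons: no multivariate or stratified Cox, no
  time-varying covariates, no proportional-hazards diagnostics.
* The Wald p-value is anticonservative for very small event counts;
  monotone-likelihood genes are flagged rather than rescued (no Firth
  correction).
* Enrichment assumes exchangeable genes (no gene-length or expression-level
  bias correction).
* The generator's cohort-mean indicator couples each patient's hazard to
  the drawn cohort (the mean is in-sample); at n ≥ 200 the effect on
  recovery is negligible but it is a dependence a purist would note.
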