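"""Synthetic tumor-cohort generator with known ground truth.

Emulates the statistical structure of a TCGA-style glioblastoma cohort:
per-gene standard-normal expression with optional strongly correlated
ligand-receptor blocks, right-censored survival whose hazard is multiplied by
exp(beta) for above-mean expressors of planted genes (so the planted log
hazard ratio is exactly the estimand of the binary-covariate Cox fit), and
GISTIC-style copy-number states carrying their own hazard effects.  Every
draw flows from one seeded generator; identical config + seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort_io import (
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
    write_clinical,
    write_copy_number,
    write_expression,
)

__all__ = [
    "PlantedPair",
    "PlantedGene",
    "CopyNumberSpec",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "write_fixture_suite",
]


@dataclass(frozen=True)
class PlantedPair:
    """A ligand-receptor pair with correlated expression and a shared effect.

    ``rho`` is the expression correlation of the two genes (bivariate
    normal); ``beta`` is the log hazard ratio carried by each gene's
    above-mean indicator (so both-high patients accrue 2*beta).
    """

    ligand: str
    receptor: str
    rho: float = 0.77
    beta: float = 0.0


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    beta: float


@dataclass(frozen=True)
class CopyNumberSpec:
    """Per-gene copy-number state distribution and hazard effects.

    ``state_probs`` maps GISTIC codes (-2..2) to probabilities summing to 1;
    ``state_log_hazard`` maps codes to additive log-hazard terms (diploid
    conventionally 0).
    """

    gene: str
    state_probs: dict
    state_log_hazard: dict = field(default_factory=dict)


@dataclass
class SyntheticCohortConfig:
    """Full generative specification of a synthetic cohort.

    Defaults describe a GBM-sized cohort: 208 patients, exponential baseline
    hazard 0.05 events/month (median overall survival ~ 14 months, typical of
    glioblastoma), administrative censoring at 60 months plus independent
    exponential dropout at 0.01/month.
    """

    n_samples: int = 208
    n_genes: int = 100
    planted_pairs: tuple = ()
    planted_single_genes: tuple = ()
    baseline_hazard: float = 0.05     # events / month
    censor_horizon: float = 60.0      # months; np.inf disables
    dropout_rate: float = 0.01        # exponential dropout, events / month
    copy_number: tuple = ()           # CopyNumberSpec entries
    dfs_hazard_multiplier: float = 1.5
    weibull_shape: float = 1.0
    round_months: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        if not self.baseline_hazard > 0:
            raise ValueError("baseline_hazard must be positive")
        if self.dropout_rate < 0 or self.censor_horizon <= 0:
            raise ValueError("invalid censoring specification")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        names = [p.ligand for p in self.planted_pairs] + \
                [p.receptor for p in self.planted_pairs] + \
                [g.gene for g in self.planted_single_genes]
        if len(names) != len(set(names)):
            raise ValueError("planted gene names must be distinct")
        for pair in self.planted_pairs:
            if not -1.0 < pair.rho < 1.0:
                raise ValueError(f"pair {pair.ligand}-{pair.receptor}: rho must be in (-1, 1)")
        for spec in self.copy_number:
            probs = np.array([spec.state_probs.get(s, 0.0) for s in (-2, -1, 0, 1, 2)])
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"copy-number probabilities for {spec.gene} must sum to 1")
            if set(spec.state_probs) - {-2, -1, 0, 1, 2}:
                raise ValueError(f"copy-number states for {spec.gene} outside -2..2")

    def planted_gene_names(self) -> list:
        out = []
        for p in self.planted_pairs:
            out += [p.ligand, p.receptor]
        out += [g.gene for g in self.planted_single_genes]
        return out


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    copy_number: CopyNumberTable | None
    truth: dict


def _survival_times(rng, log_hazard, cfg: SyntheticCohortConfig, multiplier: float = 1.0):
    """Weibull (exponential by default) event times under proportional hazards."""
    lam = cfg.baseline_hazard * multiplier
    u = rng.uniform(size=log_hazard.size)
    # proportional hazards with Weibull baseline: S(t) = exp(-(lam t)^k e^eta)
    event_t = (-np.log(u) / np.exp(log_hazard)) ** (1.0 / cfg.weibull_shape) / lam
    if cfg.dropout_rate > 0:
        dropout = rng.exponential(1.0 / cfg.dropout_rate, size=log_hazard.size)
    else:
        dropout = np.full(log_hazard.size, np.inf)
    censor_t = np.minimum(dropout, cfg.censor_horizon)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    if cfg.round_months:
        time = np.maximum(np.round(time), 1.0)
    return time, event


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model; returns data plus truth record.

    Expression: standard-normal per gene; each planted pair is bivariate
    normal with its rho.  Survival: hazard lambda * exp(sum of planted betas
    over above-mean indicators + copy-number state terms); censoring is the
    minimum of exponential dropout and the administrative horizon.  OS and
    DFS are generated from the same linear predictor (DFS with a hazard
    multiplier).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_samples

    planted = config.planted_gene_names()
    if len(planted) > config.n_genes:
        raise ValueError("n_genes smaller than the number of planted genes")
    filler = [f"G{i:05d}" for i in range(config.n_genes - len(planted))]
    genes = planted + filler
    samples = [f"S{i:04d}" for i in range(n)]

    values = rng.standard_normal((config.n_genes, n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for pair in config.planted_pairs:
        z1 = values[gene_pos[pair.ligand]]
        noise = rng.standard_normal(n)
        values[gene_pos[pair.receptor]] = pair.rho * z1 + np.sqrt(1 - pair.rho**2) * noise

    expr_df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    # linear predictor on above-(cohort-)mean indicators
    eta = np.zeros(n)
    effects = []
    for pair in config.planted_pairs:
        for g in (pair.ligand, pair.receptor):
            row = values[gene_pos[g]]
            eta += pair.beta * (row > row.mean())
        effects.append({"kind": "pair", "ligand": pair.ligand, "receptor": pair.receptor,
                        "rho": pair.rho, "beta": pair.beta})
    for pg in config.planted_single_genes:
        row = values[gene_pos[pg.gene]]
        eta += pg.beta * (row > row.mean())
        effects.append({"kind": "gene", "gene": pg.gene, "beta": pg.beta})

    cn_table = None
    if config.copy_number:
        states = np.array([-2, -1, 0, 1, 2])
        calls = {}
        for spec in config.copy_number:
            probs = np.array([spec.state_probs.get(s, 0.0) for s in states])
            drawn = rng.choice(states, size=n, p=probs)
            calls[spec.gene] = drawn
            lh = np.array([spec.state_log_hazard.get(s, 0.0) for s in states])
            eta += lh[np.searchsorted(states, drawn)]
            effects.append({"kind": "copy_number", "gene": spec.gene,
                            "state_probs": dict(spec.state_probs),
                            "state_log_hazard": dict(spec.state_log_hazard)})
        cn_df = pd.DataFrame.from_dict(calls, orient="index", columns=samples)
        cn_df.index.name = "gene"
        cn_table = CopyNumberTable(calls=cn_df)

    os_t, os_e = _survival_times(rng, eta, config)
    dfs_t, dfs_e = _survival_times(rng, eta, config, multiplier=config.dfs_hazard_multiplier)
    clin = ClinicalTable(
        data=pd.DataFrame(
            {
                "os_months": os_t,
                "os_event": os_e.astype(float),
                "dfs_months": dfs_t,
                "dfs_event": dfs_e.astype(float),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = {
        "config": asdict(config),
        "planted_effects": effects,
        "event_fraction_os": float(os_e.mean()),
        "event_fraction_dfs": float(dfs_e.mean()),
    }
    return SyntheticCohort(
        expression=ExpressionMatrix(values=expr_df, normalized=False),
        clinical=clin,
        copy_number=cn_table,
        truth=truth,
    )


def _write_truth(truth: dict, path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_fixture_suite(directory, seed: int = 0) -> dict:
    """Write a small deterministic fixture family for pipeline testing.

    Fixtures: ``null`` (no planted effects), ``single_gene`` (one harmful
    gene, beta = 1.2), ``ligand_receptor`` (one planted IL1B/OSM-like pair,
    rho = 0.77, beta = 0.9, among null pairs), and ``hetloss80`` (a tumor
    suppressor heterozygously lost in 80% of tumors with a hazard penalty).
    Returns {fixture name: {file kind: path}}.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    configs = {
        "null": SyntheticCohortConfig(n_samples=208, n_genes=60, rng_seed=seed),
        "single_gene": SyntheticCohortConfig(
            n_samples=208, n_genes=60,
            planted_single_genes=(PlantedGene("HARMFUL1", 1.2),),
            rng_seed=seed + 1,
        ),
        "ligand_receptor": SyntheticCohortConfig(
            n_samples=208, n_genes=60,
            planted_pairs=(PlantedPair("LIG_TRUE", "REC_TRUE", rho=0.77, beta=0.9),),
            rng_seed=seed + 2,
        ),
        "hetloss80": SyntheticCohortConfig(
            n_samples=206, n_genes=40,
            copy_number=(
                CopyNumberSpec(
                    gene="SUPPRESSOR1",
                    state_probs={-1: 0.8, 0: 0.2},
                    state_log_hazard={-1: 0.8},
                ),
            ),
            rng_seed=seed + 3,
        ),
    }
    out = {}
    for name, cfg in configs.items():
        cohort = simulate_cohort(cfg)
        paths = {
            "expression": directory / f"{name}_expression.tsv",
            "clinical": directory / f"{name}_clinical.tsv",
            "truth": directory / f"{name}_truth.json",
        }
        write_expression(cohort.expression, paths["expression"])
        write_clinical(cohort.clinical, paths["clinical"])
        if cohort.copy_number is not None:
            paths["copy_number"] = directory / f"{name}_copy_number.tsv"
            write_copy_number(cohort.copy_number, paths["copy_number"])
        _write_truth(cohort.truth, paths["truth"])
        out[name] = {k: str(v) for k, v in paths.items()}
    return out
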