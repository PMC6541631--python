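"""End-to-end reproducible analysis runs.

Two orchestrated flows mirror how the screening is used in practice:

* :func:`run_cyto_analysis` — the cytokine/receptor screen: normalize,
  screen the panel genes, rank, combine ligand-receptor ranks, and export the
  Kaplan-Meier comparison for the top pair's concordant dual-marker groups.
* :func:`run_gene_program_analysis` — the regulator-program screen: stratify
  patients by a target gene's Z-score, Welch-test every gene between the
  strata, run the iterative KM screen on a gene list, and enrich the
  poor-prognosis survivors against a GMT library.

Every output table carries a header comment with the package version, a hash
of the configuration, and the effective sample counts, and a run log records
the effective n at each stage; reruns with the same config and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import enrich_gene_sets, two_group_de
from .cohort_io import (
    intersect_samples,
    read_clinical,
    read_expression,
    read_gmt,
    read_pairing,
    zscore_normalize,
)
from .screen import (
    combined_rank,
    dual_marker_groups,
    iterative_km,
    screen_genes,
)
from .survival import cox_fit_binary, km_estimate, logrank_test

__all__ = ["RunConfig", "run_cyto_analysis", "run_gene_program_analysis"]


@dataclass
class RunConfig:
    """Declarative run configuration (flat keys; loadable from YAML).

    File paths are checked for existence before any computation; the config
    is echoed verbatim into the output directory for provenance.
    """

    expression: str = ""
    clinical: str = ""
    pairing: str = ""
    copy_number: str = ""
    gene_sets: str = ""
    output_dir: str = "cytoscreen_run"
    endpoint: str = "OS"
    ranking_test: str = "cox"
    aggregation: str = "mean"
    alpha: float = 0.05
    z_hi: float = 0.25
    z_lo: float = -0.25
    de_q_threshold: float = 0.05
    target_gene: str = ""
    gene_list: tuple = ()
    expression_dialect: str = "plain"
    status_dialect: str = "plain"
    already_normalized: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "gene_list" in raw and raw["gene_list"] is not None:
            raw["gene_list"] = tuple(raw["gene_list"])
        return cls(**raw)

    def validate_paths(self, required) -> None:
        for key in required:
            p = getattr(self, key)
            if not p:
                raise ValueError(f"config field {key!r} is required for this run")
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {key!r}: no such file {p!r}")

    def config_hash(self) -> str:
        # output_dir is provenance-irrelevant: the same analysis written to two
        # directories must produce byte-identical tables
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        canon = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


class _Run:
    """Output directory + run log + provenance header."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_lines: list[str] = []
        with open(self.outdir / "config_used.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)

    def log(self, msg: str) -> None:
        import sys

        self.log_lines.append(msg)
        print(msg, file=sys.stderr)

    def header(self, **counts) -> str:
        parts = [f"cytoscreen {__version__}", f"config_hash={self.config.config_hash()}"]
        parts += [f"{k}={v}" for k, v in counts.items()]
        return " ".join(parts)

    def finish(self) -> None:
        with open(self.outdir / "run.log", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.log_lines) + "\n")


def _write_table(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _stage(run: _Run, name: str):
    class _Ctx:
        def __enter__(self):
            run.log(f"[stage] {name}")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                run.log(f"[abort] stage {name!r} failed: {exc}")
            return False

    return _Ctx()


def _load_cohort(run: _Run):
    cfg = run.config
    expr = read_expression(cfg.expression, dialect=cfg.expression_dialect)
    clin = read_clinical(cfg.clinical, status_dialect=cfg.status_dialect)
    if clin.n_rejected:
        run.log(f"clinical: rejected {clin.n_rejected} unparsable row(s)")
    expr, clin, _, counts = intersect_samples(expr, clin)
    run.log(f"sample intersection: {counts}")
    if cfg.already_normalized:
        from dataclasses import replace

        expr = replace(expr, normalized=True)
    else:
        expr = zscore_normalize(expr)
        if expr.constant_genes:
            run.log(f"normalization: {len(expr.constant_genes)} constant gene(s) dropped")
    return expr, clin, counts


def run_cyto_analysis(config: RunConfig) -> dict:
    """Cytokine/receptor combined-rank screen; returns paths of the outputs."""
    config.validate_paths(["expression", "clinical", "pairing"])
    run = _Run(config)
    outputs = {}

    with _stage(run, "load+normalize"):
        expr, clin, counts = _load_cohort(run)
        pairing = read_pairing(config.pairing)

    with _stage(run, "screen"):
        panel = sorted({g for l, rs in pairing.entries for g in (l, *rs)})
        screen = screen_genes(
            expr, clin, panel, endpoint=config.endpoint,
            ranking_test=config.ranking_test, alpha=config.alpha,
        )
        run.log(
            f"screen: {screen.n_genes} genes tested on n={counts['common']} samples, "
            f"{len(screen.untestable)} untestable"
        )
        path = run.outdir / "screen.tsv"
        screen.to_tsv(path, run.header(n_samples=counts["common"], n_genes=screen.n_genes))
        outputs["screen"] = str(path)

    with _stage(run, "combined-rank"):
        combined = combined_rank(screen, pairing, aggregation=config.aggregation)
        for lig, why in combined.excluded.items():
            run.log(f"combined-rank: excluded {lig}: {why}")
        path = run.outdir / "combined_rank.tsv"
        combined.to_tsv(path, run.header(n_pairs=len(combined.table)))
        outputs["combined_rank"] = str(path)

    with _stage(run, "dual-marker-km"):
        if len(combined.table):
            top_ligand = combined.table.iloc[0]["ligand"]
            receptors = pairing.receptors_of(top_ligand)
            top_receptor = receptors[0]
            labels = dual_marker_groups(expr, top_ligand, top_receptor)
            surv = clin.endpoint(config.endpoint).loc[labels.index.intersection(
                clin.endpoint(config.endpoint).index)]
            labels = labels.loc[surv.index]
            run.log(
                f"dual-marker: {top_ligand}+{top_receptor}, "
                f"both_high={(labels == 'both_high').sum()}, "
                f"both_low={(labels == 'both_low').sum()}"
            )
            frames = []
            for grp in ("both_high", "both_low"):
                idx = labels[labels == grp].index
                curve = km_estimate(surv.loc[idx, "time"], surv.loc[idx, "event"])
                tab = curve.to_table()
                tab.insert(0, "group", grp)
                frames.append(tab)
            lr = logrank_test(surv["time"], surv["event"], labels)
            cox = cox_fit_binary(surv["time"], surv["event"], labels)
            km_table = pd.concat(frames, ignore_index=True)
            path = run.outdir / "dual_marker_km.tsv"
            _write_table(
                km_table, path,
                run.header(pair=f"{top_ligand}+{top_receptor}",
                           n_used=len(labels),
                           logrank_p=f"{lr.p_value:.6g}",
                           cox_p=f"{cox.p_value:.6g}",
                           hazard_ratio=f"{cox.hazard_ratio:.6g}"),
            )
            outputs["dual_marker_km"] = str(path)

    run.finish()
    outputs["run_log"] = str(run.outdir / "run.log")
    return outputs


def run_gene_program_analysis(config: RunConfig) -> dict:
    """Target-gene stratification -> DE -> iterative KM -> enrichment chain."""
    config.validate_paths(["expression", "clinical"])
    if not config.target_gene:
        raise ValueError("config field 'target_gene' is required for this run")
    run = _Run(config)
    outputs = {}

    with _stage(run, "load+normalize"):
        expr, clin, counts = _load_cohort(run)
        library = read_gmt(config.gene_sets) if config.gene_sets else None

    with _stage(run, "stratify"):
        from .screen import stratify_zscore

        strata = stratify_zscore(expr, config.target_gene, config.z_hi, config.z_lo)
        n_high = int((strata == "high").sum())
        n_low = int((strata == "low").sum())
        run.log(
            f"stratify {config.target_gene}: high={n_high} low={n_low} "
            f"excluded={counts['common'] - n_high - n_low}"
        )

    with _stage(run, "two-group-de"):
        de = two_group_de(
            expr,
            strata[strata == "high"].index,
            strata[strata == "low"].index,
            q_threshold=config.de_q_threshold,
        )
        upregulated = de.loc[de["up_in_high"], "gene"].tolist()
        run.log(f"de: {len(de)} genes tested, {len(upregulated)} up in high")
        path = run.outdir / "two_group_de.tsv"
        _write_table(de.drop(columns=[]), path,
                     run.header(n_high=n_high, n_low=n_low, n_genes=len(de)))
        outputs["two_group_de"] = str(path)

    with _stage(run, "iterative-km"):
        gene_list = list(config.gene_list) if config.gene_list else upregulated
        surv_screen = iterative_km(
            expr, clin, gene_list, endpoint=config.endpoint,
            alpha=config.alpha, ranking_test=config.ranking_test,
        )
        run.log(
            f"iterative-km: {len(gene_list)} candidates, "
            f"{len(surv_screen.table)} significant at alpha={config.alpha:g}, "
            f"poor fraction={surv_screen.poor_fraction():.3g}"
        )
        path = run.outdir / "iterative_km.tsv"
        surv_screen.to_tsv(path, run.header(n_candidates=len(gene_list),
                                            n_significant=len(surv_screen.table)))
        outputs["iterative_km"] = str(path)

    with _stage(run, "enrichment"):
        if library is not None and len(surv_screen.table):
            poor = surv_screen.table.loc[
                surv_screen.table["direction"] == "poor", "gene"
            ].tolist()
            universe = expr.gene_ids
            if poor:
                enr = enrich_gene_sets(poor, universe, library)
                path = run.outdir / "enrichment.tsv"
                enr.to_tsv(path, run.header(n_target=len(poor),
                                            n_universe=len(universe),
                                            n_sets=len(enr.table)))
                outputs["enrichment"] = str(path)
                run.log(f"enrichment: {len(enr.table)} sets tested, "
                        f"{len(enr.skipped)} skipped")
            else:
                run.log("enrichment: no poor-prognosis genes; skipped")
        elif library is not None:
            run.log("enrichment: empty iterative-km table; skipped")

    run.finish()
    outputs["run_log"] = str(run.outdir / "run.log")
    return outputs
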