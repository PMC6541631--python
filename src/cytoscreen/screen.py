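"""Prognostic screening of expression biomarkers against survival.

The screening recipe: each gene's cohort-mean-dichotomized expression defines
high/low expressor groups; a two-group survival test (Cox Wald by default,
logrank optionally) yields a per-gene p-value; p-values are ranked and, for
ligand-receptor panels, the ligand's and receptor's ranks are aggregated into
one combined prognostic score per cytokine signaling program.  Additional
stratifiers: Z-score thresholds with an excluded middle band, concordant
dual-marker groups, copy-number zygosity, and a two-gene cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CopyNumberTable, ExpressionMatrix, ClinicalTable
from .survival import CoxBinary, logrank_test

__all__ = [
    "dichotomize_mean",
    "stratify_zscore",
    "dual_marker_groups",
    "zygosity_groups",
    "joint_stratify",
    "select_joint_cells",
    "SurvivalScreen",
    "ScreenResults",
    "screen_genes",
    "iterative_km",
    "combined_rank",
    "CombinedRankResult",
]

ZYGOSITY_NAMES = {
    -2: "deep_deletion",
    -1: "hetloss",
    0: "diploid",
    1: "gain",
    2: "amplification",
}


def dichotomize_mean(values) -> pd.Series:
    """Split values into 'high' (> mean of non-missing) and 'low' (<= mean).

    Missing values are excluded from both the mean and the output; a value
    exactly at the mean goes to the low group (deterministic tie rule).
    """
    v = pd.Series(values, dtype=float).dropna()
    if v.size < 2:
        raise ValueError("dichotomize_mean needs at least 2 non-missing values")
    mean = v.mean()
    return pd.Series(np.where(v > mean, "high", "low"), index=v.index)


def stratify_zscore(expr: ExpressionMatrix, gene: str,
                    hi_threshold: float = 0.25,
                    lo_threshold: float = -0.25) -> pd.Series:
    """'high' iff z > hi_threshold, 'low' iff z < lo_threshold; middle excluded.

    Defaults are the +/-0.25 Z-score cut used for expressor classification.
    Requires a normalized matrix and ``hi_threshold > lo_threshold`` so the
    excluded band is well-defined (for equal thresholds use
    :func:`dichotomize_mean`).
    """
    if not expr.normalized:
        raise ValueError("stratify_zscore requires Z-score normalized expression")
    if not hi_threshold > lo_threshold:
        raise ValueError("hi_threshold must be strictly greater than lo_threshold")
    z = expr.gene(gene).dropna()
    labels = pd.Series(index=z.index, dtype=object)
    labels[z > hi_threshold] = "high"
    labels[z < lo_threshold] = "low"
    return labels.dropna()


def dual_marker_groups(expr: ExpressionMatrix, gene_a: str, gene_b: str) -> pd.Series:
    """Concordant dual-marker groups: 'both_high' / 'both_low'.

    Each gene is dichotomized at its cohort mean; patients discordant for the
    two markers are excluded.  Either concordant group being empty is an
    error (no two-group comparison is possible).
    """
    la = dichotomize_mean(expr.gene(gene_a))
    lb = dichotomize_mean(expr.gene(gene_b))
    common = la.index.intersection(lb.index)
    la, lb = la.loc[common], lb.loc[common]
    out = pd.Series(index=common, dtype=object)
    out[(la == "high") & (lb == "high")] = "both_high"
    out[(la == "low") & (lb == "low")] = "both_low"
    out = out.dropna()
    for grp in ("both_high", "both_low"):
        if (out == grp).sum() == 0:
            raise ValueError(f"dual-marker group {grp!r} is empty")
    return out


def zygosity_groups(cn: CopyNumberTable, gene: str):
    """Map GISTIC calls to zygosity labels; returns (labels, frequencies).

    Frequencies are over samples with a non-missing call, so statements like
    "hetloss in ~80% of tumors" can be read off directly.
    """
    if gene not in cn.calls.index:
        raise KeyError(f"gene {gene!r} not in copy-number table")
    calls = cn.calls.loc[gene].dropna()
    labels = calls.map(lambda c: ZYGOSITY_NAMES[int(c)]).astype(object)
    freqs = (labels.value_counts() / len(labels)).to_dict() if len(labels) else {}
    return labels, freqs


def joint_stratify(expr: ExpressionMatrix, gene_a: str, gene_b: str,
                   hi_threshold: float = 0.25,
                   lo_threshold: float = -0.25) -> pd.Series:
    """Four-way cross of two Z-threshold stratifications.

    Labels are 'high/high', 'high/low', 'low/high', 'low/low' (gene_a first);
    samples in either gene's excluded band never appear.
    """
    la = stratify_zscore(expr, gene_a, hi_threshold, lo_threshold)
    lb = stratify_zscore(expr, gene_b, hi_threshold, lo_threshold)
    common = la.index.intersection(lb.index)
    return pd.Series(
        [f"{la[s]}/{lb[s]}" for s in common], index=common, dtype=object
    )


def select_joint_cells(labels: pd.Series, cells_a, cells_b) -> pd.Series:
    """Pick two disjoint cell collections of a joint cross for a 2-group test.

    ``cells_a`` / ``cells_b`` are collections of four-way labels (e.g.
    ``{'high/low'}`` vs the rest).  Empty selections are an error.
    """
    cells_a, cells_b = set(cells_a), set(cells_b)
    if cells_a & cells_b:
        raise ValueError("cell selections overlap")
    out = pd.Series(index=labels.index, dtype=object)
    out[labels.isin(cells_a)] = "group_a"
    out[labels.isin(cells_b)] = "group_b"
    out = out.dropna()
    for grp in ("group_a", "group_b"):
        if (out == grp).sum() == 0:
            raise ValueError(f"selected cells for {grp!r} are empty")
    return out


# ---------------------------------------------------------------------------
# the per-gene screen
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "gene", "n_high", "n_low", "hazard_ratio", "cox_p", "logrank_p",
    "p_value", "q_value", "rank", "direction", "converged",
]


@dataclass
class ScreenResults:
    """Per-gene survival screen results.

    ``table`` has one row per testable gene: group sizes, hazard ratio of the
    high-expressor group, Cox Wald and logrank p-values, the ranking p-value
    (per the configured test), BH q-value, average-tie rank (1 = most
    significant), and a direction call ('poor' iff HR of high expressors > 1,
    defined only for converged fits).
    """

    table: pd.DataFrame
    untestable: dict = field(default_factory=dict)  # gene -> reason
    endpoint: str = "OS"
    ranking_test: str = "cox"
    alpha: float = 0.05

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        return self.table[self.table["p_value"] < alpha]

    def poor_fraction(self, alpha: float | None = None) -> float:
        """Among significant genes with a direction call, fraction labeled poor."""
        sig = self.significant(alpha)
        sig = sig[sig["direction"].notna()]
        if len(sig) == 0:
            return float("nan")
        return float((sig["direction"] == "poor").mean())

    def rank_of(self, gene: str) -> float:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in screen results")
        return float(row["rank"].iloc[0])

    def summary(self, top: int = 10) -> str:
        head = self.table.nsmallest(top, "rank")
        lines = [
            f"Survival screen: {self.n_genes} genes tested "
            f"({len(self.untestable)} untestable), endpoint {self.endpoint}, "
            f"ranking test {self.ranking_test}",
            f"significant at alpha={self.alpha:g}: {len(self.significant())}",
            head.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")


class SurvivalScreen:
    """Model object: screen a gene list for prognostic impact on survival.

    Parameters
    ----------
    expr : ExpressionMatrix
        Must be Z-score normalized.
    clinical : ClinicalTable
        Supplies the (time, event) endpoint.
    genes : list of str, optional
        Genes to screen (default: every gene in the matrix).  Genes absent
        from the matrix are reported in ``missing_genes`` and skipped.
    endpoint : {'OS', 'DFS'}

    ``fit()`` dichotomizes each gene at its cohort mean, runs the survival
    test per gene and returns :class:`ScreenResults`.
    """

    def __init__(self, expr: ExpressionMatrix, clinical: ClinicalTable,
                 genes=None, endpoint: str = "OS"):
        if not expr.normalized:
            raise ValueError("screen requires Z-score normalized expression")
        self.expr = expr
        self.clinical = clinical
        self.endpoint = endpoint.upper()
        requested = list(genes) if genes is not None else expr.gene_ids
        present = set(expr.gene_ids)
        self.genes = [g for g in requested if g in present]
        self.missing_genes = [g for g in requested if g not in present]
        surv = clinical.endpoint(self.endpoint)
        common = [s for s in expr.sample_ids if s in set(surv.index)]
        self._surv = surv.loc[common]
        self.n_samples = len(common)

    def fit(self, ranking_test: str = "cox", ties_method: str = "efron",
            alpha: float = 0.05) -> ScreenResults:
        if ranking_test not in ("cox", "logrank"):
            raise ValueError("ranking_test must be 'cox' or 'logrank'")
        times = self._surv["time"].to_numpy()
        events = self._surv["event"].to_numpy()
        sample_index = self._surv.index

        rows, untestable = [], {}
        for gene in self.genes:
            z = self.expr.gene(gene).reindex(sample_index)
            usable = z.notna().to_numpy()
            try:
                labels = dichotomize_mean(z)
            except ValueError as exc:
                untestable[gene] = str(exc)
                continue
            lab = labels.reindex(sample_index[usable]).to_numpy()
            n_high = int((lab == "high").sum())
            n_low = int((lab == "low").sum())
            if n_high == 0 or n_low == 0:
                untestable[gene] = "dichotomization produced an empty group"
                continue
            t, e = times[usable], events[usable]
            model = CoxBinary(t, e, lab)
            cox = model.fit(ties_method=ties_method)
            lr = logrank_test(t, e, lab)
            # 'high' sorts after 'low' is false ('high' < 'low'), so map HR to
            # the high group explicitly
            hr_high = cox.hazard_ratio if cox.groups[1] == "high" else 1.0 / cox.hazard_ratio
            direction = None
            if cox.converged:
                direction = "poor" if hr_high > 1.0 else "good"
            rows.append(
                {
                    "gene": gene,
                    "n_high": n_high,
                    "n_low": n_low,
                    "hazard_ratio": hr_high,
                    "cox_p": cox.p_value,
                    "logrank_p": lr.p_value,
                    "p_value": cox.p_value if ranking_test == "cox" else lr.p_value,
                    "direction": direction,
                    "converged": cox.converged,
                }
            )
        table = pd.DataFrame(rows, columns=[c for c in _TABLE_COLUMNS if c not in ("q_value", "rank")])
        if len(table):
            p = table["p_value"].to_numpy()
            table["q_value"] = multipletests(p, method="fdr_bh")[1]
            table["rank"] = stats.rankdata(p, method="average")
        else:
            table["q_value"] = pd.Series(dtype=float)
            table["rank"] = pd.Series(dtype=float)
        table = table[_TABLE_COLUMNS]
        return ScreenResults(
            table=table.reset_index(drop=True),
            untestable=untestable,
            endpoint=self.endpoint,
            ranking_test=ranking_test,
            alpha=alpha,
        )


def screen_genes(expr, clinical, gene_list=None, endpoint: str = "OS",
                 ranking_test: str = "cox", ties_method: str = "efron",
                 alpha: float = 0.05) -> ScreenResults:
    """Functional wrapper around :class:`SurvivalScreen`."""
    return SurvivalScreen(expr, clinical, gene_list, endpoint).fit(
        ranking_test=ranking_test, ties_method=ties_method, alpha=alpha
    )


def iterative_km(expr, clinical, gene_list=None, endpoint: str = "OS",
                 alpha: float = 0.05, ranking_test: str = "cox") -> ScreenResults:
    """Iterative Kaplan-Meier screen of a gene list.

    Runs the per-gene screen and keeps only genes with p < alpha, each with a
    poor/good direction call; the returned results' ``poor_fraction()``
    reports the share of survivors that mark poor prognosis.
    """
    full = screen_genes(expr, clinical, gene_list, endpoint,
                        ranking_test=ranking_test, alpha=alpha)
    kept = full.table[full.table["p_value"] < alpha].reset_index(drop=True)
    return ScreenResults(
        table=kept,
        untestable=full.untestable,
        endpoint=full.endpoint,
        ranking_test=full.ranking_test,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# combined ligand-receptor ranking
# ---------------------------------------------------------------------------

_AGGREGATORS = {
    "mean": lambda vals: float(np.mean(vals)),
    "sum": lambda vals: float(np.sum(vals)),
    "best": lambda vals: float(np.min(vals)),
}


@dataclass
class CombinedRankResult:
    """Per-ligand combined prognostic score (ligand rank + receptor rank)."""

    table: pd.DataFrame  # ligand, ligand_rank, receptor_rank, combined_score, order
    aggregation: str
    excluded: dict = field(default_factory=dict)  # ligand -> reason

    def top_pair(self, pairing) -> tuple:
        """(ligand, best-ranked receptor) of the top combined score."""
        lig = self.table.iloc[0]["ligand"]
        receptors = pairing.receptors_of(lig)
        return lig, receptors[0] if len(receptors) == 1 else receptors

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def combined_rank(screen: ScreenResults, pairing, aggregation: str = "mean") -> CombinedRankResult:
    """Aggregate a ligand's and its receptor(s)' screen ranks into one score.

    Multi-receptor ligands first aggregate their receptors' ranks with the
    same rule, keeping one score per ligand.  The final ordering is ascending
    by combined score with a deterministic tie-break on ligand id.  Ligands
    whose ligand or every receptor was not screened are excluded with a
    reason.
    """
    if aggregation not in _AGGREGATORS:
        raise ValueError(f"aggregation must be one of {sorted(_AGGREGATORS)}")
    agg = _AGGREGATORS[aggregation]
    ranks = dict(zip(screen.table["gene"], screen.table["rank"]))
    rows, excluded = [], {}
    for ligand, receptors in pairing.entries:
        if ligand not in ranks:
            excluded[ligand] = "ligand not screened"
            continue
        rec_ranks = [ranks[r] for r in receptors if r in ranks]
        if not rec_ranks:
            excluded[ligand] = "no screened receptor"
            continue
        receptor_rank = agg(rec_ranks)
        score = agg([ranks[ligand], receptor_rank])
        rows.append(
            {
                "ligand": ligand,
                "ligand_rank": ranks[ligand],
                "receptor_rank": receptor_rank,
                "combined_score": score,
            }
        )
    table = pd.DataFrame(rows, columns=["ligand", "ligand_rank", "receptor_rank", "combined_score"])
    table = table.sort_values(["combined_score", "ligand"], kind="mergesort").reset_index(drop=True)
    table["order"] = np.arange(1, len(table) + 1)
    return CombinedRankResult(table=table, aggregation=aggregation, excluded=excluded)
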