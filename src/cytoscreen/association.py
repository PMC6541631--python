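"""Genome-wide correlation ranking, two-group expression testing, enrichment.

* :func:`pearson_rank` ranks every gene by its Pearson correlation with an
  index gene (e.g. every expressed gene against IL1B), pairwise-complete.
* :func:`two_group_de` is a plain Welch two-sample test between expression
  strata (mean difference, p, BH q) — a deliberately simple differential-
  expression stage without moderated variances.
* :func:`enrich_gene_sets` is exact one-sided hypergeometric over-representation
  of a target list in GMT gene sets, BH-corrected across the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionMatrix, GeneSetLibrary

__all__ = ["CorrelationRank", "pearson_rank", "two_group_de",
           "EnrichmentResult", "enrich_gene_sets"]


@dataclass
class CorrelationRank:
    """Per-gene Pearson correlation with the index gene, ranked by descending r."""

    index_gene: str
    table: pd.DataFrame  # gene, r, p, n, rank
    excluded: tuple = ()  # genes with < 3 complete pairs

    def rank_of(self, gene: str) -> int:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(gene)
        return int(row["rank"].iloc[0])

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def pearson_rank(expr: ExpressionMatrix, index_gene: str) -> CorrelationRank:
    """Correlate every other gene with ``index_gene`` and rank by descending r.

    Pearson r is computed over pairwise-complete samples per gene; the
    two-sided p-value comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 df.
    Genes with fewer than 3 complete pairs are excluded.
    """
    if index_gene not in expr.values.index:
        raise KeyError(f"index gene {index_gene!r} not in expression matrix")
    y = expr.values.loc[index_gene].to_numpy(dtype=float)
    X = expr.values.drop(index=index_gene)
    genes = X.index.to_numpy()
    M = X.to_numpy(dtype=float)

    valid = ~np.isnan(M) & ~np.isnan(y)[None, :]
    n = valid.sum(axis=1).astype(float)
    Xv = np.where(valid, M, 0.0)
    Yv = np.where(valid, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        # center within the pairwise-complete mask (two-pass; avoids the
        # cancellation of the raw-sums formula)
        mx = Xv.sum(axis=1, keepdims=True) / n[:, None]
        my = Yv.sum(axis=1, keepdims=True) / n[:, None]
        Xc = np.where(valid, M - mx, 0.0)
        Yc = np.where(valid, y[None, :] - my, 0.0)
        cov = (Xc * Yc).sum(axis=1)
        vx = (Xc**2).sum(axis=1)
        vy = (Yc**2).sum(axis=1)
        r = cov / np.sqrt(vx * vy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    usable = (n >= 3) & np.isfinite(r)
    excluded = tuple(genes[~usable])
    table = pd.DataFrame(
        {"gene": genes[usable], "r": r[usable], "p": np.minimum(p[usable], 1.0),
         "n": n[usable].astype(int)}
    )
    # descending r; stable tie-break by gene id for determinism
    table = table.sort_values(["r", "gene"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return CorrelationRank(index_gene=index_gene, table=table, excluded=excluded)


def two_group_de(expr: ExpressionMatrix, samples_high, samples_low,
                 q_threshold: float = 0.05) -> pd.DataFrame:
    """Welch two-sample test of every gene between two sample groups.

    Returns a per-gene table: mean difference (high - low), Welch t, p, BH q,
    and an ``up_in_high`` flag (difference > 0 and q < ``q_threshold``).
    Genes with fewer than 2 usable samples in either group are excluded and
    listed in ``result.attrs['excluded']`` with a reason.
    """
    samples_high, samples_low = list(samples_high), list(samples_low)
    if set(samples_high) & set(samples_low):
        raise ValueError("high and low sample groups overlap")
    A = expr.values.loc[:, samples_high].to_numpy(dtype=float)
    B = expr.values.loc[:, samples_low].to_numpy(dtype=float)
    nA = np.sum(~np.isnan(A), axis=1)
    nB = np.sum(~np.isnan(B), axis=1)
    usable = (nA >= 2) & (nB >= 2)
    excluded = {
        g: "fewer than 2 usable samples in a group"
        for g in expr.values.index[~usable]
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        mA, mB = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        vA, vB = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)
        diff = mA - mB
        se2 = vA / nA + vB / nB
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (vA / nA) ** 2 / np.maximum(nA - 1, 1)
            + (vB / nB) ** 2 / np.maximum(nB - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    # zero-variance, zero-difference genes carry no evidence either way
    degenerate = usable & (se2 == 0)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = np.finfo(float).tiny

    table = pd.DataFrame(
        {
            "gene": expr.values.index[usable],
            "n_high": nA[usable],
            "n_low": nB[usable],
            "difference": diff[usable],
            "t": t[usable],
            "p": p[usable],
        }
    )
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    table["up_in_high"] = (table["difference"] > 0) & (table["q"] < q_threshold)
    table = table.reset_index(drop=True)
    table.attrs["excluded"] = excluded
    return table


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # set, overlap, set_size, target_size, universe_size, p, q, genes
    library_name: str
    skipped: tuple = ()  # sets disjoint from the universe

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        out = self.table.copy()
        out["genes"] = out["genes"].map(lambda gs: ",".join(sorted(gs)))
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def enrich_gene_sets(target_genes, universe, library: GeneSetLibrary) -> EnrichmentResult:
    """Exact hypergeometric over-representation of a target list in gene sets.

    For each set (intersected with the universe first) with K members, an
    observed overlap k with the size-n target drawn from the size-N universe
    has p = P(X >= k), X ~ Hypergeometric(N, K, n).  BH q-values are computed
    across the tested sets.  Sets disjoint from the universe are skipped.
    """
    target = set(target_genes)
    universe = set(universe)
    if not target or not universe:
        raise ValueError("target and universe must be non-empty")
    if not target <= universe:
        extra = sorted(target - universe)[:5]
        raise ValueError(f"target genes outside the universe: {extra}")
    N, n = len(universe), len(target)
    rows, skipped = [], []
    for name, genes in library.sets.items():
        in_universe = genes & universe
        if not in_universe:
            skipped.append(name)
            continue
        K = len(in_universe)
        overlap = in_universe & target
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "target_size": n,
                "universe_size": N,
                "p": min(max(p, np.finfo(float).tiny), 1.0),
                "genes": frozenset(overlap),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "target_size",
                       "universe_size", "p", "genes"]
    )
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    table = table[["set", "overlap", "set_size", "target_size",
                   "universe_size", "p", "q", "genes"]]
    return EnrichmentResult(table=table, library_name=library.name, skipped=tuple(skipped))
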