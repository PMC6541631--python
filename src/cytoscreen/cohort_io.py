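"""Cohort data model and TSV/GMT readers and writers.

The pipeline's on-disk world is plain tab-delimited text: a genes x samples
expression matrix (optionally in the cBioPortal export dialect with a second
Entrez-id column), a per-patient clinical table with overall-survival and
disease-free-survival endpoints, a GISTIC-style copy-number call table, a
ligand -> receptor pairing table, and GMT gene-set libraries.  Missing values
are written as ``NA`` and kept as NaN in memory; they are excluded pairwise
by downstream computations, never imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CopyNumberTable",
    "PairingMap",
    "GeneSetLibrary",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_copy_number",
    "write_copy_number",
    "read_pairing",
    "write_pairing",
    "read_gmt",
    "write_gmt",
    "zscore_normalize",
    "intersect_samples",
]


class CohortIOError(ValueError):
    """Malformed input file or violated data invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise CohortIOError(f"duplicate {kind} identifier(s): {', '.join(map(str, dup))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples, float dtype; NaN marks missing.
    normalized : bool
        True once per-gene Z-scoring has been applied.
    constant_genes : tuple of str
        Genes found constant during normalization (their rows are all-NaN).
    """

    values: pd.DataFrame
    normalized: bool = False
    constant_genes: tuple = ()

    def __post_init__(self):
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        self.values = self.values.astype(float)
        if self.normalized:
            self._check_normalized()

    def _check_normalized(self) -> None:
        import warnings

        v = self.values.to_numpy()
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            mu = np.nanmean(v, axis=1)
            sd = np.nanstd(v, axis=1, ddof=1)
        ok = np.isnan(mu) | ((np.abs(mu) < 1e-9) & (np.abs(sd - 1.0) < 1e-9))
        if not ok.all():
            bad = self.values.index[~ok][:5].tolist()
            raise CohortIOError(
                f"matrix flagged normalized but rows are not Z-scored: {bad}"
            )

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.values.loc[gene_id]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])


@dataclass
class ClinicalTable:
    """Per-patient survival endpoints.

    ``data`` is indexed by sample id with columns ``os_months``, ``os_event``
    and optionally ``dfs_months``, ``dfs_event``, ``subtype``.  Missing
    endpoints are NaN, never silently zero.
    """

    data: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self):
        _check_unique(self.data.index, "sample")
        for col in ("os_months", "os_event"):
            if col not in self.data.columns:
                raise CohortIOError(f"clinical table missing required column {col!r}")
        for col in ("os_months", "dfs_months"):
            if col in self.data.columns:
                t = self.data[col]
                if (t.dropna() < 0).any():
                    raise CohortIOError(f"negative time in column {col!r}")
        for col in ("os_event", "dfs_event"):
            if col in self.data.columns:
                e = self.data[col].dropna()
                if not e.isin([0, 1]).all():
                    raise CohortIOError(f"non-binary event indicator in {col!r}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def endpoint(self, which: str = "OS") -> pd.DataFrame:
        """Return (time, event) for ``which`` in {'OS', 'DFS'}, complete rows only."""
        which = which.upper()
        if which == "OS":
            cols = ["os_months", "os_event"]
        elif which == "DFS":
            cols = ["dfs_months", "dfs_event"]
            if not set(cols) <= set(self.data.columns):
                raise CohortIOError("clinical table has no DFS endpoint")
        else:
            raise ValueError(f"unknown endpoint {which!r}; use 'OS' or 'DFS'")
        sub = self.data[cols].dropna()
        sub = sub.rename(columns={cols[0]: "time", cols[1]: "event"})
        sub["event"] = sub["event"].astype(int)
        return sub


@dataclass
class CopyNumberTable:
    """GISTIC-style integer copy-number calls, genes x samples.

    Codes: -2 deep deletion, -1 heterozygous loss, 0 diploid, +1 gain,
    +2 amplification.
    """

    calls: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.calls.index, "gene")
        _check_unique(self.calls.columns, "sample")
        vals = self.calls.to_numpy()
        finite = vals[~pd.isna(vals)]
        if not np.isin(finite, [-2, -1, 0, 1, 2]).all():
            bad = sorted(set(finite) - {-2, -1, 0, 1, 2})
            raise CohortIOError(f"copy-number calls outside -2..2: {bad}")
        self.calls = self.calls.astype("Int64")

    @property
    def gene_ids(self) -> list:
        return self.calls.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.calls.columns.tolist()


@dataclass
class PairingMap:
    """Ligand -> receptor(s) pairing, e.g. IL1B -> [IL1R1]."""

    entries: tuple = ()  # tuple of (ligand, tuple_of_receptors)

    def __post_init__(self):
        ligs = [l for l, _ in self.entries]
        _check_unique(ligs, "ligand")
        for lig, recs in self.entries:
            if len(recs) == 0:
                raise CohortIOError(f"ligand {lig!r} has an empty receptor list")
        self.entries = tuple((l, tuple(r)) for l, r in self.entries)

    @property
    def ligands(self) -> list:
        return [l for l, _ in self.entries]

    def receptors_of(self, ligand: str) -> tuple:
        for l, r in self.entries:
            if l == ligand:
                return r
        raise KeyError(ligand)


@dataclass
class GeneSetLibrary:
    """Named gene sets (a GMT library in memory)."""

    name: str
    sets: dict = field(default_factory=dict)  # set name -> frozenset of genes

    def __post_init__(self):
        for nm, genes in self.sets.items():
            if len(genes) == 0:
                raise CohortIOError(f"gene set {nm!r} is empty")
        self.sets = {nm: frozenset(g) for nm, g in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_numeric_tsv(path, dialect: str = "plain", integer: bool = False) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise CohortIOError(f"{path}: expected gene-id column plus sample columns")
    if dialect == "cbioportal" and raw.shape[1] >= 2 and "entrez" in raw.columns[1].lower():
        raw = raw.drop(columns=raw.columns[1])
    elif dialect not in ("plain", "cbioportal"):
        raise ValueError(f"unknown dialect {dialect!r}")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    _check_unique(genes, "gene")
    body = raw.drop(columns=gene_col)
    out = pd.DataFrame(index=pd.Index(genes, name=gene_col), columns=body.columns, dtype=float)
    for col in body.columns:
        cells = body[col].str.strip().tolist()
        parsed = np.empty(len(cells))
        for i, cell in enumerate(cells):
            if cell == NA_TOKEN or cell == "":
                parsed[i] = np.nan
                continue
            try:
                # float() is correctly rounded, so %.17g output round-trips
                parsed[i] = float(cell)
            except ValueError:
                raise CohortIOError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2} "
                    f"(gene {genes.iloc[i]!r}), column {col!r}"
                ) from None
        out[col] = parsed
    if integer:
        finite = out.to_numpy()[~out.isna().to_numpy()]
        if not np.all(finite == np.round(finite)):
            raise CohortIOError(f"{path}: non-integer copy-number call")
    return out


def read_expression(path, dialect: str = "plain") -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    ``dialect='cbioportal'`` tolerates a second Entrez-id column (dropped) and
    ``NA`` cells; ``plain`` is the same layout without the Entrez column.
    """
    return ExpressionMatrix(values=_read_numeric_tsv(path, dialect), normalized=False)


def write_expression(m: ExpressionMatrix, path) -> None:
    # %.17g round-trips every finite double bit-exactly
    m.values.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.17g",
                    index_label=m.values.index.name or "gene")


_OS_STATUS = {"0:LIVING": 0, "1:DECEASED": 1}
_DFS_STATUS = {"0:DISEASEFREE": 0, "1:RECURRED/PROGRESSED": 1}

_COL_ALIASES = {
    "sample_id": {"sample_id", "patient_id", "sample"},
    "os_months": {"os_months"},
    "os_status": {"os_status", "os_event"},
    "dfs_months": {"dfs_months"},
    "dfs_status": {"dfs_status", "dfs_event"},
    "subtype": {"subtype", "subtype_label"},
}


def _parse_status(cell: str, dialect: str, dfs: bool) -> float:
    cell = cell.strip()
    if cell == NA_TOKEN or cell == "":
        return np.nan
    if dialect == "cbioportal":
        table = _DFS_STATUS if dfs else _OS_STATUS
        mapped = table.get(cell.upper())
        if mapped is not None:
            return float(mapped)
        raise ValueError(cell)
    if cell in ("0", "1"):
        return float(cell)
    raise ValueError(cell)


def read_clinical(path, status_dialect: str = "plain") -> ClinicalTable:
    """Read the clinical TSV (sample id, OS and optionally DFS endpoints).

    ``status_dialect='cbioportal'`` maps the strings ``0:LIVING``/``1:DECEASED``
    (and ``0:DiseaseFree``/``1:Recurred/Progressed``) to binary events;
    ``plain`` expects 0/1.  Rows whose status cannot be parsed are dropped and
    counted in ``ClinicalTable.n_rejected``.
    """
    if status_dialect not in ("plain", "cbioportal"):
        raise ValueError(f"unknown status dialect {status_dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {}
    for canon, aliases in _COL_ALIASES.items():
        for c in raw.columns:
            if c.lower() in aliases:
                cols[canon] = c
                break
    for required in ("sample_id", "os_months", "os_status"):
        if required not in cols:
            raise CohortIOError(f"{path}: missing required clinical column {required!r}")

    def num(col):
        cell = raw[cols[col]].str.strip()
        return cell.map(lambda c: np.nan if c in (NA_TOKEN, "") else float(c))

    data = pd.DataFrame({"os_months": num("os_months")})
    rejected = np.zeros(len(raw), dtype=bool)
    for key, dfs in (("os_status", False), ("dfs_status", True)):
        if key not in cols:
            continue
        parsed = []
        for i, cell in enumerate(raw[cols[key]]):
            try:
                parsed.append(_parse_status(cell, status_dialect, dfs))
            except ValueError:
                parsed.append(np.nan)
                rejected[i] = True
        data["dfs_event" if dfs else "os_event"] = parsed
    if "dfs_months" in cols:
        data["dfs_months"] = num("dfs_months")
    if "subtype" in cols:
        sub = raw[cols["subtype"]].str.strip()
        data["subtype"] = sub.where((sub != NA_TOKEN) & (sub != ""))
    data.index = pd.Index(raw[cols["sample_id"]].str.strip(), name="sample_id")
    keep = ~rejected
    return ClinicalTable(data=data.loc[keep], n_rejected=int(rejected.sum()))


def write_clinical(c: ClinicalTable, path, status_dialect: str = "plain") -> None:
    out = c.data.copy()
    if status_dialect == "cbioportal":
        rev_os = {v: k for k, v in _OS_STATUS.items()}
        rev_dfs = {0: "0:DiseaseFree", 1: "1:Recurred/Progressed"}
        out["os_event"] = out["os_event"].map(lambda v: rev_os.get(v, NA_TOKEN))
        if "dfs_event" in out.columns:
            out["dfs_event"] = out["dfs_event"].map(lambda v: rev_dfs.get(v, NA_TOKEN))
        out = out.rename(columns={"os_event": "os_status", "dfs_event": "dfs_status"})
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.17g",
               index_label="sample_id")


def read_copy_number(path, dialect: str = "plain") -> CopyNumberTable:
    """Read a genes x samples integer call table; cells outside -2..2 are an error."""
    return CopyNumberTable(calls=_read_numeric_tsv(path, dialect, integer=True))


def write_copy_number(cn: CopyNumberTable, path) -> None:
    cn.calls.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label=cn.calls.index.name or "gene")


def read_pairing(path) -> PairingMap:
    """Read ``ligand<TAB>receptor[,receptor...]`` lines (header row required)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise CohortIOError(f"{path}: empty pairing file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise CohortIOError(f"{path}: malformed pairing line {lineno}")
            receptors = tuple(r.strip() for r in parts[1].split(",") if r.strip())
            entries.append((parts[0].strip(), receptors))
    return PairingMap(entries=tuple(entries))


def write_pairing(p: PairingMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ligand\treceptors\n")
        for lig, recs in p.entries:
            fh.write(f"{lig}\t{','.join(recs)}\n")


def read_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: ``name<TAB>description<TAB>gene...`` per line."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CohortIOError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            set_name = parts[0]
            if set_name in sets:
                raise CohortIOError(f"{path}: duplicate set name {set_name!r} at line {lineno}")
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise CohortIOError(f"{path}: GMT line {lineno} has no genes")
            sets[set_name] = genes
    import os

    return GeneSetLibrary(name=name or os.path.basename(str(path)), sets=sets)


def write_gmt(lib: GeneSetLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for nm, genes in lib.sets.items():
            fh.write("\t".join([nm, lib.name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def zscore_normalize(m: ExpressionMatrix, force: bool = False) -> ExpressionMatrix:
    """Per-gene Z-scoring: (x - mean) / sd with the n-1 sample standard deviation.

    Constant genes (sd == 0) are set wholly missing and listed in
    ``constant_genes`` on the returned matrix.  Normalizing an
    already-normalized matrix is an error unless ``force=True`` (used to test
    idempotence).
    """
    if m.normalized and not force:
        raise CohortIOError("matrix is already Z-score normalized")
    import warnings

    v = m.values.to_numpy(dtype=float).copy()
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mu = np.nanmean(v, axis=1, keepdims=True)
        sd = np.nanstd(v, axis=1, ddof=1, keepdims=True)
    n_obs = np.sum(~np.isnan(v), axis=1)
    constant = (sd[:, 0] == 0) | (n_obs < 2)
    sd[constant, 0] = np.nan
    z = (v - mu) / sd
    z[constant, :] = np.nan
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(
        values=out,
        normalized=True,
        constant_genes=tuple(m.values.index[constant]),
    )


def intersect_samples(expr: ExpressionMatrix, clinical: ClinicalTable,
                      cn: CopyNumberTable | None = None):
    """Restrict all tables to their common samples (order of the expression matrix).

    Returns the restricted tables plus a dict of counts, so callers can log how
    many samples each table contributed and how many survive the intersection.
    """
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if cn is not None:
        cn_set = set(cn.sample_ids)
        common = [s for s in common if s in cn_set]
    counts = {
        "expression": len(expr.sample_ids),
        "clinical": len(clinical.sample_ids),
        "common": len(common),
    }
    expr2 = expr.subset_samples(common)
    clin2 = ClinicalTable(data=clinical.data.loc[common], n_rejected=clinical.n_rejected)
    if cn is None:
        return expr2, clin2, None, counts
    counts["copy_number"] = len(cn.sample_ids)
    cn2 = CopyNumberTable(calls=cn.calls.loc[:, common])
    return expr2, clin2, cn2, counts
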