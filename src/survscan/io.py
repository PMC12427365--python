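"""Tabular input/output and validated domain containers.

The pipeline exchanges three plain-text table formats:

* expression matrix — genes as rows, samples as columns, FPKM values;
  header ``gene_id<TAB>S1<TAB>S2...``
* clinical table — one row per sample with columns ``sample_id``, ``time``
  (follow-up, any consistent unit; must be positive) and ``event``
  (1 = event observed, 0 = right-censored)
* pan-cancer table — genes as rows, cancer types as columns, mean FPKM
  per cancer

TSV is the default dialect; CSV is accepted via the ``dialect`` argument.
Missing values are not permitted anywhere — files with empty or
non-numeric cells are rejected with the offending coordinates, since no
imputation rule is defined for this analysis.

Event coding is fixed throughout the package: ``event == 1`` means the
event (death) was observed, ``event == 0`` means the sample was
right-censored. Time units are carried opaquely; the analysis is
unit-agnostic (TCGA overall survival is typically reported in days or
months).

Floats are serialized with Python's shortest round-trip representation,
so a write/read round-trip reproduces IEEE-754 doubles exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_SEPS = {"tsv": "\t", "csv": ","}

class FormatError(ValueError):
    """A file or table violates the format contract (bad value, duplicate id...)."""


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


def _check_matrix(values: np.ndarray, row_ids, col_ids, what: str) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-finite {what} value at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise FormatError(
            f"negative {what} value {values[i, j]!r} at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r}"
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample matrix of nonnegative FPKM values."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_matrix(self.values, self.gene_ids, self.sample_ids, "expression")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample follow-up time and event indicator (1=event, 0=censored)."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event))
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise FormatError("time/event length does not match number of samples")
        if not np.all(np.isfinite(self.time)):
            raise FormatError("non-finite survival time")
        if np.any(self.time <= 0):
            i = int(np.argmax(self.time <= 0))
            raise FormatError(
                f"non-positive survival time {self.time[i]!r} for sample "
                f"{self.sample_ids[i]!r}"
            )
        ev = self.event
        if not np.all(np.isin(ev, (0, 1))):
            bad = ev[~np.isin(ev, (0, 1))][0]
            raise FormatError(f"event indicator must be 0 or 1, got {bad!r}")
        object.__setattr__(self, "event", ev.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.sample_ids), "time": self.time, "event": self.event}
        )


@dataclass(frozen=True)
class PanCancerTable:
    """Gene-by-cancer table of mean FPKM per cancer type."""

    gene_ids: tuple[str, ...]
    cancer_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_cancers)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cancer_ids", tuple(str(c) for c in self.cancer_ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cancer_ids, "cancer")
        if len(self.cancer_ids) < 2:
            raise FormatError("pan-cancer table needs at least 2 cancer types")
        if self.values.shape != (len(self.gene_ids), len(self.cancer_ids)):
            raise FormatError(
                f"pan-cancer table shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cancer_ids)} cancers"
            )
        _check_matrix(self.values, self.gene_ids, self.cancer_ids, "FPKM")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.cancer_ids)
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_numeric_table(path, dialect: str, kind: str) -> pd.DataFrame:
    """Read a row-id-indexed numeric table, failing loudly on bad cells."""
    sep = _sep(dialect)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    if len(header) < 2:
        raise FormatError(f"{kind} file {path} has no data columns")
    _check_unique(header[1:], f"{kind} column")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            cell = df.loc[row, col]
            raise FormatError(
                f"non-numeric or missing {kind} value {cell!r} at row {row!r}, "
                f"column {col!r} in {path}"
            )
        df[col] = coerced
    return df


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a gene-by-sample FPKM table; row/column order preserved from file."""
    df = _read_numeric_table(path, dialect, "expression")
    return ExpressionMatrix(tuple(df.index), tuple(df.columns), df.to_numpy(float))


def read_pan_cancer(path, dialect: str = "tsv") -> PanCancerTable:
    """Read a gene-by-cancer mean-FPKM table."""
    df = _read_numeric_table(path, dialect, "pan-cancer")
    return PanCancerTable(tuple(df.index), tuple(df.columns), df.to_numpy(float))


def read_clinical(path, dialect: str = "tsv") -> ClinicalTable:
    """Read a clinical table with columns sample_id, time, event (extras ignored)."""
    sep = _sep(dialect)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str},
                     float_precision="round_trip")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"clinical file {path} is missing column {col!r}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    if time.isna().any():
        row = df["sample_id"].iloc[time.isna().to_numpy().argmax()]
        raise FormatError(f"non-numeric time for sample {row!r} in {path}")
    if event.isna().any():
        row = df["sample_id"].iloc[event.isna().to_numpy().argmax()]
        raise FormatError(f"non-numeric event for sample {row!r} in {path}")
    return ClinicalTable(
        tuple(df["sample_id"]), time.to_numpy(float), event.to_numpy()
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    expr.to_frame().to_csv(
        path, sep=_sep(dialect), index_label="gene_id"
    )


def write_clinical(clin: ClinicalTable, path, dialect: str = "tsv") -> None:
    clin.to_frame().to_csv(
        path, sep=_sep(dialect), index=False
    )


def write_pan_cancer(table: PanCancerTable, path, dialect: str = "tsv") -> None:
    table.to_frame().to_csv(
        path, sep=_sep(dialect), index_label="gene_id"
    )


def write_results_table(records, path, dialect: str = "tsv") -> None:
    """Write two-cohort validation records as a Table-1-style TSV.

    Columns, in stable order: gene, p_discovery, p_validation, outcome
    (Better/Poorer), tier. Rows sorted by p_discovery ascending, ties
    broken by gene id.
    """
    rows = [
        {
            "gene": r.gene_id,
            "p_discovery": r.p_discovery,
            "p_validation": r.p_validation,
            "outcome": r.outcome,
            "tier": r.tier,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["gene", "p_discovery", "p_validation", "outcome", "tier"]
    )
    if len(df):
        df = df.sort_values(["p_discovery", "gene"], kind="stable")
    df.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# cohort alignment
# ---------------------------------------------------------------------------


def align_cohort(
    expr: ExpressionMatrix, clin: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict expression and clinical data to their shared samples.

    Both outputs carry the intersection of sample ids in the order the
    samples appear in the expression matrix. The number of samples dropped
    from each side is logged. Fewer than 2 shared samples is an error.
    """
    clin_pos = {s: i for i, s in enumerate(clin.sample_ids)}
    shared = [s for s in expr.sample_ids if s in clin_pos]
    if len(shared) < 2:
        raise FormatError(
            f"only {len(shared)} sample(s) shared between expression and "
            "clinical tables; need at least 2"
        )
    dropped_expr = expr.n_samples - len(shared)
    dropped_clin = clin.n_samples - len(shared)
    if dropped_expr or dropped_clin:
        log.info(
            "align_cohort: %d shared samples; dropped %d from expression, %d from clinical",
            len(shared), dropped_expr, dropped_clin,
        )
    expr_cols = [expr.sample_ids.index(s) for s in shared]
    clin_rows = [clin_pos[s] for s in shared]
    expr_out = ExpressionMatrix(expr.gene_ids, tuple(shared), expr.values[:, expr_cols])
    clin_out = ClinicalTable(
        tuple(shared), clin.time[clin_rows], clin.event[clin_rows]
    )
    return expr_out, clin_out
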