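"""Per-gene optimal-cutpoint (min-p) survival screening.

For each gene the cohort is dichotomized at every candidate FPKM cutoff —
the unique observed values lying between the 20th and 80th expression
percentiles by default — and the two groups are compared with a log-rank
test. The cutoff with the smallest p-value is selected. A gene is called
*prognostic* when that minimal p-value is below ``alpha_prognostic``
(default 0.001) and is labelled *unfavorable* when the high-expression
group has more observed than expected events, *favorable* otherwise.
Genes whose median FPKM across samples is below ``min_median_fpkm``
(default 1) are excluded before any testing.

Selecting the minimum p over many cutoffs inflates the type-I error well
above nominal; :mod:`survscan.calibration` quantifies the inflation by
simulation. No multiple-testing correction is applied, matching the raw
p < 0.001 screening rule this module implements.

Percentiles use linear interpolation between order statistics (the
numpy default); at small n a different convention shifts the candidate
window. The "high" group is ``expression > cutoff`` by default; the
``>=`` rule is available via ``ScanConfig.high_rule``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import ClinicalTable, ExpressionMatrix, _sep
from .survival import _event_time_tables, _validate_time_event

log = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "CutpointScanResult",
    "candidate_cutoffs",
    "scan_gene",
    "scan_cohort",
    "write_scan_results",
    "read_scan_results",
]


@dataclass(frozen=True)
class ScanConfig:
    """Tunable knobs of the cutoff scan (defaults are the screening rule's)."""

    lower_pct: float = 20.0        # lower edge of the candidate window, percentile
    upper_pct: float = 80.0        # upper edge of the candidate window, percentile
    alpha_prognostic: float = 0.001  # min-p threshold defining a prognostic gene
    min_median_fpkm: float = 1.0   # low-expression exclusion threshold
    min_group_size: int = 2        # smallest allowed group after a split
    high_rule: str = "gt"          # "gt": high group is expr > cutoff; "ge": expr >= cutoff

    def __post_init__(self):
        if not 0 <= self.lower_pct < self.upper_pct <= 100:
            raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
        if not 0 < self.alpha_prognostic < 1:
            raise ValueError("alpha_prognostic must lie in (0, 1)")
        if self.min_median_fpkm < 0:
            raise ValueError("min_median_fpkm must be >= 0")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.high_rule not in ("gt", "ge"):
            raise ValueError("high_rule must be 'gt' or 'ge'")


@dataclass(frozen=True)
class CutpointScanResult:
    """Outcome of the min-p scan for one gene."""

    gene_id: str
    excluded: bool
    exclude_reason: str | None      # 'low_expression' | 'degenerate' | None
    best_cutoff: float              # NaN when excluded
    best_p: float                   # NaN when excluded
    n_high: int
    n_low: int
    observed_high: float
    expected_high: float
    direction: str                  # 'favorable' | 'unfavorable' | 'none'
    prognostic: bool
    n_cutoffs_scanned: int


def candidate_cutoffs(values, config: ScanConfig = ScanConfig()) -> np.ndarray:
    """Unique observed values inside the percentile window, as sorted cutoffs.

    Cutoffs whose split would leave either group smaller than
    ``config.min_group_size`` are dropped. May return an empty array
    (degenerate gene — e.g. constant expression), which the caller treats
    as an exclusion, not an error.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-d array")
    lo = np.percentile(v, config.lower_pct)  # linear interpolation
    hi = np.percentile(v, config.upper_pct)
    cand = np.unique(v[(v >= lo) & (v <= hi)])
    if cand.size == 0:
        return cand
    vs = np.sort(v)
    if config.high_rule == "gt":
        n_high = v.size - np.searchsorted(vs, cand, side="right")
    else:
        n_high = v.size - np.searchsorted(vs, cand, side="left")
    n_low = v.size - n_high
    ok = (n_high >= config.min_group_size) & (n_low >= config.min_group_size)
    return cand[ok]


class _CohortIndex:
    """Survival quantities of a cohort that do not depend on the gene.

    Precomputed once per cohort so that scanning thousands of genes, each
    over hundreds of cutoffs, only recomputes the group-dependent pieces.
    """

    def __init__(self, clin: ClinicalTable):
        t, e = _validate_time_event(clin.time, clin.event)
        if not np.any(e == 1):
            raise ValueError("cohort has no observed events; log-rank scan undefined")
        self.n = t.size
        self.order = np.argsort(t, kind="stable")
        ts, es = t[self.order], e[self.order]
        self.ut, self.n_at, self.d = _event_time_tables(ts, es)
        self.d_sum = float(self.d.sum())
        # position of the first at-risk sample for each distinct event time
        self.starts = self.n - self.n_at
        # columns of the (cutoff x sample) membership matrix that carry events,
        # grouped by distinct event time for reduceat aggregation
        self.event_cols = np.flatnonzero(es == 1)
        lab = np.searchsorted(self.ut, ts[self.event_cols])
        self.reduce_starts = np.concatenate(([0], np.flatnonzero(np.diff(lab)) + 1))
        # map reduceat segments back onto ut (every ut occurs by construction)
        assert self.reduce_starts.size == self.ut.size

    def logrank_many(self, high: np.ndarray):
        """Log-rank statistics for many groupings at once.

        ``high`` is a boolean (n_groupings x n_samples) matrix in the
        *original* sample order; row k is the high-group membership under
        cutoff k. Returns (stat, p, observed_high, expected_high, n_high).
        """
        h = np.ascontiguousarray(high[:, self.order], dtype=np.float64)
        n_high = h.sum(axis=1)
        cum = np.cumsum(h, axis=1)
        padded = np.concatenate([np.zeros((h.shape[0], 1)), cum], axis=1)
        # high-group risk set at each distinct event time:
        # total high minus high samples with time < ut_j
        n1 = n_high[:, None] - padded[:, self.starts]
        # observed high-group events per distinct event time
        d1 = np.add.reduceat(h[:, self.event_cols], self.reduce_starts, axis=1)
        frac1 = n1 / self.n_at
        e1 = (self.d * frac1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.d * frac1 * (1.0 - frac1) * (self.n_at - self.d) / (self.n_at - 1.0)
        v = np.where(self.n_at <= 1, 0.0, v)
        v_sum = v.sum(axis=1)
        o1 = d1.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(v_sum > 0, (o1 - e1) ** 2 / v_sum, 0.0)
        p = np.where(v_sum > 0, chi2.sf(stat, 1), 1.0)
        return stat, p, o1, e1, n_high.astype(int)


def _excluded(gene_id: str, reason: str) -> CutpointScanResult:
    return CutpointScanResult(
        gene_id=gene_id, excluded=True, exclude_reason=reason,
        best_cutoff=math.nan, best_p=math.nan, n_high=0, n_low=0,
        observed_high=math.nan, expected_high=math.nan,
        direction="none", prognostic=False, n_cutoffs_scanned=0,
    )


def _scan_row(
    gene_id: str, row: np.ndarray, idx: _CohortIndex, config: ScanConfig
) -> CutpointScanResult:
    if float(np.median(row)) < config.min_median_fpkm:
        return _excluded(gene_id, "low_expression")
    cand = candidate_cutoffs(row, config)
    if cand.size == 0:
        return _excluded(gene_id, "degenerate")
    if config.high_rule == "gt":
        high = row[None, :] > cand[:, None]
    else:
        high = row[None, :] >= cand[:, None]
    stat, p, o1, e1, n_high = idx.logrank_many(high)
    best = int(np.argmin(p))  # ties: first minimum = smallest cutoff
    best_p = float(p[best])
    prognostic = bool(best_p < config.alpha_prognostic)
    if not prognostic:
        direction = "none"
    elif o1[best] > e1[best]:
        direction = "unfavorable"
    else:
        direction = "favorable"   # covers the O == E edge case
    return CutpointScanResult(
        gene_id=gene_id, excluded=False, exclude_reason=None,
        best_cutoff=float(cand[best]), best_p=best_p,
        n_high=int(n_high[best]), n_low=int(idx.n - n_high[best]),
        observed_high=float(o1[best]), expected_high=float(e1[best]),
        direction=direction, prognostic=prognostic,
        n_cutoffs_scanned=int(cand.size),
    )


def scan_gene(
    expr_row, clin: ClinicalTable, config: ScanConfig = ScanConfig(),
    gene_id: str = "gene",
) -> CutpointScanResult:
    """Min-p cutoff scan for a single gene already aligned to the cohort."""
    row = np.asarray(expr_row, dtype=float)
    if row.shape != (clin.n_samples,):
        raise ValueError("expression row length must match the clinical table")
    return _scan_row(gene_id, row, _CohortIndex(clin), config)


def scan_cohort(
    expr: ExpressionMatrix, clin: ClinicalTable, config: ScanConfig = ScanConfig()
) -> list[CutpointScanResult]:
    """Run the min-p scan over every gene of an aligned cohort.

    Returns one result per gene in the matrix's row order. The scan is
    fully deterministic: identical inputs give bit-identical results.
    """
    if expr.sample_ids != clin.sample_ids:
        raise ValueError(
            "expression and clinical samples are not aligned; call align_cohort first"
        )
    idx = _CohortIndex(clin)
    results = [
        _scan_row(g, expr.values[i], idx, config)
        for i, g in enumerate(expr.gene_ids)
    ]
    n_excl = sum(r.excluded for r in results)
    n_prog = sum(r.prognostic for r in results)
    n_unfav = sum(r.direction == "unfavorable" for r in results)
    n_fav = sum(r.direction == "favorable" for r in results)
    log.info(
        "scan_cohort: %d genes, %d excluded, %d prognostic (%d favorable, %d unfavorable)",
        len(results), n_excl, n_prog, n_fav, n_unfav,
    )
    return results


# ---------------------------------------------------------------------------
# result (de)serialization
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = [
    "gene_id", "excluded", "reason", "best_cutoff", "best_p", "n_high", "n_low",
    "observed_high", "expected_high", "direction", "prognostic", "n_cutoffs_scanned",
]


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "excluded": r.excluded,
                "reason": r.exclude_reason if r.exclude_reason else "",
                "best_cutoff": r.best_cutoff,
                "best_p": r.best_p,
                "n_high": r.n_high,
                "n_low": r.n_low,
                "observed_high": r.observed_high,
                "expected_high": r.expected_high,
                "direction": r.direction,
                "prognostic": r.prognostic,
                "n_cutoffs_scanned": r.n_cutoffs_scanned,
            }
            for r in results
        ],
        columns=_SCAN_COLUMNS,
    )


def write_scan_results(results, path, dialect: str = "tsv") -> None:
    results_to_frame(results).to_csv(
        path, sep=_sep(dialect), index=False
    )


def read_scan_results(path, dialect: str = "tsv") -> list[CutpointScanResult]:
    df = pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip")
    missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan results file {path} is missing columns {missing}")
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            CutpointScanResult(
                gene_id=str(rec.gene_id),
                excluded=bool(rec.excluded),
                exclude_reason=(str(rec.reason) if isinstance(rec.reason, str) and rec.reason else None),
                best_cutoff=float(rec.best_cutoff),
                best_p=float(rec.best_p),
                n_high=int(rec.n_high),
                n_low=int(rec.n_low),
                observed_high=float(rec.observed_high),
                expected_high=float(rec.expected_high),
                direction=str(rec.direction),
                prognostic=bool(rec.prognostic),
                n_cutoffs_scanned=int(rec.n_cutoffs_scanned),
            )
        )
    return out
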