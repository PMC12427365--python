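"""Null calibration of the min-p cutoff scan.

Dichotomizing at the cutoff that minimizes the log-rank p-value and then
reading that minimal p against a nominal threshold inflates the type-I
error far above nominal — a well-known property of minimum-p cutpoint
selection. This module measures the inflation by simulation: cohorts in
which expression is independent of survival are generated, every gene is
scanned, and the fraction of null genes whose best p falls below each
alpha is reported with Clopper–Pearson confidence intervals.

Because all genes of a replicate share one survival realization (as in a
real cohort), the per-gene outcomes are positively dependent; the CIs
treat genes as independent and are therefore approximate for n_reps=1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .scan import ScanConfig, scan_cohort
from .simulate import CohortSimConfig, simulate_cohort

__all__ = ["AlphaCalibration", "NullCalibrationReport", "null_scan_calibration"]


@dataclass(frozen=True)
class AlphaCalibration:
    alpha: float
    n_hits: int
    n_genes: int
    fraction: float
    ci_low: float      # 95% Clopper-Pearson
    ci_high: float


@dataclass(frozen=True)
class NullCalibrationReport:
    n_samples: int
    n_genes_per_rep: int
    n_reps: int
    censoring_fraction_target: float
    per_alpha: tuple[AlphaCalibration, ...]

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_genes_per_rep": self.n_genes_per_rep,
            "n_reps": self.n_reps,
            "censoring_fraction_target": self.censoring_fraction_target,
            "per_alpha": [
                {
                    "alpha": a.alpha,
                    "n_hits": a.n_hits,
                    "n_genes": a.n_genes,
                    "fraction": a.fraction,
                    "ci95_low": a.ci_low,
                    "ci95_high": a.ci_high,
                }
                for a in self.per_alpha
            ],
        }


def null_scan_calibration(
    n_genes: int,
    n_samples: int,
    n_reps: int,
    config: ScanConfig = ScanConfig(),
    seed: int = 0,
    censoring_fraction_target: float = 0.30,
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> NullCalibrationReport:
    """Measure the null best-p exceedance fractions of the cutoff scan.

    Each replicate simulates ``n_genes`` expression-independent genes for
    ``n_samples`` patients (seeded; replicate r uses ``seed + r``), scans
    them, and pools best-p values across replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_genes < 1 or n_samples < 10:
        raise ValueError("need n_genes >= 1 and n_samples >= 10")
    best_p: list[float] = []
    for rep in range(n_reps):
        sim = CohortSimConfig(
            n_samples=n_samples,
            n_null_genes=n_genes,
            n_prognostic_genes=0,
            log_hr=0.0,
            censoring_fraction_target=censoring_fraction_target,
            seed=seed + rep,
        )
        expr, clin, _ = simulate_cohort(sim)
        best_p.extend(
            r.best_p for r in scan_cohort(expr, clin, config) if not r.excluded
        )
    p = np.asarray(best_p)
    per_alpha = []
    for alpha in alphas:
        hits = int((p < alpha).sum())
        lo, hi = proportion_confint(hits, p.size, alpha=0.05, method="beta")
        per_alpha.append(
            AlphaCalibration(
                alpha=alpha, n_hits=hits, n_genes=int(p.size),
                fraction=hits / p.size, ci_low=float(lo), ci_high=float(hi),
            )
        )
    return NullCalibrationReport(
        n_samples=n_samples, n_genes_per_rep=n_genes, n_reps=n_reps,
        censoring_fraction_target=censoring_fraction_target,
        per_alpha=tuple(per_alpha),
    )
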