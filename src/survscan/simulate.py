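"""Synthetic cohorts and pan-cancer tables with known ground truth.

Survival cohorts
----------------
Expression is i.i.d. log-normal per gene (FPKM-like, strictly positive,
right-skewed). Survival is a property of the *patient*, not the gene:
one survival time is drawn per sample and every gene row is screened
against that same clinical table, which induces the realistic inter-gene
dependence of the null min-p distribution. Prognostic genes are planted
through a latent per-sample risk indicator: a fraction of samples
(1 - true_cutoff_pct/100) is designated high-risk, the hazard is
``baseline_hazard * exp(log_hr)`` for those samples and
``baseline_hazard`` otherwise, and each planted gene's expression values
are permuted so that its top order statistics land exactly on the
high-risk samples. Dichotomizing a planted gene at its recorded
``true_cutoff`` therefore reproduces the risk groups, while the marginal
FPKM distribution stays log-normal. Planted genes consequently share one
risk partition — the price of keeping a single, patient-level clinical
table.

Event times are exponential by default (Weibull via ``weibull_shape``).
Right censoring is administrative: a single censoring time is chosen by
root-finding on the model's marginal survival function so the expected
censored fraction equals the target, then verified against the realized
draw and, if sampling noise has pushed the realized fraction more than
2.5 points off target, re-anchored at the empirical quantile of the
drawn event times. Either way the output is a pure function of the
configuration, including the seed.

Pan-cancer tables
-----------------
``simulate_pan_cancer`` plants genes that satisfy each specificity
category's defining inequality with a multiplicative safety margin while
*failing* every earlier category in the classifier's precedence order.
Some combinations are geometrically impossible and raise: GroupEnriched
needs at least one non-member cancer plus two members, and Enhanced —
whose candidate cancer must exceed ``fold`` times the all-cancer mean
while some other cancer stays within ``fold``-fold of it to escape the
Enriched rule — is only plantable when the number of cancers is large
relative to ``fold * margin`` (roughly ``n > fold * margin * 1.25``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, PanCancerTable
from .specificity import CATEGORIES

__all__ = [
    "CohortSimConfig",
    "GeneTruth",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_pan_cancer",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Generator settings; the defaults mirror the discovery-cohort setting.

    n_samples=349 and censoring_fraction_target=0.30 match the TCGA-sized
    ovarian discovery cohort; log_hr=ln(3) plants a hazard ratio of 3 for
    the high-expression group at the median (50th percentile) cutoff.
    fpkm_logmean=1 gives a median FPKM of e (~2.7), safely above the
    low-expression exclusion threshold of FPKM 1; baseline_hazard is in
    reciprocal time units (time units are opaque to the pipeline).
    """

    n_samples: int = 349
    n_null_genes: int = 100
    n_prognostic_genes: int = 0
    log_hr: float = math.log(3.0)
    true_cutoff_pct: float = 50.0
    baseline_hazard: float = 0.02
    censoring_fraction_target: float = 0.30
    fpkm_logmean: float = 1.0
    fpkm_logsd: float = 1.0
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.n_null_genes < 0 or self.n_prognostic_genes < 0:
            raise ValueError("gene counts must be nonnegative")
        if self.n_null_genes + self.n_prognostic_genes == 0:
            raise ValueError("need at least one gene")
        if not 0 < self.true_cutoff_pct < 100:
            raise ValueError("true_cutoff_pct must lie in (0, 100)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.censoring_fraction_target < 1:
            raise ValueError("censoring_fraction_target must lie in [0, 1)")
        if self.fpkm_logsd <= 0:
            raise ValueError("fpkm_logsd must be > 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    is_prognostic: bool
    true_direction: str | None     # 'favorable' | 'unfavorable' | None
    true_cutoff: float             # FPKM; NaN for null genes
    log_hr: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth keyed by gene id."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)


def _surv_mixture(c, h0, h1, pi, shape):
    ca = c ** shape
    return (1.0 - pi) * math.exp(-h0 * ca) + pi * math.exp(-h1 * ca)


def _censoring_time(h0, h1, pi, shape, target):
    """Administrative censoring time with expected censored fraction = target."""
    f = lambda c: _surv_mixture(c, h0, h1, pi, shape) - target
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the censoring time")
    lo = hi / 2.0 if hi > 1.0 else 1e-12
    while f(lo) < 0:
        lo /= 2.0
        if lo < 1e-15:
            break
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate an expression matrix, clinical table and planted truth.

    Gene rows are ordered prognostic genes first (``PROG0001``...), then
    null genes (``NULL0001``...). Same config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = tuple(f"S{i+1:04d}" for i in range(n))

    effect_active = config.n_prognostic_genes > 0 and config.log_hr != 0.0
    q = config.true_cutoff_pct / 100.0
    k_high = int(round(n * (1.0 - q)))
    if config.n_prognostic_genes > 0 and not 1 <= k_high <= n - 1:
        raise ValueError(
            "true_cutoff_pct leaves an empty expression group at this n_samples"
        )
    perm = rng.permutation(n)
    high_risk = np.zeros(n, dtype=bool)
    high_risk[perm[:k_high]] = True

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth_genes: dict[str, GeneTruth] = {}

    direction = (
        "unfavorable" if config.log_hr > 0
        else ("favorable" if config.log_hr < 0 else None)
    )
    for i in range(config.n_prognostic_genes):
        gid = f"PROG{i+1:04d}"
        x = np.sort(rng.lognormal(config.fpkm_logmean, config.fpkm_logsd, n))
        low_vals, high_vals = x[: n - k_high], x[n - k_high:]
        row = np.empty(n)
        row[~high_risk] = rng.permutation(low_vals)
        row[high_risk] = rng.permutation(high_vals)
        gene_ids.append(gid)
        rows.append(row)
        truth_genes[gid] = GeneTruth(
            gene_id=gid,
            is_prognostic=config.log_hr != 0.0,
            true_direction=direction,
            true_cutoff=float(low_vals.max()),
            log_hr=config.log_hr,
        )
    for i in range(config.n_null_genes):
        gid = f"NULL{i+1:04d}"
        gene_ids.append(gid)
        rows.append(rng.lognormal(config.fpkm_logmean, config.fpkm_logsd, n))
        truth_genes[gid] = GeneTruth(
            gene_id=gid, is_prognostic=False, true_direction=None,
            true_cutoff=math.nan, log_hr=0.0,
        )

    h0 = config.baseline_hazard
    h1 = h0 * math.exp(config.log_hr) if effect_active else h0
    hazard = np.where(high_risk & effect_active, h1, h0)
    # T = (E/h)^(1/shape) with E ~ Exp(1) gives Weibull with S(t)=exp(-h t^shape)
    t_event = (rng.exponential(1.0, n) / hazard) ** (1.0 / config.weibull_shape)

    target = config.censoring_fraction_target
    if target == 0.0:
        time, event = t_event, np.ones(n, dtype=np.int64)
    else:
        pi = k_high / n if effect_active else 0.0
        c = _censoring_time(h0, h1, pi, config.weibull_shape, target)
        event = (t_event <= c).astype(np.int64)
        realized = 1.0 - event.mean()
        if abs(realized - target) > 0.025:
            # sampling noise pushed the draw off target; re-anchor on the
            # empirical quantile so the realized fraction lands on target
            c = float(np.quantile(t_event, 1.0 - target))
            event = (t_event <= c).astype(np.int64)
            realized = 1.0 - event.mean()
        if abs(realized - target) > 0.05:
            raise RuntimeError(
                f"censoring target {target:.3f} unattainable; achieved {realized:.3f}"
            )
        time = np.minimum(t_event, c)

    expr = ExpressionMatrix(tuple(gene_ids), sample_ids, np.vstack(rows))
    clin = ClinicalTable(sample_ids, time, event)
    return expr, clin, SyntheticTruth(genes=truth_genes)


# ---------------------------------------------------------------------------
# pan-cancer planting
# ---------------------------------------------------------------------------

_CAT_PREFIX = {
    "NotDetected": "ND",
    "Enriched": "ENR",
    "GroupEnriched": "GRP",
    "ExpressedInAll": "ALL",
    "Enhanced": "ENH",
    "Mixed": "MIX",
}


def enhanced_margin_cap(n_cancers: int, fold: float = 5.0) -> float:
    """Largest safety margin at which an Enhanced gene can be planted.

    The Enhanced candidate must exceed ``fold * margin`` times the mean
    over all cancers, yet a second cancer must stay within ``fold``-fold
    of it (otherwise the gene is Enriched, which takes precedence), so
    the all-cancer mean cannot drop below about (1 + 1/fold)/n of the
    candidate. The generator's construction attains the cap up to small
    slack terms reserved for strictness.
    """
    worst_sum = 1.0 + 1.15 / fold + 0.003 * max(n_cancers - 2, 0)
    return n_cancers / (fold * worst_sum)


def _plant_not_detected(rng, n, margin, fold, detect):
    return rng.uniform(0.0, 0.95 * detect / margin, n)


def _plant_enriched(rng, n, margin, fold, detect):
    v = rng.uniform(0.3 * detect, 1.5 * detect, n)
    top = int(rng.integers(n))
    others_max = np.delete(v, top).max()
    v[top] = margin * fold * others_max * (1.0 + rng.uniform(0.0, 0.05))
    return v


def _plant_group_enriched(rng, n, margin, fold, detect):
    if n < 3:
        raise ValueError("GroupEnriched needs at least 3 cancers (2 members + 1 other)")
    k = int(rng.integers(2, min(7, n - 1) + 1))
    v = rng.uniform(0.3 * detect, 1.2 * detect, n)
    members = rng.choice(n, size=k, replace=False)
    rest_max = np.delete(v, members).max()
    g = margin * fold * rest_max
    v[members] = rng.uniform(g, 1.15 * g, k)
    return v


def _plant_expressed_in_all(rng, n, margin, fold, detect):
    return rng.uniform(1.01 * margin * detect, 2.0 * margin * detect, n)


def _plant_enhanced(rng, n, margin, fold, detect):
    cap = enhanced_margin_cap(n, fold)
    if margin > cap:
        raise ValueError(
            f"Enhanced cannot be planted with margin {margin:g} at {n} cancers "
            f"(cap ~{cap:.2f}): escaping the higher-precedence Enriched rule "
            "forces the all-cancer mean too high; use more cancers or a "
            "smaller margin"
        )
    v_top = min(1.5, 1.9 / (1.0 + 1.15 / fold)) * detect
    v = rng.uniform(0.0, 0.003, n) * v_top
    top = int(rng.integers(n))
    candidates = [i for i in range(n) if i != top]
    second = candidates[int(rng.integers(n - 1))]
    v[top] = v_top
    # within fold-fold of the top cancer, so the Enriched rule cannot fire,
    # while keeping every top-k group mean below the detection threshold
    v[second] = rng.uniform(1.05, 1.15) / fold * v_top
    achieved = v[top] * n / (fold * v.sum())
    if achieved < margin:   # defensive; the cap check should prevent this
        raise ValueError(
            f"Enhanced planting achieved margin {achieved:.2f} < requested {margin:g}"
        )
    return v


def _plant_mixed(rng, n, margin, fold, detect):
    u_min = 1.3 * margin * detect / fold   # blocks the Enriched rule
    u_max = detect / (1.02 * margin)       # stays undetected
    if u_min >= u_max:
        raise ValueError(
            f"Mixed cannot be planted with margin {margin:g} at fold {fold:g}: "
            "the undetected band collides with the Enriched escape condition"
        )
    j = int(rng.integers(1, n))  # detected in 1..n-1 cancers
    v = rng.uniform(u_min, u_max, n)
    detected = rng.choice(n, size=j, replace=False)
    v[detected] = rng.uniform(1.0, 1.25, j) * margin * detect
    return v


_PLANTERS = {
    "NotDetected": _plant_not_detected,
    "Enriched": _plant_enriched,
    "GroupEnriched": _plant_group_enriched,
    "ExpressedInAll": _plant_expressed_in_all,
    "Enhanced": _plant_enhanced,
    "Mixed": _plant_mixed,
}


def simulate_pan_cancer(
    n_per_category,
    n_cancers: int = 17,
    margin: float = 1.5,
    seed: int = 0,
    fold: float = 5.0,
    detect_fpkm: float = 1.0,
) -> tuple[PanCancerTable, SyntheticTruth]:
    """Plant genes into each specificity category with a safety margin.

    ``n_per_category`` maps category names (see
    :data:`survscan.specificity.CATEGORIES`) to gene counts; missing
    categories default to 0. ``margin`` (>= 1.1) is the multiplicative
    slack with which each planted gene clears its category's defining
    inequality. Unplantable combinations raise ``ValueError``.
    """
    if margin < 1.1:
        raise ValueError("margin must be >= 1.1")
    if n_cancers < 2:
        raise ValueError("need at least 2 cancers")
    if fold < 2.5:
        raise ValueError("planting constructions assume fold >= 2.5")
    unknown = set(n_per_category) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cancer_ids = tuple(f"C{i+1:02d}" for i in range(n_cancers))
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    categories: dict[str, str] = {}
    for cat in CATEGORIES:
        count = int(n_per_category.get(cat, 0))
        if count < 0:
            raise ValueError("gene counts must be nonnegative")
        if count == 0:
            continue
        planter = _PLANTERS[cat]
        for i in range(count):
            gid = f"{_CAT_PREFIX[cat]}{i+1:04d}"
            gene_ids.append(gid)
            rows.append(planter(rng, n_cancers, margin, fold, detect_fpkm))
            categories[gid] = cat
    values = (
        np.vstack(rows) if rows else np.empty((0, n_cancers))
    )
    table = PanCancerTable(tuple(gene_ids), cancer_ids, values)
    return table, SyntheticTruth(categories=categories)
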