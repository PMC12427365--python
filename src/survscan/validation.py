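"""Two-cohort (discovery + validation) combination of scan results.

Replays the dual-dataset significance-tier logic of the ovarian-cancer
screen: a gene is *both_significant* when its best-cutoff log-rank p is
below 0.05 in both cohorts, *single_relaxed* (the "asterisk" tier) when
one cohort is below 0.05 and the other below 0.10, and *not_validated*
otherwise. All threshold comparisons are strict (p < 0.05, p < 0.10).

The outcome label comes from the discovery cohort's observed/expected
decomposition at its best cutoff: high-expression group with no more
observed than expected events → ``Better`` (favorable), more observed
than expected → ``Poorer`` (unfavorable). Discordant directions between
cohorts are flagged via ``direction_concordant`` rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .scan import CutpointScanResult

log = logging.getLogger(__name__)

__all__ = ["TIERS", "ValidationRecord", "combine_cohorts", "filter_report"]

TIERS = ("both_significant", "single_relaxed", "not_validated")

_P_STRICT = 0.05
_P_RELAXED = 0.10


@dataclass(frozen=True)
class ValidationRecord:
    gene_id: str
    p_discovery: float
    p_validation: float
    outcome: str               # 'Better' | 'Poorer'
    tier: str                  # see TIERS
    direction_concordant: bool


def _tier(p_d: float, p_v: float) -> str:
    if p_d < _P_STRICT and p_v < _P_STRICT:
        return "both_significant"
    if (p_d < _P_STRICT and p_v < _P_RELAXED) or (p_v < _P_STRICT and p_d < _P_RELAXED):
        return "single_relaxed"
    return "not_validated"


def _excess_sign(r: CutpointScanResult) -> int:
    """+1 if the high group has more observed than expected events, else -1."""
    return 1 if r.observed_high > r.expected_high else -1


def combine_cohorts(
    discovery: list[CutpointScanResult],
    validation: list[CutpointScanResult],
) -> list[ValidationRecord]:
    """Join per-gene scan results from two cohorts into validation records.

    Only genes present and non-excluded in both cohorts are evaluated;
    the number of shared genes dropped for exclusion is logged. Records
    are sorted by tier, then p_discovery, then gene id. An empty usable
    intersection is an error.
    """
    d_by = {r.gene_id: r for r in discovery}
    v_by = {r.gene_id: r for r in validation}
    shared = [g for g in d_by if g in v_by]
    if not shared:
        raise ValueError("no genes shared between discovery and validation cohorts")
    usable = [g for g in shared if not d_by[g].excluded and not v_by[g].excluded]
    n_dropped = len(shared) - len(usable)
    if n_dropped:
        log.info(
            "combine_cohorts: dropped %d of %d shared genes excluded in at least one cohort",
            n_dropped, len(shared),
        )
    if not usable:
        raise ValueError(
            "all shared genes were excluded (low expression / degenerate) in a cohort"
        )
    records = []
    for g in usable:
        rd, rv = d_by[g], v_by[g]
        outcome = "Poorer" if _excess_sign(rd) > 0 else "Better"
        records.append(
            ValidationRecord(
                gene_id=g,
                p_discovery=rd.best_p,
                p_validation=rv.best_p,
                outcome=outcome,
                tier=_tier(rd.best_p, rv.best_p),
                direction_concordant=_excess_sign(rd) == _excess_sign(rv),
            )
        )
    tier_rank = {t: i for i, t in enumerate(TIERS)}
    records.sort(key=lambda r: (tier_rank[r.tier], r.p_discovery, r.gene_id))
    return records


def filter_report(records, include_tiers) -> list[ValidationRecord]:
    """Subset records to the requested tiers, preserving order."""
    include = set(include_tiers)
    return [r for r in records if r.tier in include]
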