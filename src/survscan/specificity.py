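"""Six-category pan-cancer expression-specificity classification.

Each gene's vector of mean FPKM values across cancer types is assigned
exactly one of six categories:

* ``NotDetected`` — FPKM below the detection threshold (default 1) in
  every cancer;
* ``Enriched`` — one cancer at least ``fold`` (default 5) times higher
  than every other cancer;
* ``GroupEnriched`` — a group of 2–7 cancers whose mean FPKM is at least
  ``fold`` times higher than every non-member cancer;
* ``Enhanced`` — at least one cancer ``fold`` times higher than the mean
  over all cancers (the mean includes the cancer itself);
* ``ExpressedInAll`` — above the detection threshold in every cancer;
* ``Mixed`` — everything else.

Categories are evaluated first-match in the precedence order
NotDetected, Enriched, GroupEnriched, Enhanced, ExpressedInAll, Mixed
("hpa" order). Under the alternative "listed" order ExpressedInAll is
tested before Enhanced; that makes Enhanced unreachable for genes
detected everywhere, so "hpa" is the default. Fold conditions are
evaluated by multiplication (``a >= fold * b``), never division, so
zero-valued comparison cancers satisfy the condition automatically.

The GroupEnriched search only examines the groups formed by the top-k
expressing cancers for k = 2..7. This is exact, not a heuristic: for any
group G of size k, the top-k group has a mean at least as large and a
non-member maximum no larger, so G satisfying the rule implies top-k
does. The test suite verifies this against brute-force subset
enumeration.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PanCancerTable, _sep

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "SpecificityCall",
    "classify_gene",
    "classify_table",
    "write_specificity_table",
]

CATEGORIES = (
    "NotDetected",
    "Enriched",
    "GroupEnriched",
    "ExpressedInAll",
    "Enhanced",
    "Mixed",
)

MAX_GROUP_SIZE = 7  # largest cancer group considered for GroupEnriched


@dataclass(frozen=True)
class SpecificityCall:
    """One gene's category with the cancers and fold change that support it."""

    gene_id: str
    category: str
    cancers: tuple[str, ...]   # supporting cancers (member/enhanced); empty otherwise
    fold_achieved: float       # achieved fold over the relevant comparator; NaN if n/a
    n_detected: int            # cancers with FPKM > detection threshold


def _as_series(fpkm_by_cancer) -> pd.Series:
    s = pd.Series(fpkm_by_cancer, dtype=float)
    if s.size < 2:
        raise ValueError("classification needs at least 2 cancers")
    if not np.all(np.isfinite(s.to_numpy())) or np.any(s.to_numpy() < 0):
        raise ValueError("FPKM values must be finite and nonnegative")
    return s


def _try_enriched(v, ids, fold, detect_fpkm, require_detected):
    top = int(np.argmax(v))
    others = np.delete(v, top)
    if require_detected and v[top] < detect_fpkm:
        return None
    if np.all(v[top] >= fold * others):
        m = others.max()
        achieved = v[top] / m if m > 0 else np.inf
        return (ids[top],), achieved
    return None


def _try_group_enriched(v, ids, fold, detect_fpkm):
    # stable order: ties broken by input position
    order = np.argsort(-v, kind="stable")
    n = v.size
    for k in range(2, min(MAX_GROUP_SIZE, n - 1) + 1):
        members, rest = order[:k], order[k:]
        gmean = v[members].mean()
        if gmean < detect_fpkm:
            continue
        rest_max = v[rest].max()
        if np.all(gmean >= fold * v[rest]):
            achieved = gmean / rest_max if rest_max > 0 else np.inf
            return tuple(ids[i] for i in members), achieved
    return None


def _try_enhanced(v, ids, fold):
    mean_all = v.mean()
    hits = np.flatnonzero(v >= fold * mean_all) if mean_all > 0 else np.flatnonzero(v > 0)
    if hits.size == 0:
        return None
    achieved = v[hits].max() / mean_all if mean_all > 0 else np.inf
    return tuple(ids[i] for i in hits), achieved


def classify_gene(
    fpkm_by_cancer,
    fold: float = 5.0,
    detect_fpkm: float = 1.0,
    gene_id: str = "gene",
    precedence: str = "hpa",
    enriched_requires_detection: bool = True,
) -> SpecificityCall:
    """Classify one gene's per-cancer mean FPKM vector.

    Parameters
    ----------
    fpkm_by_cancer : mapping or Series of nonnegative FPKM keyed by cancer id
    fold : fold-change defining Enriched/GroupEnriched/Enhanced (default 5)
    detect_fpkm : detection threshold (default FPKM 1)
    precedence : "hpa" (Enhanced before ExpressedInAll, default) or
        "listed" (ExpressedInAll before Enhanced)
    enriched_requires_detection : require the top cancer of an Enriched
        call to itself exceed ``detect_fpkm``
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if precedence not in ("hpa", "listed"):
        raise ValueError("precedence must be 'hpa' or 'listed'")
    s = _as_series(fpkm_by_cancer)
    v = s.to_numpy()
    ids = list(s.index.astype(str))
    n_detected = int((v > detect_fpkm).sum())

    def call(category, cancers=(), achieved=np.nan):
        return SpecificityCall(
            gene_id=gene_id, category=category, cancers=tuple(cancers),
            fold_achieved=float(achieved), n_detected=n_detected,
        )

    if np.all(v < detect_fpkm):
        return call("NotDetected")
    hit = _try_enriched(v, ids, fold, detect_fpkm, enriched_requires_detection)
    if hit is not None:
        return call("Enriched", *hit)
    hit = _try_group_enriched(v, ids, fold, detect_fpkm)
    if hit is not None:
        return call("GroupEnriched", *hit)

    expressed_in_all = bool(np.all(v > detect_fpkm))
    enhanced = _try_enhanced(v, ids, fold)
    if precedence == "hpa":
        if enhanced is not None:
            return call("Enhanced", *enhanced)
        if expressed_in_all:
            return call("ExpressedInAll")
    else:
        if expressed_in_all:
            return call("ExpressedInAll")
        if enhanced is not None:
            return call("Enhanced", *enhanced)
    return call("Mixed")


def classify_table(
    table: PanCancerTable,
    fold: float = 5.0,
    detect_fpkm: float = 1.0,
    precedence: str = "hpa",
    enriched_requires_detection: bool = True,
) -> list[SpecificityCall]:
    """Classify every gene of a pan-cancer table; logs the category census."""
    calls = [
        classify_gene(
            pd.Series(table.values[i], index=list(table.cancer_ids)),
            fold=fold, detect_fpkm=detect_fpkm, gene_id=g,
            precedence=precedence,
            enriched_requires_detection=enriched_requires_detection,
        )
        for i, g in enumerate(table.gene_ids)
    ]
    census = Counter(c.category for c in calls)
    log.info(
        "classify_table: %d genes — %s",
        len(calls), ", ".join(f"{k}={census[k]}" for k in CATEGORIES if census[k]),
    )
    return calls


def write_specificity_table(calls, path, dialect: str = "tsv") -> None:
    """TSV with columns gene_id, category, detail (semicolon cancer ids), fold_achieved."""
    df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "category": c.category,
                "detail": ";".join(c.cancers),
                "fold_achieved": c.fold_achieved,
            }
            for c in calls
        ],
        columns=["gene_id", "category", "detail", "fold_achieved"],
    )
    df.to_csv(path, sep=_sep(dialect), index=False)
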