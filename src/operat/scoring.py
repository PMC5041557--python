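"""Composite OPERAT scoring.

Each observed item is recoded to [0, 1] with 0 the most desirable state and 1
the least desirable, multiplied by its integer Thurstone multiplier, and
summed within its domain to give a raw domain score.  Raw domain scores are
min-max transformed onto a common footing and weighted by the EAG domain
weights:

    chi = 100 / sum(EAG weights)
    transformed = (raw - raw_min) / raw_range * chi * eag_weight

The composite total is the sum of the four transformed domains and spans
0-100, higher = less desirable environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .instrument import AreaAssessment, InstrumentSpec, ItemSpec

__all__ = [
    "ScoreReport",
    "recode_item",
    "weighted_item_score",
    "raw_domain_score",
    "compute_chi",
    "transform_domain",
    "score_area",
    "score_batch",
    "scores_to_frame",
    "summary_table",
]


@dataclass
class ScoreReport:
    """Per-area raw and transformed domain scores plus the composite total."""

    area_id: str
    raw_domain: dict[str, float]
    transformed_domain: dict[str, float]
    total: float
    prorated_domains: tuple[str, ...] = ()


def recode_item(item: ItemSpec, raw_value: float) -> float:
    """Recode a raw observation onto the 0 = best, 1 = worst scale.

    Binary and proportion observations flip when the feature's presence is
    desirable; ordinal observations are mapped to equally spaced points in
    [0, 1] before the same orientation rule.
    """
    if not item.value_in_range(raw_value):
        raise ValueError(
            f"value {raw_value!r} out of range for item {item.item_id!r} "
            f"({item.value_kind})"
        )
    if item.value_kind == "ordinal":
        v = float(raw_value) / (item.ordinal_levels - 1)
    else:
        v = float(raw_value)
    return 1.0 - v if item.desirable_direction == "presence_good" else v


def weighted_item_score(item: ItemSpec, raw_value: float) -> float:
    """Recoded value times the item's Thurstone multiplier; range [0, multiplier]."""
    return recode_item(item, raw_value) * item.multiplier


def raw_domain_score(
    spec: InstrumentSpec,
    assessment: AreaAssessment,
    domain_id: str,
    *,
    allow_missing: str = "error",
) -> float:
    """Sum of weighted item scores over a domain's member items.

    ``allow_missing='prorate'`` rescales the observed-item sum to the full
    domain maximum when some items are unobserved (at least one must be
    observed); the default is a hard error naming the missing item.
    """
    items = spec.domain_items(domain_id)
    if not items:
        raise KeyError(domain_id)
    observed = [i for i in items if i.item_id in assessment.observations]
    missing = [i.item_id for i in items if i.item_id not in assessment.observations]
    if missing and allow_missing != "prorate":
        raise ValueError(
            f"area {assessment.area_id!r}: incomplete assessment, missing "
            f"item(s) {missing} in domain {domain_id!r}"
        )
    if not observed:
        raise ValueError(
            f"area {assessment.area_id!r}: no observed items in domain {domain_id!r}"
        )
    total = sum(
        weighted_item_score(i, assessment.observations[i.item_id]) for i in observed
    )
    if missing:
        observed_max = sum(i.multiplier for i in observed)
        full_max = sum(i.multiplier for i in items)
        total *= full_max / observed_max
    return total


def compute_chi(eag_weights: Sequence[float]) -> float:
    """Normalising constant: 100 divided by the sum of the EAG domain weights."""
    if len(eag_weights) == 0:
        raise ValueError("eag_weights must be nonempty")
    if any(w <= 0 for w in eag_weights):
        raise ValueError("eag_weights must all be positive")
    return 100.0 / sum(eag_weights)


def transform_domain(
    raw: float, raw_min: float, raw_range: float, chi: float, eag_weight: float
) -> float:
    """Min-max transform of a raw domain score onto its weighted 0-100 share."""
    if raw_range <= 0:
        raise ValueError("raw_range must be positive")
    if not raw_min <= raw <= raw_min + raw_range + 1e-9:
        raise ValueError(
            f"raw score {raw} outside [{raw_min}, {raw_min + raw_range}]"
        )
    return (raw - raw_min) / raw_range * chi * eag_weight


def score_area(
    spec: InstrumentSpec,
    assessment: AreaAssessment,
    *,
    allow_missing: str = "error",
) -> ScoreReport:
    """Score one area: four raw + transformed domain scores and the total."""
    raw: dict[str, float] = {}
    transformed: dict[str, float] = {}
    prorated: list[str] = []
    for d in spec.domains:
        r = raw_domain_score(spec, assessment, d.domain_id, allow_missing=allow_missing)
        raw[d.domain_id] = r
        transformed[d.domain_id] = transform_domain(
            r, d.raw_min, d.raw_max - d.raw_min, spec.chi, d.eag_weight
        )
        if allow_missing == "prorate" and any(
            i.item_id not in assessment.observations
            for i in spec.domain_items(d.domain_id)
        ):
            prorated.append(d.domain_id)
    return ScoreReport(
        area_id=assessment.area_id,
        raw_domain=raw,
        transformed_domain=transformed,
        total=sum(transformed.values()),
        prorated_domains=tuple(prorated),
    )


def score_batch(
    spec: InstrumentSpec,
    assessments: Iterable[AreaAssessment],
    *,
    allow_missing: str = "error",
) -> tuple[list[ScoreReport], pd.DataFrame]:
    """Score many areas and produce a per-domain summary table.

    The summary mirrors the published presentation: max possible raw and
    transformed score, observed min/max, mean, median and SD for each domain
    and the total.
    """
    reports = [score_area(spec, a, allow_missing=allow_missing) for a in assessments]
    if not reports:
        raise ValueError("need at least one assessment")
    return reports, summary_table(spec, reports)


def scores_to_frame(spec: InstrumentSpec, reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """Flatten score reports to a DataFrame (one row per area)."""
    rows = []
    for r in reports:
        row: dict[str, object] = {"area_id": r.area_id}
        for d in spec.domain_ids:
            row[f"raw_{d}"] = r.raw_domain[d]
        for d in spec.domain_ids:
            row[f"transformed_{d}"] = r.transformed_domain[d]
        row["total"] = r.total
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(spec: InstrumentSpec, reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """Per-domain and total summary statistics of transformed scores."""
    cols: dict[str, np.ndarray] = {
        d.domain_id: np.array([r.transformed_domain[d.domain_id] for r in reports])
        for d in spec.domains
    }
    cols["total"] = np.array([r.total for r in reports])
    max_raw = {d.domain_id: d.raw_max for d in spec.domains}
    max_raw["total"] = float("nan")
    max_tr = {
        d.domain_id: spec.chi * d.eag_weight for d in spec.domains
    }
    max_tr["total"] = 100.0
    out = {}
    for name, x in cols.items():
        out[name] = {
            "max_possible_raw": max_raw[name],
            "max_possible_transformed": max_tr[name],
            "observed_min": float(np.min(x)),
            "observed_max": float(np.max(x)),
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        }
    return pd.DataFrame(out)
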