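"""Thurstone-style item weighting from an older-people importance survey.

Survey respondents judge each candidate environmental feature twice: is it a
good or bad feature (valence), and how much does it affect satisfaction with
the area (magnitude, five ordered categories from "not at all" to "a great
deal").  The two answers combine onto a 9-point favourability scale whose
midpoint (5) is "not at all":

    1  a great deal (unfavourably)     9  a great deal (favourably)

The raw weight of an item is the median of its 9-point distribution; the
signed weight subtracts the midpoint (range -4..+4); the scoring multiplier
is the absolute signed weight (an integer between 1 and 4).  Items without a
clear valence consensus, or with a signed weight of 0, are excluded from
scoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "MAGNITUDES",
    "WeightingResponse",
    "ThurstoneResult",
    "AmbiguousResponseError",
    "to_nine_point",
    "item_weight",
    "weight_table",
    "rank_items",
]

MAGNITUDES = ("not_at_all", "very_little", "a_little", "quite_a_lot", "a_great_deal")
_MAG_STEP = {m: i for i, m in enumerate(MAGNITUDES)}  # not_at_all -> 0 ... -> 4


class AmbiguousResponseError(ValueError):
    """A non-"not at all" magnitude with no valence cannot be placed on the scale."""


@dataclass(frozen=True)
class WeightingResponse:
    """One respondent's judgement of one candidate item."""

    respondent_id: str
    item_id: str
    feature_present: Optional[bool]
    valence: Optional[str]  # "positive" | "negative" | None
    magnitude: str

    def __post_init__(self) -> None:
        if self.magnitude not in MAGNITUDES:
            raise ValueError(f"unknown magnitude {self.magnitude!r}")
        if self.valence not in (None, "positive", "negative"):
            raise ValueError(f"unknown valence {self.valence!r}")


@dataclass(frozen=True)
class ThurstoneResult:
    """Derived weighting of one item.

    ``multiplier`` is None when the item is excluded (no consensus or zero
    signed weight).
    """

    item_id: str
    nine_point_distribution: dict[int, int]
    raw_weight: int
    signed_weight: int
    multiplier: Optional[int]
    consensus: str  # "clear" | "none"
    mean_importance: float
    n_usable: int
    exclusion_reason: Optional[str] = None


def to_nine_point(valence: Optional[str], magnitude: str) -> int:
    """Map a (valence, magnitude) judgement to the 9-point favourability scale.

    "Not at all" sits at the midpoint 5 regardless of valence.  Below the
    midpoint the ladder descends with unfavourable magnitude (a great deal
    unfavourably = 1); above it ascends with favourable magnitude (a great
    deal favourably = 9).
    """
    step = _MAG_STEP[magnitude]
    if step == 0:
        return 5
    if valence == "positive":
        return 5 + step
    if valence == "negative":
        return 5 - step
    raise AmbiguousResponseError(
        f"magnitude {magnitude!r} requires a valence; none was given"
    )


def item_weight(
    responses: Sequence[WeightingResponse],
    *,
    consensus_threshold: float = 0.7,
) -> ThurstoneResult:
    """Derive an item's Thurstone weighting from its survey responses.

    Responses that cannot be placed on the scale (missing valence with a
    non-midpoint magnitude) are dropped.  The raw weight is the median of the
    9-point distribution; with an even count whose middle pair straddles two
    scale points, the point nearer the midpoint 5 is taken (equidistant pairs
    resolve to 5), keeping weights conservative integers.

    Consensus is "clear" when at least ``consensus_threshold`` of the
    non-midpoint responses share one valence; otherwise the item is excluded.
    """
    if not 0.5 <= consensus_threshold <= 1.0:
        raise ValueError("consensus_threshold must be in [0.5, 1]")
    scores: list[int] = []
    for r in responses:
        try:
            scores.append(to_nine_point(r.valence, r.magnitude))
        except AmbiguousResponseError:
            continue
    if not scores:
        raise ValueError("no usable responses for item")

    item_id = responses[0].item_id
    dist = Counter(scores)
    distribution = {k: dist.get(k, 0) for k in range(1, 10)}

    scores_sorted = sorted(scores)
    n = len(scores_sorted)
    if n % 2 == 1:
        raw = scores_sorted[n // 2]
    else:
        lo, hi = scores_sorted[n // 2 - 1], scores_sorted[n // 2]
        if lo == hi:
            raw = lo
        elif abs(lo - 5) == abs(hi - 5):
            raw = 5
        else:
            raw = lo if abs(lo - 5) < abs(hi - 5) else hi

    signed = raw - 5

    below = sum(1 for s in scores if s < 5)
    above = sum(1 for s in scores if s > 5)
    off_mid = below + above
    if off_mid == 0:
        consensus = "clear"  # unanimous indifference; excluded via signed weight 0
    else:
        consensus = (
            "clear" if max(below, above) / off_mid >= consensus_threshold else "none"
        )

    mean_importance = sum(abs(s - 5) for s in scores) / n

    multiplier: Optional[int] = None
    reason: Optional[str] = None
    if consensus == "none":
        reason = "no_consensus"
    elif signed == 0:
        reason = "zero_weight"
    else:
        multiplier = min(max(abs(signed), 1), 4)

    return ThurstoneResult(
        item_id=item_id,
        nine_point_distribution=distribution,
        raw_weight=raw,
        signed_weight=signed,
        multiplier=multiplier,
        consensus=consensus,
        mean_importance=mean_importance,
        n_usable=n,
        exclusion_reason=reason,
    )


def weight_table(
    responses: Iterable[WeightingResponse],
    *,
    consensus_threshold: float = 0.7,
) -> dict[str, ThurstoneResult]:
    """Group responses by item and weight each; keyed by item_id."""
    by_item: dict[str, list[WeightingResponse]] = {}
    for r in responses:
        by_item.setdefault(r.item_id, []).append(r)
    return {
        item_id: item_weight(rs, consensus_threshold=consensus_threshold)
        for item_id, rs in sorted(by_item.items())
    }


def rank_items(results: dict[str, ThurstoneResult]) -> list[str]:
    """Items ranked by descending mean importance; ties break by item_id."""
    if not results:
        raise ValueError("no items to rank")
    return sorted(results, key=lambda i: (-results[i].mean_importance, i))
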