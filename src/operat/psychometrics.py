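"""Validation statistics for the audit instrument.

Internal consistency (item-domain Spearman correlations, >= 0.2 criterion),
convergent validity (Spearman correlations between domain scores, residents'
perceptions and area deprivation), utility (one-way ANOVA across deprivation
quintiles / settlement types with Tukey HSD homogeneous subsets) and
inter-rater reliability (Krippendorff's alpha, >= 0.8 criterion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .instrument import AreaAssessment, InstrumentSpec
from .scoring import ScoreReport, weighted_item_score

__all__ = [
    "ResidentSurvey",
    "ReliabilityResult",
    "UtilityResult",
    "PERCEPTION_ITEMS",
    "eligible_residents",
    "item_domain_consistency",
    "aesthetic_attachment",
    "convergent_validity",
    "variance_explained",
    "utility_anova",
    "krippendorff_alpha",
    "reliability_report",
]

#: Resident perception items, 1 = strongly agree .. 6 = strongly disagree.
PERCEPTION_ITEMS = ("enjoy_living", "desirable_place", "safe_day", "safe_night")
#: Place-attachment importance items, 1 = not important .. 5 = very important.
ATTACHMENT_ITEMS = ("scenery_importance", "space_importance", "peacefulness_importance")
ATTACHMENT_SCALE = (1, 5)


@dataclass(frozen=True)
class ResidentSurvey:
    """One resident's validation-survey return."""

    respondent_id: str
    area_id: str
    age: float
    perceptions: dict[str, int]  # PERCEPTION_ITEMS, ordinal 1-6
    attachment: dict[str, int]  # ATTACHMENT_ITEMS, ordinal 1-5


@dataclass(frozen=True)
class ReliabilityResult:
    """Krippendorff's alpha for one item across raters."""

    item_id: str
    alpha: float
    n_units: int
    metric: str  # nominal | ordinal | interval
    passed: bool  # alpha >= 0.8
    note: Optional[str] = None


@dataclass(frozen=True)
class UtilityResult:
    """One-way ANOVA of a domain score across a grouping, with Tukey subsets."""

    domain_id: str
    grouping: str
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    tukey_subsets: tuple[tuple[str, ...], ...]


def eligible_residents(
    surveys: Sequence[ResidentSurvey], valid_areas: set[str], min_age: float = 65.0
) -> list[ResidentSurvey]:
    """Apply the eligibility rule: age >= 65 and a linked assessment area."""
    return [
        s
        for s in surveys
        if s.age >= min_age and s.area_id in valid_areas and not math.isnan(s.age)
    ]


def item_domain_consistency(
    assessments: Sequence[AreaAssessment],
    spec: InstrumentSpec,
    *,
    item_rest: bool = False,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Spearman correlation of each weighted item score with its domain total.

    By default the item is included in the total (scale-domain total); set
    ``item_rest=True`` for the stricter item-rest variant.  Items pass at a
    correlation of ``threshold`` (default 0.2) or more; a constant item is
    reported as failing with reason ``constant``.
    """
    if len(assessments) < 10:
        raise ValueError("need at least 10 areas for item-domain consistency")
    weighted = pd.DataFrame(
        {
            it.item_id: [
                weighted_item_score(it, a.observations[it.item_id]) for a in assessments
            ]
            for it in spec.items
        }
    )
    rows = []
    for d in spec.domains:
        member_ids = [i.item_id for i in spec.domain_items(d.domain_id)]
        total = weighted[member_ids].sum(axis=1)
        for item_id in member_ids:
            ref = total - weighted[item_id] if item_rest else total
            x = weighted[item_id]
            if x.nunique() <= 1 or ref.nunique() <= 1:
                rows.append(
                    {
                        "item_id": item_id,
                        "domain_id": d.domain_id,
                        "spearman": float("nan"),
                        "passed": False,
                        "reason": "constant",
                    }
                )
                continue
            if len(member_ids) == 1 and not item_rest:
                rho = 1.0
            else:
                rho = float(stats.spearmanr(x, ref).statistic)
            rows.append(
                {
                    "item_id": item_id,
                    "domain_id": d.domain_id,
                    "spearman": rho,
                    "passed": bool(rho >= threshold),
                    "reason": "",
                }
            )
    return pd.DataFrame(rows)


def aesthetic_attachment(survey: ResidentSurvey) -> float:
    """Composite aesthetic attachment to place, 0-100, higher = more attached.

    The transformed sum of the scenery, space and peacefulness importance
    items: min-max mapped from the summed scale range onto 0-100.
    """
    missing = [k for k in ATTACHMENT_ITEMS if k not in survey.attachment]
    if missing:
        raise ValueError(f"respondent {survey.respondent_id!r}: missing {missing}")
    lo, hi = ATTACHMENT_SCALE
    s = sum(survey.attachment[k] for k in ATTACHMENT_ITEMS)
    return (s - 3 * lo) / (3 * hi - 3 * lo) * 100.0


def convergent_validity(
    scores: Sequence[ScoreReport],
    surveys: Sequence[ResidentSurvey],
    deprivation: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Spearman correlations of domain scores with perceptions and deprivation.

    Individual-level rows pair each respondent with their area's domain
    scores (perception items and aesthetic attachment); the area-level row
    pairs domain scores with the area deprivation index.  Returns a long
    DataFrame with columns measure, level, domain_id, r_s, p, n.
    """
    score_by_area = {r.area_id: r for r in scores}
    linked = [s for s in surveys if s.area_id in score_by_area]
    if not linked:
        raise ValueError("no respondents link to scored areas")
    domain_ids = list(scores[0].transformed_domain)

    rows = []
    for measure in list(PERCEPTION_ITEMS) + ["aesthetic_attachment"]:
        if measure == "aesthetic_attachment":
            yvals = np.array([aesthetic_attachment(s) for s in linked])
        else:
            yvals = np.array([s.perceptions[measure] for s in linked], dtype=float)
        for d in domain_ids:
            xvals = np.array(
                [score_by_area[s.area_id].transformed_domain[d] for s in linked]
            )
            res = stats.spearmanr(xvals, yvals)
            rows.append(
                {
                    "measure": measure,
                    "level": "individual",
                    "domain_id": d,
                    "r_s": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": len(linked),
                    "low_power": len(linked) < 10,
                }
            )
    if deprivation is not None:
        areas = [r.area_id for r in scores if r.area_id in deprivation]
        dep = np.array([deprivation[a] for a in areas])
        for d in domain_ids:
            xvals = np.array([score_by_area[a].transformed_domain[d] for a in areas])
            res = stats.spearmanr(xvals, dep)
            rows.append(
                {
                    "measure": "deprivation_index",
                    "level": "area",
                    "domain_id": d,
                    "r_s": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": len(areas),
                    "low_power": len(areas) < 10,
                }
            )
    return pd.DataFrame(rows)


def variance_explained(r_s: float, mode: str = "round") -> int:
    """Percent of variance shared by two ranked measures: 100 * r_s**2.

    ``mode`` controls how the percentage is reduced to an integer: ``round``
    (nearest) or ``truncate`` (toward zero).
    """
    if abs(r_s) > 1:
        raise ValueError("|r_s| must be <= 1")
    pct = 100.0 * r_s * r_s
    if mode == "round":
        return int(round(pct))
    if mode == "truncate":
        return int(pct)
    raise ValueError(f"unknown mode {mode!r}")


def _tukey_subsets(
    means: dict[str, float], not_different: set[tuple[str, str]]
) -> tuple[tuple[str, ...], ...]:
    """Greedy homogeneous subsets from sorted means (SPSS-style display).

    A subset is a maximal run of consecutively-sorted groups within which no
    pair is significantly different.
    """
    order = sorted(means, key=means.get)
    k = len(order)
    subsets: list[tuple[str, ...]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            tuple(sorted((order[a], order[b]))) in not_different
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        subsets.append(tuple(order[i : j + 1]))
    # keep only maximal runs
    out = [s for s in subsets if not any(set(s) < set(t) for t in subsets if t != s)]
    seen, uniq = set(), []
    for s in out:
        if s not in seen:
            uniq.append(s)
            seen.add(s)
    return tuple(uniq)


def utility_anova(
    scores: Sequence[ScoreReport],
    groups: Mapping[str, object],
    grouping: str,
    *,
    alpha: float = 0.05,
) -> list[UtilityResult]:
    """One-way ANOVA of each transformed domain score across groups.

    ``groups`` maps area_id to its group label (deprivation quintile or
    settlement type).  Tukey HSD pairwise tests are aggregated into
    homogeneous subsets: groups that are not significantly different at
    ``alpha`` share a subset.
    """
    area_groups = {r.area_id: groups[r.area_id] for r in scores if r.area_id in groups}
    labels = sorted(set(area_groups.values()), key=str)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: sum(1 for v in area_groups.values() if v == g) for g in labels}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")

    domain_ids = list(scores[0].transformed_domain)
    results = []
    for d in domain_ids:
        by_group = {
            g: np.array(
                [
                    r.transformed_domain[d]
                    for r in scores
                    if area_groups.get(r.area_id) == g
                ]
            )
            for g in labels
        }
        F, p = stats.f_oneway(*(by_group[g] for g in labels))
        values = np.concatenate([by_group[g] for g in labels])
        glabels = np.concatenate([[str(g)] * len(by_group[g]) for g in labels])
        tk = pairwise_tukeyhsd(values, glabels, alpha=alpha)
        not_diff: set[tuple[str, str]] = set()
        for (g1, g2), rej in zip(
            [(a, b) for i, a in enumerate(tk.groupsunique) for b in tk.groupsunique[i + 1 :]],
            tk.reject,
        ):
            if not rej:
                not_diff.add(tuple(sorted((str(g1), str(g2)))))
        means = {str(g): float(np.mean(by_group[g])) for g in labels}
        results.append(
            UtilityResult(
                domain_id=d,
                grouping=grouping,
                F=float(F),
                df_between=len(labels) - 1,
                df_within=len(values) - len(labels),
                p=float(p),
                group_means=means,
                tukey_subsets=_tukey_subsets(means, not_diff),
            )
        )
    return results


def _delta_sq(values: np.ndarray, n_c: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise squared difference matrix for the chosen reliability metric."""
    k = len(values)
    if metric == "nominal":
        return 1.0 - np.eye(k)
    if metric == "interval":
        return (values[:, None] - values[None, :]) ** 2
    if metric == "ordinal":
        D = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                between = n_c[a : b + 1].sum() - (n_c[a] + n_c[b]) / 2.0
                D[a, b] = D[b, a] = between**2
        return D
    raise ValueError(f"unknown metric {metric!r}")


def krippendorff_alpha(
    ratings: np.ndarray, metric: str = "nominal"
) -> tuple[float, Optional[str]]:
    """Krippendorff's alpha for a units x raters matrix (NaN = missing).

    Uses the coincidence-matrix formulation: every ordered pair of ratings
    within a unit contributes 1/(m_u - 1) to the coincidence of its two
    values; alpha = 1 - D_o / D_e with the nominal, ordinal or interval
    difference function.  Units with fewer than two ratings are ignored.

    Returns ``(alpha, note)``; the note flags degenerate data (all ratings
    identical -> alpha 1 by convention).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be a units x raters matrix")
    usable = [row[~np.isnan(row)] for row in X]
    usable = [row for row in usable if len(row) >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 units with 2+ ratings each")

    values = np.unique(np.concatenate(usable))
    if len(values) == 1:
        return 1.0, "degenerate: all ratings identical"
    idx = {v: i for i, v in enumerate(values)}
    k = len(values)

    O = np.zeros((k, k))
    for row in usable:
        m = len(row)
        for a in range(m):
            for b in range(m):
                if a != b:
                    O[idx[row[a]], idx[row[b]]] += 1.0 / (m - 1)
    n_c = O.sum(axis=1)
    n = n_c.sum()

    D = _delta_sq(values, n_c, metric)
    Do = float((O * D).sum()) / n
    De = float((np.outer(n_c, n_c) * D).sum()) / (n * (n - 1))
    if De == 0:
        return 1.0, "degenerate: zero expected disagreement"
    return 1.0 - Do / De, None


def _metric_for(value_kind: str) -> str:
    return {"binary": "nominal", "ordinal": "ordinal", "proportion": "interval"}[
        value_kind
    ]


def reliability_report(
    rater_a: Sequence[AreaAssessment],
    rater_b: Sequence[AreaAssessment],
    spec: InstrumentSpec,
    *,
    threshold: float = 0.8,
) -> tuple[list[ReliabilityResult], int]:
    """Per-item inter-rater alpha plus the count of perfect-agreement items.

    The difference metric follows each item's value kind (nominal for binary,
    ordinal for ordinal scales, interval for proportions).  Both raters must
    have assessed the same set of areas.
    """
    areas_a = {a.area_id for a in rater_a}
    areas_b = {b.area_id for b in rater_b}
    if areas_a != areas_b:
        raise ValueError(
            f"rater area sets differ: only-A={sorted(areas_a - areas_b)}, "
            f"only-B={sorted(areas_b - areas_a)}"
        )
    a_by = {a.area_id: a for a in rater_a}
    b_by = {b.area_id: b for b in rater_b}
    order = sorted(areas_a)

    results = []
    perfect = 0
    for it in spec.items:
        va = np.array([a_by[i].observations[it.item_id] for i in order], dtype=float)
        vb = np.array([b_by[i].observations[it.item_id] for i in order], dtype=float)
        if np.array_equal(va, vb):
            perfect += 1
        metric = _metric_for(it.value_kind)
        alpha, note = krippendorff_alpha(np.column_stack([va, vb]), metric)
        results.append(
            ReliabilityResult(
                item_id=it.item_id,
                alpha=alpha,
                n_units=len(order),
                metric=metric,
                passed=bool(alpha >= threshold),
                note=note,
            )
        )
    return results, perfect
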