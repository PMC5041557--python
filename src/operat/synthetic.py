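"""Synthetic data streams with the statistical structure the pipeline assumes.

Emulates the four field-study data streams so the whole pipeline is testable
without any download:

* area assessments: 405 postcode-like areas whose 16 items are discretised
  indicators of four correlated latent factors (the published four-factor
  loading pattern), with settlement-type mean shifts and a deprivation index
  coupled to the realised domain scores with configurable signed strength;
* an item-weighting survey (545 respondents) whose 9-point favourability
  ratings scatter around planted signed weights;
* a resident validation survey (606 returns, ~500 eligible after the age-65
  and area-linkage rules) whose perception items are noisy monotone functions
  of the area's domain scores;
* a second-rater copy of a subset of assessment sheets with controllable
  per-item disagreement.

All randomness flows from one seeded numpy Generator; identical seeds give
identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .instrument import (
    AreaAssessment,
    AreaCovariates,
    InstrumentSpec,
    load_default_instrument,
)
from .psychometrics import ATTACHMENT_ITEMS, PERCEPTION_ITEMS, ResidentSurvey
from .scoring import score_area
from .thurstone import MAGNITUDES, WeightingResponse

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticBundle",
    "simulate_areas",
    "simulate_weighting_survey",
    "simulate_residents",
    "simulate_second_rater",
    "simulate_bundle",
]

#: Default coupling of each resident perception item (and the attachment
#: latent) to the standardised domain scores; signs mirror the published
#: convergent-validity pattern.
DEFAULT_PERCEPTION_COUPLINGS: dict[str, dict[str, float]] = {
    "enjoy_living": {"territorial_functioning": 0.12, "navigation_mobility": -0.11},
    "desirable_place": {"territorial_functioning": 0.15, "navigation_mobility": -0.11},
    "safe_day": {"incivilities_nuisance": 0.11},
    "safe_night": {"incivilities_nuisance": 0.20, "navigation_mobility": -0.11},
    "aesthetic_attachment": {
        "natural_elements": -0.12,
        "incivilities_nuisance": -0.09,
        "navigation_mobility": 0.11,
        "territorial_functioning": -0.10,
    },
}

#: Settlement-type mean shifts on the latent factors (score orientation:
#: higher = less desirable).  Cities have fewer natural elements and more
#: incivilities; dispersed rural areas have the most navigation barriers.
DEFAULT_SETTLEMENT_SHIFTS: dict[str, dict[str, float]] = {
    "natural_elements": {
        "city_and_town": 0.7,
        "rural_town_fringe": -0.2,
        "village_dispersed": -0.4,
    },
    "incivilities_nuisance": {
        "city_and_town": 0.5,
        "rural_town_fringe": -0.2,
        "village_dispersed": -0.3,
    },
    "navigation_mobility": {
        "city_and_town": 0.0,
        "rural_town_fringe": -0.5,
        "village_dispersed": 0.6,
    },
    "territorial_functioning": {
        "city_and_town": 0.0,
        "rural_town_fringe": 0.2,
        "village_dispersed": -0.2,
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated field design."""

    n_areas: int = 405
    n_resident_returns: int = 606
    n_weighting_respondents: int = 545
    settlement_mix: tuple[float, float, float] = (0.40, 0.20, 0.40)
    interfactor_corr: float = 0.2
    factor_deprivation_corr: tuple[float, float, float, float] = (
        0.22,
        0.25,
        -0.17,
        0.67,
    )
    uniqueness: Optional[Mapping[str, float]] = None  # default: 1 - loading**2
    proportion_scale: float = 0.15
    settlement_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SETTLEMENT_SHIFTS
    )
    perception_couplings: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_PERCEPTION_COUPLINGS
    )
    perception_noise: float = 1.0
    age_mean: float = 74.07
    age_sd: float = 7.79
    age_min: float = 65.0
    ineligible_counts: tuple[int, int, int, int] = (48, 40, 8, 10)
    # (missing area_id, unknown area_id, under 65, missing age)
    weighting_dispersion: float = 1.0
    rater_disagreement_rate: float = 0.05
    proportion_jitter_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.settlement_mix) - 1.0) > 1e-9:
            raise ValueError("settlement_mix must sum to 1")
        if any(abs(r) >= 1 for r in self.factor_deprivation_corr):
            raise ValueError("factor_deprivation_corr entries must be in (-1, 1)")
        if not 0 <= self.rater_disagreement_rate <= 1:
            raise ValueError("rater_disagreement_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score parameter recovery downstream."""

    factor_scores: pd.DataFrame  # area x domain latent factors
    loadings: pd.DataFrame  # generating item loadings (signed)
    deprivation: pd.Series
    settlement: pd.Series
    deprivation_coefficients: dict[str, float]
    planted_weights: dict[str, int] = field(default_factory=dict)
    perception_couplings: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    """All four simulated data streams plus the generating truth."""

    spec: InstrumentSpec
    assessments: list[AreaAssessment]
    weighting_survey: list[WeightingResponse]
    resident_survey: list[ResidentSurvey]
    rater_b_assessments: list[AreaAssessment]
    ground_truth: GroundTruth


_SETTLEMENTS = ("city_and_town", "rural_town_fringe", "village_dispersed")


def _discretisation_attenuation(item) -> float:
    """Correlation attenuation from discretising a standard-normal item score.

    Categorising a normal variable at cuts c_j attenuates its correlations by
    a = sum_j phi(c_j) / sd(category index); the generator divides the target
    loading by this factor (capped) so loadings recovered from the observed,
    discretised items match the configured values.
    """
    if item.value_kind == "proportion":
        return 1.0  # clamped affine map, clipping negligible
    if item.value_kind == "binary":
        cuts = np.array([0.0])
        levels = np.arange(2)
    else:
        L = item.ordinal_levels
        cuts = sps.norm.ppf(np.arange(1, L) / L)
        levels = np.arange(L)
    probs = np.diff(np.concatenate([[0.0], sps.norm.cdf(cuts), [1.0]]))
    mean = float(np.sum(levels * probs))
    var = float(np.sum(levels**2 * probs) - mean**2)
    return float(sps.norm.pdf(cuts).sum() / np.sqrt(var))


def _efa_form_from_latent(
    item, x: np.ndarray, rng: np.random.Generator, proportion_scale: float
) -> np.ndarray:
    """Discretise a latent item score to its EFA-form value."""
    if item.value_kind == "binary":
        return (x > 0).astype(float)
    if item.value_kind == "proportion":
        return np.clip(0.5 + proportion_scale * x, 0.0, 1.0)
    L = item.ordinal_levels
    cuts = sps.norm.ppf(np.arange(1, L) / L)  # roughly uniform categories
    return np.digitize(x, cuts).astype(float) / (L - 1)


def _raw_from_efa_form(item, v: np.ndarray) -> np.ndarray:
    """Invert the recoding: EFA-form value back to the raw observation scale."""
    if item.value_kind == "proportion":
        return v  # proportions stay in original form
    if item.desirable_direction == "presence_good":
        v = 1.0 - v
    if item.value_kind == "binary":
        return np.round(v)
    return np.round(v * (item.ordinal_levels - 1))


def simulate_areas(
    config: SimulationConfig,
    spec: Optional[InstrumentSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AreaAssessment], GroundTruth]:
    """Simulate area assessment sheets with covariates and ground truth.

    Latent domain factors are drawn from a correlated multivariate normal
    (pairwise correlation ``interfactor_corr``) with settlement-type mean
    shifts; item values are signed-loading combinations of their factor plus
    unique noise, discretised to each item's observation kind.  The
    deprivation index is a linear blend of the realised standardised domain
    scores calibrated to the configured signed correlations.
    """
    spec = spec or load_default_instrument()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_areas
    domains = list(spec.domain_ids)
    k = len(domains)

    corr = np.full((k, k), config.interfactor_corr)
    np.fill_diagonal(corr, 1.0)
    if np.min(np.linalg.eigvalsh(corr)) <= 0:
        raise ValueError("interfactor correlation matrix is not positive definite")

    settlement = rng.choice(_SETTLEMENTS, size=n, p=config.settlement_mix)
    F = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    for j, d in enumerate(domains):
        shifts = config.settlement_shifts.get(d, {})
        F[:, j] += np.array([shifts.get(s, 0.0) for s in settlement])

    area_ids = [f"PC{i + 1:04d}" for i in range(n)]
    obs_by_item: dict[str, np.ndarray] = {}
    for it in spec.items:
        if it.loading == 0.0:
            raise ValueError(f"item {it.item_id!r} has no generating loading")
        # disattenuate so the loading recovered from the discretised item
        # matches the configured target on the observed scale
        lam = it.loading / _discretisation_attenuation(it)
        lam = float(np.clip(lam, -0.97, 0.97))
        u = (
            config.uniqueness[it.item_id]
            if config.uniqueness and it.item_id in config.uniqueness
            else 1.0 - lam**2
        )
        j = domains.index(it.domain_id)
        x = lam * F[:, j] + np.sqrt(max(u, 0.0)) * rng.standard_normal(n)
        v = _efa_form_from_latent(it, x, rng, config.proportion_scale)
        obs_by_item[it.item_id] = _raw_from_efa_form(it, v)

    # realised standardised domain scores, for deprivation/resident coupling
    plain = [
        AreaAssessment(
            area_id=a, observations={i: float(obs_by_item[i][r]) for i in spec.item_ids}
        )
        for r, a in enumerate(area_ids)
    ]
    Z = np.column_stack(
        [
            np.array([score_area(spec, a).transformed_domain[d] for a in plain])
            for d in domains
        ]
    )
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)

    rho = np.asarray(config.factor_deprivation_corr, dtype=float)
    sigma_z = np.corrcoef(Z, rowvar=False)
    b = np.linalg.solve(sigma_z, rho)
    explained = float(b @ sigma_z @ b)
    if explained >= 1.0:
        raise ValueError(
            f"factor_deprivation_corr targets are infeasible "
            f"(implied R^2 = {explained:.3f} >= 1)"
        )
    dep = Z @ b + np.sqrt(1.0 - explained) * rng.standard_normal(n)
    quintile = pd.qcut(pd.Series(dep), 5, labels=False).to_numpy() + 1

    assessments = []
    for r, a in enumerate(area_ids):
        assessments.append(
            AreaAssessment(
                area_id=a,
                observations={i: float(obs_by_item[i][r]) for i in spec.item_ids},
                covariates=AreaCovariates(
                    deprivation_index=float(dep[r]),
                    deprivation_quintile=int(quintile[r]),
                    settlement_type=str(settlement[r]),
                ),
            )
        )

    truth = GroundTruth(
        factor_scores=pd.DataFrame(F, index=area_ids, columns=domains),
        loadings=pd.DataFrame(
            {
                "domain_id": [i.domain_id for i in spec.items],
                "loading": [i.loading for i in spec.items],
            },
            index=list(spec.item_ids),
        ),
        deprivation=pd.Series(dep, index=area_ids, name="deprivation_index"),
        settlement=pd.Series(settlement, index=area_ids, name="settlement_type"),
        deprivation_coefficients=dict(zip(domains, b)),
    )
    return assessments, truth


def _score_to_response(
    respondent_id: str, item_id: str, score: int, rng: np.random.Generator
) -> WeightingResponse:
    """Express a 9-point favourability score as a survey response record."""
    present = bool(rng.random() < 0.5)
    if score == 5:
        return WeightingResponse(respondent_id, item_id, present, None, "not_at_all")
    valence = "positive" if score > 5 else "negative"
    return WeightingResponse(
        respondent_id, item_id, present, valence, MAGNITUDES[abs(score - 5)]
    )


def simulate_weighting_survey(
    config: SimulationConfig,
    planted_weights: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
    *,
    no_consensus_items: Sequence[str] = (),
) -> list[WeightingResponse]:
    """Simulate the item-weighting survey around planted signed weights.

    Each respondent's 9-point rating of an item is the planted weight's scale
    position (5 + weight) plus Gaussian dispersion, rounded and clipped to
    1-9.  Items listed in ``no_consensus_items`` are drawn bimodally (half
    favourable, half unfavourable) so they fail the consensus rule.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    for item, w in planted_weights.items():
        if not -4 <= int(w) <= 4:
            raise ValueError(f"planted weight for {item!r} outside -4..4")
    responses: list[WeightingResponse] = []
    n = config.n_weighting_respondents
    for item_id, w in planted_weights.items():
        if item_id in no_consensus_items:
            mag = max(abs(int(w)), 2)
            scores = np.where(np.arange(n) % 2 == 0, 5 + mag, 5 - mag)
        else:
            noise = rng.normal(0.0, config.weighting_dispersion, size=n)
            scores = np.clip(np.round(5 + int(w) + noise), 1, 9).astype(int)
        for r in range(n):
            responses.append(
                _score_to_response(f"R{r + 1:04d}", item_id, int(scores[r]), rng)
            )
    return responses


def simulate_residents(
    config: SimulationConfig,
    spec: InstrumentSpec,
    assessments: Sequence[AreaAssessment],
    rng: Optional[np.random.Generator] = None,
) -> list[ResidentSurvey]:
    """Simulate the resident validation survey, ineligible returns included.

    Perception items (1 = strongly agree .. 6 = strongly disagree) are
    discretised affine functions of the respondent's area's standardised
    domain scores plus individual noise; attachment importance items derive
    from a shared attachment latent.  Ineligible returns (missing or unknown
    area, under-65 or missing age) are appended to exercise the eligibility
    filter.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    domains = list(spec.domain_ids)
    reports = [score_area(spec, a) for a in assessments]
    Z = np.column_stack(
        [np.array([r.transformed_domain[d] for r in reports]) for d in domains]
    )
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    area_ids = [a.area_id for a in assessments]

    n_bad_area, n_unknown_area, n_young, n_noage = config.ineligible_counts
    n_eligible = config.n_resident_returns - sum(config.ineligible_counts)
    if n_eligible <= 0:
        raise ValueError("ineligible_counts exceed n_resident_returns")

    a, b = (config.age_min - config.age_mean) / config.age_sd, np.inf
    surveys: list[ResidentSurvey] = []

    def perception_vector(zrow: np.ndarray) -> tuple[dict[str, int], dict[str, int]]:
        perceptions = {}
        for item in PERCEPTION_ITEMS:
            coup = config.perception_couplings.get(item, {})
            latent = sum(
                c * zrow[domains.index(d)] for d, c in coup.items()
            ) + config.perception_noise * rng.standard_normal()
            cuts = sps.norm.ppf(np.arange(1, 6) / 6) * np.sqrt(
                config.perception_noise**2 + sum(c * c for c in coup.values())
            )
            perceptions[item] = int(np.digitize(latent, cuts)) + 1
        coup = config.perception_couplings.get("aesthetic_attachment", {})
        latent = sum(c * zrow[domains.index(d)] for d, c in coup.items())
        attachment = {}
        for item in ATTACHMENT_ITEMS:
            xi = latent + config.perception_noise * rng.standard_normal()
            cuts = sps.norm.ppf(np.arange(1, 5) / 5) * np.sqrt(
                config.perception_noise**2 + sum(c * c for c in coup.values())
            )
            # attachment latent is oriented higher = more attached; item scale
            # 1..5 with 5 = very important
            attachment[item] = int(np.digitize(xi, cuts)) + 1
        return perceptions, attachment

    rid = 0
    for _ in range(n_eligible):
        rid += 1
        idx = int(rng.integers(len(area_ids)))
        age = float(sps.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                                      random_state=rng))
        perceptions, attachment = perception_vector(Z[idx])
        surveys.append(
            ResidentSurvey(f"V{rid:04d}", area_ids[idx], age, perceptions, attachment)
        )

    def random_perceptions() -> tuple[dict[str, int], dict[str, int]]:
        return (
            {p: int(rng.integers(1, 7)) for p in PERCEPTION_ITEMS},
            {p: int(rng.integers(1, 6)) for p in ATTACHMENT_ITEMS},
        )

    for _ in range(n_bad_area):
        rid += 1
        p, at = random_perceptions()
        surveys.append(ResidentSurvey(f"V{rid:04d}", "", 72.0, p, at))
    for _ in range(n_unknown_area):
        rid += 1
        p, at = random_perceptions()
        surveys.append(ResidentSurvey(f"V{rid:04d}", "PC9999X", 75.0, p, at))
    for _ in range(n_young):
        rid += 1
        idx = int(rng.integers(len(area_ids)))
        p, at = random_perceptions()
        surveys.append(
            ResidentSurvey(f"V{rid:04d}", area_ids[idx], float(rng.integers(40, 65)), p, at)
        )
    for _ in range(n_noage):
        rid += 1
        idx = int(rng.integers(len(area_ids)))
        p, at = random_perceptions()
        surveys.append(ResidentSurvey(f"V{rid:04d}", area_ids[idx], float("nan"), p, at))
    return surveys


def simulate_second_rater(
    assessments: Sequence[AreaAssessment],
    config: SimulationConfig,
    spec: Optional[InstrumentSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[AreaAssessment]:
    """Copy rater A's sheets with per-item disagreement at the configured rate.

    Binary items flip; ordinal items jitter by one level (clamped);
    proportion items take clamped Gaussian jitter.
    """
    spec = spec or load_default_instrument()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rate = config.rater_disagreement_rate
    out = []
    for a in assessments:
        obs = {}
        for it in spec.items:
            v = a.observations[it.item_id]
            if rng.random() < rate:
                if it.value_kind == "binary":
                    v = 1.0 - v
                elif it.value_kind == "ordinal":
                    step = 1.0 if rng.random() < 0.5 else -1.0
                    v = float(np.clip(v + step, 0, it.ordinal_levels - 1))
                else:
                    v = float(
                        np.clip(v + rng.normal(0.0, config.proportion_jitter_sd), 0, 1)
                    )
            obs[it.item_id] = v
        out.append(AreaAssessment(area_id=a.area_id, observations=obs,
                                  covariates=a.covariates))
    return out


def simulate_bundle(
    config: Optional[SimulationConfig] = None,
    spec: Optional[InstrumentSpec] = None,
    *,
    n_reliability_areas: int = 10,
) -> SyntheticBundle:
    """Generate all four data streams from one seeded generator."""
    config = config or SimulationConfig()
    spec = spec or load_default_instrument()
    rng = np.random.default_rng(config.seed)

    assessments, truth = simulate_areas(config, spec, rng)
    planted = {
        it.item_id: it.multiplier
        * (1 if it.desirable_direction == "presence_good" else -1)
        for it in spec.items
    }
    weighting = simulate_weighting_survey(config, planted, rng)
    residents = simulate_residents(config, spec, assessments, rng)
    subset = assessments[:n_reliability_areas]
    rater_b = simulate_second_rater(subset, config, spec, rng)

    truth.planted_weights = planted
    truth.perception_couplings = {
        k: dict(v) for k, v in config.perception_couplings.items()
    }
    return SyntheticBundle(
        spec=spec,
        assessments=assessments,
        weighting_survey=weighting,
        resident_survey=residents,
        rater_b_assessments=rater_b,
        ground_truth=truth,
    )
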