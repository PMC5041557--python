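"""Data model of the OPERAT instrument.

OPERAT (Older People's External Residential Assessment Tool) is a 16-item
observational audit of external residential environments.  Items are grouped
into four domains -- Natural Elements; Incivilities and Nuisance; Navigation
and Mobility; Territorial Functioning -- each carrying an integer importance
weight assigned by an Expert Advisory Group (EAG).  Every item has an integer
Thurstone multiplier between 1 and 4 derived from an older-people importance
survey.

This module houses the typed instrument definition, the configuration loader
(YAML or JSON), and validation of the shipped default instrument against the
published structural constraints (per-domain raw maxima 9/10/13/14, item
counts 3/3/5/5, EAG weights 1/1/2/1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "ItemSpec",
    "DomainSpec",
    "InstrumentSpec",
    "AreaCovariates",
    "AreaAssessment",
    "ConfigurationError",
    "ValidationCheck",
    "load_instrument",
    "load_default_instrument",
    "serialize_instrument",
    "validate_default_instrument",
]

VALUE_KINDS = ("binary", "ordinal", "proportion")
DIRECTIONS = ("presence_good", "presence_bad")
SETTLEMENT_TYPES = ("city_and_town", "rural_town_fringe", "village_dispersed")

#: Published per-domain constraints of the default 16-item instrument.
DEFAULT_DOMAIN_ORDER = (
    "natural_elements",
    "incivilities_nuisance",
    "navigation_mobility",
    "territorial_functioning",
)
DEFAULT_RAW_MAXIMA = {
    "natural_elements": 9,
    "incivilities_nuisance": 10,
    "navigation_mobility": 13,
    "territorial_functioning": 14,
}
DEFAULT_ITEM_COUNTS = {
    "natural_elements": 3,
    "incivilities_nuisance": 3,
    "navigation_mobility": 5,
    "territorial_functioning": 5,
}
DEFAULT_EAG_WEIGHTS = {
    "natural_elements": 1,
    "incivilities_nuisance": 1,
    "navigation_mobility": 2,
    "territorial_functioning": 1,
}


class ConfigurationError(ValueError):
    """Raised when an instrument configuration violates its schema."""


@dataclass(frozen=True)
class ItemSpec:
    """A single observed item of the audit instrument.

    ``loading`` is the signed reference factor loading of the item in the
    published four-factor solution; it is carried for documentation and for
    the synthetic-data generator, and plays no role in scoring.
    """

    item_id: str
    label: str
    domain_id: str
    value_kind: str
    desirable_direction: str
    multiplier: int
    loading: float = 0.0
    ordinal_levels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ConfigurationError(
                f"item {self.item_id!r}: value_kind must be one of {VALUE_KINDS}, "
                f"got {self.value_kind!r}"
            )
        if self.desirable_direction not in DIRECTIONS:
            raise ConfigurationError(
                f"item {self.item_id!r}: desirable_direction must be one of "
                f"{DIRECTIONS}, got {self.desirable_direction!r}"
            )
        if not isinstance(self.multiplier, int) or not 1 <= self.multiplier <= 4:
            raise ConfigurationError(
                f"item {self.item_id!r}: multiplier must be an integer in 1-4, "
                f"got {self.multiplier!r}"
            )
        if self.value_kind == "ordinal":
            if self.ordinal_levels is None or self.ordinal_levels < 2:
                raise ConfigurationError(
                    f"item {self.item_id!r}: ordinal items need ordinal_levels >= 2"
                )
        elif self.ordinal_levels is not None:
            raise ConfigurationError(
                f"item {self.item_id!r}: ordinal_levels only applies to ordinal items"
            )

    def value_in_range(self, value: float) -> bool:
        """Whether ``value`` lies on this item's declared observation scale."""
        if self.value_kind == "binary":
            return value in (0, 1)
        if self.value_kind == "proportion":
            return 0.0 <= value <= 1.0
        return float(value).is_integer() and 0 <= value <= self.ordinal_levels - 1


@dataclass(frozen=True)
class DomainSpec:
    """One of the four OPERAT domains with its EAG importance weight."""

    domain_id: str
    name: str
    eag_weight: int
    raw_min: float = 0.0
    raw_max: float = 0.0  # filled in by load_instrument from member multipliers

    def __post_init__(self) -> None:
        if not isinstance(self.eag_weight, int) or self.eag_weight < 1:
            raise ConfigurationError(
                f"domain {self.domain_id!r}: eag_weight must be a positive integer"
            )


@dataclass(frozen=True)
class InstrumentSpec:
    """The full instrument: items, domains and the normalising constant chi.

    chi = 100 / sum of EAG weights, so that the composite score spans 0-100.
    """

    instrument_name: str
    items: tuple[ItemSpec, ...]
    domains: tuple[DomainSpec, ...]
    chi: float

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i.item_id for i in self.items)

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d.domain_id for d in self.domains)

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def domain(self, domain_id: str) -> DomainSpec:
        for d in self.domains:
            if d.domain_id == domain_id:
                return d
        raise KeyError(domain_id)

    def domain_items(self, domain_id: str) -> tuple[ItemSpec, ...]:
        return tuple(i for i in self.items if i.domain_id == domain_id)


@dataclass(frozen=True)
class AreaCovariates:
    """Structural covariates of an assessed postcode area.

    ``deprivation_index`` is a Townsend-like area deprivation score (higher =
    more deprived); ``deprivation_quintile`` is its within-dataset quintile
    (1 = least deprived, 5 = most deprived).
    """

    deprivation_index: float
    deprivation_quintile: int
    settlement_type: str

    def __post_init__(self) -> None:
        if self.settlement_type not in SETTLEMENT_TYPES:
            raise ConfigurationError(
                f"settlement_type must be one of {SETTLEMENT_TYPES}, "
                f"got {self.settlement_type!r}"
            )
        if not 1 <= self.deprivation_quintile <= 5:
            raise ConfigurationError("deprivation_quintile must be in 1-5")


@dataclass
class AreaAssessment:
    """One area's raw item observations from a walk-through audit."""

    area_id: str
    observations: dict[str, float]
    covariates: Optional[AreaCovariates] = None

    def validate_against(self, spec: InstrumentSpec) -> None:
        """Check completeness and per-item range; raise on violation."""
        missing = [i for i in spec.item_ids if i not in self.observations]
        if missing:
            raise ValueError(
                f"area {self.area_id!r}: missing observations for items {missing}"
            )
        for it in spec.items:
            v = self.observations[it.item_id]
            if not it.value_in_range(v):
                raise ValueError(
                    f"area {self.area_id!r}: value {v!r} out of range for item "
                    f"{it.item_id!r} ({it.value_kind})"
                )


def _parse_config(config_text: str) -> dict:
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config does not parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError("config must be a mapping at top level")
    return doc


def load_instrument(config_text: str) -> InstrumentSpec:
    """Parse and validate an instrument configuration (YAML or JSON text).

    The document needs top-level keys ``instrument_name``, ``domains`` and
    ``items``.  Domain raw maxima are derived from member-item multipliers;
    chi is derived from the EAG weights.

    Raises
    ------
    ConfigurationError
        On any schema violation, naming the offending field.
    """
    doc = _parse_config(config_text)
    for key in ("instrument_name", "domains", "items"):
        if key not in doc:
            raise ConfigurationError(f"config missing required key {key!r}")

    domains_raw = []
    for d in doc["domains"]:
        for key in ("domain_id", "name", "eag_weight"):
            if key not in d:
                raise ConfigurationError(f"domain entry missing {key!r}: {d}")
        domains_raw.append(d)
    domain_ids = [d["domain_id"] for d in domains_raw]
    if len(set(domain_ids)) != len(domain_ids):
        raise ConfigurationError("duplicate domain_id in config")

    items = []
    for entry in doc["items"]:
        for key in ("item_id", "domain_id", "value_kind", "desirable_direction",
                    "multiplier"):
            if key not in entry:
                raise ConfigurationError(
                    f"item entry {entry.get('item_id', '?')!r} missing {key!r}"
                )
        if entry["domain_id"] not in domain_ids:
            raise ConfigurationError(
                f"item {entry['item_id']!r} references unknown domain "
                f"{entry['domain_id']!r}"
            )
        items.append(
            ItemSpec(
                item_id=entry["item_id"],
                label=entry.get("label", entry["item_id"]),
                domain_id=entry["domain_id"],
                value_kind=entry["value_kind"],
                desirable_direction=entry["desirable_direction"],
                multiplier=entry["multiplier"],
                loading=float(entry.get("loading", 0.0)),
                ordinal_levels=entry.get("ordinal_levels"),
            )
        )
    item_ids = [i.item_id for i in items]
    if len(set(item_ids)) != len(item_ids):
        raise ConfigurationError("duplicate item_id in config")

    domains = []
    for d in domains_raw:
        members = [i for i in items if i.domain_id == d["domain_id"]]
        if not members:
            raise ConfigurationError(f"domain {d['domain_id']!r} has no items")
        raw_max = float(sum(i.multiplier for i in members))
        if "raw_max" in d and float(d["raw_max"]) != raw_max:
            raise ConfigurationError(
                f"domain {d['domain_id']!r}: declared raw_max {d['raw_max']} "
                f"does not equal sum of member multipliers {raw_max}"
            )
        domains.append(
            DomainSpec(
                domain_id=d["domain_id"],
                name=d["name"],
                eag_weight=int(d["eag_weight"]),
                raw_min=float(d.get("raw_min", 0.0)),
                raw_max=raw_max,
            )
        )

    total_weight = sum(d.eag_weight for d in domains)
    chi = 100.0 / total_weight
    return InstrumentSpec(
        instrument_name=str(doc["instrument_name"]),
        items=tuple(items),
        domains=tuple(domains),
        chi=chi,
    )


def load_default_instrument() -> InstrumentSpec:
    """Load the shipped default 16-item OPERAT definition."""
    text = (
        resources.files("operat.data")
        .joinpath("default_instrument.yaml")
        .read_text(encoding="utf-8")
    )
    return load_instrument(text)


def serialize_instrument(spec: InstrumentSpec) -> str:
    """Serialize an InstrumentSpec back to YAML; round-trips load_instrument."""
    doc = {
        "instrument_name": spec.instrument_name,
        "domains": [
            {
                "domain_id": d.domain_id,
                "name": d.name,
                "eag_weight": d.eag_weight,
                "raw_min": d.raw_min,
                "raw_max": d.raw_max,
            }
            for d in spec.domains
        ],
        "items": [
            {
                "item_id": i.item_id,
                "label": i.label,
                "domain_id": i.domain_id,
                "value_kind": i.value_kind,
                "desirable_direction": i.desirable_direction,
                "multiplier": i.multiplier,
                "loading": i.loading,
                **({"ordinal_levels": i.ordinal_levels} if i.ordinal_levels else {}),
            }
            for i in spec.items
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


@dataclass(frozen=True)
class ValidationCheck:
    """One structural check of a loaded instrument against published values."""

    name: str
    passed: bool
    detail: str


def validate_default_instrument(spec: InstrumentSpec) -> list[ValidationCheck]:
    """Check a spec against the published default-instrument constraints.

    Verifies per-domain raw maxima (9, 10, 13, 14), item counts (3, 3, 5, 5)
    and EAG weights (1, 1, 2, 1) in the canonical domain order, plus chi = 20.
    Returns a report; failures are listed, never raised.
    """
    checks: list[ValidationCheck] = []
    for domain_id in DEFAULT_DOMAIN_ORDER:
        try:
            d = spec.domain(domain_id)
        except KeyError:
            checks.append(
                ValidationCheck("domain_present", False, f"{domain_id} absent")
            )
            continue
        expected_max = DEFAULT_RAW_MAXIMA[domain_id]
        checks.append(
            ValidationCheck(
                "raw_max",
                d.raw_max == expected_max,
                f"{domain_id}: raw_max {d.raw_max} (expected {expected_max})",
            )
        )
        n_items = len(spec.domain_items(domain_id))
        expected_n = DEFAULT_ITEM_COUNTS[domain_id]
        checks.append(
            ValidationCheck(
                "item_count",
                n_items == expected_n,
                f"{domain_id}: {n_items} items (expected {expected_n})",
            )
        )
        expected_w = DEFAULT_EAG_WEIGHTS[domain_id]
        checks.append(
            ValidationCheck(
                "eag_weight",
                d.eag_weight == expected_w,
                f"{domain_id}: eag_weight {d.eag_weight} (expected {expected_w})",
            )
        )
    checks.append(
        ValidationCheck("chi", spec.chi == 20.0, f"chi {spec.chi} (expected 20)")
    )
    return checks


def assessment_from_row(spec: InstrumentSpec, row: Mapping[str, object]) -> AreaAssessment:
    """Build an AreaAssessment from one mapping/CSV row keyed by item_id."""
    obs = {i: float(row[i]) for i in spec.item_ids if i in row}
    cov = None
    if all(k in row and row[k] not in (None, "") for k in
           ("deprivation_index", "deprivation_quintile", "settlement_type")):
        cov = AreaCovariates(
            deprivation_index=float(row["deprivation_index"]),
            deprivation_quintile=int(row["deprivation_quintile"]),
            settlement_type=str(row["settlement_type"]),
        )
    a = AreaAssessment(area_id=str(row["area_id"]), observations=obs, covariates=cov)
    a.validate_against(spec)
    return a
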