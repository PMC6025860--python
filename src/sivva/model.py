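"""Domain types and the criteria registry for SIVVA-style assessments.

SIVVA (Standardized Index of Vulnerability and Value) is a modular expert
scoring instrument.  Each *criterion* receives a score in ``{0} ∪ [1, 6]``:
0 means not enough information, 1–2 positive impact, 3 no impact, and 4–6
increasingly negative impact.  Criteria are grouped into themed *modules*
(e.g. Vulnerability, Adaptive Capacity) and each module aggregates to a
normalized score on [0, 1].

Two variants of the instrument exist:

* ``natcom`` — for natural communities: Ecosystem Status (ES, three
  alternative criterion sets of three criteria each), Vulnerability (VU,
  nine criteria) and Conservation Value (CV, three criteria).
* ``species`` — Vulnerability (V, twelve), Adaptive Capacity (AC, six),
  Conservation Value (CV, five) and Information Availability (IA, five).

This module defines the data model and validation; scoring lives in
:mod:`sivva.scoring`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SUBREGIONS",
    "SCENARIOS",
    "VARIANTS",
    "SivvaError",
    "ConfigurationError",
    "ValidationError",
    "CriterionDef",
    "ModuleDef",
    "Score",
    "AssessmentSheet",
    "Registry",
    "Dataset",
    "load_criteria_config",
    "default_registry",
]

#: The six Gulf Coast subregion codes, west to east: Laguna Madre, Western
#: Gulf Coastal Plain, Mississippi Alluvial Plain, Southern Coastal Plain,
#: Central Florida Coastal Plain, Southern Florida Coastal Plain.
SUBREGIONS: tuple[str, ...] = ("LM", "WGCP", "MAP", "SCP", "CFCP", "SFCP")

#: Climate scenarios: SC1 low emissions / low sea-level rise, SC2 low
#: emissions / high SLR, SC3 high emissions / high SLR.
SCENARIOS: tuple[str, ...] = ("SC1", "SC2", "SC3")

VARIANTS: tuple[str, ...] = ("species", "natcom")

#: Required criterion counts per module, per variant.
EXPECTED_MODULE_SIZES: dict[str, dict[str, int]] = {
    "natcom": {"ES": 9, "VU": 9, "CV": 3},
    "species": {"V": 12, "AC": 6, "CV": 5, "IA": 5},
}

#: Module id whose criteria are organized into alternative sets.
ES_MODULE_ID = "ES"
ES_SET_COUNT = 3


class SivvaError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(SivvaError):
    """A criteria registry or run configuration violates an invariant."""


class ValidationError(SivvaError):
    """Input data (sheets, scores, labels) violates an invariant."""


@dataclass(frozen=True)
class CriterionDef:
    """A single scored item of the instrument."""

    id: str
    module_id: str
    description: str = ""
    weight: float = 1.0
    set_id: str | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigurationError(
                f"criterion {self.id!r}: weight must be >= 0, got {self.weight}"
            )


@dataclass(frozen=True)
class ModuleDef:
    """A themed block of criteria aggregated into one normalized score."""

    id: str
    variant: str
    name: str
    criteria: tuple[CriterionDef, ...]

    @property
    def set_ids(self) -> tuple[str, ...]:
        """Distinct criterion-set ids in registry order (ES only)."""
        seen: list[str] = []
        for c in self.criteria:
            if c.set_id is not None and c.set_id not in seen:
                seen.append(c.set_id)
        return tuple(seen)

    def criteria_in_set(self, set_id: str) -> tuple[CriterionDef, ...]:
        return tuple(c for c in self.criteria if c.set_id == set_id)


@dataclass(frozen=True)
class Score:
    """A criterion score: 0 = insufficient information, else in [1, 6].

    ``uncertain`` marks the assessor's scoring-uncertainty checkbox; it can
    only be set on an actual score (value > 0), since a 0 already expresses
    a different kind of uncertainty (missing knowledge).
    """

    value: float
    uncertain: bool = False

    def __post_init__(self) -> None:
        v = float(self.value)
        if not (v == 0.0 or 1.0 <= v <= 6.0):
            raise ValidationError(
                f"score must be 0 or in [1, 6], got {self.value}"
            )
        if self.uncertain and v == 0.0:
            raise ValidationError("a score of 0 cannot be flagged uncertain")

    @property
    def scored(self) -> bool:
        return float(self.value) > 0.0


@dataclass
class AssessmentSheet:
    """One assessor's criterion scores for one entity × subregion × scenario."""

    entity: str
    subregion: str
    scenario: str
    assessor: str
    scores: dict[str, Score] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subregion not in SUBREGIONS:
            raise ValidationError(
                f"unknown subregion {self.subregion!r}; expected one of {SUBREGIONS}"
            )
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.entity, self.subregion, self.scenario, self.assessor)


@dataclass(frozen=True)
class Registry:
    """The criteria registry for one instrument variant."""

    variant: str
    modules: tuple[ModuleDef, ...]

    def __post_init__(self) -> None:
        validate_registry(self.variant, self.modules)

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.modules)

    def module(self, module_id: str) -> ModuleDef:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def criteria(self) -> dict[str, CriterionDef]:
        return {c.id: c for m in self.modules for c in m.criteria}

    def validate_sheet(self, sheet: AssessmentSheet) -> None:
        known = self.criteria
        for cid in sheet.scores:
            if cid not in known:
                raise ValidationError(
                    f"sheet {sheet.key}: unknown criterion id {cid!r} "
                    f"for variant {self.variant!r}"
                )


def validate_registry(variant: str, modules: Iterable[ModuleDef]) -> None:
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    modules = tuple(modules)
    expected = EXPECTED_MODULE_SIZES[variant]
    got_ids = [m.id for m in modules]
    if got_ids != list(expected):
        raise ConfigurationError(
            f"variant {variant!r} requires modules {list(expected)} "
            f"in order, got {got_ids}"
        )
    for m in modules:
        n = len(m.criteria)
        if n != expected[m.id]:
            raise ConfigurationError(
                f"module {m.id!r} must have {expected[m.id]} criteria, got {n}"
            )
        if not any(c.weight > 0 for c in m.criteria):
            raise ConfigurationError(
                f"module {m.id!r}: at least one criterion needs weight > 0"
            )
        is_es = variant == "natcom" and m.id == ES_MODULE_ID
        for c in m.criteria:
            if (c.set_id is not None) != is_es:
                where = "required for" if is_es else "only allowed in"
                raise ConfigurationError(
                    f"criterion {c.id!r}: set_id is {where} the NATCOM "
                    f"Ecosystem Status module"
                )
        if is_es:
            sets = m.set_ids
            if len(sets) != ES_SET_COUNT or any(
                len(m.criteria_in_set(s)) != 3 for s in sets
            ):
                raise ConfigurationError(
                    "Ecosystem Status must have exactly 3 criterion sets "
                    "of 3 criteria each"
                )
        ids = [c.id for c in m.criteria]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"module {m.id!r}: duplicate criterion ids")


@dataclass
class Dataset:
    """A collection of assessment sheets for one variant, plus the entity
    catalog (names and expected assessment counts)."""

    variant: str
    sheets: list[AssessmentSheet]
    catalog: "pd.DataFrame | None" = None  # noqa: F821 - optional pandas table

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str, str]] = set()
        for s in self.sheets:
            if s.key in seen:
                raise ValidationError(f"duplicate sheet for {s.key}")
            seen.add(s.key)

    def coverage_report(self) -> list[tuple[str, str, str, int]]:
        """(entity, subregion, scenario, n_assessors) for cells with fewer
        than two independent assessments — the design target; reported,
        not fatal."""
        counts: dict[tuple[str, str, str], int] = {}
        for s in self.sheets:
            cell = (s.entity, s.subregion, s.scenario)
            counts[cell] = counts.get(cell, 0) + 1
        return sorted(
            (e, r, c, n) for (e, r, c), n in counts.items() if n < 2
        )

    def __len__(self) -> int:
        return len(self.sheets)


# ---------------------------------------------------------------------------
# Registry loading

def _parse_registry(doc: Mapping) -> Registry:
    try:
        variant = doc["variant"]
        raw_modules = doc["modules"]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"registry config missing key: {exc}") from exc
    modules = []
    for rm in raw_modules:
        mid = rm["id"]
        criteria = tuple(
            CriterionDef(
                id=rc["id"],
                module_id=mid,
                description=rc.get("description", ""),
                weight=float(rc.get("weight", 1.0)),
                set_id=rc.get("set_id"),
            )
            for rc in rm["criteria"]
        )
        modules.append(
            ModuleDef(id=mid, variant=variant, name=rm.get("name", mid),
                      criteria=criteria)
        )
    return Registry(variant=variant, modules=tuple(modules))


def load_criteria_config(path: str | Path) -> Registry:
    """Load a criteria registry from a YAML or JSON config file.

    The config declares ``variant`` and a list of ``modules``, each with
    ordered ``criteria`` entries ``{id, description, weight, set_id?}``.
    Raises :class:`ConfigurationError` if module/criterion counts, weights,
    or ES set structure violate the instrument's invariants.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _parse_registry(doc)


_DEFAULT_FILES = {
    "natcom": "natcom_criteria.yaml",
    "species": "species_criteria.yaml",
}


def default_registry(variant: str) -> Registry:
    """The packaged default registry (all weights 1.0) for a variant."""
    if variant not in _DEFAULT_FILES:
        raise ConfigurationError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    ref = resources.files("sivva.data").joinpath(_DEFAULT_FILES[variant])
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _parse_registry(doc)
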