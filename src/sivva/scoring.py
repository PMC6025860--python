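"""Module scoring for a single assessment sheet.

A module's score is the weighted mean of its criterion scores normalized by
the maximum attainable points: ``Σ w_i·s_i / Σ w_i·6`` over the criteria the
assessor actually scored (s_i > 0).  Criteria scored 0 ("not enough
information") are excluded from both numerator and denominator; what they
cost is tracked separately as *completeness*, the fraction of the module's
weighted point capacity that was scored.  The raw s/6 normalization is used,
so with every criterion scored the attainable range is [1/6, 1].

The NATCOM Ecosystem Status module is special: its nine criteria form three
alternative sets (area decline, function decline, rarity) and only the
worst-scoring — highest — set counts.  Ties break by registry order; a set
with no scored criteria is not a candidate.

An overall prioritization score combines module values by a value scheme
(module weights summing to 1); equal weights give the plain mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    AssessmentSheet,
    CriterionDef,
    Dataset,
    ModuleDef,
    Registry,
    SivvaError,
    ValidationError,
)

__all__ = [
    "ModuleScore",
    "WeightScheme",
    "score_module",
    "resolve_ecosystem_status",
    "overall_score",
    "score_sheet",
    "score_dataset",
]

#: Maximum criterion score; module values are normalized against it.
MAX_SCORE = 6.0


@dataclass(frozen=True)
class ModuleScore:
    """A normalized module score with completeness accounting.

    ``value`` is None for an *unscored module* (no criterion with positive
    weight received a score > 0) — a distinguished result, not an error.
    """

    module_id: str
    value: float | None
    completeness: float
    n_scored: int
    chosen_set: str | None = None

    @property
    def scored(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class WeightScheme:
    """A value scheme: module weights summing to 1."""

    name: str
    weights: tuple[tuple[str, float], ...]

    def __init__(self, name: str, weights: Mapping[str, float]):
        items = tuple((str(k), float(v)) for k, v in weights.items())
        if any(w < 0 for _, w in items):
            raise ValidationError(f"scheme {name!r}: negative module weight")
        total = sum(w for _, w in items)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"scheme {name!r}: weights must sum to 1, got {total!r}"
            )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "weights", items)

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)

    def __getitem__(self, module_id: str) -> float:
        return self.as_dict()[module_id]


def _score_criteria(
    sheet: AssessmentSheet, criteria: Iterable[CriterionDef]
) -> tuple[float | None, float, int]:
    """Weighted-sum scoring over a criterion list.

    Returns (value, completeness, n_scored) where completeness is relative
    to the full weighted capacity of *these* criteria.
    """
    num = 0.0
    den = 0.0
    capacity = 0.0
    n_scored = 0
    for c in criteria:
        capacity += c.weight * MAX_SCORE
        s = sheet.scores.get(c.id)
        if s is None or not s.scored:
            continue
        num += c.weight * float(s.value)
        den += c.weight * MAX_SCORE
        if c.weight > 0:
            n_scored += 1
    if den == 0.0:
        return None, 0.0, 0
    completeness = den / capacity if capacity > 0 else 0.0
    return num / den, completeness, n_scored


def resolve_ecosystem_status(
    sheet: AssessmentSheet, es_module: ModuleDef
) -> tuple[str | None, ModuleScore]:
    """Apply the highest-set rule to the Ecosystem Status module.

    Each criterion set is scored independently; the set with the maximal
    value (the worst status) becomes the module score and the others are
    ignored.  Ties break toward the first set in registry order.  Sets with
    no scored criteria are not candidates; if no set is scorable the result
    is the unscored-module sentinel.
    """
    sets = es_module.set_ids
    if len(sets) != 3:
        raise SivvaError(
            f"module {es_module.id!r} does not have 3 criterion sets"
        )
    best: tuple[str, float, float, int] | None = None
    for set_id in sets:
        value, completeness, n_scored = _score_criteria(
            sheet, es_module.criteria_in_set(set_id)
        )
        if value is None:
            continue
        if best is None or value > best[1]:
            best = (set_id, value, completeness, n_scored)
    if best is None:
        return None, ModuleScore(es_module.id, None, 0.0, 0, None)
    set_id, value, completeness, n_scored = best
    return set_id, ModuleScore(es_module.id, value, completeness, n_scored, set_id)


def score_module(sheet: AssessmentSheet, module: ModuleDef) -> ModuleScore:
    """Score one module of one sheet.

    For the NATCOM Ecosystem Status module the highest-set rule applies and
    ``chosen_set`` records the winning set; for every other module the score
    runs over all criteria.
    """
    if module.set_ids:
        return resolve_ecosystem_status(sheet, module)[1]
    value, completeness, n_scored = _score_criteria(sheet, module.criteria)
    return ModuleScore(module.id, value, completeness, n_scored)


def overall_score(
    module_scores: Mapping[str, "ModuleScore | float"],
    scheme: WeightScheme,
) -> float:
    """Combine module values under a value scheme: ``Σ_m w_m · value_m``.

    Modules with zero scheme weight may be absent or unscored; a positive
    weight on an unscored module is an error naming the module.
    """
    total = 0.0
    for module_id, w in scheme.weights:
        if w == 0.0:
            continue
        ms = module_scores.get(module_id)
        value = ms.value if isinstance(ms, ModuleScore) else ms
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValidationError(
                f"scheme {scheme.name!r} puts weight {w} on module "
                f"{module_id!r}, which has no score"
            )
        total += w * float(value)
    return total


def score_sheet(
    sheet: AssessmentSheet, registry: Registry
) -> dict[str, ModuleScore]:
    """Score every module of a sheet; returns module_id → ModuleScore."""
    registry.validate_sheet(sheet)
    return {m.id: score_module(sheet, m) for m in registry.modules}


def score_dataset(dataset: Dataset, registry: Registry) -> pd.DataFrame:
    """Score every sheet of a dataset into a long-format table.

    Columns: entity, subregion, scenario, assessor, module, value,
    completeness, n_scored, chosen_set.  Unscored modules appear with a
    missing value so completeness gaps stay visible.
    """
    rows = []
    for sheet in dataset.sheets:
        for module_id, ms in score_sheet(sheet, registry).items():
            rows.append(
                {
                    "entity": sheet.entity,
                    "subregion": sheet.subregion,
                    "scenario": sheet.scenario,
                    "assessor": sheet.assessor,
                    "module": module_id,
                    "value": ms.value,
                    "completeness": ms.completeness,
                    "n_scored": ms.n_scored,
                    "chosen_set": ms.chosen_set,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "entity", "subregion", "scenario", "assessor", "module",
            "value", "completeness", "n_scored", "chosen_set",
        ],
    )
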