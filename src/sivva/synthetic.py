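"""Synthetic expert-elicitation datasets with known structure.

Raw expert sheets from real assessments are rarely shareable, so every
pipeline stage here is exercised on generated panels whose ground truth is
known.  The generative model mirrors the assessment design: each entity is
scored by a panel of assessors in every subregion × scenario cell it
occupies, and each criterion score is

    s = clamp_[1,6]( μ_entity,module + α_subregion + β_scenario + γ_assessor + ε )

with a fixed per-assessor intercept γ_a ~ N(0, σ_a), i.i.d. noise
ε ~ N(0, σ_ε), additive region and scenario effects on the score scale, and
clamping (not resampling) at the [1, 6] bounds — a known bias source when μ
sits near an edge.  A configurable fraction of criteria is set to 0 to
emulate "not enough information", and uncertainty flags are Bernoulli.
Entity × subregion absences are representable and produce no sheets.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import (
    SCENARIOS,
    SUBREGIONS,
    AssessmentSheet,
    Dataset,
    Registry,
    Score,
    ValidationError,
    default_registry,
)

__all__ = ["SyntheticConfig", "generate", "make_gcva_like"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the elicitation generator.

    ``baseline`` is the mean score μ: a scalar applied everywhere, or a
    mapping ``(entity, module_id) → μ`` (missing keys fall back to
    ``baseline_default``).  Effects are in score units (a +1 region effect
    shifts unclamped module values by exactly 1/6).
    """

    variant: str = "natcom"
    entities: tuple[str, ...] = ("community-1", "community-2")
    subregions: tuple[str, ...] = SUBREGIONS
    scenarios: tuple[str, ...] = SCENARIOS
    assessors_per_cell: int = 2
    baseline: "float | Mapping[tuple[str, str], float]" = 3.5
    baseline_default: float = 3.5
    region_effects: Mapping[str, float] = field(default_factory=dict)
    scenario_effects: Mapping[str, float] = field(default_factory=dict)
    assessor_bias_sd: float = 0.3
    noise_sd: float = 0.5
    flag_prob: float = 0.10
    zero_prob: float = 0.05
    absences: tuple[tuple[str, str], ...] = ()
    round_to_half: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("assessor_bias_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("flag_prob", "zero_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.assessors_per_cell < 1:
            raise ValidationError("assessors_per_cell must be >= 1")
        for eff in (self.region_effects, self.scenario_effects):
            if any(not np.isfinite(v) for v in eff.values()):
                raise ValidationError("effects must be finite")

    def mu(self, entity: str, module_id: str) -> float:
        if isinstance(self.baseline, (int, float)):
            return float(self.baseline)
        return float(self.baseline.get((entity, module_id), self.baseline_default))


def _clamp(x: float) -> float:
    return min(6.0, max(1.0, x))


def _iter_scores(config: SyntheticConfig, registry: Registry):
    """Core draw sequence: yields one record per sheet with raw (unclamped)
    and clamped criterion values, so the generator and its diagnostic view
    share one random stream."""
    rng = np.random.default_rng(config.seed)
    absences = set(config.absences)
    for entity in config.entities:
        panel = {
            f"{entity}|a{j + 1}": rng.normal(0.0, config.assessor_bias_sd)
            for j in range(config.assessors_per_cell)
        }
        for subregion in config.subregions:
            if (entity, subregion) in absences:
                continue
            alpha = float(config.region_effects.get(subregion, 0.0))
            for scenario in config.scenarios:
                beta = float(config.scenario_effects.get(scenario, 0.0))
                for assessor, gamma in panel.items():
                    records = []
                    for module in registry.modules:
                        mu = config.mu(entity, module.id)
                        for crit in module.criteria:
                            if rng.random() < config.zero_prob:
                                records.append((crit.id, 0.0, 0.0, False))
                                continue
                            eps = rng.normal(0.0, config.noise_sd)
                            raw = mu + alpha + beta + gamma + eps
                            if config.round_to_half:
                                raw = round(raw * 2.0) / 2.0
                            flagged = bool(rng.random() < config.flag_prob)
                            records.append(
                                (crit.id, raw, _clamp(raw), flagged)
                            )
                    yield entity, subregion, scenario, assessor, records


def generate(config: SyntheticConfig, registry: Registry | None = None) -> Dataset:
    """Generate a full assessment dataset from a synthetic config.

    Each entity gets a fixed panel of ``assessors_per_cell`` assessors who
    score every subregion × scenario cell the entity occupies (the "set"
    design: one assessor covers all scenarios).  Returns a validated
    :class:`Dataset`; byte-identical output for identical configs.
    """
    registry = registry or default_registry(config.variant)
    sheets: list[AssessmentSheet] = []
    for entity, subregion, scenario, assessor, records in _iter_scores(
        config, registry
    ):
        scores = {
            cid: Score(clamped, uncertain=flagged)
            for cid, _raw, clamped, flagged in records
        }
        sheets.append(
            AssessmentSheet(
                entity=entity,
                subregion=subregion,
                scenario=scenario,
                assessor=assessor,
                scores=scores,
            )
        )
    return Dataset(variant=config.variant, sheets=sheets)


def raw_scores(
    config: SyntheticConfig, registry: Registry | None = None
) -> "pd.DataFrame":
    """Diagnostic view of the generator: the same draws as :func:`generate`
    but with the *unclamped* criterion values, as a long DataFrame.

    Useful for checking the additive structure (cell means converge to
    μ + α_r + β_s) without the bias the [1, 6] clamp introduces at extreme
    baselines.  Zero scores (insufficient information) appear as 0 in both
    columns.
    """
    import pandas as pd

    registry = registry or default_registry(config.variant)
    rows = []
    for entity, subregion, scenario, assessor, records in _iter_scores(
        config, registry
    ):
        for cid, raw, clamped, flagged in records:
            rows.append(
                {
                    "entity": entity, "subregion": subregion,
                    "scenario": scenario, "assessor": assessor,
                    "criterion_id": cid, "raw": raw, "score": clamped,
                    "uncertain": flagged,
                }
            )
    return pd.DataFrame(rows)


#: Entity × subregion absences of the study design (blank table rows).
GCVA_ABSENCES = {
    "natcom": (("barrier islands", "SFCP"),),
    "species": (
        ("Kemp's ridley sea turtle", "MAP"),
        ("Kemp's ridley sea turtle", "SFCP"),
        ("Kemp's ridley sea turtle", "CFCP"),
    ),
}

_GCVA_ENTITIES = {
    "natcom": (
        "mangrove", "tidal emergent marsh", "oyster reef", "barrier islands",
    ),
    "species": (
        "roseate spoonbill", "blue crab", "clapper rail", "mottled duck",
        "spotted seatrout", "eastern oyster", "American oystercatcher",
        "red drum", "black skimmer", "Kemp's ridley sea turtle",
        "Wilson's plover",
    ),
}


def make_gcva_like(seed: int, variant: str = "natcom") -> Dataset:
    """A preset panel sized like the Gulf Coast assessment.

    4 natural communities or 11 species across 6 subregions × 3 scenarios,
    with 2–4 assessors per entity panel and the study's entity × subregion
    absences.  Baselines, region and scenario effects are drawn once per
    dataset from the seed (region spread exceeding scenario spread, the
    structure the variance analysis expects to find).
    """
    if variant not in _GCVA_ENTITIES:
        raise ValidationError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9157]))
    entities = _GCVA_ENTITIES[variant]
    registry = default_registry(variant)
    baseline = {
        (e, m.id): float(rng.uniform(2.5, 4.5))
        for e in entities
        for m in registry.modules
    }
    region_effects = {r: float(rng.normal(0.0, 0.5)) for r in SUBREGIONS}
    scenario_effects = {s: float(rng.normal(0.0, 0.2)) for s in SCENARIOS}
    config = SyntheticConfig(
        variant=variant,
        entities=entities,
        assessors_per_cell=int(rng.integers(2, 5)),
        baseline=baseline,
        region_effects=region_effects,
        scenario_effects=scenario_effects,
        assessor_bias_sd=0.3,
        noise_sd=0.5,
        flag_prob=0.10,
        zero_prob=0.05,
        absences=GCVA_ABSENCES[variant],
        seed=seed,
    )
    return generate(config, registry)
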