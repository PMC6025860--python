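"""Aggregation of sheet-level scores into marginal tables and rankings.

Marginal tables average per-sheet module values by entity × climate
scenario or entity × subregion (over assessors and over the crossed
factor), the shape in which assessment results are conventionally printed.
Entity summaries then average a marginal table's rows per entity, and
rankings combine module summaries under alternative *value schemes* —
module-weight vectors encoding different conservation value systems.

Rank 1 is the highest overall score, i.e. the highest conservation
priority.  Ties (at 1e-9 resolution) use competition ranking: tied entities
share the smallest applicable rank and the next rank skips the tied count
(1, 2, 2, 4).  The spread of an entity's rank across schemes ("rank range")
measures how sensitive its priority is to the value system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import SCENARIOS, SUBREGIONS, SivvaError, ValidationError
from .scoring import WeightScheme, overall_score

__all__ = [
    "MarginalTable",
    "PriorityTable",
    "builtin_schemes",
    "marginal_means",
    "entity_summary",
    "rank_entities",
    "priority_table",
    "rank_range",
]

#: Tie resolution for rankings: overall scores closer than this are tied.
RANK_RESOLUTION = 1e-9

_BUILTIN: dict[str, list[tuple[str, tuple[float, ...]]]] = {
    # (ES, VU, CV)
    "natcom": [
        ("33/33/33", (1 / 3, 1 / 3, 1 / 3)),
        ("50/25/25", (0.50, 0.25, 0.25)),
        ("25/50/25", (0.25, 0.50, 0.25)),
        ("0/100/0", (0.00, 1.00, 0.00)),
        ("50/50/0", (0.50, 0.50, 0.00)),
    ],
    # (V, AC, CV, IA)
    "species": [
        ("25/25/25/25", (0.25, 0.25, 0.25, 0.25)),
        ("45/25/20/10", (0.45, 0.25, 0.20, 0.10)),
        ("20/20/50/10", (0.20, 0.20, 0.50, 0.10)),
        ("15/15/35/35", (0.15, 0.15, 0.35, 0.35)),
        ("100/0/0/0", (1.00, 0.00, 0.00, 0.00)),
    ],
}

_MODULE_ORDER = {"natcom": ("ES", "VU", "CV"), "species": ("V", "AC", "CV", "IA")}


def builtin_schemes(variant: str) -> list[WeightScheme]:
    """The built-in value schemes for a variant (first is equal weighting)."""
    if variant not in _BUILTIN:
        raise ValidationError(f"unknown variant {variant!r}")
    modules = _MODULE_ORDER[variant]
    return [
        WeightScheme(name, dict(zip(modules, w)))
        for name, w in _BUILTIN[variant]
    ]


@dataclass
class MarginalTable:
    """Module scores averaged by entity × level.

    ``frame`` is indexed by (entity, level) with one column per module;
    missing cells mean the entity is absent from that level, never zero.
    """

    variant: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValidationError("marginal values must lie in [0, 1]")

    @property
    def modules(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def cell(self, entity: str, level: str) -> pd.Series:
        return self.frame.loc[(entity, level)]


def marginal_means(scores: pd.DataFrame, variant: str, by: str) -> MarginalTable:
    """Average per-sheet module values into an entity × level table.

    ``scores`` is the long table from :func:`sivva.scoring.score_dataset`.
    ``by`` selects the level family: ``"scenario"`` averages over assessors
    and subregions within each scenario; ``"subregion"`` averages over
    assessors and scenarios.  Unscored modules are skipped; combinations
    with no sheets stay missing.
    """
    if by not in ("scenario", "subregion"):
        raise ValidationError(f"by must be 'scenario' or 'subregion', got {by!r}")
    modules = _MODULE_ORDER[variant]
    wide = (
        scores.pivot_table(
            index=["entity", by], columns="module", values="value",
            aggfunc="mean",
        )
        .reindex(columns=list(modules))
    )
    wide.index.names = ["entity", "level"]
    return MarginalTable(variant=variant, frame=wide)


def entity_summary(
    marginals: MarginalTable, over: str = "scenario"
) -> pd.DataFrame:
    """Per-entity module means over a marginal table's row family.

    ``over`` restricts the rows averaged: ``"scenario"`` uses the SC1–SC3
    rows, ``"subregion"`` the six subregion rows.  Rows that are entirely
    missing (entity absent from a level) are skipped, not treated as zero.
    Returns a frame indexed by entity with one column per module.
    """
    if over == "scenario":
        levels: tuple[str, ...] = SCENARIOS
    elif over == "subregion":
        levels = SUBREGIONS
    else:
        raise ValidationError(
            f"over must be 'scenario' or 'subregion', got {over!r}"
        )
    frame = marginals.frame
    sub = frame[frame.index.get_level_values("level").isin(levels)]
    if sub.empty:
        raise SivvaError(f"no {over} rows present in the marginal table")
    return sub.groupby(level="entity", sort=False).mean()


def rank_entities(summaries: pd.DataFrame, scheme: WeightScheme) -> pd.DataFrame:
    """Rank entities under one value scheme.

    Returns a frame indexed by entity with columns ``overall`` (the
    scheme-weighted score), ``rank`` (competition ranking, 1 = highest
    priority) and ``margin`` (distance to the nearest other entity's
    overall score — small margins flag near-ties).
    """
    if len(summaries) < 2:
        raise ValidationError("ranking needs at least 2 entities")
    overall = pd.Series(
        {
            entity: overall_score(row.to_dict(), scheme)
            for entity, row in summaries.iterrows()
        },
        name="overall",
    )
    # quantize so floating noise below the resolution cannot split a tie
    quantized = np.round(overall.to_numpy() / RANK_RESOLUTION) * RANK_RESOLUTION
    ranks = rankdata(-quantized, method="min").astype(int)
    margins = np.array(
        [
            np.min(np.abs(np.delete(overall.to_numpy(), i) - v))
            for i, v in enumerate(overall.to_numpy())
        ]
    )
    return pd.DataFrame(
        {"overall": overall, "rank": ranks, "margin": margins},
        index=overall.index,
    )


@dataclass
class PriorityTable:
    """Entity rankings across several value schemes."""

    variant: str
    schemes: list[WeightScheme]
    ranks: pd.DataFrame = field(repr=False)     # entity × scheme, int
    overall: pd.DataFrame = field(repr=False)   # entity × scheme, float
    margins: pd.DataFrame = field(repr=False)   # entity × scheme, float

    @property
    def rank_range(self) -> pd.Series:
        """Max minus min rank per entity across schemes."""
        return (self.ranks.max(axis=1) - self.ranks.min(axis=1)).rename(
            "rank_range"
        )

    def near_ties(self, threshold: float = 0.01) -> pd.DataFrame:
        """Boolean mask of ranks whose score margin is below ``threshold``."""
        return self.margins < threshold


def priority_table(
    summaries: pd.DataFrame,
    schemes: list[WeightScheme],
    variant: str,
) -> PriorityTable:
    """Rank entities under every scheme and collect ranks, scores, margins."""
    if not schemes:
        raise ValidationError("at least one value scheme is required")
    ranks = {}
    overall = {}
    margins = {}
    for scheme in schemes:
        r = rank_entities(summaries, scheme)
        ranks[scheme.name] = r["rank"]
        overall[scheme.name] = r["overall"]
        margins[scheme.name] = r["margin"]
    return PriorityTable(
        variant=variant,
        schemes=list(schemes),
        ranks=pd.DataFrame(ranks),
        overall=pd.DataFrame(overall),
        margins=pd.DataFrame(margins),
    )


def rank_range(priority: PriorityTable) -> pd.Series:
    """Per-entity spread of ranks across schemes (max − min)."""
    return priority.rank_range
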