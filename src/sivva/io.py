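"""Readers and writers for assessment sheets and the packaged fixtures.

Assessment sheets travel as long-format CSV with one row per criterion
score: ``entity, entity_type, subregion, scenario, assessor, criterion_id,
score, uncertain``.  The packaged fixtures mirror the published summary
tables cell-for-cell: the entity catalog with assessment counts, and the
two marginal-score tables (natural communities and species) whose blank
cells are preserved as missing values.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AssessmentSheet,
    Dataset,
    Registry,
    Score,
    ValidationError,
)
from .prioritize import MarginalTable

__all__ = ["read_sheets", "write_sheets", "load_fixture", "SHEET_COLUMNS"]

SHEET_COLUMNS = (
    "entity",
    "entity_type",
    "subregion",
    "scenario",
    "assessor",
    "criterion_id",
    "score",
    "uncertain",
)

_FIXTURE_FILES = {
    "table1": "table1_entities.csv",
    "table2": "table2_natcom_marginals.csv",
    "table3": "table3_species_marginals.csv",
}
_FIXTURE_VARIANT = {"table2": "natcom", "table3": "species"}


def read_sheets(path: str | Path, registry: Registry) -> Dataset:
    """Read long-format assessment sheets from CSV into a Dataset.

    Every row is validated: scores must lie in ``{0} ∪ [1, 6]``, a 0 score
    cannot carry the uncertainty flag, criterion ids must belong to the
    registry, and duplicated (entity, subregion, scenario, assessor,
    criterion) rows are rejected.  Errors name the offending CSV row.
    """
    df = pd.read_csv(
        path, dtype={"uncertain": "Int64"}, float_precision="round_trip"
    )
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sheet file missing columns: {sorted(missing)}")

    known = registry.criteria
    key_cols = ["entity", "subregion", "scenario", "assessor", "criterion_id"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]  # +2: header + 0-base
        raise ValidationError(f"duplicate score rows at CSV lines {rows}")

    sheets: dict[tuple[str, str, str, str], AssessmentSheet] = {}
    for i, row in df.iterrows():
        line = int(i) + 2
        cid = str(row["criterion_id"])
        if cid not in known:
            raise ValidationError(
                f"CSV line {line}: unknown criterion id {cid!r} for "
                f"variant {registry.variant!r}"
            )
        try:
            score = Score(
                value=float(row["score"]),
                uncertain=bool(int(row["uncertain"])),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"CSV line {line}: {exc}") from exc
        key = (
            str(row["entity"]),
            str(row["subregion"]),
            str(row["scenario"]),
            str(row["assessor"]),
        )
        if key not in sheets:
            try:
                sheets[key] = AssessmentSheet(*key)
            except ValidationError as exc:
                raise ValidationError(f"CSV line {line}: {exc}") from exc
        sheets[key].scores[cid] = score
    return Dataset(variant=registry.variant, sheets=list(sheets.values()))


def write_sheets(
    dataset: Dataset, path: str | Path, entity_types: dict[str, str] | None = None
) -> None:
    """Write a Dataset back to long-format CSV (round-trips read_sheets)."""
    rows = []
    for sheet in dataset.sheets:
        etype = (entity_types or {}).get(sheet.entity, dataset.variant)
        for cid, score in sheet.scores.items():
            rows.append(
                {
                    "entity": sheet.entity,
                    "entity_type": etype,
                    "subregion": sheet.subregion,
                    "scenario": sheet.scenario,
                    "assessor": sheet.assessor,
                    "criterion_id": cid,
                    "score": score.value,
                    "uncertain": int(score.uncertain),
                }
            )
    pd.DataFrame(rows, columns=list(SHEET_COLUMNS)).to_csv(path, index=False)


def load_fixture(name: str) -> "pd.DataFrame | MarginalTable":
    """Load a packaged fixture.

    ``table1`` returns the entity catalog (names, host community, number of
    independent assessments) as a DataFrame.  ``table2`` (natural
    communities: ES/VU/CV) and ``table3`` (species: V/AC/CV/IA) return the
    published marginal-score tables as :class:`MarginalTable`, with blank
    cells preserved as missing.
    """
    if name not in _FIXTURE_FILES:
        raise ValidationError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    ref = resources.files("sivva.data").joinpath(_FIXTURE_FILES[name])
    text = ref.read_text(encoding="utf-8")
    df = pd.read_csv(StringIO(text))
    if name == "table1":
        return df
    frame = df.set_index(["entity", "level"]).astype(float)
    frame.columns.name = "module"
    # fully blank rows mean the entity was not assessed at that level
    assert frame.to_numpy().size > 0
    vals = frame.to_numpy()
    if not np.all(np.isnan(vals) | ((vals >= 0) & (vals <= 1))):
        raise ValidationError(f"fixture {name}: values outside [0, 1]")
    return MarginalTable(variant=_FIXTURE_VARIANT[name], frame=frame)
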