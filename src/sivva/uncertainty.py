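"""Propagation of scoring uncertainty by Monte-Carlo perturbation.

An assessor who is unsure of a score can flag it; flagged scores are
perturbed by δ drawn uniformly from {−1, 0, +1}, independently per
criterion, and the sheet is rescored.  Repeating this (1000 simulations by
default) yields the spread of each module score and of the overall
prioritization score attributable to scoring uncertainty.  Because module
values are weight-normalized, a flag on a heavily weighted criterion moves
the overall score more than a flag on a trivial one.

Perturbed scores are clamped to [1, 6] so the score domain is preserved
(a flagged 6 can only reach 5 or stay at 6).  Scores of 0 — insufficient
information — cannot carry a flag and are never perturbed.

For small numbers of flagged criteria *k*, :func:`enumerate_exact` walks
all 3^k equally likely outcomes and provides the exact distribution; it is
the reference the Monte-Carlo path is tested against.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np

from .model import AssessmentSheet, Registry, Score, ValidationError
from .scoring import WeightScheme, overall_score, score_sheet

__all__ = [
    "UncertaintySummary",
    "perturb_sheet",
    "mc_summary",
    "enumerate_exact",
    "ExactDistribution",
    "sheet_rng",
]

DELTAS = (-1.0, 0.0, 1.0)
MAX_EXACT_FLAGS = 12  # 3^12 = 531441 outcomes


@dataclass(frozen=True)
class UncertaintySummary:
    """Spread of one target score (a module or the overall score)."""

    target: str
    n_sims: int
    mean: float
    sd: float
    min: float
    max: float


def sheet_rng(seed: int, sheet: AssessmentSheet) -> np.random.Generator:
    """Deterministic per-sheet RNG substream.

    The stream is derived from (seed, sheet key) so results are reproducible
    per sheet regardless of processing order.
    """
    key = "|".join(sheet.key).encode("utf-8")
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(key)]))


def perturb_sheet(
    sheet: AssessmentSheet, rng: np.random.Generator
) -> AssessmentSheet:
    """One perturbation draw: each flagged score s becomes clamp(s + δ)
    with δ ~ Uniform{−1, 0, +1}; unflagged and zero scores are untouched."""
    new_scores: dict[str, Score] = {}
    for cid, score in sheet.scores.items():
        if score.uncertain:
            delta = DELTAS[rng.integers(0, 3)]
            v = min(6.0, max(1.0, float(score.value) + delta))
            new_scores[cid] = Score(value=v, uncertain=True)
        else:
            new_scores[cid] = score
    return AssessmentSheet(
        entity=sheet.entity,
        subregion=sheet.subregion,
        scenario=sheet.scenario,
        assessor=sheet.assessor,
        scores=new_scores,
    )


def _score_targets(
    sheet: AssessmentSheet, registry: Registry, scheme: WeightScheme
) -> dict[str, float]:
    module_scores = score_sheet(sheet, registry)
    out = {
        mid: ms.value for mid, ms in module_scores.items() if ms.value is not None
    }
    out["overall"] = overall_score(module_scores, scheme)
    return out


def mc_summary(
    sheet: AssessmentSheet,
    registry: Registry,
    scheme: WeightScheme,
    n_sims: int = 1000,
    seed: int = 0,
) -> dict[str, UncertaintySummary]:
    """Monte-Carlo uncertainty summary per module and for the overall score.

    Runs ``n_sims`` independent perturbations of the sheet's flagged scores
    and summarizes each scored module's value and the scheme-weighted
    overall score.  With no flagged criteria every draw is identical and
    sd is exactly 0.  Reproducible given ``seed`` (a per-sheet substream is
    derived from the seed and the sheet's identity).
    """
    if n_sims < 1:
        raise ValidationError(f"n_sims must be >= 1, got {n_sims}")
    rng = sheet_rng(seed, sheet)
    draws: dict[str, list[float]] = {}
    for _ in range(n_sims):
        for target, value in _score_targets(
            perturb_sheet(sheet, rng), registry, scheme
        ).items():
            draws.setdefault(target, []).append(value)
    out = {}
    for target, values in draws.items():
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[target] = UncertaintySummary(
            target=target,
            n_sims=n_sims,
            mean=float(arr.mean()),
            sd=sd,
            min=float(arr.min()),
            max=float(arr.max()),
        )
    return out


@dataclass(frozen=True)
class ExactDistribution:
    """All 3^k equally likely perturbation outcomes for a sheet."""

    flagged: tuple[str, ...]
    outcomes: dict[str, np.ndarray]  # target -> array of 3^k scores

    def summary(self, target: str = "overall") -> UncertaintySummary:
        arr = self.outcomes[target]
        return UncertaintySummary(
            target=target,
            n_sims=arr.size,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=0)),  # exact distribution sd
            min=float(arr.min()),
            max=float(arr.max()),
        )


def enumerate_exact(
    sheet: AssessmentSheet, registry: Registry, scheme: WeightScheme
) -> ExactDistribution:
    """Exact perturbation distribution by brute-force enumeration.

    Walks every combination of δ ∈ {−1, 0, +1} over the k flagged criteria
    (3^k outcomes, each equally likely) and records the resulting module and
    overall scores.  Refuses k > 12; use :func:`mc_summary` instead there.
    """
    flagged = tuple(cid for cid, s in sheet.scores.items() if s.uncertain)
    k = len(flagged)
    if k > MAX_EXACT_FLAGS:
        raise ValidationError(
            f"{k} flagged criteria gives 3^{k} outcomes; exact enumeration "
            f"is limited to k <= {MAX_EXACT_FLAGS} — use mc_summary"
        )
    outcomes: dict[str, list[float]] = {}
    for deltas in itertools.product(DELTAS, repeat=k):
        new_scores = dict(sheet.scores)
        for cid, delta in zip(flagged, deltas):
            v = min(6.0, max(1.0, float(sheet.scores[cid].value) + delta))
            new_scores[cid] = Score(value=v, uncertain=True)
        variant = AssessmentSheet(
            entity=sheet.entity,
            subregion=sheet.subregion,
            scenario=sheet.scenario,
            assessor=sheet.assessor,
            scores=new_scores,
        )
        for target, value in _score_targets(variant, registry, scheme).items():
            outcomes.setdefault(target, []).append(value)
    return ExactDistribution(
        flagged=flagged,
        outcomes={t: np.asarray(v) for t, v in outcomes.items()},
    )
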