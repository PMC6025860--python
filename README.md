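# sivva

Multi-criteria climate-vulnerability scoring and conservation prioritization
for expert-elicited assessments of species and natural communities, in the
style of the Standardized Index of Vulnerability and Value (SIVVA).

## Who this is for

Conservation scientists and planners who collect expert scoring sheets —
panels of assessors rating an entity (a species or a natural community)
against a fixed set of criteria, separately for each geographic subregion and
each future climate scenario — and need a tested, reproducible path from raw
sheets to normalized scores, uncertainty intervals, priority rankings, and a
variance partition of *where* the scores vary (geography vs. climate
scenario).

## The instrument

Each criterion is scored on a 0–6 scale: 0 = not enough information,
1–2 = positive impact, 3 = no impact, 4–6 = increasingly negative impact
(fractional scores such as 3.5 are allowed). Criteria are grouped into
modules; a module's score is the normalized weighted sum

```
value = Σᵢ wᵢ·sᵢ / Σᵢ wᵢ·6        over criteria with sᵢ > 0
```

so it lies on [0, 1]. Criteria scored 0 are excluded from the value and
accounted separately as **completeness** (the fraction of the module's
weighted point capacity actually scored). Two variants are built in:

* **natcom** — natural communities: Ecosystem Status (ES; three alternative
  criterion sets, of which only the *worst-scoring* set counts), Vulnerability
  (VU, 9 criteria), Conservation Value (CV, 3);
* **species** — Vulnerability (V, 12), Adaptive Capacity (AC, 6),
  Conservation Value (CV, 5), Information Availability (IA, 5).

An overall prioritization score is a weighted mean of module values under a
**value scheme** (module weights summing to 1); the built-in schemes range
from equal weighting to vulnerability-only. Scoring uncertainty is
propagated by Monte Carlo: every score an assessor flagged as uncertain is
perturbed by −1/0/+1 (clamped to [1, 6]) and the sheet rescored, 1000 times
by default. Entities are ranked per scheme (rank 1 = highest priority,
competition ranking for ties), and a two-factor ANOVA partitions score
variance into subregion vs. scenario components (η² shares, sequential sums
of squares reported in both factor orders).

## Worked example

```python
from sivva import (default_registry, Score, AssessmentSheet, score_sheet,
                   overall_score, builtin_schemes, mc_summary)

registry = default_registry("natcom")
scores = {cid: Score(4.0) for cid in registry.criteria}
scores["vu_slr_loss"] = Score(5.5, uncertain=True)   # unsure about this one
scores["cv_endemism"] = Score(0.0)                    # not enough information
sheet = AssessmentSheet("tidal emergent marsh", "MAP", "SC2",
                        "assessor-07", scores)

module_scores = score_sheet(sheet, registry)
equal = builtin_schemes("natcom")[0]
print({m: round(ms.value, 4) for m, ms in module_scores.items()})
print("overall:", round(overall_score(module_scores, equal), 4))
s = mc_summary(sheet, registry, equal, n_sims=1000, seed=42)["overall"]
print(f"MC mean {s.mean:.4f} sd {s.sd:.4f} range [{s.min:.4f}, {s.max:.4f}]")
```

prints

```
{'ES': 0.6667, 'VU': 0.6944, 'CV': 0.6667}
overall: 0.6759
MC mean 0.6748 sd 0.0038 range [0.6698, 0.6790]
```

ES is 0.6667 because all three of its criterion sets score 4/6 and the
highest set counts; VU is 0.6944 = (8·4 + 5.5)/(9·6); CV excludes the
zero-scored endemism criterion (completeness 2/3) and averages the remaining
two. The overall score is the equal-weight mean, and the Monte-Carlo spread
comes entirely from the one flagged criterion: ±1 on one of nine VU criteria
moves the overall score by at most 1/(9·6·3) ≈ 0.006.

Ranking the packaged community summary table under equal weights:

```python
from sivva import load_fixture, entity_summary, rank_entities
summary = entity_summary(load_fixture("table2"), over="scenario")
print(rank_entities(summary, equal).round(4))
```

```
                      overall  rank  margin
barrier islands        0.6100     3  0.0011
tidal emergent marsh   0.6944     1  0.0833
mangrove               0.5700     4  0.0400
oyster reef            0.6111     2  0.0011
```

Tidal emergent marsh is the clear top priority; barrier islands and oyster
reef are a near-tie (margin ≈ 0.001, i.e. inside the rounding of the
published two-decimal table), which the `margin` column makes explicit.

## Command line

```bash
sivva simulate --seed 1 --variant natcom --out sheets.csv   # synthetic panel
sivva run sheets.csv --out-dir out --seed 1                 # full pipeline
sivva prioritize --fixture table2                           # rank packaged tables
sivva reproduce-gcva                                        # compare to published ranks
```

`run` writes per-sheet scores, uncertainty summaries, marginal tables,
priority tables with margins, ANOVA tables, assessor QC, and a manifest with
input/output checksums so a run is re-derivable bit-for-bit.

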