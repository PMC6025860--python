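# Methods

This note documents the scoring model, the aggregation and statistical
procedures, the synthetic-data generator the test suite relies on, and the
design choices made where more than one reading was defensible.

## Scoring model

**Criterion scale.** Scores live in {0} ∪ [1, 6]. Zero is a distinguished
"not enough information" marker, not a low score; 1–2 indicate positive
impacts, 3 no impact, 4–6 increasingly negative impacts. Fractional scores
are permitted at any resolution (no forced 0.5 grid), since assessors in
practice record values like 3.5.

**Module value.** For module criteria with weights wᵢ ≥ 0 and scores sᵢ,

value = Σ wᵢ·sᵢ / Σ wᵢ·6, summed over criteria with sᵢ > 0.

The raw s/6 normalization is used deliberately — *not* (s−1)/5 — so the
attainable range with every criterion scored is [1/6, 1]. This follows the
instrument's literal definition (weight × score from 1 to 6, normalized by
the maximum total points). Users who want a 0-anchored scale can rescale
downstream; the package does not do it silently. A module in which no
positively weighted criterion received a score > 0 yields a distinguished
*unscored* result (`value is None`, completeness 0) rather than an
exception, because downstream stages need to distinguish "bad input" from
"honest ignorance".

**Completeness.** Zero scores are excluded from the value but never
discarded: completeness = Σ_{scored} wᵢ·6 / Σ_{all} wᵢ·6 is reported next to
every value. Folding completeness into the value would conflate "we don't
know" with "no impact"; keeping them side by side is the
insufficient-knowledge accounting the instrument prescribes.

**Ecosystem Status highest-set rule.** The natural-community ES module
contains three alternative three-criterion sets (area decline, function
decline, rarity). Each set is scored independently by the same weighted-sum
rule; the set with the **highest** value — the worst status — becomes the
module score and the others are ignored. Two edge cases the instrument's
description leaves open are resolved as follows: a fully unscored set is not
a candidate (otherwise a panel that skipped the rarity set entirely could
never produce an ES score), and exact ties break toward the first set in
registry order, which is deterministic and documented. The ES module's
completeness is that of the chosen set.

**Overall score.** Σ_m w_m · value_m under a value scheme whose weights sum
to 1 (checked to 1e-9). Equal weights reproduce the plain mean. Positive
weight on an unscored module is an error naming the module — silently
renormalizing the remaining weights would change the value system mid-run.

## Uncertainty propagation

Assessors can flag a score as uncertain. Flagged scores are perturbed by δ
drawn **uniformly** from {−1, 0, +1}, independently per criterion, and the
sheet rescored; 1000 simulations by default. The three outcomes are listed
by the instrument without probabilities; the uniform reading is the
maximum-entropy choice and is isolated in one constant (`DELTAS`) should a
different kernel be wanted. Perturbed scores are clamped to [1, 6] — the
alternative (allowing transient 0.5 or 6.5) would leak out of the score
domain and make a flagged 6 *worse* than an unflagged 6 on average in a
different way; clamping keeps the domain and concentrates a boundary score's
spread on the feasible side. Zero scores cannot carry flags and are never
perturbed.

For k flagged criteria the exact outcome distribution has 3^k equally
likely points; `enumerate_exact` materializes it up to k = 12 and is the
oracle the Monte-Carlo path is tested against (mean within 3 standard
errors; MC range contained in the exact support). The MC summary reports
sample sd (ddof 1); the enumeration reports the exact distribution sd
(ddof 0). Reproducibility: every sheet gets its own substream derived from
(seed, sheet identity) via `SeedSequence`, so results do not depend on
processing order.

## Aggregation and ranking

Per-sheet module values are averaged into **marginal tables** by entity ×
scenario (over assessors and subregions) or entity × subregion (over
assessors and scenarios). Absent entity × subregion combinations stay
missing — an entity that does not occur in a subregion is never scored zero
there.

**Entity summaries for ranking** are taken over the *scenario* rows of a
marginal table by default: each scenario row already averages subregions and
assessors, and no scenario cell is blank for any entity, so the path is
deterministic and complete. The subregion-row path is exposed
(`over="subregion"`) for sensitivity checks; with it, fully missing rows are
skipped, not zero-filled.

**Ranking.** Overall scores under a scheme are ranked descending (rank 1 =
highest priority). Ties at 1e-9 resolution use competition ranking (1, 2,
2, 4) — the convention visible in published ranking tables of this kind.
Every rank is accompanied by a **margin**: the distance to the nearest other
entity's overall score. Margins below 0.01 are labelled near-ties by the
reporting tools, because the packaged reference tables are printed to two
decimals and differences inside the rounding cannot support a rank claim.
`reproduce_gcva_tables()` compares recomputed ranks to the published ones
under this rule: the robust ranks (top community, top and bottom species)
reproduce exactly; a minority of adjacent pairs differ within
rounding-level margins, which is expected when re-deriving ranks from
rounded marginals rather than from the raw sheets.

**Rank range** (max − min rank across schemes) summarizes how sensitive an
entity's priority is to the value system.

**Built-in value schemes.** Communities (ES/VU/CV): 33/33/33, 50/25/25,
25/50/25, 0/100/0, 50/50/0. Species (V/AC/CV/IA): 25/25/25/25, 45/25/20/10,
20/20/50/10, 15/15/35/35, 100/0/0/0. One published table caption lists the
species module order with "Adaptive Capacity" appearing twice; the final
entry is read as Information Availability, the only reading consistent with
four modules.

## Variance analysis

**Two-factor ANOVA.** Sheet-level module values are decomposed by subregion
and scenario (fixed factors, OLS via statsmodels). "% of variation" is
eta-squared, 100·SS_factor/SS_total — the only definition consistent with
reporting a factor's share of total variation. Designs here are unbalanced
(entities absent from subregions), so sequential (Type-I) sums of squares
are order-dependent; both orders are computed and reported side by side
rather than privileging one. The interaction term is included only when the
subregion × scenario crossing is complete and replicated (a missing cell
makes the interaction design rank-deficient); whether it was included is
recorded on the result. Additivity of the components to SS_total is
asserted on every run. A constant response returns an all-zero
decomposition with undefined F (reported as missing), not an error.

**Paired module contrast.** A standard two-sided paired t-test (df = n−1)
for questions like "are status scores worse than vulnerability scores?".
Identical lists return t = 0, p = 1 explicitly (the textbook statistic is
0/0 there).

**Normality gate.** Shapiro–Wilk with α = 0.05 (configurable) recommends
the parametric path or the rank-based fallback; the fallback provided is a
rank-transform two-factor analysis (ranks replace the response, the same
sequential ANOVA runs), the simplest non-parametric analogue that preserves
the factorial structure. Constant samples raise, as the statistic is
undefined.

**Assessor screens.** Two screens, matching elicitation QC practice: (1)
each assessor's mean sheet value against the 95% t-interval of the grand
mean of assessor means; (2) for every entity × subregion × scenario cell
scored by ≥ 2 assessors, the across-assessor variance — an assessor whose
average cell variance deviates from the mean cell variance by more than
2 SD fails the disagreement screen. An assessor never paired with another
passes the second screen vacuously (reported as NaN).

## Synthetic elicitation generator

The generator emulates the assessment design so every stage is testable
without real sheets: each entity has a fixed panel of assessors, and every
panel member scores all subregion × scenario cells the entity occupies
(the "assessment set" design — one response per scenario). Criterion scores
are

s = clamp₍₁,₆₎(μ_entity,module + α_subregion + β_scenario + γ_assessor + ε)

with γ_a ~ N(0, σ_a) fixed per assessor, ε ~ N(0, σ_ε) i.i.d., additive
effects on the score scale (the simplest structure consistent with a
factorial variance question), a configurable fraction of criteria zeroed to
emulate insufficient information, and Bernoulli uncertainty flags on scored
criteria.

Defaults: μ = 3.5 (scale midpoint of the scored range), σ_a = 0.3,
σ_ε = 0.5, flag probability 0.10, zero probability 0.05, two assessors per
panel — the minimum the design targets. Flag and bias magnitudes are not
reported for real panels; these defaults are conservative round values on
the score scale and are configurable. **Clamping, not truncated
resampling**, is used at the [1, 6] bounds; at extreme baselines this biases
cell means toward the interior, which is why `raw_scores()` exposes the
unclamped draws for structural checks (cell means converge to μ + α + β).

What the generator does **not** model: assessor × entity interactions,
correlated criteria within a module, informative missingness (zeros are
random), or panel-recruitment effects. Passing tests on synthetic panels
therefore demonstrate that the pipeline recovers the structure it assumes —
additive region/scenario effects, random assessor intercepts — not that
real expert panels satisfy those assumptions.

The `make_gcva_like` preset generates a panel sized like the Gulf Coast
study (4 communities or 11 species, 6 subregions, 3 scenarios, 2–4
assessors, with the study's entity × subregion absences) for end-to-end
demonstrations; its baselines and effects are drawn once per dataset from
the seed with region spread (SD 0.5) exceeding scenario spread (SD 0.2),
the structure the variance stage is meant to detect.

**Variance-recovery experiment.** `region_scenario_recovery` draws, per
replicate, subregion effects ~ N(0, 0.8) and scenario effects ~ N(0, 0.2),
generates a single-entity panel (6 × 3 cells × 2 assessors), and checks
that the ANOVA attributes more variation to subregion than to scenario. At
these settings the recovery rate over 200 replicates exceeds 95%; the
replicate size (36 sheets) is the smallest fully crossed, minimally
replicated design, which keeps the 200-replicate experiment fast while
leaving the test sensitive.

## Numerical choices and edge cases

- Rank ties are resolved at 1e-9 resolution (scores are quantized before
  ranking) so floating noise cannot split a genuine tie.
- Weight-scheme sums are validated to 1e-9; module weights must be ≥ 0.
- CSV round-trips use pandas' round-trip float parsing so written sheets
  re-read bit-identically.
- Sheet files are validated row-by-row with CSV line numbers in every error
  (out-of-range scores, flags on zero scores, unknown criteria, duplicate
  keys).
- Subregion and scenario vocabularies are closed (six subregion codes,
  SC1–SC3); unknown labels are errors, never silently added.

## Known limitations

- Default criterion weights are 1.0: the packaged registries carry the
  correct module/criterion structure, but real applications of the
  instrument adjust weights, and published per-criterion weights are not
  available to ship. All results on the packaged tables are therefore
  equal-weight results.
- Re-deriving rankings from rounded two-decimal marginal tables cannot
  recover every published rank; margins are reported so that every
  rounding-level ambiguity is visible rather than asserted away.
- The ANOVA treats assessors as exchangeable replicates within cells; a
  mixed-effects treatment (assessor as random effect) is out of scope.
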