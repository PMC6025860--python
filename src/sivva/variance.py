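"""Statistical stage: variance partitioning and assessor quality control.

The central question the factorial ANOVA answers is whether assessment
scores vary more across geographic subregions than across climate
scenarios.  Sheet-level module values are decomposed into subregion,
scenario, (optionally) interaction and residual components; the share of
variation a factor explains is eta-squared, ``100 · SS_factor / SS_total``.

Because the assessment design is unbalanced (entities absent from some
subregions), sequential (Type-I) sums of squares depend on factor order;
both orders — (subregion, scenario) and (scenario, subregion) — are
computed and reported side by side so the order dependence is visible.

Supporting procedures: a paired t-test for module contrasts (e.g. is
Ecosystem Status scored worse than Vulnerability?), a Shapiro–Wilk gate
recommending the parametric or rank-based path, a rank-transform two-factor
analysis as the non-parametric fallback, and screens that flag assessors
whose mean scores fall outside the 95% confidence interval of the
across-assessor mean or whose within-entity disagreement is extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .model import ValidationError

__all__ = [
    "VarianceDecomposition",
    "PairedTestResult",
    "NormalityGate",
    "AssessorReport",
    "two_way_anova",
    "rank_transform_anova",
    "paired_module_test",
    "normality_gate",
    "assessor_outlier_check",
]

_FACTOR_ORDER = ("subregion", "scenario")


@dataclass
class VarianceDecomposition:
    """Sequential two-way ANOVA of module values, both factor orders.

    ``table`` uses order (subregion, scenario); ``table_reversed`` the
    opposite.  Rows: each factor, ``subregion:scenario`` when the
    interaction is estimable, and ``residual``; columns: ``ss``, ``df``,
    ``F``, ``p``, ``pct_variation`` (eta-squared, in percent).
    """

    response: str
    table: pd.DataFrame
    table_reversed: pd.DataFrame
    interaction: bool
    n_obs: int

    @property
    def ss_total(self) -> float:
        return float(self.table["ss"].sum())

    def pct(self, factor: str) -> float:
        return float(self.table.loc[factor, "pct_variation"])


def _anova_one_order(
    data: pd.DataFrame, order: tuple[str, str], interaction: bool
) -> pd.DataFrame:
    terms = [f"C({order[0]})", f"C({order[1]})"]
    if interaction:
        terms.append(f"C({_FACTOR_ORDER[0]}):C({_FACTOR_ORDER[1]})")
    model = smf.ols("value ~ " + " + ".join(terms), data=data).fit()
    aov = sm.stats.anova_lm(model, typ=1)

    def _label(raw: str) -> str:
        if raw == "Residual":
            return "residual"
        return (
            raw.replace("C(", "").replace(")", "").replace(":", ":")
        )

    table = pd.DataFrame(
        {
            "ss": aov["sum_sq"].to_numpy(),
            "df": aov["df"].to_numpy(),
            "F": aov["F"].to_numpy(),
            "p": aov["PR(>F)"].to_numpy(),
        },
        index=[_label(ix) for ix in aov.index],
    )
    ss_total = table["ss"].sum()
    table["pct_variation"] = (
        100.0 * table["ss"] / ss_total if ss_total > 0 else 0.0
    )
    return table


def _degenerate_table(data: pd.DataFrame, interaction: bool) -> pd.DataFrame:
    """All observations identical: SS 0 everywhere, F/p undefined."""
    n_r = data["subregion"].nunique()
    n_s = data["scenario"].nunique()
    rows = {
        "subregion": n_r - 1,
        "scenario": n_s - 1,
    }
    if interaction:
        rows["subregion:scenario"] = (n_r - 1) * (n_s - 1)
    rows["residual"] = len(data) - 1 - sum(rows.values())
    return pd.DataFrame(
        {
            "ss": 0.0,
            "df": list(rows.values()),
            "F": np.nan,
            "p": np.nan,
            "pct_variation": 0.0,
        },
        index=list(rows.keys()),
    )


def two_way_anova(
    scores: pd.DataFrame, response: str, include_interaction: bool | None = None
) -> VarianceDecomposition:
    """Partition one module's sheet-level values by subregion and scenario.

    ``scores`` is the long table from :func:`sivva.scoring.score_dataset`
    (or any frame with columns ``module``, ``value``, ``subregion``,
    ``scenario``).  Unbalanced designs are allowed; sequential sums of
    squares are reported for both factor orders.  The interaction term is
    included automatically when cells hold replicates (and residual degrees
    of freedom remain), dropped otherwise; ``include_interaction`` forces
    the choice.
    """
    data = scores[scores["module"] == response].dropna(subset=["value"])
    data = data[["value", "subregion", "scenario"]].copy()
    if data.empty:
        raise ValidationError(f"no observations for module {response!r}")
    for factor in _FACTOR_ORDER:
        if data[factor].nunique() < 2:
            raise ValidationError(
                f"factor {factor!r} has fewer than 2 levels; ANOVA needs "
                f"variation in both factors"
            )
    cells = data.groupby(["subregion", "scenario"]).size()
    if include_interaction is None:
        # estimable only on a complete crossing with within-cell replication;
        # a missing cell makes the interaction design rank-deficient
        complete = len(cells) == (
            data["subregion"].nunique() * data["scenario"].nunique()
        )
        include_interaction = bool(complete and len(data) > len(cells))
    interaction = include_interaction

    if np.isclose(data["value"].var(ddof=0), 0.0):
        table = _degenerate_table(data, interaction)
        table_rev = table.reindex(
            ["scenario", "subregion"]
            + [ix for ix in table.index if ix not in _FACTOR_ORDER]
        )
    else:
        table = _anova_one_order(data, _FACTOR_ORDER, interaction)
        table_rev = _anova_one_order(
            data, tuple(reversed(_FACTOR_ORDER)), interaction
        )
    decomp = VarianceDecomposition(
        response=response,
        table=table,
        table_reversed=table_rev,
        interaction=interaction,
        n_obs=len(data),
    )
    # additivity sanity check on every run
    for t in (decomp.table, decomp.table_reversed):
        ss = t["ss"].to_numpy()
        if (ss < -1e-9).any():
            raise AssertionError("negative sum of squares")
        if not np.isclose(ss.sum(), decomp.ss_total, rtol=1e-8, atol=1e-10):
            raise AssertionError("sums of squares do not total SS_total")
    return decomp


def rank_transform_anova(scores: pd.DataFrame, response: str) -> VarianceDecomposition:
    """Non-parametric fallback: two-factor analysis on rank-transformed
    values (ranks replace the response, then the sequential ANOVA runs
    unchanged)."""
    data = scores[scores["module"] == response].dropna(subset=["value"]).copy()
    data["value"] = stats.rankdata(data["value"].to_numpy())
    return two_way_anova(data, response)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


def paired_module_test(values_a, values_b) -> PairedTestResult:
    """Two-sided paired t-test of two equally long score lists (paired by
    index); df = n − 1.  Identical lists give t = 0, p = 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired test needs two equal-length 1-d lists")
    n = a.size
    if n < 2:
        raise ValidationError("paired test needs at least 2 pairs")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(diffs.mean(), 0.0) else np.inf * np.sign(diffs.mean())
        p = 1.0 if t == 0.0 else 0.0
        return PairedTestResult(t=float(t), df=n - 1, p=p,
                                mean_diff=float(diffs.mean()))
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue),
        mean_diff=float(diffs.mean()),
    )


@dataclass(frozen=True)
class NormalityGate:
    W: float
    p: float
    recommendation: str  # "parametric" | "nonparametric"


def normality_gate(values, alpha: float = 0.05) -> NormalityGate:
    """Shapiro–Wilk screen deciding the analysis path.

    Scores passing (p ≥ α) are treated as quantitative and analysed
    parametrically; otherwise the rank-based two-factor path is
    recommended.  Constant samples have no defined statistic and raise.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValidationError("normality test needs at least 3 observations")
    if np.allclose(arr.std(ddof=0), 0.0):
        raise ValidationError("normality statistic undefined for a constant sample")
    w, p = stats.shapiro(arr)
    rec = "parametric" if p >= alpha else "nonparametric"
    return NormalityGate(W=float(w), p=float(p), recommendation=rec)


@dataclass
class AssessorReport:
    """Per-assessor consistency screens.

    ``frame`` is indexed by assessor with columns ``mean`` (mean module
    value over the assessor's sheets), ``inside_ci`` (mean within the 95%
    CI of the across-assessor grand mean), ``pair_variance`` (the
    assessor's mean within-cell variance, NaN when never paired) and
    ``variance_ok`` (within 2 SD of the mean within-cell variance).
    """

    frame: pd.DataFrame
    ci_low: float
    ci_high: float
    var_mean: float
    var_sd: float

    @property
    def outliers(self) -> list[str]:
        mask = ~self.frame["inside_ci"] | ~self.frame["variance_ok"]
        return list(self.frame.index[mask])


def assessor_outlier_check(scores: pd.DataFrame) -> AssessorReport:
    """Screen assessors for systematic bias and excess disagreement.

    ``scores`` is the long table from :func:`sivva.scoring.score_dataset`.
    Each assessor's mean module value is compared with the 95% confidence
    interval of the grand mean of assessor means (t-based, df = number of
    assessors − 1).  Disagreement is screened through within-cell variances:
    for every (entity, subregion, scenario) cell scored by ≥ 2 assessors the
    across-assessor variance of the sheet mean is computed; an assessor
    whose average cell variance deviates from the overall mean cell
    variance by more than 2 SD fails ``variance_ok``.
    """
    data = scores.dropna(subset=["value"])
    sheet_means = (
        data.groupby(["entity", "subregion", "scenario", "assessor"])["value"]
        .mean()
        .rename("sheet_value")
        .reset_index()
    )
    assessor_means = sheet_means.groupby("assessor")["sheet_value"].mean()
    n = len(assessor_means)
    if n < 3:
        raise ValidationError(f"assessor screen needs >= 3 assessors, got {n}")
    grand = float(assessor_means.mean())
    sd = float(assessor_means.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    ci_low, ci_high = grand - half, grand + half
    inside = (assessor_means >= ci_low) & (assessor_means <= ci_high)

    cell_groups = sheet_means.groupby(["entity", "subregion", "scenario"])
    cell_var = cell_groups["sheet_value"].var(ddof=1).dropna()
    var_mean = float(cell_var.mean()) if len(cell_var) else 0.0
    var_sd = float(cell_var.std(ddof=1)) if len(cell_var) > 1 else 0.0

    per_assessor_var = {}
    multi = sheet_means.merge(
        cell_var.rename("cell_variance"),
        left_on=["entity", "subregion", "scenario"],
        right_index=True,
        how="inner",
    )
    for assessor, grp in multi.groupby("assessor"):
        per_assessor_var[assessor] = float(grp["cell_variance"].mean())
    pair_variance = assessor_means.index.map(
        lambda a: per_assessor_var.get(a, np.nan)
    )
    variance_ok = pd.Series(
        [
            True if np.isnan(v) else abs(v - var_mean) <= 2 * var_sd + 1e-12
            for v in pair_variance
        ],
        index=assessor_means.index,
    )
    frame = pd.DataFrame(
        {
            "mean": assessor_means,
            "inside_ci": inside,
            "pair_variance": pair_variance,
            "variance_ok": variance_ok,
        }
    )
    return AssessorReport(
        frame=frame, ci_low=ci_low, ci_high=ci_high,
        var_mean=var_mean, var_sd=var_sd,
    )
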