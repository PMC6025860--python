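"""Factorial ANOVA, paired contrasts, normality gate, assessor screens."""

import numpy as np
import pandas as pd
import pytest

from sivva.model import ValidationError, default_registry
from sivva.prioritize import builtin_schemes
from sivva.scoring import score_dataset
from sivva.synthetic import SyntheticConfig, generate
from sivva.variance import (
    assessor_outlier_check,
    normality_gate,
    paired_module_test,
    rank_transform_anova,
    two_way_anova,
)


def long_frame(values_by_cell, module="VU", reps=1):
    """Score table from {(subregion, scenario): value or [values]}."""
    rows = []
    i = 0
    for (r, s), vals in values_by_cell.items():
        vals = np.atleast_1d(vals)
        for v in vals:
            rows.append(
                {"entity": "e", "subregion": r, "scenario": s,
                 "assessor": f"a{i}", "module": module, "value": v}
            )
            i += 1
    return pd.DataFrame(rows)


def balanced_ss_oracle(data):
    """Hand sums of squares for a balanced two-factor design with
    replicates: between-level SS from group means, interaction from cell
    means, residual from within-cell deviations."""
    y = data["value"].to_numpy()
    grand = y.mean()
    ss = {}
    for factor in ("subregion", "scenario"):
        ss[factor] = sum(
            len(g) * (g["value"].mean() - grand) ** 2
            for _, g in data.groupby(factor)
        )
    cell_means = data.groupby(["subregion", "scenario"])["value"].transform(
        "mean"
    )
    a_means = data.groupby("subregion")["value"].transform("mean")
    b_means = data.groupby("scenario")["value"].transform("mean")
    ss["subregion:scenario"] = float(
        ((cell_means - a_means - b_means + grand) ** 2).sum()
    )
    ss["residual"] = float(((y - cell_means) ** 2).sum())
    return ss


class TestTwoWayAnova:
    def test_degenerate_constant_data(self):
        data = long_frame(
            {(r, s): 0.5 for r in ("LM", "MAP") for s in ("SC1", "SC2")}
        )
        d = two_way_anova(data, "VU")
        assert d.ss_total == 0.0
        assert (d.table["pct_variation"] == 0.0).all()
        assert d.table["F"].isna().all()

    def test_additive_noiseless_design_has_zero_residual(self):
        region = {"LM": 0.0, "MAP": 0.2}
        scen = {"SC1": 0.0, "SC2": 0.1}
        data = long_frame(
            {
                (r, s): 0.4 + region[r] + scen[s]
                for r in region for s in scen
            }
        )
        d = two_way_anova(data, "VU", include_interaction=False)
        assert d.table.loc["residual", "pct_variation"] == pytest.approx(
            0.0, abs=1e-8
        )
        oracle = balanced_ss_oracle(data)
        # balanced: sequential SS equal the marginal oracle SS
        for factor in ("subregion", "scenario"):
            assert d.table.loc[factor, "ss"] == pytest.approx(
                oracle[factor], abs=1e-12
            )
        assert d.pct("subregion") > d.pct("scenario")

    def test_matches_projection_oracle_on_balanced_replicated_design(self):
        rng = np.random.default_rng(11)
        cells = {
            (r, s): rng.uniform(0.2, 0.8, size=3)
            for r in ("LM", "MAP", "SCP") for s in ("SC1", "SC2", "SC3")
        }
        data = long_frame(cells)
        d = two_way_anova(data, "VU")
        assert d.interaction
        oracle = balanced_ss_oracle(data)
        for factor, ss in oracle.items():
            assert d.table.loc[factor, "ss"] == pytest.approx(ss, abs=1e-8)
        assert d.table["ss"].sum() == pytest.approx(
            sum(oracle.values()), abs=1e-8
        )

    def test_unbalanced_orders_reported_side_by_side(self):
        rng = np.random.default_rng(2)
        cells = {
            (r, s): rng.uniform(0, 1, size=2)
            for r in ("LM", "MAP") for s in ("SC1", "SC2")
        }
        cells.pop(("MAP", "SC2"))
        data = long_frame(cells)
        d = two_way_anova(data, "VU")
        # the missing cell makes the interaction inestimable
        assert not d.interaction
        assert set(d.table.index) == {"subregion", "scenario", "residual"}
        # same total, possibly different per-factor split
        assert d.table["ss"].sum() == pytest.approx(
            d.table_reversed["ss"].sum()
        )
        assert not np.isclose(
            d.table.loc["subregion", "ss"],
            d.table_reversed.loc["subregion", "ss"],
        )

    def test_single_level_factor_named_in_error(self):
        data = long_frame({("LM", s): 0.5 for s in ("SC1", "SC2")})
        with pytest.raises(ValidationError, match="subregion"):
            two_way_anova(data, "VU")

    def test_rank_transform_preserves_effect_ordering(self):
        region = {"LM": -0.3, "MAP": 0.3, "SCP": 0.0}
        rng = np.random.default_rng(8)
        cells = {
            (r, s): 0.5 + region[r] + rng.normal(0, 0.02, size=4)
            for r in region for s in ("SC1", "SC2", "SC3")
        }
        data = long_frame(cells)
        d = rank_transform_anova(data, "VU")
        assert d.pct("subregion") > d.pct("scenario")


class TestPairedTest:
    def test_identical_lists(self):
        r = paired_module_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert r.t == 0.0 and r.p == 1.0 and r.mean_diff == 0.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 32)
        b = a + rng.normal(0.1, 0.05, 32)
        r = paired_module_test(a, b)
        assert r.df == 31

    def test_hand_computed_toy(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [0.5, 2.5, 2.0, 3.0, 4.0]
        d = np.array(a) - np.array(b)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        r = paired_module_test(a, b)
        assert r.t == pytest.approx(t_hand)
        assert r.df == 4
        assert r.mean_diff == pytest.approx(d.mean())

    def test_status_exceeds_vulnerability_on_marginals(self):
        """On the packaged community table, status scores sit above
        vulnerability scores (positive mean difference, significant)."""
        from sivva.io import load_fixture

        frame = load_fixture("table2").frame.dropna()
        r = paired_module_test(frame["ES"], frame["VU"])
        assert r.mean_diff > 0
        assert r.t > 0
        assert r.p < 1e-4
        assert r.df == len(frame) - 1

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            paired_module_test([1, 2], [1, 2, 3])


class TestNormalityGate:
    def test_bell_shaped_sample_is_parametric(self):
        rng = np.random.default_rng(42)
        gate = normality_gate(rng.normal(0.5, 0.1, size=100))
        assert gate.recommendation == "parametric"
        assert 0 < gate.W <= 1

    def test_two_point_sample_is_nonparametric(self):
        values = np.array([1.0, 6.0] * 20)
        gate = normality_gate(values)
        assert gate.recommendation == "nonparametric"
        assert gate.p < 0.05

    def test_constant_sample_raises(self):
        with pytest.raises(ValidationError):
            normality_gate([2.0, 2.0, 2.0, 2.0])

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            normality_gate([1.0, 2.0])


class TestAssessorScreens:
    def _panel_scores(self, bias=0.0, seed=0, n_assessors=6):
        config = SyntheticConfig(
            variant="natcom",
            entities=("e1", "e2"),
            assessors_per_cell=n_assessors,
            assessor_bias_sd=0.15,
            noise_sd=0.4,
            flag_prob=0.0,
            zero_prob=0.0,
            seed=seed,
        )
        dataset = generate(config)
        if bias:
            target = dataset.sheets[0].assessor
            for sheet in dataset.sheets:
                if sheet.assessor == target:
                    for cid, s in sheet.scores.items():
                        sheet.scores[cid] = type(s)(
                            min(6.0, s.value + bias), s.uncertain
                        )
        registry = default_registry("natcom")
        return score_dataset(dataset, registry), (
            dataset.sheets[0].assessor if bias else None
        )

    def test_identical_assessors_all_pass(self):
        scores, _ = self._panel_scores(seed=1)
        # make every assessor identical by averaging within cells
        flat = scores.copy()
        flat["value"] = 0.5
        report = assessor_outlier_check(flat)
        assert report.frame["inside_ci"].all()
        assert report.frame["variance_ok"].all()

    def test_biased_assessor_flagged(self):
        flagged = 0
        for seed in range(20):
            scores, target = self._panel_scores(bias=1.5, seed=seed)
            report = assessor_outlier_check(scores)
            if target in report.outliers:
                flagged += 1
        assert flagged >= 19  # ≥95% of replicates

    def test_small_bias_does_not_change_entity_ranks(self):
        from sivva.prioritize import entity_summary, marginal_means, \
            rank_entities

        scores, target = self._panel_scores(bias=0.2, seed=5)
        equal = builtin_schemes("natcom")[0]

        def ranks(frame):
            marg = marginal_means(frame, "natcom", by="scenario")
            return rank_entities(entity_summary(marg), equal)["rank"]

        full = ranks(scores)
        without = ranks(scores[scores["assessor"] != target])
        assert (full == without).all()

    def test_needs_three_assessors(self):
        scores, _ = self._panel_scores(n_assessors=2)
        one_panel = scores[scores["entity"] == "e1"]  # two assessors only
        with pytest.raises(ValidationError):
            assessor_outlier_check(one_panel)
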