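"""Domain types, criteria registries, sheet IO and packaged fixtures."""

import numpy as np
import pytest
import yaml

from sivva.io import load_fixture, read_sheets, write_sheets
from sivva.model import (
    AssessmentSheet,
    ConfigurationError,
    Score,
    ValidationError,
    default_registry,
    load_criteria_config,
)
from sivva.synthetic import SyntheticConfig, generate


class TestRegistry:
    def test_natcom_module_structure(self, natcom_registry):
        sizes = {m.id: len(m.criteria) for m in natcom_registry.modules}
        assert sizes == {"ES": 9, "VU": 9, "CV": 3}
        es = natcom_registry.module("ES")
        assert len(es.set_ids) == 3
        assert all(len(es.criteria_in_set(s)) == 3 for s in es.set_ids)
        # set structure is exclusive to ES
        assert all(c.set_id is None for c in natcom_registry.module("VU").criteria)

    def test_species_module_structure(self, species_registry):
        sizes = {m.id: len(m.criteria) for m in species_registry.modules}
        assert sizes == {"V": 12, "AC": 6, "CV": 5, "IA": 5}

    def test_wrong_criterion_count_names_module(self, tmp_path):
        registry = default_registry("natcom")
        doc = {
            "variant": "natcom",
            "modules": [
                {
                    "id": m.id,
                    "name": m.name,
                    "criteria": [
                        {"id": c.id, "weight": c.weight, "set_id": c.set_id}
                        for c in m.criteria
                    ],
                }
                for m in registry.modules
            ],
        }
        doc["modules"][1]["criteria"] = doc["modules"][1]["criteria"][:8]
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigurationError, match="VU"):
            load_criteria_config(path)

    def test_negative_weight_rejected(self, tmp_path):
        registry = default_registry("species")
        doc = {
            "variant": "species",
            "modules": [
                {
                    "id": m.id,
                    "criteria": [
                        {"id": c.id, "weight": c.weight} for c in m.criteria
                    ],
                }
                for m in registry.modules
            ],
        }
        doc["modules"][0]["criteria"][0]["weight"] = -1.0
        path = tmp_path / "bad.json"
        import json

        path.write_text(json.dumps(doc))
        with pytest.raises(ConfigurationError, match="weight"):
            load_criteria_config(path)

    def test_config_round_trips_default(self, tmp_path, species_registry):
        # a YAML dump of the default registry loads back identically
        doc = {
            "variant": "species",
            "modules": [
                {
                    "id": m.id,
                    "name": m.name,
                    "criteria": [
                        {"id": c.id, "description": c.description,
                         "weight": c.weight}
                        for c in m.criteria
                    ],
                }
                for m in species_registry.modules
            ],
        }
        path = tmp_path / "species.yaml"
        path.write_text(yaml.safe_dump(doc))
        loaded = load_criteria_config(path)
        assert loaded.module_ids == species_registry.module_ids
        assert loaded.criteria.keys() == species_registry.criteria.keys()


class TestScore:
    @pytest.mark.parametrize("value", [0, 1, 3.5, 6])
    def test_valid_values(self, value):
        assert Score(value).value == value

    @pytest.mark.parametrize("value", [-1, 0.5, 6.5, 7])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValidationError):
            Score(value)

    def test_zero_cannot_be_uncertain(self):
        with pytest.raises(ValidationError):
            Score(0, uncertain=True)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValidationError, match="subregion"):
            AssessmentSheet("e", "XX", "SC1", "a")
        with pytest.raises(ValidationError, match="scenario"):
            AssessmentSheet("e", "LM", "SC9", "a")


class TestSheetIO:
    def _minimal_csv(self, tmp_path, score="3", uncertain="0", cid="vu_slr_loss"):
        path = tmp_path / "sheets.csv"
        header = (
            "entity,entity_type,subregion,scenario,assessor,"
            "criterion_id,score,uncertain\n"
        )
        vu = default_registry("natcom").module("VU")
        rows = [
            f"mangrove,natcom,LM,SC1,a1,{c.id},3,0" for c in vu.criteria
        ]
        rows[0] = f"mangrove,natcom,LM,SC1,a1,{cid},{score},{uncertain}"
        path.write_text(header + "\n".join(rows) + "\n")
        return path

    def test_minimal_sheet_reads(self, tmp_path, natcom_registry):
        dataset = read_sheets(self._minimal_csv(tmp_path), natcom_registry)
        assert len(dataset) == 1
        assert len(dataset.sheets[0].scores) == 9

    def test_score_out_of_range_names_row(self, tmp_path, natcom_registry):
        path = self._minimal_csv(tmp_path, score="6.5")
        with pytest.raises(ValidationError, match="line 2"):
            read_sheets(path, natcom_registry)

    def test_zero_with_flag_rejected(self, tmp_path, natcom_registry):
        path = self._minimal_csv(tmp_path, score="0", uncertain="1")
        with pytest.raises(ValidationError, match="uncertain"):
            read_sheets(path, natcom_registry)

    def test_unknown_criterion_rejected(self, tmp_path, natcom_registry):
        path = self._minimal_csv(tmp_path, cid="not_a_criterion")
        with pytest.raises(ValidationError, match="not_a_criterion"):
            read_sheets(path, natcom_registry)

    def test_duplicate_rows_rejected(self, tmp_path, natcom_registry):
        path = tmp_path / "dup.csv"
        src = self._minimal_csv(tmp_path)
        lines = src.read_text().splitlines()
        path.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_sheets(path, natcom_registry)

    def test_round_trip(self, tmp_path, natcom_registry):
        dataset = generate(
            SyntheticConfig(
                variant="natcom",
                entities=("mangrove", "oyster reef"),
                subregions=("LM", "MAP"),
                flag_prob=0.3,
                zero_prob=0.1,
                seed=7,
            ),
            natcom_registry,
        )
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_sheets(dataset, p1)
        again = read_sheets(p1, natcom_registry)
        write_sheets(again, p2)
        assert p1.read_text() == p2.read_text()
        assert len(again) == len(dataset)


class TestFixtures:
    def test_table2_cells(self):
        t2 = load_fixture("table2")
        cell = t2.cell("barrier islands", "SC1")
        assert (cell["ES"], cell["VU"], cell["CV"]) == (0.86, 0.50, 0.49)
        # the one blank row: barrier islands in the Southern Florida plain
        assert t2.cell("barrier islands", "SFCP").isna().all()
        missing = int(t2.frame.isna().to_numpy().sum())
        assert missing == 3  # exactly that one 3-module row
        assert t2.frame.shape == (36, 3)

    def test_table3_cells(self):
        t3 = load_fixture("table3")
        cell = t3.cell("blue crab", "SC2")
        assert tuple(cell[["V", "AC", "CV", "IA"]]) == (0.41, 0.21, 0.46, 0.56)
        for level in ("MAP", "SFCP", "CFCP"):
            assert t3.cell("Kemp's ridley sea turtle", level).isna().all()
        assert int(t3.frame.isna().to_numpy().sum()) == 12  # 3 rows x 4 modules
        assert t3.frame.shape == (99, 3 + 1)

    def test_table3_values_in_unit_interval(self):
        t3 = load_fixture("table3")
        vals = t3.frame.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0

    def test_table1_catalog(self):
        t1 = load_fixture("table1")
        assert len(t1) == 15
        assert (t1["entity_type"] == "natcom").sum() == 4
        assert (t1["entity_type"] == "species").sum() == 11
        row = t1[t1["entity"] == "eastern oyster"].iloc[0]
        assert row["n_assessments"] == 37

    def test_unknown_fixture(self):
        with pytest.raises(ValidationError):
            load_fixture("table9")
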