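import numpy as np
import pytest

from sivva.model import (
    AssessmentSheet,
    CriterionDef,
    ModuleDef,
    Score,
    default_registry,
)


@pytest.fixture(scope="session")
def natcom_registry():
    return default_registry("natcom")


@pytest.fixture(scope="session")
def species_registry():
    return default_registry("species")


def make_sheet(scores, entity="mangrove", subregion="LM", scenario="SC1",
               assessor="a1"):
    """Build a sheet from {criterion_id: value | (value, uncertain)}."""
    parsed = {}
    for cid, v in scores.items():
        if isinstance(v, tuple):
            parsed[cid] = Score(value=v[0], uncertain=v[1])
        else:
            parsed[cid] = Score(value=v)
    return AssessmentSheet(entity=entity, subregion=subregion,
                           scenario=scenario, assessor=assessor, scores=parsed)


def make_module(weights, module_id="M", variant="species"):
    """A standalone module with criteria c1..cN and the given weights.

    Not registry-validated (arbitrary sizes allowed) — for unit tests of the
    scoring arithmetic only.
    """
    criteria = tuple(
        CriterionDef(id=f"c{i + 1}", module_id=module_id, weight=w)
        for i, w in enumerate(weights)
    )
    return ModuleDef(id=module_id, variant=variant, name=module_id,
                     criteria=criteria)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
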