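import pytest

from mpqs import (
    Config,
    EAAThresholds,
    EAAVector,
    FoodItem,
    FoodTable,
    MG_ABSOLUTE,
    MG_PER_G_PROTEIN,
)
from mpqs.config import DEFAULT_EAA_LIST


def profile(**overrides) -> EAAVector:
    """A full 9-EAA profile (mg per g protein), default 60 everywhere."""
    values = {e: 60.0 for e in DEFAULT_EAA_LIST}
    values.update(overrides)
    return EAAVector(values, MG_PER_G_PROTEIN)


@pytest.fixture
def config() -> Config:
    return Config()


@pytest.fixture
def toy_table() -> FoodTable:
    """Three hand-built foods with known complementarity.

    The cereal is lysine-poor, the legume sulfur-AA-poor, the dairy item
    balanced and rich; every number is chosen for easy hand computation.
    """
    return FoodTable.from_items(
        [
            FoodItem(
                code="C1", name="toy cereal", food_group="cereals",
                protein=10.0, energy=350.0,
                aa_profile=profile(lys=20.0, saa=40.0),
                digestibility=0.8, provenance="native",
            ),
            FoodItem(
                code="L1", name="toy legume", food_group="legumes",
                protein=20.0, energy=300.0,
                aa_profile=profile(lys=70.0, saa=15.0),
                digestibility=0.75, provenance="native",
            ),
            FoodItem(
                code="D1", name="toy dairy", food_group="dairy",
                protein=25.0, energy=400.0,
                aa_profile=profile(**{e: 80.0 for e in DEFAULT_EAA_LIST}),
                digestibility=0.95, provenance="native",
            ),
        ]
    )


@pytest.fixture
def flat_thresholds() -> EAAThresholds:
    """1000 mg for every EAA at lunch — trivial to reason about by hand."""
    return EAAThresholds(
        EAAVector({e: 1000.0 for e in DEFAULT_EAA_LIST}, MG_ABSOLUTE), "lunch"
    )
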