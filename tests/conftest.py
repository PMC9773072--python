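"""Shared fixtures: tiny hand-built foods, diaries and DRI rules."""

from __future__ import annotations

import pytest

from dairysim import (
    Child,
    Diary,
    DietRecord,
    DRIRule,
    DRITable,
    FoodCompositionEntry,
    NutrientVector,
)


def entry(food_id, subtype="NONE", name=None, **per100g) -> FoodCompositionEntry:
    return FoodCompositionEntry(
        food_id, name or food_id, subtype, NutrientVector(per100g)
    )


def diary(child_id="c1", age=50, foods=(), days=(1, 2, 3, 4)) -> Diary:
    """Build a 4-day diary; ``foods`` is (food_id, grams, day) or
    (food_id, grams) for every-day items."""
    day_types = {1: "working", 2: "working", 3: "weekend", 4: "weekend"}
    records = []
    for item in foods:
        if len(item) == 3:
            fid, grams, d = item
            records.append(DietRecord(child_id, d, day_types[d], fid, grams))
        else:
            fid, grams = item
            for d in days:
                records.append(DietRecord(child_id, d, day_types[d], fid, grams))
    # ensure all 4 days appear so the diary validates
    present = {r.day for r in records}
    for d in set(days) - present:
        records.append(DietRecord(child_id, d, day_types[d], "filler", 0.0))
    dia = Diary(Child(child_id, age), records)
    dia.validate()
    return dia


@pytest.fixture
def compositions():
    return {
        "milk_liq": entry(
            "milk_liq", "LIQUID_MILK", "Liquid milk",
            energy=54, protein=3.0, fat=3.2, carbohydrate=3.4,
            calcium=104, potassium=109, vitamin_b2=0.14,
        ),
        "powder": entry(
            "powder", "MILK_POWDER", "Milk powder",
            energy=480, protein=20.0, fat=18, carbohydrate=55,
            calcium=670, vitamin_d=6.0,
        ),
        "yog": entry(
            "yog", "YOGURT", "Yogurt",
            energy=72, protein=2.5, fat=2.7, carbohydrate=9.3, calcium=118,
        ),
        "cheese": entry(
            "cheese", "OTHER_DAIRY", "Cheese",
            energy=328, protein=25.7, fat=23.5, calcium=799,
        ),
        "bread": entry(
            "bread", name="Bread",
            energy=280, protein=8.0, fat=3.0, carbohydrate=55, fiber=2.5,
            iron=2.0, vitamin_b1=0.1,
        ),
        "veg": entry(
            "veg", name="Vegetable",
            energy=25, protein=1.2, carbohydrate=4.0, fiber=1.8,
            potassium=200, vitamin_c=30, vitamin_a=50,
        ),
        "filler": entry("filler", name="Filler (zero)"),
    }


@pytest.fixture
def dri():
    return DRITable(
        [
            DRIRule("calcium", 36, 73, "EAR", 600),
            DRIRule("protein", 36, 73, "EAR", 25),
            DRIRule("potassium", 36, 73, "AI", 1200),
            DRIRule("vitamin_c", 36, 73, "EAR", 40),
            DRIRule("fiber_density", 36, 73, "FIBER_DENSITY", 10),
            DRIRule("fat_energy_pct", 49, 73, "AMDR_UPPER", 30),
        ]
    )
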