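"""Domain types, file readers/writers, and their validation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dairysim import (
    Child,
    ConfigError,
    DRIRule,
    DRITable,
    NutrientVector,
    SchemaError,
    ValidationError,
    load_composition_table,
    load_diet_records,
    load_dri_table,
    load_supplement_records,
)
from dairysim.core import (
    write_composition_table,
    write_diet_records,
    write_supplement_records,
)
from dairysim.nutrients import NUTRIENTS, NegativeComponentError

from conftest import diary, entry


# ---------------------------------------------------------------------------
# NutrientVector algebra
# ---------------------------------------------------------------------------

# dyadic rationals are exact in binary floating point, so the algebra laws
# hold exactly, not just approximately
dyadic = st.integers(0, 2**20).map(lambda n: n / 1024.0)
vectors = st.lists(dyadic, min_size=len(NUTRIENTS), max_size=len(NUTRIENTS)).map(
    NutrientVector
)


class TestNutrientVector:
    def test_named_access_and_dict_roundtrip(self):
        v = NutrientVector({"energy": 54.0, "protein": 3.0})
        assert v.energy == 54.0 and v.protein == 3.0 and v.fat == 0.0
        assert NutrientVector(v.as_dict()) == v

    def test_negative_rejected(self):
        with pytest.raises(NegativeComponentError):
            NutrientVector({"iron": -1.0})

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            NutrientVector({"unobtainium": 1.0})

    @given(vectors, vectors, vectors)
    @settings(max_examples=100, deadline=None)
    def test_addition_associative_exact(self, a, b, c):
        assert ((a + b) + c) == (a + (b + c)) or np.allclose(
            ((a + b) + c).values, (a + (b + c)).values, rtol=0, atol=0
        )

    @given(vectors, vectors, st.integers(0, 64).map(lambda n: n / 8.0))
    @settings(max_examples=100, deadline=None)
    def test_scaling_distributes_exact(self, a, b, s):
        left = s * (a + b)
        right = s * a + s * b
        assert np.array_equal(left.values, right.values)

    def test_clipped_rejects_large_negative(self):
        v = NutrientVector({"energy": 100.0}) - NutrientVector({"energy": 150.0})
        with pytest.raises(NegativeComponentError):
            v.clipped()


# ---------------------------------------------------------------------------
# Composition table I/O
# ---------------------------------------------------------------------------


class TestCompositionIO:
    def test_roundtrip(self, compositions, tmp_path):
        p = tmp_path / "comp.csv"
        write_composition_table(compositions, p)
        back = load_composition_table(p)
        assert set(back) == set(compositions)
        for fid in compositions:
            assert back[fid].per100g == compositions[fid].per100g
            assert back[fid].dairy_subtype == compositions[fid].dairy_subtype

    def test_parse_values(self, compositions, tmp_path):
        p = tmp_path / "comp.csv"
        write_composition_table(compositions, p)
        assert load_composition_table(p)["milk_liq"].per100g.protein == 3.0

    def test_missing_column_named(self, compositions, tmp_path):
        import pandas as pd

        p = tmp_path / "comp.csv"
        write_composition_table(compositions, p)
        df = pd.read_csv(p).drop(columns=["vitamin_d"])
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="vitamin_d"):
            load_composition_table(p)

    def test_negative_value_reports_row(self, compositions, tmp_path):
        import pandas as pd

        p = tmp_path / "comp.csv"
        write_composition_table(compositions, p)
        df = pd.read_csv(p)
        df.loc[1, "iron"] = -0.5
        df.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="row 2"):
            load_composition_table(p)

    def test_unknown_subtype_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="dairy_subtype"):
            entry("x", "CHEESE_WHEEL")

    def test_large_table_size(self, tmp_path):
        # a pool the size of a real survey food list parses completely
        table = {f"f{i:03d}": entry(f"f{i:03d}", energy=float(i)) for i in range(323)}
        p = tmp_path / "comp.csv"
        write_composition_table(table, p)
        assert len(load_composition_table(p)) == 323


# ---------------------------------------------------------------------------
# Diet record I/O
# ---------------------------------------------------------------------------


class TestDietRecordIO:
    def test_roundtrip_preserves_values(self, compositions, tmp_path):
        diaries = {
            "c1": diary("c1", 40, [("milk_liq", 348.0), ("bread", 60.125)]),
            "c2": diary("c2", 66, [("veg", 80.0, 1), ("bread", 30.0, 2),
                                   ("milk_liq", 100.0, 3), ("yog", 55.5, 4)]),
        }
        p = tmp_path / "diet.csv"
        write_diet_records(diaries, p)
        back = load_diet_records(p, compositions)
        assert set(back) == {"c1", "c2"}
        orig = sorted((r.day, r.food_id, r.amount) for r in diaries["c1"].records)
        rt = sorted((r.day, r.food_id, r.amount) for r in back["c1"].records)
        assert orig == rt
        assert back["c2"].child == Child("c2", 66)

    def test_strict_rejects_three_day_child(self, compositions, tmp_path):
        diaries = {"c9": diary("c9", 50, [("bread", 50.0)])}
        diaries["c9"].records = [r for r in diaries["c9"].records if r.day != 4]
        p = tmp_path / "diet.csv"
        write_diet_records(diaries, p)
        with pytest.raises(ValidationError, match="c9"):
            load_diet_records(p, compositions, strict=True)
        assert "c9" in load_diet_records(p, compositions, strict=False)

    def test_unknown_food_referential_error(self, compositions, tmp_path):
        from dairysim import ReferentialError

        diaries = {"c1": diary("c1", 50, [("bread", 50.0)])}
        p = tmp_path / "diet.csv"
        write_diet_records(diaries, p)
        with pytest.raises(ReferentialError):
            load_diet_records(p, {k: v for k, v in compositions.items() if k == "veg"})

    def test_day_outside_range_rejected(self):
        from dairysim import DietRecord

        with pytest.raises(ValidationError):
            DietRecord("c1", 5, "working", "bread", 10.0)

    def test_negative_amount_rejected(self):
        from dairysim import DietRecord

        with pytest.raises(ValidationError):
            DietRecord("c1", 1, "working", "bread", -1.0)


class TestSupplementIO:
    def test_roundtrip(self, tmp_path):
        from dairysim import SupplementRecord

        recs = {
            "c1": [
                SupplementRecord("c1", d, NutrientVector({"vitamin_d": 5.0, "calcium": 120.0}))
                for d in (1, 2, 3, 4)
            ]
        }
        p = tmp_path / "supp.csv"
        write_supplement_records(recs, p)
        back = load_supplement_records(p)
        assert len(back["c1"]) == 4
        assert back["c1"][0].nutrients == recs["c1"][0].nutrients

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "supp.csv"
        p.write_text("child_id,day,magnesium\nc1,1,5\n")
        with pytest.raises(SchemaError, match="magnesium"):
            load_supplement_records(p)


# ---------------------------------------------------------------------------
# DRI table
# ---------------------------------------------------------------------------


class TestDRITable:
    def test_lookup_in_band(self):
        t = DRITable([DRIRule("calcium", 36, 48, "EAR", 600)])
        assert t.require("calcium", 40).threshold == 600
        assert t.lookup("calcium", 48) is None

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            DRITable(
                [
                    DRIRule("calcium", 36, 60, "EAR", 500),
                    DRIRule("calcium", 48, 72, "EAR", 650),
                ]
            )

    def test_every_in_range_age_resolves_uniquely(self, dri):
        for age in range(37, 73):
            rules = dri.rules_for_age(age)
            assert list(rules).count("calcium") == 1

    def test_fiber_density_rule_accepted(self, dri):
        rule = dri.require("fiber_density", 50)
        assert rule.rule_type == "FIBER_DENSITY" and rule.threshold == 10

    def test_unknown_nutrient_rejected(self):
        with pytest.raises(ConfigError):
            DRIRule("selenium_ox", 36, 48, "EAR", 10)

    def test_yaml_and_json_loaders(self, tmp_path):
        yaml_p = tmp_path / "dri.yaml"
        yaml_p.write_text(
            "rules:\n"
            "  - {nutrient: calcium, age_min_months: 36, age_max_months: 48,\n"
            "     rule_type: EAR, threshold: 600}\n"
        )
        json_p = tmp_path / "dri.json"
        json_p.write_text(
            '[{"nutrient": "calcium", "age_min_months": 36,'
            ' "age_max_months": 48, "rule_type": "EAR", "threshold": 600}]'
        )
        assert load_dri_table(yaml_p).require("calcium", 40).threshold == 600
        assert load_dri_table(json_p).require("calcium", 40).threshold == 600

    def test_bundled_default_covers_survey_ages(self):
        from dairysim import default_dri_path

        t = load_dri_table(default_dri_path())
        for age in (37, 47, 48, 49, 60, 61, 72):
            assert t.require("calcium", age).threshold > 0
            assert t.require("potassium", age).rule_type == "AI"


class TestChild:
    @pytest.mark.parametrize(
        "age, group", [(37, "37-48"), (48, "37-48"), (49, "49-60"),
                       (60, "49-60"), (61, "61-72"), (72, "61-72")]
    )
    def test_age_group_boundaries(self, age, group):
        assert Child("c", age).age_group == group

    def test_out_of_range_age(self):
        with pytest.raises(ValidationError):
            Child("c", 80).age_group
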