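"""Domain types and validated readers/writers for diet-survey data.

File formats (all UTF-8 CSV with decimal point, or JSON/YAML for the DRI
configuration):

* diet records: ``child_id, age_months, day, day_type, food_id, amount_g``
* food composition: ``food_id, name, dairy_subtype`` plus the 20 canonical
  nutrient columns, values per 100 g edible portion as consumed
* supplements: ``child_id, day`` plus any subset of the nutrient columns
* DRI configuration: list of rules ``{nutrient, age_min_months,
  age_max_months, rule_type, threshold}`` with half-open age bands
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .nutrients import NUTRIENTS, NutrientVector

DAIRY_SUBTYPES = ("NONE", "LIQUID_MILK", "MILK_POWDER", "YOGURT", "OTHER_DAIRY")
DAIRY_ONLY = tuple(s for s in DAIRY_SUBTYPES if s != "NONE")
DAY_TYPES = ("working", "weekend")
RULE_TYPES = ("EAR", "AI", "FIBER_DENSITY", "AMDR_UPPER")

#: Derived quantities a DRI rule may address, beyond raw nutrient names.
DERIVED_QUANTITIES = ("fiber_density", "fat_energy_pct")

#: Paper-defined age strata for preschool children, half-open in months.
AGE_GROUPS = (("37-48", 37, 49), ("49-60", 49, 61), ("61-72", 61, 73))


class SchemaError(ValueError):
    """An input file is missing a required column."""


class ValidationError(ValueError):
    """A row value violates its contract (range, enumeration, day count)."""


class ReferentialError(KeyError):
    """A record references an unknown food or child."""


class ConfigError(ValueError):
    """A DRI or scenario configuration is inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def age_group_of(age_months: int) -> str:
    for label, lo, hi in AGE_GROUPS:
        if lo <= age_months < hi:
            return label
    raise ValidationError(f"age {age_months} months outside supported range 37-72")


@dataclass(frozen=True)
class Child:
    child_id: str
    age_months: int

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_months)


@dataclass(frozen=True)
class DietRecord:
    """One food eaten by one child on one diary day (g edible raw weight)."""

    child_id: str
    day: int
    day_type: str
    food_id: str
    amount: float

    def __post_init__(self) -> None:
        if self.day not in (1, 2, 3, 4):
            raise ValidationError(f"day {self.day} outside 1-4 (child {self.child_id})")
        if self.day_type not in DAY_TYPES:
            raise ValidationError(f"unknown day_type {self.day_type!r}")
        if self.amount < 0:
            raise ValidationError(
                f"negative amount {self.amount} (child {self.child_id}, food {self.food_id})"
            )


@dataclass(frozen=True)
class FoodCompositionEntry:
    food_id: str
    name: str
    dairy_subtype: str
    per100g: NutrientVector

    def __post_init__(self) -> None:
        if self.dairy_subtype not in DAIRY_SUBTYPES:
            raise ValidationError(
                f"unknown dairy_subtype {self.dairy_subtype!r} for food {self.food_id}"
            )

    @property
    def is_dairy(self) -> bool:
        return self.dairy_subtype != "NONE"


@dataclass(frozen=True)
class SupplementRecord:
    child_id: str
    day: int
    nutrients: NutrientVector


@dataclass(frozen=True)
class DRIRule:
    nutrient: str
    age_min_months: int
    age_max_months: int  # half-open: rule applies to [min, max)
    rule_type: str
    threshold: float

    def __post_init__(self) -> None:
        valid_names = set(NUTRIENTS) | set(DERIVED_QUANTITIES)
        if self.nutrient not in valid_names:
            raise ConfigError(f"unknown nutrient {self.nutrient!r} in DRI rule")
        if self.rule_type not in RULE_TYPES:
            raise ConfigError(f"unknown rule_type {self.rule_type!r}")
        if self.threshold <= 0:
            raise ConfigError(f"non-positive threshold for {self.nutrient}")
        if self.age_min_months >= self.age_max_months:
            raise ConfigError(f"empty age band for {self.nutrient}")

    def covers(self, age_months: int) -> bool:
        return self.age_min_months <= age_months < self.age_max_months


class DRITable:
    """Per-nutrient, per-age-band reference rules with non-overlap validation."""

    def __init__(self, rules: Iterable[DRIRule]) -> None:
        self.rules = list(rules)
        by_nutrient: dict[str, list[DRIRule]] = {}
        for r in self.rules:
            by_nutrient.setdefault(r.nutrient, []).append(r)
        for nutrient, rs in by_nutrient.items():
            rs.sort(key=lambda r: r.age_min_months)
            for a, b in zip(rs, rs[1:]):
                if b.age_min_months < a.age_max_months:
                    raise ConfigError(
                        f"overlapping age bands for {nutrient}: "
                        f"[{a.age_min_months},{a.age_max_months}) and "
                        f"[{b.age_min_months},{b.age_max_months})"
                    )
        self._by_nutrient = by_nutrient

    def lookup(self, nutrient: str, age_months: int) -> DRIRule | None:
        for r in self._by_nutrient.get(nutrient, ()):
            if r.covers(age_months):
                return r
        return None

    def rules_for_age(self, age_months: int) -> dict[str, DRIRule]:
        out = {}
        for nutrient, rs in self._by_nutrient.items():
            for r in rs:
                if r.covers(age_months):
                    out[nutrient] = r
        return out

    def require(self, nutrient: str, age_months: int) -> DRIRule:
        rule = self.lookup(nutrient, age_months)
        if rule is None:
            raise ConfigError(f"no DRI rule for {nutrient} at age {age_months} months")
        return rule


@dataclass
class Diary:
    """A validated 4-day diary for one child."""

    child: Child
    records: list[DietRecord] = field(default_factory=list)

    def validate(self) -> None:
        days = {r.day for r in self.records}
        if days != {1, 2, 3, 4}:
            raise ValidationError(
                f"child {self.child.child_id}: diary covers days {sorted(days)}, "
                "expected exactly days 1-4"
            )
        day_types = {}
        for r in self.records:
            prev = day_types.setdefault(r.day, r.day_type)
            if prev != r.day_type:
                raise ValidationError(
                    f"child {self.child.child_id}: day {r.day} has mixed day types"
                )
        n_working = sum(1 for t in day_types.values() if t == "working")
        if n_working != 2:
            raise ValidationError(
                f"child {self.child.child_id}: expected 2 working + 2 weekend days, "
                f"got {n_working} working"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_COMP_META = ("food_id", "name", "dairy_subtype")


def load_composition_table(path: str | Path) -> dict[str, FoodCompositionEntry]:
    """Read a food composition CSV into a ``food_id`` lookup.

    Every one of the 20 canonical nutrient columns must be present; unknown
    dairy subtype strings and negative values are rejected with the row
    number.
    """
    df = pd.read_csv(path, dtype={"food_id": str, "name": str, "dairy_subtype": str})
    missing = [c for c in (*_COMP_META, *NUTRIENTS) if c not in df.columns]
    if missing:
        raise SchemaError(f"composition table missing column(s): {missing}")
    table: dict[str, FoodCompositionEntry] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        values = [getattr(row, n) for n in NUTRIENTS]
        if any(v < 0 for v in values):
            raise ValidationError(f"negative nutrient value in composition row {i + 1}")
        entry = FoodCompositionEntry(
            food_id=row.food_id,
            name=row.name,
            dairy_subtype=row.dairy_subtype,
            per100g=NutrientVector(values),
        )
        if entry.food_id in table:
            raise ValidationError(f"duplicate food_id {entry.food_id!r} (row {i + 1})")
        table[entry.food_id] = entry
    return table


def write_composition_table(
    table: Mapping[str, FoodCompositionEntry], path: str | Path
) -> None:
    rows = []
    for e in table.values():
        row = {"food_id": e.food_id, "name": e.name, "dairy_subtype": e.dairy_subtype}
        row.update(e.per100g.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=[*_COMP_META, *NUTRIENTS]).to_csv(path, index=False)


_DAY_TYPE_ALIASES = {
    "working": "working", "w": "working", "workday": "working",
    "weekend": "weekend", "e": "weekend", "we": "weekend",
}


def load_diet_records(
    path: str | Path,
    compositions: Mapping[str, FoodCompositionEntry] | None = None,
    *,
    strict: bool = True,
    ages: Mapping[str, int] | None = None,
) -> dict[str, Diary]:
    """Read a diet diary CSV into per-child :class:`Diary` groups.

    In strict mode (default) each child must contribute exactly 4 distinct
    days, 2 working and 2 weekend. When ``compositions`` is given, unknown
    food ids raise :class:`ReferentialError`. Ages come from an
    ``age_months`` column or the ``ages`` mapping.
    """
    df = pd.read_csv(path, dtype={"child_id": str, "food_id": str})
    required = ("child_id", "day", "day_type", "food_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"diet records missing column(s): {missing}")
    amount_col = "amount_g" if "amount_g" in df.columns else "amount"
    if amount_col not in df.columns:
        raise SchemaError("diet records missing column(s): ['amount_g']")

    diaries: dict[str, Diary] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        child_id = row.child_id
        if child_id not in diaries:
            if ages is not None and child_id in ages:
                age = int(ages[child_id])
            elif "age_months" in df.columns:
                age = int(getattr(row, "age_months"))
            else:
                raise SchemaError(
                    "no age_months column and no ages mapping supplied"
                )
            diaries[child_id] = Diary(Child(child_id, age))
        day_type_raw = str(row.day_type).strip().lower()
        if day_type_raw not in _DAY_TYPE_ALIASES:
            raise ValidationError(f"unknown day_type {row.day_type!r} (row {i + 1})")
        food_id = row.food_id
        if compositions is not None and food_id not in compositions:
            raise ReferentialError(
                f"unknown food_id {food_id!r} (row {i + 1}, child {child_id})"
            )
        diaries[child_id].records.append(
            DietRecord(
                child_id=child_id,
                day=int(row.day),
                day_type=_DAY_TYPE_ALIASES[day_type_raw],
                food_id=food_id,
                amount=float(getattr(row, amount_col)),
            )
        )
    if strict:
        for diary in diaries.values():
            diary.validate()
    return diaries


def write_diet_records(diaries: Mapping[str, Diary], path: str | Path) -> None:
    rows = [
        {
            "child_id": r.child_id,
            "age_months": d.child.age_months,
            "day": r.day,
            "day_type": r.day_type,
            "food_id": r.food_id,
            "amount_g": r.amount,
        }
        for d in diaries.values()
        for r in d.records
    ]
    pd.DataFrame(
        rows, columns=["child_id", "age_months", "day", "day_type", "food_id", "amount_g"]
    ).to_csv(path, index=False)


def load_supplement_records(path: str | Path) -> dict[str, list[SupplementRecord]]:
    """Read a supplements CSV (``child_id, day`` + nutrient columns)."""
    df = pd.read_csv(path, dtype={"child_id": str})
    for col in ("child_id", "day"):
        if col not in df.columns:
            raise SchemaError(f"supplement records missing column(s): ['{col}']")
    nutrient_cols = [c for c in df.columns if c in NUTRIENTS]
    unknown = [c for c in df.columns if c not in ("child_id", "day", *NUTRIENTS)]
    if unknown:
        raise SchemaError(f"unknown supplement column(s): {unknown}")
    out: dict[str, list[SupplementRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        amounts = {c: float(getattr(row, c)) for c in nutrient_cols}
        if any(v < 0 for v in amounts.values()):
            raise ValidationError(f"negative supplement amount in row {i + 1}")
        day = int(row.day)
        if day not in (1, 2, 3, 4):
            raise ValidationError(f"supplement day {day} outside 1-4 (row {i + 1})")
        out.setdefault(row.child_id, []).append(
            SupplementRecord(row.child_id, day, NutrientVector(amounts))
        )
    return out


def write_supplement_records(
    supplements: Mapping[str, list[SupplementRecord]], path: str | Path
) -> None:
    rows = []
    for recs in supplements.values():
        for r in recs:
            row = {"child_id": r.child_id, "day": r.day}
            row.update(r.nutrients.as_dict())
            rows.append(row)
    pd.DataFrame(rows, columns=["child_id", "day", *NUTRIENTS]).to_csv(path, index=False)


def load_dri_table(path: str | Path) -> DRITable:
    """Read a DRI configuration (JSON or YAML list of rules)."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if isinstance(raw, dict) and "rules" in raw:
        raw = raw["rules"]
    if not isinstance(raw, list):
        raise ConfigError("DRI configuration must be a list of rules")
    rules = []
    for item in raw:
        try:
            rules.append(
                DRIRule(
                    nutrient=item["nutrient"],
                    age_min_months=int(item["age_min_months"]),
                    age_max_months=int(item["age_max_months"]),
                    rule_type=item["rule_type"],
                    threshold=float(item["threshold"]),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"DRI rule missing field {exc}") from None
    return DRITable(rules)


def default_dri_path() -> Path:
    """Path of the bundled editable DRI configuration (values user-verify)."""
    return Path(__file__).parent / "data" / "dri_2013_cn.yaml"
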