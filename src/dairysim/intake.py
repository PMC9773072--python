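"""Intake computation: liquid milk equivalents, daily means, DRI adequacy.

The unit of analysis is the child's 4-day mean daily intake (diet plus
supplements), assessed with the EAR cut-point method: a child whose mean
observed intake falls strictly below the reference threshold is classified
inadequate. Dairy items other than liquid milk are converted to liquid milk
equivalents (LME) by the ratio of their protein content to a reference
liquid-milk protein content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core import (
    Child,
    ConfigError,
    DAIRY_ONLY,
    Diary,
    DRITable,
    FoodCompositionEntry,
    ReferentialError,
    SupplementRecord,
)
from .nutrients import KCAL_PER_G_FAT, NUTRIENTS, NutrientVector

N_DIARY_DAYS = 4

#: Default reference liquid-milk protein content, g per 100 g.
DEFAULT_REF_MILK_PROTEIN = 3.0


class DomainError(ValueError):
    """An operation was applied outside its domain (e.g. zero energy)."""


# ---------------------------------------------------------------------------
# Liquid milk equivalents
# ---------------------------------------------------------------------------


def lme_of_record(
    record_amount: float,
    entry: FoodCompositionEntry,
    ref_milk_protein: float = DEFAULT_REF_MILK_PROTEIN,
) -> float:
    """Liquid-milk-equivalent grams of one dairy record.

    Liquid milk counts as itself; every other dairy subtype is converted by
    protein ratio: ``amount * protein_per_100g / ref_milk_protein``.
    """
    if not entry.is_dairy:
        raise DomainError(f"food {entry.food_id} is not a dairy product")
    if ref_milk_protein <= 0:
        raise ConfigError("reference milk protein must be positive")
    if entry.dairy_subtype == "LIQUID_MILK":
        return record_amount
    return record_amount * entry.per100g.protein / ref_milk_protein


@dataclass
class DairyProfile:
    """Per-child dairy consumption summary (4-day means)."""

    child_id: str
    lme_total: float
    lme_by_subtype: dict[str, float]
    consumed_any_dairy: bool
    consumed_subtype: dict[str, bool]
    dairy_contribution: NutrientVector


def dairy_profile(
    diary: Diary,
    compositions: Mapping[str, FoodCompositionEntry],
    ref_milk_protein: float = DEFAULT_REF_MILK_PROTEIN,
) -> DairyProfile:
    """Summarise the dairy side of a diary: LME totals, flags, nutrients."""
    lme_by_subtype = {s: 0.0 for s in DAIRY_ONLY}
    consumed = {s: False for s in DAIRY_ONLY}
    contribution = NutrientVector()
    for r in diary.records:
        entry = _entry(compositions, r.food_id)
        if not entry.is_dairy:
            continue
        lme_by_subtype[entry.dairy_subtype] += lme_of_record(
            r.amount, entry, ref_milk_protein
        )
        if r.amount > 0:
            consumed[entry.dairy_subtype] = True
        contribution = contribution + (r.amount / 100.0) * entry.per100g
    lme_by_subtype = {s: v / N_DIARY_DAYS for s, v in lme_by_subtype.items()}
    lme_total = sum(lme_by_subtype.values())
    return DairyProfile(
        child_id=diary.child.child_id,
        lme_total=lme_total,
        lme_by_subtype=lme_by_subtype,
        consumed_any_dairy=any(consumed.values()),
        consumed_subtype=consumed,
        dairy_contribution=(1.0 / N_DIARY_DAYS) * contribution,
    )


# ---------------------------------------------------------------------------
# Mean daily intake
# ---------------------------------------------------------------------------


@dataclass
class ChildIntake:
    """A child's mean daily intake: diet, supplements and dairy breakdown."""

    child: Child
    intake: NutrientVector
    diet_only: NutrientVector
    supplement: NutrientVector
    dairy: DairyProfile


def _entry(
    compositions: Mapping[str, FoodCompositionEntry], food_id: str
) -> FoodCompositionEntry:
    try:
        return compositions[food_id]
    except KeyError:
        raise ReferentialError(f"unknown food_id {food_id!r}") from None


def mean_daily_intake(
    diary: Diary,
    compositions: Mapping[str, FoodCompositionEntry],
    supplements: list[SupplementRecord] | None = None,
    ref_milk_protein: float = DEFAULT_REF_MILK_PROTEIN,
) -> ChildIntake:
    """Compute a child's 4-day mean daily nutrient intake.

    ``diet_only`` is the mean over the 4 diary days of the summed per-food
    contributions (amount/100 x per-100 g composition); supplements declared
    on any day are averaged over the 4 days and added on top.
    """
    diet = NutrientVector()
    for r in diary.records:
        diet = diet + (r.amount / 100.0) * _entry(compositions, r.food_id).per100g
    diet = (1.0 / N_DIARY_DAYS) * diet
    supp = NutrientVector()
    for s in supplements or ():
        supp = supp + s.nutrients
    supp = (1.0 / N_DIARY_DAYS) * supp
    return ChildIntake(
        child=diary.child,
        intake=diet + supp,
        diet_only=diet,
        supplement=supp,
        dairy=dairy_profile(diary, compositions, ref_milk_protein),
    )


def cohort_intakes(
    diaries: Mapping[str, Diary],
    compositions: Mapping[str, FoodCompositionEntry],
    supplements: Mapping[str, list[SupplementRecord]] | None = None,
    ref_milk_protein: float = DEFAULT_REF_MILK_PROTEIN,
) -> list[ChildIntake]:
    supplements = supplements or {}
    return [
        mean_daily_intake(
            d, compositions, supplements.get(cid), ref_milk_protein
        )
        for cid, d in diaries.items()
    ]


# ---------------------------------------------------------------------------
# Derived quantities and DRI classification
# ---------------------------------------------------------------------------


def fat_energy_percent(v: NutrientVector) -> float:
    """Percent of total energy from fat (9 kcal per g of fat)."""
    if v.energy <= 0:
        raise DomainError("fat energy percent undefined at zero energy")
    return 100.0 * KCAL_PER_G_FAT * v.fat / v.energy


def fiber_density(v: NutrientVector) -> float:
    """Dietary fiber per 1,000 kcal of energy."""
    if v.energy <= 0:
        raise DomainError("fiber density undefined at zero energy")
    return 1000.0 * v.fiber / v.energy


@dataclass
class AdequacyFlags:
    """Inadequacy/excess flags for exactly the rules present at this age.

    ``inadequate`` maps rule keys (nutrient names, plus ``fiber_density``) to
    True where the intake falls strictly below the threshold;
    ``fat_excessive`` is present only where an AMDR upper bound is defined.
    """

    child_id: str
    inadequate: dict[str, bool] = field(default_factory=dict)
    fat_excessive: bool | None = None


def classify_adequacy(
    intake: NutrientVector, child: Child, dri: DRITable
) -> AdequacyFlags:
    """Apply every DRI rule defined for the child's age to an intake vector.

    Comparisons are strict: intake exactly at an EAR/AI threshold is
    adequate, fat %E exactly at the AMDR upper bound is not excessive.
    """
    flags = AdequacyFlags(child_id=child.child_id)
    for nutrient, rule in dri.rules_for_age(child.age_months).items():
        if rule.rule_type in ("EAR", "AI"):
            flags.inadequate[nutrient] = intake[nutrient] < rule.threshold
        elif rule.rule_type == "FIBER_DENSITY":
            flags.inadequate[nutrient] = fiber_density(intake) < rule.threshold
        elif rule.rule_type == "AMDR_UPPER":
            flags.fat_excessive = fat_energy_percent(intake) > rule.threshold
    return flags


def cohort_adequacy(
    flag_sets: list[AdequacyFlags],
) -> dict[str, tuple[int, int]]:
    """Count inadequate (and fat-excessive) children per rule.

    Returns ``rule_key -> (count, n_assessed)`` where ``n_assessed`` is the
    number of children for whom that rule was defined.
    """
    counts: dict[str, list[int]] = {}
    for f in flag_sets:
        for key, bad in f.inadequate.items():
            c = counts.setdefault(key, [0, 0])
            c[0] += int(bad)
            c[1] += 1
        if f.fat_excessive is not None:
            c = counts.setdefault("fat_energy_pct", [0, 0])
            c[0] += int(f.fat_excessive)
            c[1] += 1
    return {k: (c[0], c[1]) for k, c in counts.items()}


def intake_frame(cohort: list[ChildIntake]):
    """Tidy per-child intake table: one column per nutrient plus LME."""
    import pandas as pd

    rows = []
    for ci in cohort:
        row = {
            "child_id": ci.child.child_id,
            "age_months": ci.child.age_months,
            "age_group": ci.child.age_group,
        }
        row.update(ci.intake.as_dict())
        row["lme_total"] = ci.dairy.lme_total
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["child_id", "age_months", "age_group", *NUTRIENTS, "lme_total"],
    )
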