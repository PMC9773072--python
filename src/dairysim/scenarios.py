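"""The five dairy simulation models: substitution and top-up scenarios.

Scenario 1 (models 1-3) replaces each child's entire dairy intake with an
equal liquid-equivalent volume of a single substitute food (soymilk, cow's
milk, or reconstituted FMP-PSC). Scenario 2 (models 4-5) adds cow's milk or
FMP-PSC only to children below the recommended dairy amount (350 g/day LME),
raising each exactly to the recommendation; children at or above it are left
untouched. Supplements and non-dairy foods are never altered.

Substitution operates on the child-level mean dairy contribution; by
linearity of the intake computation this equals a record-by-record rebuild
of the diary, which the test-suite verifies against an independent
record-level oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .core import ConfigError, DRITable, FoodCompositionEntry
from .intake import (
    AdequacyFlags,
    ChildIntake,
    classify_adequacy,
    cohort_adequacy,
)
from .nutrients import NutrientVector

MODES = ("SUBSTITUTE", "TOPUP")

#: Recommended daily dairy intake for preschool children, g/d LME.
DEFAULT_TARGET_AMOUNT = 350.0


@dataclass(frozen=True)
class ScenarioModel:
    """One of the five simulation models.

    ``substitute.per100g`` is interpreted per 100 g of liquid(-equivalent)
    product, so matching-volume replacement and topping up to g/day targets
    share one axis for all substitutes.
    """

    model_id: int
    mode: str
    substitute: FoodCompositionEntry
    target_amount: float = DEFAULT_TARGET_AMOUNT

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown scenario mode {self.mode!r}")
        if not 1 <= self.model_id <= 5:
            raise ConfigError(f"model_id {self.model_id} outside 1-5")
        if self.mode == "TOPUP" and self.target_amount <= 0:
            raise ConfigError("top-up target amount must be positive")


@dataclass
class SimulatedIntake:
    child_id: str
    model_id: int
    intake_post: NutrientVector
    delta_energy: float
    lme_post: float


def substitute_dairy(ci: ChildIntake, m: ScenarioModel) -> SimulatedIntake:
    """Replace all dairy with a matching volume of the substitute food."""
    if m.mode != "SUBSTITUTE":
        raise ConfigError(f"model {m.model_id} is not a substitution model")
    lme = ci.dairy.lme_total
    post = (
        ci.intake - ci.dairy.dairy_contribution + (lme / 100.0) * m.substitute.per100g
    ).clipped()
    return SimulatedIntake(
        child_id=ci.child.child_id,
        model_id=m.model_id,
        intake_post=post,
        delta_energy=post.energy - ci.intake.energy,
        lme_post=lme,
    )


def topup_dairy(ci: ChildIntake, m: ScenarioModel) -> SimulatedIntake:
    """Add substitute up to the recommended amount; never remove intake."""
    if m.mode != "TOPUP":
        raise ConfigError(f"model {m.model_id} is not a top-up model")
    lme = ci.dairy.lme_total
    add = max(0.0, m.target_amount - lme)
    post = ci.intake + (add / 100.0) * m.substitute.per100g
    return SimulatedIntake(
        child_id=ci.child.child_id,
        model_id=m.model_id,
        intake_post=post,
        delta_energy=post.energy - ci.intake.energy,
        lme_post=max(lme, m.target_amount),
    )


def apply_model(ci: ChildIntake, m: ScenarioModel) -> SimulatedIntake:
    if m.mode == "SUBSTITUTE":
        return substitute_dairy(ci, m)
    return topup_dairy(ci, m)


@dataclass
class ScenarioResult:
    """Per-child simulated intakes plus post-simulation adequacy flags."""

    model: ScenarioModel
    simulated: list[SimulatedIntake]
    flags: list[AdequacyFlags]

    def adequacy_counts(self) -> dict[str, tuple[int, int]]:
        return cohort_adequacy(self.flags)


def run_scenario(
    cohort: list[ChildIntake], m: ScenarioModel, dri: DRITable
) -> ScenarioResult:
    """Apply a model to every child and reclassify adequacy after it."""
    if not cohort:
        raise ValueError("empty cohort")
    simulated = [apply_model(ci, m) for ci in cohort]
    flags = [
        classify_adequacy(sim.intake_post, ci.child, dri)
        for ci, sim in zip(cohort, simulated)
    ]
    return ScenarioResult(model=m, simulated=simulated, flags=flags)


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------


def default_scenario_path() -> Path:
    return Path(__file__).parent / "data" / "scenarios_default.yaml"


def load_scenario_config(
    path: str | Path | None = None,
    compositions: Mapping[str, FoodCompositionEntry] | None = None,
) -> tuple[list[ScenarioModel], float]:
    """Load scenario models from YAML.

    Returns the model list and the configured reference liquid-milk protein
    content. A model's substitute is either a key into the file's
    ``substitutes`` section (inline per-100 g composition) or a
    ``substitute_food_id`` resolved against a composition table.
    """
    path = Path(path) if path is not None else default_scenario_path()
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    target_default = float(raw.get("target_amount", DEFAULT_TARGET_AMOUNT))
    ref_protein = float(raw.get("reference_milk_protein", 3.0))
    inline: dict[str, FoodCompositionEntry] = {}
    for key, spec in (raw.get("substitutes") or {}).items():
        inline[key] = FoodCompositionEntry(
            food_id=key,
            name=spec.get("name", key),
            dairy_subtype="LIQUID_MILK",
            per100g=NutrientVector(spec["per100g"]),
        )
    models = []
    for item in raw["models"]:
        sub_key = item.get("substitute")
        if sub_key in inline:
            substitute = inline[sub_key]
        elif compositions is not None and item.get("substitute_food_id") in compositions:
            substitute = compositions[item["substitute_food_id"]]
        else:
            raise ConfigError(
                f"model {item.get('model_id')}: unknown substitute {sub_key!r}"
            )
        models.append(
            ScenarioModel(
                model_id=int(item["model_id"]),
                mode=item["mode"],
                substitute=substitute,
                target_amount=float(item.get("target_amount", target_default)),
            )
        )
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate model_id in scenario configuration")
    return models, ref_protein
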