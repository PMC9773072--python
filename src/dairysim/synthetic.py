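"""Synthetic diet-survey cohort generator.

Emulates the structure of a 4-day online-diary dairy survey of Chinese
preschool children: three age strata (default 224/226/226 children aged
37-48, 49-60 and 61-72 months), ~92% dairy consumers, a right-skewed
liquid-milk-equivalent (LME) distribution calibrated to the survey's
quartiles (median 174 g/d, IQR ~85-256 among consumers), an age-declining
milk-powder subtype mix, ~41% dietary-supplement users, zero-inflated
vitamin D and a heavy-tailed two-component iodine distribution.

Fidelity targets are structural (the consumption marginals), not
nutritional: the background (non-dairy) diet is drawn from a generated
60-food pool with plausible order-of-magnitude compositions, so per-nutrient
cohort medians are plausible but are not calibrated to any external survey.

All randomness flows through one ``numpy`` generator stream seeded from
``CohortSpec.seed``, making every output byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .core import (
    Child,
    ConfigError,
    DAIRY_ONLY,
    Diary,
    DietRecord,
    FoodCompositionEntry,
    SupplementRecord,
)
from .intake import DomainError
from .nutrients import NUTRIENTS, NutrientVector

_Z75 = float(sps.norm.ppf(0.75))  # 0.6745...


def calibrate_lognormal(median: float, p25: float, p75: float) -> tuple[float, float]:
    """Fit (mu, sigma) of a lognormal to three quartiles.

    ``mu = ln(median)`` exactly; ``sigma`` minimises the squared error of
    the log 25th/75th percentiles, i.e. the average of the two one-sided
    sigma estimates.
    """
    if not 0 < p25 < median < p75:
        raise DomainError("quartiles must satisfy 0 < p25 < median < p75")
    mu = float(np.log(median))
    s_lo = (mu - np.log(p25)) / _Z75
    s_hi = (np.log(p75) - mu) / _Z75
    return mu, float((s_lo + s_hi) / 2.0)


@dataclass
class CohortSpec:
    """Generation parameters; defaults are the surveyed study conditions."""

    n_per_age_group: dict[str, int] = field(
        default_factory=lambda: {"37-48": 224, "49-60": 226, "61-72": 226}
    )
    dairy_consumer_prob: dict[str, float] = field(
        default_factory=lambda: {"37-48": 0.9375, "49-60": 0.9241, "61-72": 0.9152}
    )
    # marginal (all-children) subtype consumption probabilities per age group
    subtype_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "LIQUID_MILK": {"37-48": 0.5446, "49-60": 0.5973, "61-72": 0.6283},
            "MILK_POWDER": {"37-48": 0.5000, "49-60": 0.4204, "61-72": 0.3097},
            "YOGURT": {"37-48": 0.3393, "49-60": 0.3584, "61-72": 0.3496},
            "OTHER_DAIRY": {"37-48": 0.1964, "49-60": 0.1593, "61-72": 0.1681},
        }
    )
    # consumer-conditional LME quartiles, g/d
    lme_median: float = 174.0
    lme_p25: float = 84.61
    lme_p75: float = 255.70
    supplement_user_prob: float = 0.411
    n_background_foods: int = 60
    foods_per_day: tuple[int, int] = (8, 15)
    ref_milk_protein: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_age_group.values()):
            raise ConfigError("n per age group must be positive")
        probs = [*self.dairy_consumer_prob.values(), self.supplement_user_prob]
        for sub in self.subtype_probs.values():
            probs.extend(sub.values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    diaries: dict[str, Diary]
    supplements: dict[str, list[SupplementRecord]]
    compositions: dict[str, FoodCompositionEntry]
    truth: dict[str, dict]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import core

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "diet": outdir / "diet_records.csv",
            "supplements": outdir / "supplements.csv",
            "compositions": outdir / "compositions.csv",
            "truth": outdir / "truth.json",
        }
        core.write_diet_records(self.diaries, paths["diet"])
        core.write_supplement_records(self.supplements, paths["supplements"])
        core.write_composition_table(self.compositions, paths["compositions"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# Food pool
# ---------------------------------------------------------------------------

# Fixed dairy compositions (per 100 g as consumed; powder per 100 g powder).
_DAIRY_FOODS = {
    "dairy_liquid_milk": ("Liquid milk", "LIQUID_MILK", {
        "energy": 62, "carbohydrate": 4.8, "protein": 3.0, "fat": 3.4,
        "calcium": 107, "iron": 0.3, "zinc": 0.42, "iodine": 1.9,
        "potassium": 120, "vitamin_a": 24, "vitamin_b1": 0.03,
        "vitamin_b2": 0.14, "vitamin_b3": 0.1, "vitamin_b6": 0.04,
        "vitamin_b9": 5, "vitamin_b12": 0.3, "vitamin_c": 1,
    }),
    "dairy_milk_powder": ("Formula milk powder", "MILK_POWDER", {
        "energy": 470, "carbohydrate": 55, "protein": 15, "fat": 20,
        "fiber": 2.5, "dha": 45, "calcium": 600, "iron": 6.5, "zinc": 6,
        "iodine": 27, "potassium": 450, "vitamin_a": 280, "vitamin_b1": 0.35,
        "vitamin_b2": 0.7, "vitamin_b3": 3.0, "vitamin_b6": 0.25,
        "vitamin_b9": 90, "vitamin_b12": 1.6, "vitamin_c": 50, "vitamin_d": 6.5,
    }),
    "dairy_yogurt": ("Yogurt", "YOGURT", {
        "energy": 72, "carbohydrate": 9.3, "protein": 2.5, "fat": 2.7,
        "calcium": 118, "iron": 0.4, "zinc": 0.53, "iodine": 0.9,
        "potassium": 150, "vitamin_a": 26, "vitamin_b1": 0.03,
        "vitamin_b2": 0.15, "vitamin_b3": 0.2, "vitamin_b6": 0.02,
        "vitamin_b9": 6, "vitamin_b12": 0.3, "vitamin_c": 1,
    }),
    "dairy_cheese": ("Cheese", "OTHER_DAIRY", {
        "energy": 328, "carbohydrate": 3.5, "protein": 25.7, "fat": 23.5,
        "calcium": 799, "iron": 2.4, "zinc": 6.97, "iodine": 30,
        "potassium": 75, "vitamin_a": 152, "vitamin_b1": 0.06,
        "vitamin_b2": 0.91, "vitamin_b3": 0.6, "vitamin_b6": 0.08,
        "vitamin_b9": 18, "vitamin_b12": 1.5,
    }),
}

# Median (per 100 g) and lognormal spread of background-food nutrient
# densities; chosen so typical 4-day diaries land in plausible daily ranges
# for a preschool diet (roughly 1,000 kcal/d, 30 g/d protein, ...).
_BACKGROUND_MEDIANS = {
    "energy": (110.0, 0.7),
    "carbohydrate": (13.0, 0.9),
    "protein": (3.0, 0.9),
    "fat": (3.5, 1.0),
    "fiber": (0.45, 1.0),
    "dha": (0.8, 1.5),
    "calcium": (18.0, 1.0),
    "iron": (1.0, 0.8),
    "zinc": (0.5, 0.8),
    "iodine": (1.6, 1.0),
    "potassium": (100.0, 0.7),
    "vitamin_a": (22.0, 1.2),
    "vitamin_b1": (0.035, 0.8),
    "vitamin_b2": (0.05, 0.8),
    "vitamin_b3": (0.75, 0.8),
    "vitamin_b6": (0.08, 0.8),
    "vitamin_b9": (12.0, 0.9),
    "vitamin_b12": (0.15, 1.3),
    "vitamin_c": (5.0, 1.5),
    # vitamin D deliberately absent from ordinary foods: dietary vitamin D
    # comes only from fortified dairy (milk powder) and supplements, which
    # produces the zero-inflated distribution seen in surveys
    "vitamin_d": (0.0, 0.0),
}

# Seaweed/iodized-source food eaten only by "high-iodine household"
# children; with the low ordinary-food iodine background this yields the
# two-component, heavy-tailed iodine distribution surveys report.
_SEAWEED = ("Kelp/seaweed (iodine-rich)", "NONE", {
    "energy": 15, "carbohydrate": 2.0, "protein": 1.2, "fiber": 0.5,
    "iodine": 800.0, "potassium": 80, "calcium": 45, "iron": 0.9,
})
_HIGH_IODINE_PROB = 0.42


def _background_pool(rng: np.random.Generator, n: int) -> dict[str, FoodCompositionEntry]:
    pool: dict[str, FoodCompositionEntry] = {}
    for i in range(n):
        comp = {}
        for nutrient, (med, sigma) in _BACKGROUND_MEDIANS.items():
            if med == 0:
                comp[nutrient] = 0.0
            else:
                comp[nutrient] = float(med * rng.lognormal(0.0, sigma))
        fid = f"bg_{i:03d}"
        pool[fid] = FoodCompositionEntry(fid, f"Background food {i}", "NONE",
                                         NutrientVector(comp))
    return pool


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_POWDER_GRAMS_PER_LME = None  # derived per spec at runtime


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate diaries, supplements, a composition table and the truth file.

    Deterministic for a fixed ``spec.seed``: running twice yields identical
    records. Per child, a dairy-consumer flag and subtype flags are drawn,
    the daily LME is drawn from the lognormal calibrated to the spec
    quartiles and split across the child's subtypes; subtype grams follow
    from the protein-ratio conversion. Background foods and supplements are
    layered on top; the latent per-child truth (true LME, subtype split,
    consumer flags) is retained for recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mu, sigma = calibrate_lognormal(spec.lme_median, spec.lme_p25, spec.lme_p75)

    compositions = {
        fid: FoodCompositionEntry(fid, name, subtype, NutrientVector(comp))
        for fid, (name, subtype, comp) in _DAIRY_FOODS.items()
    }
    compositions.update(_background_pool(rng, spec.n_background_foods))
    bg_ids = sorted(fid for fid in compositions if fid.startswith("bg_"))
    compositions["seaweed"] = FoodCompositionEntry(
        "seaweed", _SEAWEED[0], _SEAWEED[1], NutrientVector(_SEAWEED[2])
    )

    subtype_food = {
        "LIQUID_MILK": "dairy_liquid_milk",
        "MILK_POWDER": "dairy_milk_powder",
        "YOGURT": "dairy_yogurt",
        "OTHER_DAIRY": "dairy_cheese",
    }
    # grams of product delivering 1 g LME, by protein ratio
    grams_per_lme = {
        s: 1.0
        if s == "LIQUID_MILK"
        else spec.ref_milk_protein / compositions[subtype_food[s]].per100g.protein
        for s in DAIRY_ONLY
    }

    diaries: dict[str, Diary] = {}
    supplements: dict[str, list[SupplementRecord]] = {}
    truth: dict[str, dict] = {}
    idx = 0
    for group, n in spec.n_per_age_group.items():
        lo = int(group.split("-")[0])
        hi = int(group.split("-")[1])
        for _ in range(n):
            idx += 1
            cid = f"c{idx:04d}"
            age = int(rng.integers(lo, hi + 1))
            child = Child(cid, age)
            # day layout: days 1-4, a random 2 of them weekend
            weekend_days = set(rng.choice(4, size=2, replace=False) + 1)
            day_types = {
                d: ("weekend" if d in weekend_days else "working") for d in (1, 2, 3, 4)
            }
            records: list[DietRecord] = []

            # ---- dairy side ------------------------------------------
            is_consumer = rng.random() < spec.dairy_consumer_prob[group]
            subtype_grams_daily: dict[str, float] = {}
            lme = 0.0
            if is_consumer:
                p_any = spec.dairy_consumer_prob[group]
                flags = {
                    s: rng.random() < min(1.0, spec.subtype_probs[s][group] / p_any)
                    for s in DAIRY_ONLY
                }
                if not any(flags.values()):
                    flags["LIQUID_MILK"] = True
                active = [s for s in DAIRY_ONLY if flags[s]]
                lme = float(rng.lognormal(mu, sigma))
                shares = rng.dirichlet(np.full(len(active), 2.0))
                day_w = rng.dirichlet(np.full(4, 8.0)) * 4.0
                for s, share in zip(active, shares):
                    daily_lme = lme * share
                    grams = daily_lme * grams_per_lme[s]
                    subtype_grams_daily[s] = grams
                    for d in (1, 2, 3, 4):
                        records.append(
                            DietRecord(cid, d, day_types[d], subtype_food[s],
                                       grams * float(day_w[d - 1]))
                        )

            # ---- background diet -------------------------------------
            for d in (1, 2, 3, 4):
                k = int(rng.integers(spec.foods_per_day[0], spec.foods_per_day[1] + 1))
                foods = rng.choice(bg_ids, size=k, replace=False)
                grams = np.clip(rng.lognormal(np.log(60.0), 0.5, size=k), 5.0, 300.0)
                for fid, g in zip(foods, grams):
                    records.append(DietRecord(cid, d, day_types[d], str(fid), float(g)))

            # high-iodine household: seaweed-like food on two diary days
            if rng.random() < _HIGH_IODINE_PROB:
                for d in sorted(int(x) + 1 for x in rng.choice(4, 2, replace=False)):
                    records.append(
                        DietRecord(cid, d, day_types[d], "seaweed",
                                   float(rng.uniform(10.0, 60.0)))
                    )

            diaries[cid] = Diary(child, records)

            # ---- supplements -----------------------------------------
            if rng.random() < spec.supplement_user_prob:
                dose = {}
                if rng.random() < 0.6:
                    dose["vitamin_d"] = float(rng.uniform(2.5, 10.0))
                if rng.random() < 0.4:
                    dose["calcium"] = float(rng.uniform(50.0, 300.0))
                if rng.random() < 0.4:
                    dose["vitamin_c"] = float(rng.uniform(20.0, 100.0))
                if rng.random() < 0.2:
                    dose["iron"] = float(rng.uniform(1.0, 5.0))
                if rng.random() < 0.2:
                    dose["zinc"] = float(rng.uniform(1.0, 5.0))
                if not dose:
                    dose["vitamin_c"] = float(rng.uniform(20.0, 100.0))
                days = (1, 2, 3, 4) if rng.random() < 0.7 else tuple(
                    int(d) for d in sorted(rng.choice(4, size=2, replace=False) + 1)
                )
                supplements[cid] = [
                    SupplementRecord(cid, d, NutrientVector(dose)) for d in days
                ]

            truth[cid] = {
                "age_months": age,
                "age_group": group,
                "consumer": bool(is_consumer),
                "lme_total": lme,
                "subtype_grams_daily": subtype_grams_daily,
            }

    return SyntheticCohort(diaries, supplements, compositions, truth)
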