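"""Model/Results surface tying the pipeline together.

:class:`DairyScenarioModel` is constructed from diaries, a food composition
table, a DRI rule table and a scenario list; :meth:`~DairyScenarioModel.fit`
computes baseline intakes and adequacy, applies every scenario model, runs
the paired/between-model tests, and returns a
:class:`DairyScenarioResults` carrying per-child values, cohort summaries
and table renderers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import core, intake, scenarios, stats
from .core import Diary, DRITable, FoodCompositionEntry, SupplementRecord
from .intake import AdequacyFlags, ChildIntake
from .nutrients import NUTRIENTS
from .scenarios import ScenarioModel, ScenarioResult


@dataclass(frozen=True)
class Conventions:
    """Reporting/test conventions (defaults reproduce SPSS semantics)."""

    quantile_method: str = "type6"
    wilcoxon_method: str = "spss"
    mcnemar_method: str = "auto"
    percent_ndigits: int = 2
    alpha: float = 0.05

    def describe(self) -> dict[str, object]:
        return {
            "quantile_method": self.quantile_method,
            "wilcoxon_method": self.wilcoxon_method,
            "mcnemar_method": self.mcnemar_method,
            "rounding": f"half-up, {self.percent_ndigits} dp",
            "alpha": self.alpha,
        }


#: Contrast letters of the between-model significance scheme.
CONTRASTS: tuple[tuple[str, object, object], ...] = (
    ("a", 1, "baseline"),
    ("b", 2, "baseline"),
    ("c", 3, "baseline"),
    ("d", 2, 1),
    ("e", 3, 1),
    ("f", 3, 2),
    ("g", 4, "baseline"),
    ("h", 5, "baseline"),
    ("i", 5, 4),
)


class DairyScenarioModel:
    """Dairy substitution/top-up simulation on a surveyed cohort.

    Parameters
    ----------
    diaries
        Per-child validated 4-day diaries.
    compositions
        ``food_id`` -> per-100 g composition lookup.
    dri
        DRI rule table covering every child's age.
    supplements
        Optional per-child supplement records.
    scenario_models
        The scenario list; defaults to the bundled five-model configuration.
    """

    def __init__(
        self,
        diaries: Mapping[str, Diary],
        compositions: Mapping[str, FoodCompositionEntry],
        dri: DRITable,
        supplements: Mapping[str, list[SupplementRecord]] | None = None,
        scenario_models: list[ScenarioModel] | None = None,
        ref_milk_protein: float = intake.DEFAULT_REF_MILK_PROTEIN,
        conventions: Conventions = Conventions(),
    ) -> None:
        if not diaries:
            raise ValueError("empty cohort")
        self.diaries = dict(diaries)
        self.compositions = dict(compositions)
        self.dri = dri
        self.supplements = dict(supplements or {})
        if scenario_models is None:
            scenario_models, ref_default = scenarios.load_scenario_config()
            if ref_milk_protein is None:
                ref_milk_protein = ref_default
        self.scenario_models = scenario_models
        self.ref_milk_protein = ref_milk_protein
        self.conventions = conventions
        self._check_dri_coverage()

    @classmethod
    def from_files(
        cls,
        diet_csv: str | Path,
        composition_csv: str | Path,
        dri_path: str | Path | None = None,
        supplements_csv: str | Path | None = None,
        scenario_yaml: str | Path | None = None,
        **kwargs,
    ) -> "DairyScenarioModel":
        compositions = core.load_composition_table(composition_csv)
        diaries = core.load_diet_records(diet_csv, compositions)
        dri = core.load_dri_table(dri_path or core.default_dri_path())
        supplements = (
            core.load_supplement_records(supplements_csv) if supplements_csv else None
        )
        models, ref_protein = scenarios.load_scenario_config(
            scenario_yaml, compositions
        )
        kwargs.setdefault("ref_milk_protein", ref_protein)
        return cls(diaries, compositions, dri, supplements, models, **kwargs)

    def _check_dri_coverage(self) -> None:
        missing = set()
        nutrients_with_rules = {
            r.nutrient for r in self.dri.rules
        }
        for d in self.diaries.values():
            age = d.child.age_months
            for nutrient in nutrients_with_rules:
                # a nutrient ruled for *some* band must cover every child
                if self.dri.lookup(nutrient, age) is None and nutrient not in (
                    "fat_energy_pct",
                ):
                    missing.add((nutrient, age))
        if missing:
            raise core.ConfigError(
                f"DRI coverage gaps (nutrient, age_months): {sorted(missing)}"
            )

    def fit(self) -> "DairyScenarioResults":
        cohort = intake.cohort_intakes(
            self.diaries, self.compositions, self.supplements, self.ref_milk_protein
        )
        baseline_flags = [
            intake.classify_adequacy(ci.intake, ci.child, self.dri) for ci in cohort
        ]
        results = {
            m.model_id: scenarios.run_scenario(cohort, m, self.dri)
            for m in self.scenario_models
        }
        return DairyScenarioResults(self, cohort, baseline_flags, results)


class DairyScenarioResults:
    """Fitted before/after cohort: estimates, tests and table renderers."""

    def __init__(
        self,
        model: DairyScenarioModel,
        cohort: list[ChildIntake],
        baseline_flags: list[AdequacyFlags],
        scenario_results: dict[int, ScenarioResult],
    ) -> None:
        self.model = model
        self.cohort = cohort
        self.baseline_flags = baseline_flags
        self.scenario_results = scenario_results
        self.conventions = model.conventions

    # -- accessors ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.cohort)

    def intake_frame(self) -> pd.DataFrame:
        return intake.intake_frame(self.cohort)

    def nutrient_values(self, nutrient: str, group: int | str = "baseline") -> np.ndarray:
        """Per-child values of a nutrient (or derived quantity) per group.

        ``nutrient`` may also be ``fat_energy_pct`` or ``fiber_density``.
        """
        derived = {
            "fat_energy_pct": intake.fat_energy_percent,
            "fiber_density": intake.fiber_density,
        }
        if group == "baseline":
            vectors = [ci.intake for ci in self.cohort]
        else:
            vectors = [s.intake_post for s in self.scenario_results[int(group)].simulated]
        if nutrient in derived:
            return np.array([derived[nutrient](v) for v in vectors])
        return np.array([v[nutrient] for v in vectors])

    def fat_energy_values(self, group: int | str = "baseline") -> np.ndarray:
        if group == "baseline":
            return np.array(
                [intake.fat_energy_percent(ci.intake) for ci in self.cohort]
            )
        sims = self.scenario_results[int(group)].simulated
        return np.array([intake.fat_energy_percent(s.intake_post) for s in sims])

    def energy_changes(self, model_id: int) -> np.ndarray:
        return np.array(
            [s.delta_energy for s in self.scenario_results[model_id].simulated]
        )

    def lme_values(self) -> np.ndarray:
        return np.array([ci.dairy.lme_total for ci in self.cohort])

    def inadequacy_flags(
        self, rule_key: str, group: int | str = "baseline"
    ) -> list[bool]:
        flag_sets = (
            self.baseline_flags
            if group == "baseline"
            else self.scenario_results[int(group)].flags
        )
        if rule_key == "fat_energy_pct":
            return [f.fat_excessive for f in flag_sets if f.fat_excessive is not None]
        return [f.inadequate[rule_key] for f in flag_sets if rule_key in f.inadequate]

    def adequacy_counts(self, group: int | str = "baseline") -> dict[str, tuple[int, int]]:
        flag_sets = (
            self.baseline_flags
            if group == "baseline"
            else self.scenario_results[int(group)].flags
        )
        return intake.cohort_adequacy(flag_sets)

    # -- tests ----------------------------------------------------------
    def paired_value_test(
        self, nutrient: str, group_a: int | str, group_b: int | str
    ) -> stats.PairedTestResult:
        """Wilcoxon signed-rank between two groups' per-child values."""
        a = self.nutrient_values(nutrient, group_a)
        b = self.nutrient_values(nutrient, group_b)
        try:
            return stats.wilcoxon_signed_rank(
                a, b, method=self.conventions.wilcoxon_method
            )
        except intake.DomainError:
            return stats.PairedTestResult("WILCOXON_SR", 0.0, 1.0, 0, degenerate=True)

    def paired_flag_test(
        self, rule_key: str, group_a: int | str, group_b: int | str
    ) -> stats.PairedTestResult:
        """McNemar between two groups' inadequacy flags."""
        return stats.mcnemar(
            self.inadequacy_flags(rule_key, group_a),
            self.inadequacy_flags(rule_key, group_b),
            method=self.conventions.mcnemar_method,
        )

    def contrast_letters(self, nutrient: str, model_id: int, kind: str = "value") -> str:
        """Significance letters (a-i) attached to one model's cell."""
        letters = []
        for letter, m, ref in CONTRASTS:
            if m != model_id:
                continue
            if kind == "value":
                res = self.paired_value_test(nutrient, ref, m)
            else:
                res = self.paired_flag_test(nutrient, ref, m)
            if res.p_value < self.conventions.alpha and not res.degenerate:
                letters.append(letter)
        return "".join(letters)

    def energy_change_test(self, scenario: int) -> stats.GroupTestResult:
        """Between-model energy-change comparison within one scenario."""
        if scenario == 1:
            return stats.kruskal_wallis(
                self.energy_changes(1), self.energy_changes(2), self.energy_changes(3)
            )
        if scenario == 2:
            return stats.mann_whitney(self.energy_changes(4), self.energy_changes(5))
        raise ValueError("scenario must be 1 or 2")

    # -- presentation ----------------------------------------------------
    def quartile_summary(self, values) -> stats.QuartileSummary:
        return stats.quartiles(values, method=self.conventions.quantile_method)

    def table(self, table_id: int) -> pd.DataFrame:
        from . import report

        return report.render_table(self, table_id)

    def summary(self) -> str:
        from . import report

        return report.summary_text(self)

    def to_csv(self, outdir: str | Path) -> list[Path]:
        """Write tidy per-model results CSVs plus the rendered tables."""
        from . import report

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        frame = self.intake_frame()
        p = outdir / "baseline_intakes.csv"
        frame.to_csv(p, index=False)
        written.append(p)
        for mid, res in self.scenario_results.items():
            rows = []
            for sim in res.simulated:
                row = {"child_id": sim.child_id, "model_id": mid,
                       "delta_energy": sim.delta_energy, "lme_post": sim.lme_post}
                row.update({n: sim.intake_post[n] for n in NUTRIENTS})
                rows.append(row)
            p = outdir / f"model_{mid}_intakes.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)
        p = outdir / "tidy_results.csv"
        report.tidy_results(self).to_csv(p, index=False)
        written.append(p)
        for tid in (1, 2, 3, 4, 5, 6):
            p = outdir / f"table_{tid}.csv"
            self.table(tid).to_csv(p, index=False)
            written.append(p)
        p = outdir / "run_header.txt"
        p.write_text(
            "\n".join(f"{k}: {v}" for k, v in self.conventions.describe().items())
            + f"\nn: {self.n}\n"
        )
        written.append(p)
        return written
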