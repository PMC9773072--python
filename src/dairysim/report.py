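"""Renderers reproducing the survey-report table layouts.

Six tables: (1) dairy intake before simulation by age group; (2) total
energy and energy changes per model; (3) macronutrients; (4) energy
contribution from fat by the two older age strata; (5) minerals;
(6) vitamins. Cells follow the reporting conventions: ``P50 (P25, P75)``
with 2-dp values, ``N (%)`` via the half-up percent convention, p-values
below 0.001 rendered ``<0.001``, and superscript-style contrast letters
a-i attached where the corresponding paired test is significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intake, stats
from .core import AGE_GROUPS

MACRONUTRIENT_ROWS = (
    ("Carbohydrate (g/d)", "carbohydrate", "carbohydrate"),
    ("Protein (g/d)", "protein", "protein"),
    ("Fat (g/d)", "fat", None),
    ("Dietary fiber (g/d)", "fiber", "fiber_density"),
    ("DHA (mg/d)", "dha", None),
)
MINERAL_ROWS = (
    ("Calcium (mg/d)", "calcium", "calcium"),
    ("Iron (mg/d)", "iron", "iron"),
    ("Zinc (mg/d)", "zinc", "zinc"),
    ("Iodine (ug/d)", "iodine", "iodine"),
    ("Potassium (mg/d)", "potassium", "potassium"),
)
VITAMIN_ROWS = (
    ("Vitamin A (ug RAE/d)", "vitamin_a", "vitamin_a"),
    ("Vitamin B1 (mg/d)", "vitamin_b1", "vitamin_b1"),
    ("Vitamin B2 (mg/d)", "vitamin_b2", "vitamin_b2"),
    ("Vitamin B3 (mg NE/d)", "vitamin_b3", "vitamin_b3"),
    ("Vitamin B6 (mg/d)", "vitamin_b6", "vitamin_b6"),
    ("Vitamin B9 (ug DFE/d)", "vitamin_b9", "vitamin_b9"),
    ("Vitamin B12 (ug/d)", "vitamin_b12", "vitamin_b12"),
    ("Vitamin C (mg/d)", "vitamin_c", "vitamin_c"),
    ("Vitamin D (ug/d)", "vitamin_d", "vitamin_d"),
)

GROUP_LABELS = {
    "baseline": "Before simulation",
    1: "Model 1",
    2: "Model 2",
    3: "Model 3",
    4: "Model 4",
    5: "Model 5",
}


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def n_pct_cell(count: int, n: int) -> str:
    return f"{count} ({stats.percent(count, n):.2f}%)"


def _groups_present(results) -> list:
    return ["baseline"] + sorted(results.scenario_results)


def _value_cell(results, nutrient: str, group) -> str:
    qs = results.quartile_summary(results.nutrient_values(nutrient, group))
    cell = qs.formatted()
    if group != "baseline":
        letters = results.contrast_letters(nutrient, group, kind="value")
        if letters:
            cell += f" ^{letters}"
    return cell


def _flag_cell(results, rule_key: str, group) -> str:
    flags = results.inadequacy_flags(rule_key, group)
    cell = n_pct_cell(sum(flags), len(flags))
    if group != "baseline":
        letters = results.contrast_letters(rule_key, group, kind="flag")
        if letters:
            cell += f" ^{letters}"
    return cell


# ---------------------------------------------------------------------------
# Table renderers
# ---------------------------------------------------------------------------


def table1(results) -> pd.DataFrame:
    """Dairy intakes before simulation, overall and by age stratum."""
    cohort = results.cohort
    groups = [label for label, _, _ in AGE_GROUPS]
    subsets = {"All": cohort}
    for label, lo, hi in AGE_GROUPS:
        subsets[label] = [ci for ci in cohort if lo <= ci.child.age_months < hi]
    target = next(
        (m.target_amount for m in results.model.scenario_models if m.mode == "TOPUP"),
        350.0,
    )

    def flag_row(name, getter):
        row = {"Parameter": name}
        counts = {}
        for label, subset in subsets.items():
            flags = [getter(ci) for ci in subset]
            counts[label] = (sum(flags), len(flags))
            row[label] = n_pct_cell(*counts[label])
        table = [
            [counts[g][0], counts[g][1] - counts[g][0]] for g in groups
        ]
        try:
            row["P"] = format_p(stats.chi_square_independence(table).p_value)
        except intake.DomainError:
            row["P"] = "/"  # degenerate margin (e.g. every child consumes)
        return row

    rows = [
        flag_row("Dairy consumption N (%)", lambda ci: ci.dairy.consumed_any_dairy),
        flag_row("Liquid milk N (%)", lambda ci: ci.dairy.consumed_subtype["LIQUID_MILK"]),
        flag_row("Milk powder N (%)", lambda ci: ci.dairy.consumed_subtype["MILK_POWDER"]),
        flag_row("Yogurt N (%)", lambda ci: ci.dairy.consumed_subtype["YOGURT"]),
        flag_row("Other dairy foods N (%)", lambda ci: ci.dairy.consumed_subtype["OTHER_DAIRY"]),
    ]
    lme_row = {"Parameter": "Liquid milk equivalents (g/d)"}
    for label, subset in subsets.items():
        lme_row[label] = results.quartile_summary(
            [ci.dairy.lme_total for ci in subset]
        ).formatted()
    lme_row["P"] = format_p(
        stats.kruskal_wallis(
            *[[ci.dairy.lme_total for ci in subsets[g]] for g in groups]
        ).p_value
    )
    rows.append(lme_row)
    rows.append(
        flag_row(
            "Below dairy recommendation N (%)",
            lambda ci: ci.dairy.lme_total < target,
        )
    )
    return pd.DataFrame(rows, columns=["Parameter", "All", *groups, "P"])


def table2(results) -> pd.DataFrame:
    """Total energy intake and per-model energy changes."""
    rows = [
        {
            "Group": "Before simulation",
            "Total energy": results.quartile_summary(
                results.nutrient_values("energy")
            ).formatted(),
            "Changes of energy": "/",
            "P": "/",
        }
    ]
    scen_of = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2}
    scen_p = {}
    for scen in (1, 2):
        if all(m in results.scenario_results for m in ([1, 2, 3] if scen == 1 else [4, 5])):
            scen_p[scen] = format_p(results.energy_change_test(scen).p_value)
    for mid in sorted(results.scenario_results):
        scen = scen_of[mid]
        rows.append(
            {
                "Group": f"Model {mid}",
                "Total energy": _value_cell(results, "energy", mid),
                "Changes of energy": results.quartile_summary(
                    results.energy_changes(mid)
                ).formatted(),
                "P": scen_p.get(scen, "/"),
            }
        )
    return pd.DataFrame(rows, columns=["Group", "Total energy", "Changes of energy", "P"])


def _nutrient_block_table(results, row_spec) -> pd.DataFrame:
    rows = []
    for display, nutrient, rule_key in row_spec:
        for group in _groups_present(results):
            rows.append(
                {
                    "Nutrient": display,
                    "Group": GROUP_LABELS[group],
                    "P50 (P25, P75)": _value_cell(results, nutrient, group),
                    "N (%)": _flag_cell(results, rule_key, group) if rule_key else "/",
                }
            )
    return pd.DataFrame(rows, columns=["Nutrient", "Group", "P50 (P25, P75)", "N (%)"])


def table3(results) -> pd.DataFrame:
    return _nutrient_block_table(results, MACRONUTRIENT_ROWS)


def table5(results) -> pd.DataFrame:
    return _nutrient_block_table(results, MINERAL_ROWS)


def table6(results) -> pd.DataFrame:
    return _nutrient_block_table(results, VITAMIN_ROWS)


def table4(results) -> pd.DataFrame:
    """Energy contribution from fat, for strata with an AMDR upper bound."""
    from .model import CONTRASTS

    rows = []
    for label, lo, hi in AGE_GROUPS:
        idx = [
            i
            for i, ci in enumerate(results.cohort)
            if lo <= ci.child.age_months < hi
        ]
        if not idx:
            continue
        flags0 = _subset_flags(results, "baseline", idx)
        if not flags0:
            continue  # no AMDR upper bound configured for this stratum
        for group in _groups_present(results):
            pct_e = results.fat_energy_values(group)[idx]
            qs = results.quartile_summary(pct_e).formatted()
            flags = _subset_flags(results, group, idx)
            cell_n = n_pct_cell(sum(flags), len(flags))
            if group != "baseline":
                v_letters, f_letters = _subset_letters(results, idx, group, CONTRASTS)
                if v_letters:
                    qs += f" ^{v_letters}"
                if f_letters:
                    cell_n += f" ^{f_letters}"
            rows.append(
                {
                    "Age group": label,
                    "Group": GROUP_LABELS[group],
                    "Fat (%E)": qs,
                    "N (%)": cell_n,
                }
            )
    return pd.DataFrame(rows, columns=["Age group", "Group", "Fat (%E)", "N (%)"])


def _subset_flags(results, group, idx) -> list[bool]:
    flag_sets = (
        results.baseline_flags
        if group == "baseline"
        else results.scenario_results[int(group)].flags
    )
    return [
        flag_sets[i].fat_excessive
        for i in idx
        if flag_sets[i].fat_excessive is not None
    ]


def _subset_letters(results, idx, model_id, contrasts) -> tuple[str, str]:
    v_letters, f_letters = [], []
    for letter, m, ref in contrasts:
        if m != model_id:
            continue
        a = results.fat_energy_values(ref)[idx]
        b = results.fat_energy_values(m)[idx]
        try:
            res = stats.wilcoxon_signed_rank(
                a, b, method=results.conventions.wilcoxon_method
            )
            if res.p_value < results.conventions.alpha:
                v_letters.append(letter)
        except intake.DomainError:
            pass
        fa = _subset_flags(results, ref, idx)
        fb = _subset_flags(results, m, idx)
        res = stats.mcnemar(fa, fb, method=results.conventions.mcnemar_method)
        if res.p_value < results.conventions.alpha and not res.degenerate:
            f_letters.append(letter)
    return "".join(v_letters), "".join(f_letters)


_TABLES = {1: table1, 2: table2, 3: table3, 4: table4, 5: table5, 6: table6}


def render_table(results, table_id: int) -> pd.DataFrame:
    try:
        fn = _TABLES[int(table_id)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown table_id {table_id!r} (expected 1-6)") from None
    return fn(results)


def tidy_results(results) -> pd.DataFrame:
    """Long-format results: one row per (variable, group)."""
    rows = []
    specs = [("energy", "energy", None)] + [
        (n, n, k) for _, n, k in (*MACRONUTRIENT_ROWS, *MINERAL_ROWS, *VITAMIN_ROWS)
        if n != "energy"
    ]
    for _, nutrient, rule_key in specs:
        for group in _groups_present(results):
            values = results.nutrient_values(nutrient, group)
            qs = results.quartile_summary(values)
            row = {
                "variable": nutrient,
                "group": GROUP_LABELS[group],
                "p50": qs.p50,
                "p25": qs.p25,
                "p75": qs.p75,
                "n": len(values),
                "count_inadequate": np.nan,
                "pct_inadequate": np.nan,
                "test": "",
                "statistic": np.nan,
                "p": np.nan,
            }
            if rule_key:
                flags = results.inadequacy_flags(rule_key, group)
                row["count_inadequate"] = sum(flags)
                row["pct_inadequate"] = stats.percent(sum(flags), len(flags))
            if group != "baseline":
                res = results.paired_value_test(nutrient, "baseline", group)
                row["test"] = res.test_name
                row["statistic"] = res.statistic
                row["p"] = res.p_value
            rows.append(row)
    return pd.DataFrame(rows)


def summary_text(results) -> str:
    """Compact fitted summary: cohort, conventions and headline table."""
    lines = [
        "Dairy scenario simulation results",
        "=" * 50,
        f"children: {results.n}",
        f"scenario models: {sorted(results.scenario_results)}",
    ]
    for k, v in results.conventions.describe().items():
        lines.append(f"{k}: {v}")
    lme = results.lme_values()
    consumers = sum(1 for ci in results.cohort if ci.dairy.consumed_any_dairy)
    lines.append(
        f"dairy consumers: {n_pct_cell(consumers, results.n)}"
    )
    lines.append(
        "LME g/d: "
        + results.quartile_summary(lme).formatted()
    )
    lines.append("")
    lines.append("Total energy (kcal/d):")
    lines.append(table2(results).to_string(index=False))
    return "\n".join(lines)
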