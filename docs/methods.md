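# Methods

## Unit of analysis and intake model

The analysis unit is the child's 4-day mean daily intake. Each diary covers
days 1–4 (two working days, two weekend days); per-food contributions are
`grams / 100 × per-100 g composition`, summed within days and averaged over
the four days. Supplements declared on any diary day are averaged over the
same four days and added on top, for every nutrient they declare — no
frequency normalisation is applied, so a supplement taken once contributes
a quarter of its dose to the daily mean. The intake vector is energy (kcal)
plus 19 nutrients with fixed units (g for macronutrients and fiber; mg or
µg for micronutrients; µg RAE, mg NE and µg DFE for vitamins A, B3 and B9).
Units are never inferred from files: input columns must carry the canonical
names.

No usual-intake (within-person variance) adjustment is made — adequacy is
assessed by the plain EAR cut-point on observed 4-day means. This
overstates the tails of the usual-intake distribution relative to NCI/SPADE
style methods; it is the convention of the survey reports this package
mirrors, and scenario *differences* (the quantity of interest) are less
affected than levels.

## Liquid milk equivalents

Dairy subtypes are LIQUID_MILK, MILK_POWDER, YOGURT and OTHER_DAIRY.
Liquid milk counts as itself; every other subtype converts by protein
ratio against a reference liquid-milk protein content (default
3.0 g/100 g, configurable — the conversion basis is protein for all
subtypes, including cheese). Grams and millilitres are treated as
equivalent for dairy liquids (no density correction), so the 350 g/day
recommendation and "matching volume" substitution share one axis.

## DRI classification

Rules live in an editable YAML file (`data/dri_2013_cn.yaml`, values
marked user-verify, since the engine must not hard-code thresholds), one
rule per nutrient × half-open age band in months:

* `EAR` / `AI`: inadequate iff intake **strictly below** the threshold;
* `FIBER_DENSITY`: inadequate iff `1000 × fiber / energy < 10 g/1,000 kcal`;
* `AMDR_UPPER`: fat surplus iff `100 × 9 × fat / energy` **strictly above**
  the bound (configured from 49 months only, so the fat %E table covers the
  two older strata).

Boundary equality is adequate / non-excessive everywhere. Children aged
36–47 months use the 1–3 y reference band, 48 months onward the 4–6 y
band. Flags exist exactly for the rules defined at the child's age;
nutrients without a rule emit no flag.

## Scenario models

* **Substitution (models 1–3).** `intake_post = intake − dairy_contribution
  + (LME/100) × substitute_per100g`. The substitute composition is per
  100 g liquid(-equivalent) product; reconstituted FMP-PSC uses the same
  axis. Volume is conserved child-by-child. Tiny negative residues (below
  1e-9 relative) are clipped to zero; anything larger raises an internal
  consistency error.
* **Top-up (models 4–5).** `add = max(0, 350 − LME)`; the substitute is
  added on top and nothing is ever removed from children at or above the
  recommendation (cap-free). Supplements are never altered by any
  scenario.

Substitution operates on child-level mean dairy contributions rather than
record-by-record; by linearity of the intake computation the two are
identical, and the test suite verifies the vector engine against an
independent record-level re-simulation oracle to 1e-9 relative.

Default substitute compositions ship in `data/scenarios_default.yaml`
(user-verify placeholders). The energy densities — soymilk 30, cow's milk
62, FMP-PSC 79 kcal/100 g — were chosen for consistency with the survey's
top-up arithmetic (a child at the consumer-median 174 g/d LME gains
(350−174)/100 × 62 ≈ 109 kcal/d under the cow's-milk top-up).

## Statistical conventions

Defaults reproduce SPSS output semantics; each is selectable.

* **Quantiles**: type 6 (HAVERAGE; linear interpolation at (n+1)p). Type 7
  and Tukey hinges are available.
* **Percentages**: exact ratio, rounded half-up to 2 dp. Percentage-point
  changes difference the *already rounded* percentages and round again —
  the convention of printed tables, which can differ in the last digit
  from the unrounded-count difference.
* **Wilcoxon signed-rank**: zero differences dropped, midranks for ties,
  tie-corrected normal z with no continuity correction, two-sided normal
  p. An exact enumeration mode (≤ 20 non-zero pairs) doubles the smaller
  tail probability. At n = 8 the normal approximation is within 0.08
  absolute of the exact p (the analytic worst case for untied ranks is
  0.068).
* **McNemar**: with discordant counts b, c — exact two-sided binomial
  `min(1, 2·P(Bin(b+c, ½) ≤ min(b,c)))` when `b+c < 25`, else the
  continuity-corrected chi-square `(|b−c|−1)²/(b+c)` on 1 df. Zero
  discordance is reported as degenerate (p = 1), not an error.
* **Kruskal-Wallis / Mann-Whitney / Pearson chi-square**: scipy backends;
  the Mann-Whitney normal approximation is tie-corrected without
  continuity correction, with exact enumeration for small tie-free
  samples. All-identical data yield H = 0, p = 1 by convention.
* Significance is two-sided at 0.05 with no multiplicity adjustment. The
  pairwise scheme letters a–i mark model-vs-baseline and within-scenario
  model-vs-model contrasts.

## Synthetic cohort generator

The generator emulates the *structure* of a 4-day online-diary survey of
676 preschool children; all draws flow through one seeded numpy generator,
so output is byte-reproducible.

* Strata 224/226/226 children aged 37–48 / 49–60 / 61–72 months; ages
  uniform within stratum.
* Dairy consumer flags per stratum (93.75 / 92.41 / 91.52%); subtype flags
  conditional on consuming, calibrated so the *marginal* probabilities
  match the surveyed mix (liquid milk ≈ 54–63%, milk powder declining
  50 → 31% with age, yogurt ≈ 35%, other dairy ≈ 16–20%).
* Consumer LME is lognormal. `calibrate_lognormal(median, p25, p75)` sets
  µ = ln(median) and σ as the average of the two one-sided quartile
  estimates; the target quartiles 174.00 (84.61, 255.70) g/d are treated
  as consumer-conditional (a lognormal calibrated to them plus an ~8%
  point mass at zero cannot also give 174 as the all-children median).
  Asymmetric quartiles cannot all be matched by a two-parameter lognormal;
  the median is matched exactly and the IQR approximately. Totals are
  split across the child's subtypes by a Dirichlet draw and across days by
  a Dirichlet day-weight with mean exactly preserved, so the latent truth
  file agrees with the intake engine's recomputation to 1e-9.
* The background diet draws 8–15 foods/day from a generated 60-food pool
  whose nutrient densities are lognormal around plausible per-100 g
  medians. Ordinary foods carry no vitamin D — dietary vitamin D comes
  only from fortified milk powder and supplements, producing the
  zero-inflated distribution surveys report. Iodine is two-component: a
  low dietary background plus a seaweed-like food eaten only by
  "high-iodine household" children (42%), giving the heavy right tail.
* 41.1% of children use supplements (vitamin D, calcium, vitamin C, iron,
  zinc in random combinations; daily or on two of four days).

Fidelity targets are the consumption marginals (consumer share, consumer-
median LME, subtype mix, supplement share), **not** per-nutrient intake
levels: those depend on a national food composition table that is not
bundled, so baseline medians are plausible in order of magnitude only.
Passing tests therefore demonstrate the pipeline's arithmetic, invariances
and conventions — not nutritional conclusions about any real population.

## Problem sizes and numerical choices

The test suite exercises cohorts of 20–90 children for engine tests and
ten full 676-child cohorts for marginal-recovery checks; null calibration
uses 2,000 seeded replicates per test (Wilcoxon n = 100 pairs,
Mann-Whitney 50/50, Kruskal-Wallis 3×30, McNemar 200 pairs at 30% flag
prevalence — the asymptotic regime where the nominal 5% level is
meaningful). The acceptance script runs one full 676-child cohort.
Degenerate inputs are defined throughout: zero energy makes fat %E and
fiber density domain errors; all-zero paired differences is a domain
error; zero discordance is a degenerate p = 1; empty quantile input is an
error; ties take midranks everywhere.

## Known limitations

* The bundled DRI thresholds and substitute compositions are editable
  placeholders (user-verify), not authoritative values.
* The EAR cut-point on 4-day means ignores within-person variance.
* No density correction between g and ml of dairy liquids.
* Scenarios alter dairy foods only; fortified nutrients arriving through
  supplements are untouched.
* Single-substitute scenarios only — no mixed dairy portfolios.
* Vitamin D adequacy reflects diet alone; sunlight-driven status is out of
  scope.
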