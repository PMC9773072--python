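# 2013 Chinese Dietary Reference Intakes, preschool age bands.
#
# PLACEHOLDER DEFAULTS -- user-verify. The engine never hard-codes
# thresholds; replace these values with the official 2013 Chinese DRI
# tables before drawing substantive conclusions. Age bands are half-open
# in months: [36,48) covers children aged 3 (the 1-3 y reference band),
# [48,73) covers children aged 4-6 (the 4-6 y reference band).
#
# rule_type: EAR (inadequate iff intake < threshold)
#            AI  (same comparison; used where no EAR exists: potassium)
#            FIBER_DENSITY (inadequate iff fiber g/1000 kcal < threshold)
#            AMDR_UPPER (excessive iff fat %E > threshold)
rules:
  # ---- children aged 3 (36-47 months) -------------------------------
  - {nutrient: carbohydrate, age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 120}     # g/d
  - {nutrient: protein,      age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 20}      # g/d
  - {nutrient: calcium,      age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 500}     # mg/d
  - {nutrient: iron,         age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 7}       # mg/d
  - {nutrient: zinc,         age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 3.2}     # mg/d
  - {nutrient: iodine,       age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 65}      # ug/d
  - {nutrient: potassium,    age_min_months: 36, age_max_months: 48, rule_type: AI,  threshold: 900}     # mg/d
  - {nutrient: vitamin_a,    age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 220}     # ug RAE/d
  - {nutrient: vitamin_b1,   age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 0.5}     # mg/d
  - {nutrient: vitamin_b2,   age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 0.5}     # mg/d
  - {nutrient: vitamin_b3,   age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 5}       # mg NE/d
  - {nutrient: vitamin_b6,   age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 0.5}     # mg/d
  - {nutrient: vitamin_b9,   age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 130}     # ug DFE/d
  - {nutrient: vitamin_b12,  age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 0.8}     # ug/d
  - {nutrient: vitamin_c,    age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 35}      # mg/d
  - {nutrient: vitamin_d,    age_min_months: 36, age_max_months: 48, rule_type: EAR, threshold: 8}       # ug/d
  - {nutrient: fiber_density, age_min_months: 36, age_max_months: 48, rule_type: FIBER_DENSITY, threshold: 10}  # g/1000 kcal

  # ---- children aged 4-6 (48-72 months) -----------------------------
  - {nutrient: carbohydrate, age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 120}
  - {nutrient: protein,      age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 25}
  - {nutrient: calcium,      age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 650}
  - {nutrient: iron,         age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 7}
  - {nutrient: zinc,         age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 4.6}
  - {nutrient: iodine,       age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 65}
  - {nutrient: potassium,    age_min_months: 48, age_max_months: 73, rule_type: AI,  threshold: 1200}
  - {nutrient: vitamin_a,    age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 260}
  - {nutrient: vitamin_b1,   age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 0.6}
  - {nutrient: vitamin_b2,   age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 0.6}
  - {nutrient: vitamin_b3,   age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 6}
  - {nutrient: vitamin_b6,   age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 0.6}
  - {nutrient: vitamin_b9,   age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 160}
  - {nutrient: vitamin_b12,  age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 1.0}
  - {nutrient: vitamin_c,    age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 40}
  - {nutrient: vitamin_d,    age_min_months: 48, age_max_months: 73, rule_type: EAR, threshold: 8}
  - {nutrient: fiber_density, age_min_months: 48, age_max_months: 73, rule_type: FIBER_DENSITY, threshold: 10}
  # Fat AMDR upper bound assessed for the two older survey strata only
  # (no bound below 49 months).
  - {nutrient: fat_energy_pct, age_min_months: 49, age_max_months: 73, rule_type: AMDR_UPPER, threshold: 30}   # %E
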