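# Default scenario configuration: the five dairy simulation models.
#
# Substitute compositions are per 100 g liquid(-equivalent) product --
# soymilk and cow's milk as drunk, the formulated milk powder for
# preschool children (FMP-PSC) as reconstituted liquid. PLACEHOLDER
# DEFAULTS -- user-verify: the product label / national food composition
# values should replace these before substantive use. Units per 100 g:
# energy kcal; carbohydrate/protein/fat/fiber g; dha mg; calcium mg;
# iron mg; zinc mg; iodine ug; potassium mg; vitamin_a ug RAE;
# vitamin_b1/b2 mg; vitamin_b3 mg NE; vitamin_b6 mg; vitamin_b9 ug DFE;
# vitamin_b12 ug; vitamin_c mg; vitamin_d ug.
target_amount: 350    # recommended daily dairy intake, g/d liquid milk equivalent
reference_milk_protein: 3.0   # g protein / 100 g liquid milk, LME conversion base

substitutes:
  soymilk:
    name: "Soymilk"
    per100g:
      energy: 30
      carbohydrate: 1.8
      protein: 2.9
      fat: 1.5
      fiber: 1.2
      dha: 0
      calcium: 12
      iron: 0.4
      zinc: 0.3
      iodine: 0
      potassium: 120
      vitamin_a: 0
      vitamin_b1: 0.02
      vitamin_b2: 0.02
      vitamin_b3: 0.2
      vitamin_b6: 0.02
      vitamin_b9: 38
      vitamin_b12: 0
      vitamin_c: 0
      vitamin_d: 0
  cow_milk:
    name: "Cow's milk"
    per100g:
      energy: 62
      carbohydrate: 4.8
      protein: 3.0
      fat: 3.4
      fiber: 0
      dha: 0
      calcium: 107
      iron: 0.3
      zinc: 0.42
      iodine: 1.9
      potassium: 120
      vitamin_a: 24
      vitamin_b1: 0.03
      vitamin_b2: 0.14
      vitamin_b3: 0.1
      vitamin_b6: 0.04
      vitamin_b9: 5
      vitamin_b12: 0.3
      vitamin_c: 1
      vitamin_d: 0
  fmp_psc:
    name: "FMP-PSC (reconstituted)"
    per100g:
      energy: 79
      carbohydrate: 8.6
      protein: 2.9
      fat: 3.3
      fiber: 1.2
      dha: 9.2
      calcium: 140
      iron: 1.27
      zinc: 1.23
      iodine: 5.4
      potassium: 78
      vitamin_a: 42.6
      vitamin_b1: 0.057
      vitamin_b2: 0.12
      vitamin_b3: 0.42
      vitamin_b6: 0.034
      vitamin_b9: 16
      vitamin_b12: 0.43
      vitamin_c: 4.1
      vitamin_d: 1.2

# The paper's five models: 1-3 replace all dairy (volume matched),
# 4-5 top up existing dairy to the target amount.
models:
  - {model_id: 1, mode: SUBSTITUTE, substitute: soymilk}
  - {model_id: 2, mode: SUBSTITUTE, substitute: cow_milk}
  - {model_id: 3, mode: SUBSTITUTE, substitute: fmp_psc}
  - {model_id: 4, mode: TOPUP, substitute: cow_milk, target_amount: 350}
  - {model_id: 5, mode: TOPUP, substitute: fmp_psc, target_amount: 350}
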