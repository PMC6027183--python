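# pnacid

Prediction of the renal acid load and pH of compounded parenteral-nutrition
(PN) admixtures.

Patients on long-term PN receive their entire daily intake from one
compounded bag, so the bag's acid content determines their daily renal acid
load — a suspected driver of metabolic acidosis and metabolic bone disease.
`pnacid` is a calculator for the nutrition specialist and the compounding
pharmacist: from the bag's final composition it predicts

- **TA**, the titratable acidity (mmol of 0.1 M NaOH to bring the bag to
  pH 7.4) — the *preformed* fixed acid;
- **PMAL**, the potential metabolic acid load — the fixed acid that
  catabolism of the nutrients will *produce*;
- **PTAL = TA + PMAL**, the potential total acid load per bag (≙ per day),
  flagged against the 50 / 75 / 100 mmol/day thresholds;
- the admixture **pH**, the leading indicator of physico-chemical stability.

## The model

With species concentrations in mmol/L and the bag volume V in mL, the
metabolic load is a stoichiometric account of acid producers (sulfur and
cationic amino acids, phospholipid at 1/5 weight) and acid consumers (the
organic anions acetate and gluconate):

```
PMAL (mmol) = [2·Cys + 2·Met + Lys + His + Arg + PL/5 − acetate − gluconate] · V/1000
```

TA and pH are affine in eight covariates (glucose, lipid, amino acid in
g/100 mL; Ca, P, Na, K, Mg in mmol/L), with published coefficients for one
product line shipped as the default set:

```
TA (mmol) = [0.769 − 0.029·glu + 0.619·lip + 1.001·aa + 0.078·Ca + 0.487·P
             − 0.004·Na + 0.002·K − 0.070·Mg] · V/1000
pH        =  5.894 − 0.007·glu + 0.026·lip + 0.050·aa + 0.009·Ca − 0.036·P
             − 0.001·Na + 0.0003·K − 0.003·Mg
```

Because manufacturers acidify their stock solutions differently, the
coefficients must be re-derived for any new product line from a set of
bench titrations (OLS; `pnacid fit`), and the refitted predictor validated
against measurements by Passing–Bablok regression with a cusum linearity
check and Bland–Altman limits of agreement (`pnacid compare`).

## Worked example

```python
from pnacid import (MixtureComposition, derive_species, compute_pmal,
                    compute_ptal, predict_ta, predict_ph)

bag = MixtureComposition(
    "bag-001", volume_ml=1979,
    glucose=9.1, lipid=2.2, amino_acid=3.3,          # g/100 mL
    calcium=3.0, phosphorus=6.1, sodium=51.1,         # mmol/L
    potassium=25.2, magnesium=4.6,
)
bag = derive_species(bag)            # acetate, gluconate, AA species, PL
ta = predict_ta(bag)                 # 15.63 mmol
ph = predict_ph(bag)                 # 5.80
pmal = compute_pmal(bag)             # 66.85 mmol
result = compute_ptal(ta, pmal, mixture_id=bag.mixture_id, ph=ph)
print(f"TA {result.ta:.1f}  PMAL {result.pmal:.1f}  PTAL {result.ptal:.1f}  "
      f">50 {result.exceeds_50}  >75 {result.exceeds_75}")
```

prints

```
TA 15.6  PMAL 66.9  PTAL 82.5  >50 True  >75 True
```

This bag delivers a potential daily acid load of 82.5 mmol — well above the
50 mmol/day level at which acid-base rebalancing (e.g., swapping chloride
salts for acetate) is worth considering. About 81% of the load is of
metabolic origin, so it would be invisible to a titration of the bag alone.

The same computation from the shell, with a per-bag label:

```
pnacid simulate --n 5 --seed 1 --out mixtures.csv
pnacid compute --input mixtures.csv --out report.csv --labels labels/
```

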