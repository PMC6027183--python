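# Methods

## Scope and model

`pnacid` computes the potential renal acid load of compounded
parenteral-nutrition (PN) admixtures from their final composition. Three
quantities are modelled:

**Metabolic acid load (PMAL).** Catabolism of some nutrients produces
fixed (non-volatile) acid; others consume it. The sulfur amino acids
cysteine and methionine yield 2 mmol H+ per mmol on sulfur oxidation, the
cationic amino acids lysine, histidine and arginine 1 mmol H+ per mmol,
and phospholipid contributes through its phosphate at weight 1/5. The
organic anions acetate and gluconate are oxidised to CO2 and water and
consume 1 mmol H+ per mmol. With concentrations c_s in mmol/L, the per-bag
load is `PMAL = (Σ w_s c_s) · V/1000` with signed weights
{+2, +2, +1, +1, +1, +0.2, −1, −1}. The weight table is configurable:
anionic amino acids (aspartate, glutamate) carry −1 in products that
contain them, but are absent from the default because the reference
amino-acid product has none. PMAL can legitimately be negative (acid
consumers dominate).

The interpretation of PMAL as *potential* assumes a nil nitrogen balance:
every administered amino acid is eventually oxidised. Under a markedly
positive or negative balance the realised metabolic load differs; no
quantitative correction exists, and none is attempted.

**Titratable acidity (TA) and pH.** Both are modelled as affine functions
of eight covariates — glucose, lipid, amino acid (g/100 mL), calcium,
phosphorus, sodium, potassium, magnesium (mmol/L). TA is extensive:
the fitted bracket is an acidity concentration (mmol/L) and is multiplied
by V/1000, so predictions are exactly linear in bag volume. pH is
intensive and carries no volume term. The shipped default coefficient set
(`coefficients/iacone2018.json`) stores published values for one specific
product line, verbatim to their printed decimals; it is an artifact, never
re-derived.

**Total load.** `PTAL = TA + PMAL`, reported per bag and read as mmol/day
(one bag infused per day). Threshold flags use strict comparison against
50, 75 and 100 mmol/day; the flags are nested by construction.

## Species derivation

Prescriptions specify macronutrient and electrolyte totals; the species in
the PMAL formula come from fixed properties of the stock products. The
default `StockProfile` encodes: 8.5 mmol/L acetate per g/100 mL amino acid
(an amino-acid stock stabilised at 85 mmol/L acetate per 10 g/100 mL),
0.75 mmol/L phospholipid per g/100 mL lipid (15 mmol/L in a 20% emulsion),
2 mol gluconate per mol calcium (calcium gluconate stoichiometry), and a
per-species amino-acid spectrum. The spectrum is approximated from paired
cohort means (e.g., methionine 12.0/3.3 mmol/L per g/100 mL) because the
product's per-amino-acid formulation is not published; users with a
datasheet should supply species columns explicitly — supplied values are
never overwritten, which also makes derivation idempotent and homogeneous
of degree 1.

## Refitting for a new product line

Different manufacturers acidify stocks differently, so the TA/pH
coefficients are product-line-specific. `TitratableAcidityModel` and
`MixturePHModel` refit them by ordinary least squares (statsmodels) on
paired bench titrations; a minimum of 10 observations is enforced and
rank-deficient designs are rejected with the offending columns named (via
pivoted QR). The TA regression response is the volume-normalised acidity
`TA·1000/V`, which preserves the bracket-times-volume structure of the
predictor; the estimation equation behind the original published fit is not
stated, so this parameterisation is documented as this package's choice.
The organic anions and individual amino-acid species are excluded from the
covariates: under a single product line they are exact linear functions of
amino acid, calcium and the chloride salts, and would make the design
singular.

A note on cohort means: evaluating the TA equation at the covariate means
gives 15.63 mmol, slightly above the cohort-mean measured TA of 15.2,
because the model is bilinear in concentration × volume and the two are
correlated in real prescriptions; this is expected, not an error.

## Method-comparison statistics

Agreement of predictions with measurements uses the standard trio for
error-in-both-variables comparisons:

- **Passing–Bablok regression** (implemented from the original method):
  slope = shifted median of the N pairwise slopes, discarding pairs with
  equal x and slopes of exactly −1, with offset K = #{slopes < −1};
  intercept = median(y − b·x). 95% CIs from the rank-based normal
  approximation, intercept CI evaluated at the slope bounds. The estimator
  is symmetric under axis exchange (b → 1/b, exact when the retained slope
  count is odd) and equivariant under positive scaling provided no
  pairwise slope is carried across −1 by the scaling.
- **Cusum linearity test**: residual signs, ordered by x, scored
  +√(M/L) / −√(L/M) (L above, M below the line) and accumulated; the
  maximum excursion scaled by 1/√(L+M) is referred to the asymptotic
  Kolmogorov distribution. Exact small-n tables are out of scope. When all
  residuals lie on one side (e.g., an exact affine fit) the test is
  degenerate and reports p = 1. Detection power is modest at small n: a
  pure quadratic needs ~40 points before the asymptotic p drops below
  0.05.
- **Bland–Altman**: differences d = y − x; bias = mean(d), limits of
  agreement bias ± 1.96·SD (sample SD, n−1), bias CI via t on n−1 df.
- **KS normality**: sup-distance between the empirical CDF and a normal
  with sample mean/SD; the p-value uses the Lilliefors correction by
  default (parameters estimated from the sample — the convention of common
  clinical statistics software), with the plain KS p available by flag.

Which variable is x and which is y must be stated explicitly by the user;
Passing–Bablok treats both as error-prone, so the assignment only fixes
the reporting direction.

## Synthetic cohorts

No raw compositions of real cohorts are published, so testing uses a
generator that emulates the marginal distributions observed in a 50-bag
adult cohort: each of volume, glucose, lipid, amino acid, calcium,
phosphorus, sodium, potassium and magnesium is drawn from an independent
normal truncated to the observed min–max (e.g., glucose 9.1 ± 3.1 g/100 mL
on [3.0, 21.1]; volume 1979 ± 574 mL on [630, 3000]) by rejection
sampling (cap 1000 rounds per field), then species are derived through the
stock profile. Simulated titrations add Gaussian noise to the model
predictions with σ_TA = 0.35 mmol and σ_pH = 0.06 — calibration choices
that reproduce measured-vs-predicted correlations of r ≈ 0.998 (TA) and
≈ 0.96 (pH) at the cohort's dispersion, i.e. a tight, single-product-line
titration campaign.

What the generator does *not* emulate: the correlation structure of real
prescriptions (volume co-varies with macronutrient load; only marginals
are matched), osmolarity (no composition → osmolarity formula is
available), and patient-level covariates. Consequently, passing tests
demonstrate correctness of the computations and recoverability of
coefficients under the stated noise — not that the shipped coefficients
transfer to other product lines, which is exactly why the refit workflow
exists.

## Numerical and design choices

- All internal computation is at full precision; presentation rounds TA /
  PMAL / PTAL to 0.1 mmol and pH to 0.01, the reporting precision of the
  underlying bench methods.
- Threshold comparisons are strict (>).
- Validation errors name the offending field and CSV row/column.
- Test problem sizes: property suites use cohorts of 20–50 bags, 200-seed
  replicate sets for the Passing–Bablok oracle and CI-coverage checks
  (50 pairs per replicate, matching the reference cohort size), 1000–5000
  draws for distributional checks. The complete suite runs in a few
  seconds.

## Known limitations

- The amino-acid spectrum ratios are cohort-mean approximations, not a
  product datasheet.
- The linear pH model extrapolates poorly far outside its calibration
  range; predictions outside (0, 14) are returned with a warning.
- Cusum p-values are asymptotic; for n ≲ 20 they are conservative.
- PMAL assumes complete oxidation of administered amino acids (nil
  nitrogen balance).
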