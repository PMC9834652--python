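# Methods

## Scope and data flow

The pipeline models one respiration-chamber energy trial in growing barrows:
eight diets (a corn–soybean-meal basal diet, six wheat-bran diets, one
wheat-shorts diet; test ingredients included at 30 % as-fed), six pigs per
diet, a total-collection balance period, several fed chamber days and one
8-h overnight fasting window per pig. Stages:

1. `feed_tables` — validated ingredient/diet chemistry and CSV I/O.
2. `chamber_calorimetry` — Brouwer heat production, methane energy,
   respiratory quotient, FHP extrapolation.
3. `energy_balance` — ATTD, nitrogen balance, the GE→DE→ME→RE→NE cascade per
   pig, covariance adjustment of THP, diet means.
4. `ingredient_energetics` — difference-method ingredient GE/DE/ME/NE with
   the measured-GE anchoring chain.
5. `prediction_stats` — composition-based NE predictions and their relative
   error, Pearson correlations, OLS and stepwise equation selection.
6. `synthetic_data` / `datasets` — ground-truth experiment generator and the
   packaged reference tables.
7. `pipeline` / `cli` — orchestration, report bundle, reproduction report.

## Assumptions of the energy model

* Heat production is a linear gas-exchange functional (Brouwer coefficients
  16.18, 5.02, −2.17, −5.99); no activity partitioning or analyzer-drift
  correction.
* FHP measured over 8 h extrapolates linearly to 24 h; fasting urinary N is
  the amount excreted within the window (callers prorate longer collections
  by time), keeping FHP a pure function of its window.
* Metabolic size scaling uses BW^0.60 with the period's single recorded body
  weight.
* Energy units are kJ internally; MJ appears only at report boundaries.
* Diet-level values follow the per-pig-first convention: every quantity is
  computed per pig, then averaged per diet (n = 6). Ratios of means differ
  slightly and are not used; this is why, e.g., diet GE × mean ATTD does not
  exactly equal the reported mean DE.
* The mineral/vitamin carrier (~3 % of each diet) is energy-free, so the
  basal mixture's energy is the basal diet's energy divided by the mixture
  share 0.97 (the formulation constant; the formulation sum is 97.35 % but
  the published constant is used by default and is configurable).

## Key parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| Brouwer coefficients | 16.18 / 5.02 / 2.17 / 5.99 | kJ per L or g | factorial calorimetry standard |
| methane energy | 39.5 | kJ/L CH₄ | combustion enthalpy convention |
| protein energy | 23.86 | kJ/g protein | body-protein energy density |
| CP:N | 6.25 | – | Kjeldahl convention |
| metabolic exponent | 0.60 | – | growing-pig energy scaling |
| MEI reference | 2,254 | kJ/kg BW^0.60/d | experiment-mean ME intake for THP adjustment |
| mixture fraction | 0.97 | – | mixture share of the basal diet |
| fasting window | 8 | h | overnight fasting HP measurement |
| stepwise entry/stay α | 0.15 | – | see below |
| VIF limit | 10 | – | conventional severe-collinearity bound |
| CV denominator | population (n) | – | matches the published ingredient-table CVs (CP: 5.98 → printed 6.0; the sample form gives 6.55) |

## Covariance adjustment of THP

Within each collection period a single least-squares slope b of THP on MEI is
fitted across the period's pigs, pooled over diets, and each pig moves along
it: adjTHP_i = THP_i + b·(MEI_ref − MEI_i). Diet-specific slopes are not
identifiable from six pigs per period and are out of scope. If all MEI are
equal the slope is undefined and raw THP is returned with a warning.

## Inclusion-fraction basis

Inclusions are published as-fed while energies are per kg DM. By default the
difference method converts fractions to a DM basis: the test ingredient uses
its assayed DM, the mineral carrier an assumed 99 % DM, and the mixture's DM
share follows by closure against the analyzed diet DM. A config switch
(`basis="as-fed"`) keeps raw as-fed fractions for sensitivity analysis. On the
packaged tables the two bases differ by well under the reproduction slack of
the ingredient energy values, which in any case cannot be regenerated exactly
from diet means (per-animal records were never published); synthetic tests
assert exactness under a matched basis.

## Stepwise selection

Forward selection by smallest partial-F p-value below the entry threshold,
followed by backward removal of any term above the stay threshold, with a
variance-inflation guard; every admissible model on the path is returned,
ranked by R² (desc) then RMSE (asc), ties by fewer parameters then
alphabetical names, so output is deterministic. The thresholds default to
0.15, the stepwise convention of the major statistical packages: with n = 6
the partial-F p-values for adding an energy term to a one-variable model are
≈ 0.14, so a 0.05 entry threshold would make the well-supported two-variable
equations (GE+CP, GE+ME; R² ≈ 0.94) unreachable even though their overall
F-tests are significant. AIC and BIC are reported in the Gaussian form
n·ln(SSE/n) + 2k and n·ln(SSE/n) + k·ln(n) (k counts the intercept); other
software uses different additive constants, so only differences within one
run are meaningful. RMSE uses residual degrees of freedom, √(SSE/(n−p−1)).

## Synthetic-data generator

The generator is the testing substrate: per-diet truths (digestibilities,
urinary and methane energy fractions of DE, fed/fasted RQ, FHP per kg
BW^0.60, target NE, protein-retention share of RE) plus herd settings
(6 pigs/diet, BW ~ N(41, 2²) kg, DMI = 0.156·BW^0.60 kg/d, 4 fed chamber
days, 8-h fast). Defaults come from the packaged diet-mean tables, so the
synthetic herd is magnitude-realistic (THP ≈ 1,200–1,290 kJ/kg BW^0.60/d,
RQ 1.07–1.09 fed / 0.81–0.84 fasted, FHP ≈ 765–816). Gas volumes come from
inverting the Brouwer equation at the configured RQ:
O₂ = (HP + 2.17·CH₄ + 5.99·N)/(16.18 + 5.02·RQ), CO₂ = RQ·O₂ — so with zero
noise the analysis reproduces every configured quantity to machine precision,
which the tests assert.

Measurement noise is multiplicative mean-one log-normal with a configurable
CV (0 for oracle tests, 3 % for realism), applied only to measured
quantities. Feed intake is one weighing measurement per pig, so a single
intake factor multiplies DMI and all intake-derived flows together (its error
then largely cancels in per-kg-DM energy densities), while fecal and urinary
outputs and each day's gas volumes get independent factors. Energy is
conserved in the latent truth, not in the noisy measurements. Fasting urinary
N is a configurable fraction (default 0.5) of the fed-state excretion rate,
prorated to the window.

What the generator does not emulate: within-day gas kinetics and circadian
HP, activity, growth across periods, chamber washout dynamics, correlated
assay errors. Passing tests therefore demonstrate correctness of the
accounting and estimation chain, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* Negative digestibility (fecal > intake), negative REL (lipid mobilization)
  and negative difference-method energies are flagged with warnings but
  returned; impossible domains (zero intake, zero O₂, nonpositive fractions)
  raise typed errors.
* Derived chemistry: SDF = TDF − IDF (tolerance 0.02 % DM against an assayed
  value) and CP = 6.25·N (tolerance 0.05 % DM) absorb two-decimal rounding of
  published tables; missing optional analytes stay absent rather than zero.
* Zero-variance columns in the correlation matrix yield NaN with a warning
  rather than an arbitrary value.
* Simulation feasibility (target NE ≤ implied ME, nonnegative urinary N and
  THP) is checked before any record is generated.

## Known limitations

* Mixed-model inference (random period/chamber effects, multiple-comparison
  letters) is out of scope; diet summaries are simple means.
* The reproduction report excludes, as documented exceptions, printed cells
  that do not follow from printed inputs: the IDF-involved and NE/ME rows of
  the published correlation matrix, the wheat-shorts composition-based NE
  predictions, and all cells requiring unpublished per-animal records.
* n = 6 ingredients forbids any out-of-sample validation of the prediction
  equations; the reported R² are in-sample.
* Problem sizes in tests and the acceptance script (48-pig herds, 60 noisy
  replicates) are chosen to make the Monte-Carlo assertions stable while the
  suite stays quick to run.
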