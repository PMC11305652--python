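# Methods

## Model

The package models the pH dependence of plasma strong ion difference (SID)
in whole blood and its relation to whole-blood base excess (BE).

**Titrable charge.** Albumin and hemoglobin carry imidazole groups treated
as a single class with common dissociation constant pK 6.75. The charge per
liter is `Z_pH = c·n·10^(−pH)/(10^(−pK)+10^(−pH))` with `c` the protein
concentration in mMol/L and `n` the number of titrable groups. Albumin uses
n = 16 and MW 66,500 g/mol and titrates at plasma pH. Hemoglobin is
parameterized per tetramer (MW 64,458 g/mol) and titrates at red-cell pH;
a per-monomer parameterization with n/4 and MW/4 is numerically identical
and is asserted as a property test.

**Red-cell pH map.** Intracellular pH is taken as linear in plasma pH,
`pH_rbc = 0.76·pH + 1.571` (pH_rbc 7.195 at plasma 7.40), a Funder–Wieth-type
relation. The hemoglobin group count (n = 26 per tetramer) and this map are
*calibrated constants*: they were fixed once by an exhaustive grid search
(n in [20, 40] step 0.5, slope in [0.70, 1.00] step 0.01, intercept anchored
at plasma pH 7.40) minimizing the worst-cell error against eight published
whole-blood hemoglobin-charge group means, with the anchor constrained to
the physiologic red-cell pH window 7.15–7.30. The unconstrained optimum
(anchor ≈ 7.04) fits marginally better but puts red-cell pH outside the
physiologic range, so the constrained fit (max cell error 0.56 mEq/L) was
adopted. Both constants are exposed in `BufferParams` and can be overridden.

**Expected SID.** With a baseline step (pH closest to 7.40, PCO₂ closest to
40 mmHg), `SID_exp = SID_b + ΔZ_alb + ΔZ_hb` (albumin-only for isolated
plasma), or `SID_exp(β) = SID_b − β·(pH − pH_b)` using the noncarbonic
buffer value. The CLSI variant replaces β by 1.43·[Hb] + 7.7.

**Base excess and whole-blood SID.** BE follows Lang–Zander:
`BE = r·[(HCO₃⁻ − 24.26) + β·(pH − 7.40)] − 0.2·[Hb]·(1 − sO₂)` with
`r = 1 − 0.0143·[Hb]`. The metabolic component of a SID change is
`ΔSID_wb = r·(SID − SID_exp(β))`. Henderson–Hasselbalch plumbing uses
pK′ 6.105 and CO₂ solubility 0.0307 mMol/L/mmHg; it is needed only by the
simulator and consistency checks, since analyzers report HCO₃⁻ directly.

## Analysis pipeline

β is fitted per series as the negated OLS slope of HCO₃⁻ on pH over all
equilibration steps — the titration curve is near-linear over the tonometry
range and a single slope is robust to analyzer noise; pairwise finite
differences would amplify it. Acid-loaded samples use their *own* fitted β
in `SID_exp(β)` (their buffer value genuinely differs from the control's),
while the baseline BE is computed with the control sample's β. Series too
short to fit (single-step group-mean tables) may carry an externally
determined β in `TonometrySeries.beta_known`.

Baselines: the 5% CO₂ step (experiment 1), the 12% CO₂ step (experiment 2),
or the control sample's step with PCO₂ closest to 40 mmHg (experiment 3,
shared by that subject's acid-loaded series). Baseline steps are excluded
from every agreement analysis since measured and expected values coincide
there by definition.

Bland–Altman agreement uses the n−1 sample SD and limits at exactly
±1.96·SD; differences are oriented comparator − ΔBE (so plasma ΔSID biased
*positive* against ΔBE means it under-shoots the acid load). A result is
flagged clinically acceptable when |bias| ≤ 1 mEq/L and the largest absolute
difference is < 3 mEq/L. Group comparisons use Student's t (equal
variances) and Pearson's r via scipy; a brute-force formula oracle backs
them in the tests. The Fencl–Stewart comparator implements the Story-type
constants (sodium-chloride reference 38 mEq/L, albumin coefficient 0.25 per
g/L deficit from 42 g/L, lactate one-to-one), all configurable; its output
is reported, never asserted numerically, because the partition's defect —
ignoring redistribution — is exactly what the package quantifies.

## Synthetic data

The simulator emulates the tonometry experiments' structure: groups with
published albumin/hemoglobin distributions (healthy 4.8±0.2 / 14.2±0.9,
septic 3.1±0.5 / 10.4±0.8, diluted 5.0±0.2 / 7.0±0.9 g/dL, and the
acid-loading donors 5.0±0.2 / 13.9±1.3), baseline SID drawn from each
group's baseline-column mean±SD, baseline pH N(7.40, 0.03), all truncated at
±3 SD. Equilibration maps gas fraction to blood PCO₂ through a
piecewise-linear empirical characteristic anchored at the mean equilibration
pressures observed at 2/5/12/20% CO₂ (tonometers do not fully equilibrate
blood to the nominal fraction); outside the anchors the ideal slope
(713 mmHg per unit fraction) continues the map.

Per subject the true β is β_CLSI by default (`beta_source="zph"` instead
differentiates the titrable-charge model); each acid load lowers true BE
one-for-one; per CO₂ level the pH is solved by Brent bisection so that BE
and Henderson–Hasselbalch hold simultaneously (residual strictly increasing
in pH, tolerance 1e−12), and plasma SID is placed at
`SID_exp(β) − load/r`, making ΔSID_wb = −load exact before noise.
Electrolyte redistribution allocates the required SID change as
Cl −0.55, Na +0.40, Ca +0.04, K +0.01 (fractions configurable, validated to
sum to 1 in charge) — proportions chosen to match the observed direction and
rough magnitude of per-analyte shifts during respiratory acidosis. Noise
defaults are analyzer-grade: pH 0.005, PCO₂ 1 mmHg, HCO₃⁻ 0.3, Na/Cl 0.5,
K 0.05, Ca 0.01 mMol/L, Lac 0.1 mEq/L, independent across analytes and
steps. One seeded `numpy` Generator drives everything; a scenario's seed
fully determines its output, and ground truth (per-subject β, baseline
state, per-step pre-noise values) is returned alongside the data.

Because the simulator's truth model *is* the analysis model, passing
end-to-end tests demonstrates internal consistency and recoverability under
noise — not the physical correctness of the redistribution hypothesis on
real blood, which only the packaged published group means and their derived
rows anchor. Real-data features deliberately not modeled: within-subject
correlated analyzer error, Donnan-equilibrium red-cell mechanics,
oxygen-dissociation coupling (sO₂ fixed at 1.0, all experiments were
oxygenated), phosphate/2,3-BPG buffering, temperature deviations from 37 °C.

## Numerical choices and degenerate inputs

Physiologic-range violations on electrolytes warn rather than raise
(tonometry drives blood far outside normal); structural violations
(negative concentrations, non-finite values, pH outside 6.0–8.2) raise.
β estimation requires ≥ 2 distinct pH values; Bland–Altman ≥ 2 pairs; the
two-sample t test returns (0, 1) for identical zero-variance groups and
raises on zero-variance groups with unequal means. `bicarbonate_ratio`
rejects hemoglobin outside [0, 25] g/dL and any parameterization driving
r ≤ 0. Baseline ties (equal |PCO₂ − 40|) resolve to the lowest step index.
Analyses of group-mean tables treat each column as a pseudo-subject and use
tolerances widened to 0.15–0.3 mEq/L, since one-decimal rounding of every
mean propagates through the derived chains.

## Problem sizes

Default test and verification runs use 4–10 simulated subjects with 4–10
CO₂ levels, 200 subjects for the β-recovery property, 1,000 Monte-Carlo
replicates for the OLS slope-recovery check, and 10,000 draws for sampling
means — sizes at which the statistical assertions are stable across seeds
while the whole suite stays interactive (a few seconds).

## Known limitations

The hemoglobin charge constants are calibrated to eight group means, not to
titration of purified hemoglobin; they should be re-fitted before use far
outside pH 6.9–7.7 or in species other than human. The model omits
phosphate species entirely and treats magnesium as constant (measured at
baseline only). All quantities are in vitro whole-blood conventions; the
extracellular ("standard") base excess used at the bedside has a lower
buffer value, so in vivo SID redistribution is expected to be smaller than
this model predicts.
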