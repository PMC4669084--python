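# Methods

## Tracer mass balance

All isotope arithmetic is performed in atom fractions; δ¹³C values appear
only at I/O boundaries. Conversions use R_VPDB = 0.0112372 and are exact
inverses of one another (round-trip error < 1e-12 relative over
δ ∈ [−100, 3·10⁶] ‰, covering natural abundance through a 97 atom% label).

The δ¹³C of total CO₂ in a vial is the concentration-weighted mean of the
headspace and dissolved phases. The equilibrium fractionation between
gaseous and aqueous CO₂ is handled as a **signed, configurable offset added
to the gas-phase δ before weighting, default +1 ‰**. The sign and phase of
application are a genuine design choice (equilibrium fractionation at 10 °C
is of this order but its application depends on instrument calibration
conventions); the default is documented here, surfaced as
`gas_correction`, and mirrored by the simulator's `gas_offset` so the two
cancel exactly in closed-loop tests.

Excess ¹³C is E = F_sample − F̄_background with the background taken as the
**mean of the per-vial control atom fractions** at the same sampling day
(mean of F, not F of the mean δ — the difference is second-order at these
enrichments but the choice is fixed and tested). Negative E (sample below
background, possible under noise) is retained and logged, never clipped:
clipping would bias cumulative sums upward.

Substrate attribution divides by the substrate's atom fraction
(E·C_total/0.97), the standard SIP estimator. Note its small intrinsic
bias: carbon respired from the labelled substrate displaces background CO₂
with excess (F_substrate − F_background), not F_substrate, so the estimator
under-attributes by a factor (0.97 − F_bg)/0.97 ≈ 0.989, and unlabelled
pools whose δ differs from the background (diatom detritus at −18 ‰ vs
sediment OC at −22 ‰) contribute a further ≲0.1 % apparent signal. These
are properties of the estimator itself, not of this implementation.

## Mineralisation series

Sampling is destructive, so the cumulative series is the sequence of
per-day treatment means across different vial sets, not a per-vial
trajectory. Day-0 substrate-derived CO₂ is forced to zero (the substrate
has just been added); measured day-0 vials serve as initial-condition QC.
Per-interval rates are finite differences of the cumulative means; their
products with interval lengths reconstruct the final cumulative value
exactly. Replicate-level quantities are always computed first, then
mean/SE (SE = sd/√n over vials). Concentrations are held internally as
μg C per vial and converted to μg C mL⁻¹ wet sediment by the configured
sediment volume (20 mL default).

## PLFA analysis

I_PLFA = E·conc/0.97 per PLFA against the day- and name-matched control
mean δ. Bacterial biomarkers are i15:0, a15:0, i16:0 and 18:1ω7;
microeukaryote biomarkers are the C18 PUFAs plus 18:1ω9. "C18 PUFA" is
concretised as {18:2ω6, 18:3ω3, 18:3ω6} (configurable — the membership of
this set varies between labs). Proportional enrichment is normalised over
**all** measured PLFAs first; the mean-enrichment < 0.001 filter is applied
afterwards (strict `<`: a mean of exactly 0.001 is retained). The empirical
logit ln((p + ε)/(1 − p + ε)) with ε = 0.1 is used rather than the
numerator-only variant because it is finite at both endpoints and exactly
antisymmetric about p = 0.5, matching common ecological usage. PLFA names
are canonicalised (ω→w, n-notation→w-notation, hyphenated branch prefixes
collapsed) before any matching.

## Statistics

The treatment/time model is an OLS fit with both factors categorical,
decomposed by **sequential (type-1) ANOVA in entry order** (time, then
treatment, then interaction); term sums of squares are order-dependent by
design, their total is not. Tukey HSD post-hocs use the full model's
residual mean square and degrees of freedom with Tukey–Kramer standard
errors for unbalanced groups; studentized-range probabilities come from
`scipy.stats.studentized_range` (accuracy well below the 1e-6 target). For
two groups the Tukey p equals the pooled t-test p (q = √2·|t|), which the
suite asserts. p-values are reported exactly; threshold-style presentation
is left to the caller.

PLS2 is implemented with NIPALS (weight-vector convergence tolerance 1e-10,
500-iteration cap, error on non-convergence or on a zero-variance column
under scaling). Each X-weight vector's largest-magnitude element is made
positive, making output deterministic. Explained variance is reported for
the response block per component (predictor-block variance is also
emitted). The treatment/time analysis uses condition indicator dummies as
predictors of empirical-logit enrichment profiles, observations being the
treatment(×day) conditions; biplot variable coordinates are correlations of
each variable with the X-scores. The isolate comparison restricts both
matrices to common PLFAs (≥3 required), uses genus profiles as predictors
(unit-variance scaled, as is conventional for profile blocks on different
scales), and reports per-genus correlations with axes 1–3. Because no
genus-level PLFA compilation is publicly deposited, the packaged reference
database is a clearly labelled **synthetic** Dirichlet fixture (14 PLFAs ×
24 genera, seed-deterministic); only the machinery, not any real genus
ranking, is claimed.

## Synthetic experiment generator

The simulator emulates the 4-treatment (CTRL, lignocellulose-only LC,
LC + 1× diatoms, LC + 2× diatoms) × 5-timepoint (0, 7, 14, 21, 28 d) ×
3-replicate destructive-sampling design: 20 mL sediment + 20 mL water per
vial at 10 °C, lignocellulose at 0.15 mg C mL⁻¹ (97 atom% ¹³C, C/N 107),
diatoms at 0.23/0.47 mg C mL⁻¹.

Carbon pools: background OC mineralises at a slowly declining baseline
(2.5, 2.0, 1.8, 1.6 μg C mL⁻¹ d⁻¹ per interval — a typical coastal-sediment
magnitude); diatom detritus decays first-order (k = 0.15 d⁻¹, 50 %
mineralisable), reproducing the dose-dependent first-week respiration
pulse; an initial DIC stock of 15 μg C mL⁻¹ at the background δ keeps day-0
vials measurable. Pool δ defaults (−22 ‰ background, −18 ‰ diatom, −25 ‰
baseline PLFA carbon) are typical literature magnitudes, configurable.
Produced CO₂ splits 60/40 between headspace and water, with the gas-phase δ
offset mirroring (inversely) the analysis-side fractionation correction.
Measurement noise — δ sd 0.3 ‰ (IRMS-precision scale) and 2 % relative
concentration sd — is added last, per phase and per PLFA.

**Truth convention.** Lignocellulose mineralisation is configured as
interval rates **on the estimator scale**: the simulator inverts the
E·C_total/0.97 attribution exactly (correcting for the
(F_lc − F_bg)/F_lc factor and for the unlabelled-diatom δ offset) when
generating vial atom fractions, and the truth record stores those apparent
rates. This makes "noise-free pipeline recovers configured truth to 1e-9"
a meaningful closed loop and pins the named scenarios to the published
values exactly. The physically mixed alternative would leave the ~1 %
estimator bias discussed above between configuration and recovery.

Scenarios: `"rates-paper"` encodes the printed interval rates
(1.28/1.05/0.62 μg C mL⁻¹ d⁻¹ for days 0–7 in 2D/1D/LC; 0.63/0.45/0.83 for
days 7–14; 0.02 thereafter for "near-zero" tails); `"cumulative-paper"`
rescales that shape so day-28 cumulative fractions are exactly
7.0/7.0/8.6 % — the two printed sets are mutually inconsistent at rounding
precision (1.28 + 0.63 over two weeks implies ≈8.9 %, not 8.6 %), hence two
scenarios; `"null"` zeroes the lignocellulose rates and sets the diatom δ
equal to the background δ so labelled treatments show exactly zero excess.

PLFA labelling couples to respiration: assimilated substrate C entering the
PLFA pool is 0.02 × apparent cumulative respired C (growth efficiency ×
PLFA share of biomass C), allocated across PLFAs with a microeukaryote
share decreasing with diatom dose (0.30/0.18/0.08 for LC/1D/2D) — encoding
the observed inverse relationship between eukaryote enrichment and diatom
amendment — and fixed within-group weights. 15:0 and cy19:0 receive no
label, exercising the low-enrichment filter.

What the generator does **not** emulate: carbonate speciation or
temperature-dependent gas partitioning (the phase split is prescribed, not
chemical), oxygen dynamics, microbial population dynamics, community
succession in PLFA baselines, unlabelled-growth changes in PLFA
concentrations, or vial-to-vial heterogeneity beyond i.i.d. measurement
noise. Passing recovery tests therefore demonstrates correctness of the
inversion arithmetic and statistics, not robustness to real-data
pathologies such as drift, outliers or heteroscedastic replicates.

## Problem sizes and determinism

Simulated experiments are 60 vials (4 × 5 × 3) with 14 PLFAs per vial; the
stochastic calibration check uses 200 replicate experiments, which runs in
seconds. All randomness flows through a single `numpy` generator seeded per
run; identical config + seed gives byte-identical output tables (fixed
`%.12g` float formatting). The stochastic calibration check compares each
experiment's recovered rates with the truth against three Monte-Carlo
standard errors estimated from the simulation ensemble — the actual
sampling spread of the estimator — rather than each experiment's own
3-replicate SE, whose heavy-tailed t₂ distribution at the day-0-anchored
interval would make ±3-SE coverage a property of small-sample t quantiles
rather than of the pipeline.

## Known limitations

* The tracer estimator's intrinsic ~1 % attribution bias is documented but
  not corrected (matching standard practice).
* Cumulative series assume per-day treatment means are comparable across
  destructively sampled vial sets; vial-lineage effects are not modelled.
* Tukey intervals assume homoscedastic residuals from the full model; no
  Welch-type correction is offered.
* The isolate comparison is only as meaningful as the reference profiles;
  the shipped fixture is synthetic and serves testing and API purposes.
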