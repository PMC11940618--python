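# Methods

## Scope and data flow

The package analyses plate-format cytotoxicity screens of renal proximal
tubule cell sources: raw per-well luminescence (proportional to viable cell
count) → percent-of-vehicle viability → censored logistic points of
departure → medium dosimetry → margins of safety against human serum Cmax →
binary nephrotoxicity calls, confusion matrices, and an MCC ranking of cell
sources. Each stage is usable on its own; `run_pipeline` composes them.

## Vehicle normalization

Within each (cell source, drug) series, viability_i = 100 ×
signal_i / mean(vehicle signals), vehicle wells being those dosed at 0 µM
(vehicle controls). Vehicle wells are retained with their normalized
values, so their group mean is 100 by construction. Normalization is
per-series because each simulated or imported series carries its own
vehicle wells; a shared-plate layout can be expressed by passing a
different `group_by`.

## Concentration–response model

The fitted curve is the decreasing logistic

    v(c) = bottom + (top − bottom) / (1 + (c / ec50)^hill)

with **top fixed at 100 %**: the data are vehicle-anchored by construction,
and fixing the upper asymptote keeps the remaining three parameters
(bottom, ec50, hill) identifiable on a 7-point nonzero concentration
series. Fitting is bounded nonlinear least squares (scipy `least_squares`,
trust-region reflective) on replicate-level points — replicate-level rather
than concentration means, to use all information — with the concentration
axis parameterised as log10(ec50). Bounds: bottom ∈ [0, 100], hill ∈
[0.1, 10], ec50 ∈ [c_min/10, c_max×10]. Vehicle wells are excluded from the
fit (they anchor normalization only). Five deterministic starts with
log-spaced EC50 guesses spanning the tested range protect against local
minima; there is no randomness in the fit. Optimizer tolerances are 1e-12
so that noiseless synthetic data are recovered to better than 1e-6
relative.

Asymptotic standard errors come from the Gauss–Newton covariance
`(JᵀJ)⁻¹ · SSE/(n−p)`; they are NaN when the information matrix is
singular (e.g. perfectly flat data).

**Flat-response rejection.** A fit is marked `fit_ok = False` when the
fitted bottom exceeds 90 % or the logistic does not beat the flat
no-response model (v ≡ 100, zero free parameters) on AIC
(n·ln(SSE/n) + 2k). Rejected fits censor both PODs.

**Points of departure.** The EC50 POD is the concentration of 50 %
viability, the IC10 the concentration of a 10 % decrease (90 % viability).
Both are solved in closed form, c = ec50·((top−t)/(t−bottom))^(1/hill);
when no solution exists (bottom ≥ threshold) or the solution exceeds the
highest tested concentration, the POD is right-censored and reported as a
strict bound "> c_max". Censoring propagates through free-concentration
scaling (the bound scales) and margins of safety (reported as lower
bounds, never point estimates). Non-monotone (hormetic) data are fitted
as-is; the monotonicity guarantees apply only when bottom < top.

## Synthetic data generator

`TruthParams` encodes the screening design the package targets: the
8-point series 0, 0.3, 1, 3, 10, 30, 100, 300 µM (0 = vehicle), replicate
wells per concentration (default 3), and a logistic truth. Noise is
multiplicative log-normal with unit mean and a specified CV (default 10 %),
chosen because luminescence viability signals are positive with roughly
concentration-proportional spread; the vehicle expectation is an arbitrary
10⁶ units since only ratios matter. One seeded `numpy` generator per
dataset; identical parameters give byte-identical output.

The generator does **not** emulate plate spatial or edge effects, the
96- vs 384-well distinction, pipetting covariance between neighbouring
wells, or assay-floor saturation. Passing recovery tests therefore show
that the estimator inverts its own generating model under realistic noise
levels — not that real plates are free of those artefacts.

## Packaged reference panel

The 12-drug annotation table (human serum Cmax ranges in µM, risk classes
High/Intermediate/Low, vehicle) and a per-cell-source call matrix for 9
cell sources ship as CSVs. High and intermediate risk count as in vivo
positives, low as negatives; Gentamicin and Streptomycin are excluded from
scoring because the tested range was subtoxic for them, leaving 10 scored
compounds (8 positives, 2 negatives). For cell sources whose per-drug calls
the study narrative enumerates (the OAT1-overexpressing TERT1 and ciPTEC
lines; the negatives for lines with stated specificity) the calls are
flagged `verified`; for the remaining lines only the marginal TP/FN/FP/TN
counts are pinned down and the stored assignment is one consistent choice,
flagged unverified — tests assert only marginals for those lines.

## Medium dosimetry

f_ub,media comes from an equilibrium mass balance of a neutral chemical
over equivalent sorbent volumes:

    f_ub,media = V_w / (V_w + K_prot·V_prot + K_lip·V_lip + K_aw·V_air + V_pl)

Defaults: serum contains 38 g/L protein and 2.5 g/L lipid per unit serum
volume (typical fetal bovine serum), converted to equivalent volumes with
densities 1.36 and 0.90 g/mL; serum-albumin affinity
log K_prot = 0.71·logKow + 0.42; storage-lipid affinity
log K_lip = 1.01·logKow + 0.12; air from K_aw with log Kaw defaulting to
−30 for non-volatiles (the air term is then numerically zero);
polystyrene sorption (optional, off by default)
log K_pl[m] = 0.97·logKow − 6.94, multiplied by the wetted area. All
correlations are swappable callables. Melting point and water solubility
are carried in the profile for alternative model plug-ins but unused by the
default correlations.

Limitations: ionization is ignored (neutral-species model), so the free
fraction of strong acids and bases at medium pH is approximate; cellular
uptake and time-resolved depletion are out of scope. Exact reproduction of
any specific published f_ub,media table is not claimed — the model is
specified by the equations above and verified by its conservation and
monotonicity properties (free fraction in (0, 1], equal to 1 exactly with
no sorbing phases, decreasing in logKow/serum fraction/logKaw, compartment
fractions summing to 1).

## Margins of safety

MOS_nominal = POD/Cmax_total; MOS_free multiplies by f_ub,media/f_ub,plasma.
When a Cmax range was reported the **maximum** end is used by default —
the conservative choice, giving the smallest margin — configurable to the
minimum or midpoint. MOS is computed per cell source; a
minimum-POD-across-sources aggregation (preferring uncensored PODs) is
available for a most-sensitive-cell summary.

## Classification and ranking

In vitro positive ⇔ EC50 POD strictly below 300 µM; censored PODs and
values at the threshold are negative. Metrics: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/total, and MCC. A rate with a
zero denominator is NaN (undefined, deliberately not 0); MCC with a zero
marginal is 0 by the usual convention. Displayed percentages round halves
up (62.5 → 63). Ranking is by descending MCC with ties broken by accuracy,
then sensitivity, then name — MCC leads because it summarises all four
cells of the matrix and tolerates the 8:2 class imbalance of the panel.

## Numerical and design choices

- Problem sizes: recovery tests use the 8-point series × 3 replicates, a
  3×3 grid of (hill, EC50) truths and 20 seeds per cell — small enough to
  run interactively, large enough for a stable median error.
- The brute-force oracle for fit quality is a 50×50×50 grid over
  (bottom, ec50, hill); the closed-form POD is cross-checked against
  Brent root-finding at 1e-9 relative tolerance.
- Determinism: fixed inputs and seed give byte-identical output files; the
  run log hashes the analytic configuration (excluding the output path).
- Degenerate inputs: empty tables, missing vehicle wells, non-positive
  vehicle means, < 4 distinct nonzero concentrations, and non-finite
  values are rejected with stage-labelled errors; a failed stage writes no
  partial outputs.

## Known limitations

- The logistic POD is a curve-fit point estimate; no benchmark-dose-style
  confidence bound on the POD itself is computed (the parameter standard
  errors are reported instead).
- With only two in vivo negatives per panel, specificity and MCC move in
  large quanta; rankings between sources differing by one call are not
  statistically distinguishable.
- The dosimetry model is neutral-species and equilibrium-only.
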