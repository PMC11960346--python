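# Methods

## The model

Let **x** = (x_TST, x_SB, x_LPA, x_MVPA) be a participant's average daily
minutes in total sleep time, sedentary behaviour, light and
moderate-to-vigorous physical activity, closed to 1440 min. Compositions
live on the simplex, so inference uses Aitchison geometry: the pivot
sequential binary partition (first row +1 −1 −1 −1, then drop the previous
numerator and promote the next part) defines orthonormal balances

z_k = √(r s / (r + s)) · ln( g(numerator) / g(denominator) ),

with g the geometric mean and r, s the part counts on each side. The
contrast matrix V (4×3) satisfies VᵀV = I and z = Vᵀ ln x; distances are
preserved (ILR is an isometry of the Aitchison metric), and the transform
is inverted by x = C(exp(Vz)) with C the closure operator.

WEMWBS is modelled as ordinary least squares on (z₁, z₂, z₃) plus
covariates in three nested specifications: model 1 unadjusted, model 2
adding age (linear, uncentred), sex, education (low/medium/high), marital
status and professional activity, model 3 adding smoking and chronic
conditions. Standard errors are classical (homoskedastic); overall model
fit is R² and the F-test p-value. Dummy references are the first-listed
category of each variable (male, low education, married/cohabitant,
professionally active, non-smoker, no chronic condition). Participants
with a missing chronic-condition status are dropped listwise in model 3
only; models 1–2 keep them.

Per-behaviour reporting uses pivot rotation: refit with behaviour b in the
first coordinate and report that coefficient. Because all four rotations
span the same column space, fitted values, R² and the F statistic are
identical across rotations, and the four rotated coefficients satisfy
Σ_b β*_b = 0 exactly (the rotated first coordinates are a rank-3 linear
image of one ILR vector). Coefficients are reported per unit ILR: a
"per-hour" rescaling of a single coordinate is not well defined, because
one behaviour cannot change alone on the simplex; interpretable
time-denominated effects are provided by the substitution module instead.

## Isotemporal substitution

For a reallocation of t minutes from behaviour A to behaviour B at a
reference composition (the sample geometric mean of the analysed
participants — the conventional choice), the predicted well-being change is

Δ(t) = (z(x_realloc) − z(x_ref))ᵀ β_ILR,

where the reallocated composition subtracts t from A and adds t to B,
leaving the other parts and the 1440-min total unchanged. Covariates are
held at any fixed value and cancel in the difference, so no covariate
averaging is needed. The 95% CI is the delta method with the t
distribution at the fit's residual degrees of freedom:
Δ ± t_{0.975, df} √(dᵀ Σ_ILR d), d the ILR difference. For a linear model
this coincides with refitting at the shifted composition. The default grid
is all 12 ordered pairs × {5, …, 60} min in 5-min steps; cells where t
would exhaust the donor behaviour are reported as infeasible rather than
clipped or dropped.

## Accelerometer preprocessing

* **Non-wear**: an epoch is non-wear iff it lies in a zero-count run of at
  least `window_min` (default 90) minutes, where runs may be bridged by
  non-zero interruptions of at most `spike_tolerance_min` (default 2)
  minutes each; bridged spike epochs are non-wear too. Interruptions at
  the edges of a run never bridge.
* **Sleep**: a centred weighted moving-window count score (default weights
  0.04, 0.04, 0.2, 1, 0.2, 0.04, 0.04; threshold 100 counts), sleep iff
  score < threshold, edges padded by repeating boundary epochs. The window
  must have odd length.
* **Cut-points**: SB iff vm3 ≤ `sb_upper`, LPA iff ≤ `lpa_upper`, MVPA
  above (boundaries inclusive on the lower class). The shipped defaults
  (2860 / 3940 counts·min⁻¹ VM3) are **illustrative**: published wrist
  cut-point sets for older adults vary, and studies should supply their
  own values via the YAML config, as should users wanting vendor-equivalent
  non-wear/sleep parameters.
* **Days and inclusion**: days are calendar-aligned midnight-to-midnight;
  partial first/last days are dropped. A day is valid iff waking wear time
  (SB+LPA+MVPA, sleep excluded) is ≥ 600 min, boundary inclusive. A
  participant is included iff ≥ 4 valid days; behaviour minutes are
  averaged over valid days first, then closed to 1440.

Zeros: the pipeline checks for zero parts before log-ratio work; if
present, multiplicative replacement (zeros → δ = 1 min, non-zero parts
rescaled to preserve the total) is available. The replacement is a
robustness path for user or synthetic data — an analysis whose raw data
contain no zeros proceeds untransformed.

## Synthetic cohort calibration

The generator emulates the published marginals of a cohort of 410 adults
aged 55+ (of 453 accelerometer wearers):

* **Compositions**: ILR vectors ~ N(ilr(μ), Σ) with μ = (339, 832.8,
  154.8, 113.4) min. Σ is induced by independent per-part log variances
  (0.0515, 0.0515, 0.275, 0.275), chosen so the pairwise log-ratio
  variances are s_i + s_j: exactly 0.103 for TST–SB (the most co-dependent
  pair) and 0.550 for LPA–MVPA (the least), with the remaining pairs at
  0.3265, inside that range. Independence across log-parts is the simplest
  structure consistent with the published variance range; only the range,
  not the full matrix, anchors the calibration.
* **Effect sizes**: the default ILR effect vector is the unique β whose
  four pivot-rotated coefficients equal (−2.17, −0.43, 1.96, 0.64) WEMWBS
  points — the published unadjusted per-behaviour associations, which sum
  to zero as the rotation identity requires (clr coefficients are √3/2
  times the per-behaviour values).
* **Covariates**: drawn independently of the composition from the
  published frequencies (71% female; education 45/32/20; 77%
  married/cohabitant; 4% professionally active; 3% smokers; chronic
  39/54/7 yes/no/missing; age ~ N(71.3, 6.3²) truncated to [55, 95]).
  Additive score effects follow the published per-category means (e.g.
  single −4.28, high education +3.28). An optional `confounded` switch
  makes age and sex shift the ILR mean (older/female → more sleep and SB,
  less MVPA) to exercise covariate adjustment; it is off by default.
* **WEMWBS**: intercept and residual noise SD are solved analytically from
  the configured effects and marginals so that the linear score has mean
  53.75 and SD 8.43 before rounding to integers and clipping to [14, 70].
  Clipping removes ~2–3% of the upper tail, attenuating the realised SD by
  roughly 0.2 points and recovered effect sizes by a few percent — visible
  in large-n recovery tests and accepted as a mild, documented bias.
* **Epoch streams**: each day is laid out as contiguous blocks (sleep, SB
  with a short low-count wind-down ramp, LPA, MVPA, then non-wear zeros)
  with counts drawn from behaviour-conditional regimes (sleep 1–30, SB
  110–2860, LPA 2861–3940, MVPA 3941–8000 counts/min) chosen so the
  default classifiers recover the block labels; daily targets scale the
  participant's composition to 1340 min of sleep + wear (≈100 min
  non-wear). A deterministic `short_wear_fraction` (default 43/453) of
  participants receive only 3 valid days, reproducing the 453 → 410
  attrition. The streams emulate block structure and durations only — not
  diurnal count waveforms, device noise spectra, naps, or within-day
  behaviour fragmentation — so preprocessing tests demonstrate correctness
  of the classification rules, not field performance of the parameter
  defaults.

## Numerical choices

* Natural logarithms throughout; closure and round-trip identities are
  asserted at 1e-9 relative tolerance (one constants block in `coda.py`).
* Rotation invariance is asserted to 1e-9 on fitted values and deltas.
* OLS is delegated to statsmodels and cross-checked against explicit
  normal-equations solves in the tests; the rank of the design is checked
  before fitting and a named collinearity error raised.
* CIs use t quantiles at the residual df, not normal quantiles.
* Zero-minute reallocations return Δ = 0 with a zero-width CI by the
  algebra itself (d = 0), kept as an explicit null check.
* Report CSVs are rounded to 2 decimals for side-by-side reading;
  full-precision companions are always written.

## Problem sizes in the test-suite and acceptance runs

Unit and property tests run on cohorts of 12–410 participants and epoch
streams of 3–8 participants × 5–6 days. Monte-Carlo checks use 100
replicate cohorts (n = 410) for coefficient recovery (each generating ILR
coefficient within 2 SE in ≥ 93/100) and 1000 replicate null cohorts for
type-I calibration (rejection rate within [0.035, 0.065] at α = 0.05).
Convergence checks of the sample centre use n = 10⁴. The acceptance script
uses n = 410 for the analysis stages and streams 453 participants × 6 days
of 60-s epochs through preprocessing.

## Known limitations

* Cross-sectional, single-outcome design: no longitudinal or mixed-effects
  support, no subgroup (e.g. sex-stratified) analyses.
* One-to-one reallocations only; reallocating one behaviour to all others
  simultaneously is out of scope.
* No parsing of proprietary device formats (AGD/GT3X); epoch input is CSV.
* D = 4 parts is assumed by the pipeline surface, though the SBP/ILR code
  is generic in D.
* The covariate generator draws covariates independently by default, so
  adjusted and unadjusted models differ little on default synthetic data;
  use `confounded=True` to study adjustment behaviour.
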