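# Methods

This note documents the models implemented in `cb1tacs`, the synthetic
data they are validated against, and the numerical choices that were
genuinely open. Units throughout: time in seconds on data grids, rate
constants in 1/min (K1 in ml·cm⁻³·min⁻¹), activity concentrations in
kBq/ml, all decay-corrected to injection time.

## Acquisition model

The default acquisition design is a 90-min-class dynamic scan of 33
contiguous frames (1×30″, 6×10″, 3×20″, 3×30″, 3×60″, 6×120″, 8×300″,
3×600″ — 5340 s total) with the tracer injected 30 s after scan start, so
the first frame carries no signal. Two clocks coexist: the scan clock
(frame schedule) and the injection clock (kinetics, input function);
`FrameSchedule.injection_offset` converts between them. All model curves
are evaluated on a fine uniform grid (1 s default) and averaged over
frames by exact trapezoidal integration — midpoint sampling would be
biased in the early 10-s frames where the bolus peak moves fast.

Frame weights for all weighted fits follow the count-statistics rule
`w_i = L_i / T_i` (frame length over true-coincidence rate), which is the
reciprocal variance of a frame-mean concentration under Poisson counting.
When a TAC carries no trues rates the fits fall back to uniform weights
with a logged warning.

## Plasma input

`derive_input_function` builds the metabolite-corrected input from raw
blood data in the standard way: the continuous-detector whole-blood
segment (~first 15 min) is cross-calibrated against the overlapping
discrete samples by a single multiplicative factor, the discrete samples
take over beyond the detector's support via linear interpolation, and two
fitted corrections convert whole blood to parent tracer in plasma — a
plasma-over-blood ratio (linear in time, clamped positive; the ratio
drifts slowly as cells/plasma partitioning equilibrates) and a parent
fraction modelled as a Hill sigmoid `1/(1+(t/t50)^h)`. The Hill form is
monotone non-increasing and bounded in [0, 1] by construction, and
extrapolates cleanly over late samples where the metabolite assay is
impossible at low count rates. Both model families are deliberately
low-dimensional: with ≤ 9 discrete samples anything richer is
under-determined.

The synthetic counterpart (`simulate_input`) is a Feng-type bolus — a
linear upslope times a fast exponential plus two slower washout
exponentials — with defaults chosen to look like a ~370 MBq injection of
a lipophilic, slowly metabolised ligand: peak ≈ 20 kBq/ml at ≈ 0.9 min,
a tail time-constant of ~80 min, plasma-over-blood 1.6, parent fraction
falling from 1 to ≈ 0.2 at 90 min (t50 = 25 min, h = 1.3). Whole blood is
defined as parent/(pob·pf), so the correction identity holds exactly.
Per-session shape jitter (amplitudes ±20 %, rates ±10 %) emulates
physiological variation; it is tied to the cohort's within-subject knob
(below) so that a zero-variability cohort is exactly repeatable.

## Compartmental models (2kbv, 4kbv)

Both plasma-input models include a variable blood-volume fraction `bv`
multiplying the *whole-blood* curve (the vascular signal contains
metabolites, so whole blood, not parent plasma, is the right carrier):

* 1TC: `C(t) = (1−bv)·K1·Cp ⊛ e^{−k2 t} + bv·Cb(t)`, `V_T = K1/k2`;
* 2TC: the bi-exponential impulse response with eigenrates from
  (k2, k3, k4), `V_T = (K1/k2)(1+k3/k4)`.

`bv` is bounded to [0, 0.2] (5 % is the physiological norm; anything
above 20 % signals a failed fit, not biology).

Fitting uses variable projection: for fixed rate constants the model is
linear in the amplitude `a = K1(1−bv)` and in `bv`, so those two are
solved by a constrained 2×2 weighted least-squares at every step and the
nonlinear search runs only over log-rates. Starts come from a
deterministic 3-point log-spaced grid per rate (9 candidates for 2kbv, 27
for 4kbv); all candidates are ranked by initial cost and the best few (3
and 6 respectively) are polished with a bounded trust-region optimiser
(relative tolerances 1e-8), ties broken by lowest residual then lowest
`bv`. A fit in which every start fails is returned as a flagged NaN row —
never an exception — so cohort runs always complete; a fitted k4 at its
lower bound is flagged `k4_near_zero` (the 2TC V_T diverges there, which
is exactly how the model misbehaves on noisy 90-min data). Reported V_T
is always the exact algebraic combination of the reported rates.

The V_T reported by the spectral methods below divides out the fitted
blood fraction (tissue amplitudes carry a `(1−bv)` factor under this
signal model), so all V_T routes estimate the same quantity.

## Spectral analysis and the decay boundary

Classic spectral analysis solves, by non-negative least squares,

    C(t) ≈ Σ_j α_j · Cp ⊛ e^{−β_j t} + α_bv · Cb(t),  α ≥ 0,

on a log-spaced rate grid (100 points) between a slow and a fast
frequency boundary, with `V_T` the integral of the fitted impulse
response. The conventional boundaries — 0.00063 s⁻¹ and 0.1 s⁻¹ — are
stated on the *non-decay-corrected* scale, where the ¹¹C decay constant
λ = 5.663·10⁻⁴ s⁻¹ adds to every tissue clearance rate and the slow
boundary just above λ therefore spans all physically possible components.
Since this package works with decay-corrected data, the fit convolves the
corrected input with the *shifted* rates `β_j − λ` and reports
`V_T = Σ α_j/(β_j − λ)`; this is algebraically identical to fitting
uncorrected data with the stated boundaries, and it is what makes V_T
recovery exact for clearance rates well below 0.0378 min⁻¹ (every
regional k2 in the emulated tracer's range). A component landing exactly
on the fast boundary is treated as residual vascular signal and excluded
from V_T.

The voxelwise variant shares one basis across all voxels of a dynamic
volume, skips all-zero voxels, and samples the resulting map by mask
means — deterministic given the inputs.

## Rank shaping

Rank-shaping regularisation replaces the positivity constraint by a
linear solution whose singular spectrum is filtered according to an
expected signal-to-noise parameter R. The construction used here:

* basis columns are rescaled to unit distribution volume (column j
  multiplied by its rate `β_j − λ`, so its impulse response integrates to
  one); each coefficient is then directly a V_T contribution and the
  filter shrinks the solution in the norm that matters for the outcome;
* the rate grid is log-spaced in the corrected rates (150 points), which
  keeps the grid dense where the tracer's components actually live;
* with the weighted design `A = U S Vᵀ`, the solution at parameter R is
  `x(R) = V φ(S) S⁻¹ Uᵀ y` with the order-2 Wiener filter
  `φ_i = s_i⁴/(s_i⁴ + (s_1/R)⁴)` — components whose singular value falls
  below the expected noise floor `s_1/R` are suppressed;
* `V_T(R)` is evaluated on 66 points over R ∈ [1, 10¹³] and the reported
  V_T is the mean over the *last* 5-point window whose mean relative
  slope |dV_T/dlog₁₀R| is below 1 %/decade, restricted to windows before
  the onset of noise amplification (slope > 50 %/decade). On noisy data
  that plateau sits at R of a few hundred (≈ the data's actual SNR); on
  noise-free data the admissible window keeps moving right until the
  solution has converged to the minimum-norm fit, which is why the R grid
  extends far beyond physically plausible SNR. If no window qualifies the
  flattest one is reported with a warning flag.

Two honest limitations. First, a sign-indefinite linear estimator must
extrapolate the multi-hour tail of the slowest basis components from a
90-min window without the positivity prior that protects classic SA; the
residual noise-free V_T error is ~1–2 % across the emulated V_T range
(worst ≈ 2 %), not machine precision. Second, under realistic noise the
plateau sits on the still-rising part of the transient, giving the known
behaviours of this estimator family: a compressed dynamic range and
underestimation of the highest-binding regions.

## SRTM and mSUV

The SRTM is solved by basis functions: the apparent reference efflux rate
k2a is scanned over 100 log-spaced values in [0.006, 0.6] min⁻¹, the two
linear coefficients are solved by weighted least squares at each, and the
best grid point is refined by bounded scalar minimisation, giving
`BP_ND = k2/k2a − 1`. The measured reference frames enter the linear term
directly (they *are* the frame averages of the reference curve); only the
convolution term uses the interpolated continuous reference. A target
identical to the reference yields exactly R1 = 1, BP_ND = 0.

mSUV is the duration-weighted mean activity over a fixed late window —
1790 s to 3530 s post-injection (~30–59 min), frames overlapping the
window counted in proportion to their overlap — times `(weight+70)/2`
divided by injected dose (MBq). The window is defined by time, not frame
index, so it is robust to schedule variants. `global_intensity` is the
companion whole-image statistic: the mean of voxels above 1/8 of the
volume mean.

## Reliability statistics

Signed percent difference `2(retest−test)/(test+retest)·100` (NaN when
the pair sums to zero); per-region tables report the *median of its
magnitude* together with the signed min–max range, because a signed
median centres near zero and hides the typical change. ICC is the
one-way random, single-measures ICC(1,1) from the explicit ANOVA
decomposition, default denominator `MSBS + (k−1)·MSWS`; a `"printed"`
variant with denominator `MSBS + df_WS·MSWS` exists for comparison with
sources that publish that form (it is always smaller). Between-subject CV
defaults to the CV of per-subject test/retest means (sample SD, n−1); a
per-session-then-average mode is available since the convention is not
universal. Bland–Altman uses the second argument as reference (the
one-tissue compartmental V_T by convention) with 1.96·SD limits of
agreement. Negative or wild estimates from unstable fits are kept as
ordinary values — deleting them would overstate reliability; NaNs are
excluded pairwise with exclusion counts in the table. ICC ≥ 0.75 is the
conventional "good reliability" read-out.

## The synthetic cohort and what it does (not) show

Each subject carries one unit-mean log-normal factor (CV `bs_cv`, default
0.35) and each session another (CV `ws_cv`, default 0.10), both shared
across regions and multiplying a fixed regional V_T profile (pallidum
10.8 … pons 3.0; pallidum/pons = 3.6). Sharing across regions encodes the
view that most session-to-session variation is global and
calibration-like (dose, peripheral metabolism, input-function error), and
it has two deliberate consequences: direct V_T read-outs obey the
variance-component prediction `ICC ≈ bs_cv²/(bs_cv²+ws_cv²) ≈ 0.92`,
while *ratio* measures (a pseudo-reference BP_ND) cancel the shared
factors, so their between-subject variance collapses and their ICC is
driven by measurement noise alone — which is the mechanism by which
pseudo-reference SRTM fails on real data of this kind. K1 is drawn
uniformly in [0.08, 0.20] min⁻¹ per subject and region (stable across
sessions), k2 follows as K1/V_T, `bv` is fixed at 0.05. Demographics are
sampled inside the reference cohort's ranges (ages 25–65, doses 316–399
MBq, intervals 1–309 days).

Noise is zero-mean Gaussian with per-frame SD
`noise_scale·sqrt(C_i/L_i)` — the variance structure the `L_i/T_i`
weights assume — with `noise_scale = 1` giving ~2 % errors on late
high-binding frames and ~7 % near the peak; trues rates are filled
proportionally to frame activity (50 counts·s⁻¹ per kBq/ml, floor 10) so
weights stay finite in the empty pre-injection frame. Phantoms assign
each region a rectangular block of voxels with independent voxel noise.

What passing tests show: the estimators are correct (noise-free recovery
to their documented accuracy), the statistics match independent oracles,
and the *relative* behaviour of the seven methods under noise matches
what 90-min CB1 data produce — fragile 4kbv/SRTM, robust
2kbv/SA/mSUV, preserved binding heterogeneity. What they do not show:
absolute agreement with any real cohort's numbers. The generator omits
scanner physics (scatter, randoms, attenuation, resolution), head motion,
metabolite-model error, region-specific biological session effects, and
partial-volume mixing, all of which shape real-data magnitudes.

## Problem sizes and determinism

Default analyses run a 15-subject, two-session, eight-region cohort
(240 TACs; ~1–2 min for all seven methods on one core); variance-
component studies that need only true V_T values skip TAC synthesis
(`generate_tacs=False`). Phantoms default to 8×8×4 voxels. Every random
draw descends from a single integer seed through `numpy`'s SeedSequence;
a fixed seed reproduces all pipeline artifacts byte for byte, and output
CSVs carry version/seed/config-hash provenance headers.

Known limitations, beyond the generator's scope above: the 4kbv
multi-start is deliberately small (its real-data instability is a finding
to reproduce, not to optimise away); the RS-SA plateau rule is a
deterministic automation of what is usually a visual read and its ~2 %
noise-free floor is intrinsic to the linear construction; the blood
pipeline fits only the two named correction families; and no
delay/dispersion correction of the blood detector is attempted.
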