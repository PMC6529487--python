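# Methods

This note documents the models behind `albupet`, the defaults and why
they were chosen, the numerical choices, and what the synthetic data do
and do not establish about real studies.

## Plasma model

Plasma kinetics follow a two-compartment model with zero-order infusion:
amounts A₁ (central, volume V₁) and A₂ (peripheral, volume V₂) obey

    dA₁/dt = in(t) − (CL/V₁)A₁ − (Q/V₁)A₁ + (Q/V₂)A₂
    dA₂/dt =                     (Q/V₁)A₁ − (Q/V₂)A₂

with clearance CL, distributional clearance Q and in(t) = dose/TI on
[0, TI]. Two compartments are the minimal structure that produces the
biexponential decline the study observed (a distribution phase of
roughly 100 h followed by first-order terminal elimination); nothing in
the downstream analysis depends on more structure. The model is solved
by eigendecomposition of the 2×2 rate matrix, giving exact closed-form
concentrations, integrals and a piecewise-exponential representation.
Degenerate (repeated-eigenvalue) parameter sets are rejected rather than
regularized; they do not occur at physiological values.

Defaults (units in parentheses) are calibrated to the cohort-mean
non-compartmental read-out of the clinical study the package models:

| parameter | default | rationale |
|---|---|---|
| dose_mass (ng) | 1e6 | 1 mg minimum dose for LC-MS/MS quantifiability |
| dose_activity (Bq) | 14.0e6 | mean administered activity ~14 MBq |
| infusion_duration (h) | 1/3 | ~20-min IV infusion |
| central_volume (mL) | 2564 | dose/Cmax with Cmax ≈ 390 ng/mL (≈ plasma volume) |
| peripheral_volume (mL) | 2870 | Vss = V₁+V₂ = 5434 mL |
| clearance (mL/h) | 9.7 | cohort mean |
| intercompartment_clearance (mL/h) | 33.4 | chosen so the slow eigenvalue gives T½ = 422 h |
| isotope_half_life (h) | 78.41 | physical ⁸⁹Zr constant (the field's rounded "3.3 days" would be 79.2; configurable) |
| scan_times (h) | 7, 79, 120, 168 | the four PET/CT sessions |
| blood_times (h) | 1…1032 | the clinical draw schedule to 43 days |

The implied fast half-life is ≈ 25.8 h, so the distribution phase is
effectively over within ~100–130 h; the study quotes only the phase
duration ("approximately 100 h"), not a fast half-life, so this value is
a calibration choice. `TwoCompartmentModel.from_nca_parameters`
constructs a model from (CL, Vss, fast T½, terminal T½) directly via the
standard eigenvalue relations when explicit micro-constants are not
wanted.

Mass balance — central + peripheral + CL·∫C dt = infused dose — closes
to machine precision and is asserted at 1e-6 relative in the tests. Organ
time-activity curves (below) are *concentration observables* driven by
the plasma curve: the peripheral compartment already aggregates tissue
distribution, so organ content is deliberately not added again to this
balance. Urinary excretion is accounted as a sub-portion of the cleared
amount.

## Organ extravasation

Each organ's decay-corrected concentration per mL of whole organ is

    C_org(t) = tp_min·C_p(t) + f_I·C_I(t) + R(t)

with f_I = V_I/V_org, interstitial concentration
dC_I/dt = k_ex(r_eq·C_p − C_I), and a residualized pool
dR/dt = k_res·f_I·C_I that never decreases in decay-corrected terms
(⁸⁹Zr-desferrioxamine fragments remain trapped after catabolism of the
carrier). r_eq ∈ (0, 1] encodes the interstitial exclusion space for
albumin-sized proteins (~16–26 %, hence r_eq ≈ 0.74–0.84 for
muscle-like organs). The heart VoI mixes tissue with chamber blood at a
configurable blood fraction (default 0.5), reproducing the blood-like
ratio a whole-heart VoI measures. All pools are evaluated in closed form
by convolving the piecewise-exponential plasma representation against
the exchange kernel; sampled plasma curves are first converted to a
piecewise-exponential (log-linear) interpolant. Exact rate resonance in
the convolution is handled with the analytic t·e^(−kt) term, not by
perturbation.

Default per-organ kinetics reproduce the four qualitative groups the
study reports: brain k_ex = 0 (vascular confinement at t/p = 0.025, the
bundled brain table entry being calibrated to that measured plateau);
lung/liver/spleen k_ex ≈ 0.8–1 h⁻¹ with r_eq = 0.95 (at their maximum
from the first scan); muscle/pancreas/parotid/bone marrow/testis
k_ex ≈ 0.003–0.008 h⁻¹ (still rising at day 7); kidney k_ex = 0.1 h⁻¹
with k_res = 0.025 h⁻¹ (t/p climbing past the theoretical maximum to
~1.1 and a day-7 SUV near 9). Testis is given a small k_res but
classifies as "increasing" under the defaults; pushing it past its
maximum within 7 days would require a residualization rate comparable to
kidney, which we did not consider physiological for a 36 mL organ.

A caution on the bounds: t/p is a kinetic quantity, and with a decaying
plasma input a slowly-exchanging interstitial pool lags the decline, so
at sufficiently late times C_I can exceed r_eq·C_p and the ratio can
drift above (t/p)_max without any residualization. Over the 7-day
imaging window — where t/p analysis is defined — the default organ set
stays strictly inside its bounds, and that is the window over which the
confinement property is asserted. For constant plasma the pool
approaches equilibrium monotonically from below and the bound holds at
all times (property-tested).

## Physiology table

Per-organ volumes (V_org, V_P, V_I) and mass fractions for a ~75 kg
reference adult male are bundled as a plain-text CSV, typed in from
standard PBPK volume compilations (Shah & Betts 2012; ICRP reference
values for organs absent there), with the brain plasma volume calibrated
as above. The loader validates V_P + V_I ≤ V_org, positivity and
mass_fraction ∈ (0,1) per row, and accepts user-supplied tables with the
same columns. Exact per-organ bound values are configuration, not claims:
the published study plots its bounds but does not tabulate them.

## Urine

Excretion rate is proportional to plasma concentration, normalized so
the cumulative decay-corrected excretion at 24 h equals
`urine_fraction_24h` (default 0.039, between the two measured subjects'
3.8 % and 4.0 %). Urine concentration over a collection interval assumes
a constant 1.5 L/day urine flow; the day-6/day-1 concentration ratio
under the default kinetics is ~0.40, consistent with the reported
"about one third".

## Decay, noise and the phantom

Measurements are truth × 2^(−t/T½) × lognormal(mean 1, CV). Noise is
multiplicative lognormal (default CV 10 %) because counting and PET
concentrations are positive with roughly proportional error. A single
integer seed drives every stochastic draw through one
`numpy.random.Generator`, making all outputs bit-reproducible.

The phantom places each organ as an axis-aligned ellipsoid inside a body
ellipsoid on a 60×40×40 grid at 6 mm spacing (head-to-thigh scale);
overlapping or out-of-body organs are rejected. Organ VoIs are uniform,
so SUVmean is exact and partial-volume effects are absent by
construction — scanner resolution, reconstruction and registration are
out of scope. VoI extraction erodes by a configurable margin (default
one 26-connected shell) so no VoI voxel touches another label. SUVpeak
averages over voxels whose centers fall within the radius of a 1 cm³
sphere, maximized over candidate centers whose full sphere lies inside
the VoI; VoIs too small for one sphere fall back to SUVmean with a flag.
Voxel-center membership makes both operations deterministic and
brute-force checkable.

## NCA conventions

AUC/AUMC use linear-up/log-down trapezoids (exact on exponential
declines). λz is fitted on suffixes of the strictly-post-Tmax positive
points (≥ 3 points, Tmax excluded), selecting the window with maximal
adjusted R²; ties within 1e-12 go to the longer window, which makes the
choice deterministic on noise-free data. Extrapolation uses the last
*observed* concentration. MRT subtracts TI/2 for infusion input (bolus
mode available; the published analysis does not state which was used,
and the difference — 10 min against an MRT of ~560 h — is far below
every tolerance here). Volumes: Vss = CL·MRT, V_initial = dose/Cmax.
The outlier screen is leave-one-out per time point with a default 5 SD
threshold: the study reports excluding one 8.4 SD point but states no
rule, so the threshold is explicit configuration.

## Reporting

Effective dose per subject is PET coefficient (default 0.448 mSv/MBq) ×
administered activity, plus n_CT × 0.5 mSv; an externally computed PET
effective dose (e.g. from organ dosimetry software, which this package
does not reimplement) can be supplied instead. Display rounding is one
decimal for MBq and mSv; JSON retains full precision. Cohort statistics
use the sample (n−1) SD throughout. The pipeline simulates its eight
subjects from the bundled cohort table (real weights and administered
activities) with lognormal CV-12 % between-subject variability on the
kinetic parameters.

## Problem sizes

The test suite and acceptance script run at the study's own scale: 8
subjects, 11 organs, 4 scan times, ≤ 13 plasma samples per subject, and
60×40×40 phantom grids. The full pipeline completes in about one second;
no stage required scaling beyond the study's actual dimensions.

## What passing tests show — and do not

The generator reproduces the *statistical structure* the analysis
assumes: biexponential plasma kinetics, organ curves bounded by the
volume ratios, residualizing accumulation, ~4 % urinary recovery,
multiplicative noise. It does not emulate scanner physics (resolution,
scatter, partial volume), anatomical organ shapes, within-organ
heterogeneity (e.g. cortex-vs-medulla kidney gradients are reduced to a
single organ-level rate), free-label impurities, or target-mediated
disposition of conjugated payloads. Passing the end-to-end tests
therefore validates the analysis chain's correctness and internal
consistency, not the physiological fidelity of any particular parameter
value; on real data the quantification stages consume NIfTI volumes,
label maps and CSV sample tables through the same interfaces.
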