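# Methods

This note records the modelling assumptions, estimator choices and
numerical conventions behind `thermokin`, in the spirit of a methods
appendix: what each component computes, why it computes it that way, and
what the synthetic-data experiments do and do not demonstrate.

## Temperature profiles

All internal temperatures are kelvin; degrees Celsius exist only at file
and CLI boundaries (`temp_C` CSV headers, `--target-c` flags), because
every rate law uses absolute temperature. Profiles are finite sampled
series starting at t = 0 with strictly increasing times. When a requested
duration is not an integer multiple of the sampling step, the exact
endpoint is appended as a final (shorter) interval so integrals always
cover the full exposure.

Synthetic water-bath transients are piecewise: a linear ramp from
baseline (37 °C) to the setpoint over the ramp time, an exact hold at the
setpoint, and an exponential relaxation toward baseline with time
constant cool-down/3, so the profile is within e⁻³ ≈ 5% of baseline when
the stated cool-down ends. The functional forms of the measured ramp and
cool-down curves are not published for this protocol; linear/exponential
is a stand-in chosen to match the qualitative shape of bath heating, and
the hold phase is deliberately noiseless — thermocouple-level error
belongs to the synthetic-data layer, not to the deterministic profile
builder. The two-step heat-up used in practice (a hotter bath to shorten
the ramp, then transfer) is collapsed into a single linear ramp of the
characterized ramp time, since only the delivered T(t) matters to the
models.

## Forward models

*Arrhenius.* Ω(t) is the cumulative trapezoidal integral of
k(T) = exp(ln A − Eₐ/RT) over the profile samples. Trapezoidal
integration is exact for constant temperature and second-order accurate
on smooth profiles (the test suite asserts the error ratio ≈ 4 when the
step is halved on a linear ramp). The gas constant defaults to
8.314 J·K⁻¹·mol⁻¹ but is a field of the parameter block, so coefficient
sets derived with a rounded constant can be reproduced exactly.

*Time-delayed Arrhenius.* The shoulder line t_d = b − m·T goes negative
above T = b/m (≈318.65 K for the KPC coefficients); negative delays are
clamped to zero since the model only distinguishes before/after. The
published model is defined for isothermal exposures; for time-varying
profiles this package integrates a normalized delay accumulator
ξ(t) = ∫ dτ/t_d(T(τ)), starting damage when ξ ≥ 1, with t_d = 0 instants
completing the delay immediately. This is the natural continuous
extension: it reduces exactly to waiting t_d(T) at constant temperature
(asserted sample-by-sample in the tests), and hot instants consume the
remaining shoulder proportionally faster. Within the crossing interval
the start time is located by linear interpolation of ξ and the first
partial damage increment uses the interpolated rate, so isothermal grids
whose samples straddle the shoulder still match the closed form.

*Two-state survival.* C(τ,T) = logistic(γT − β − ατ), as published. The
thermodynamic derivation leaves the sign convention of its intermediate
quantities ambiguous; the operative form used everywhere here is the
logistic expression above, and no separate Φ/K fields are exposed.

*CEM43.* t₄₃ = Σ Δtᵢ(min)·R^(43 − Tᵢ,°C) with the interval's midpoint
temperature, consistent with the trapezoidal treatment of Ω. The
reference exponent is fixed at 43 °C; the configurable break temperature
only selects between r_above (default 0.5, applied strictly above the
break) and r_below (0.25). At exactly 43 °C the exponent is zero, so the
strictness of the comparison is observable only through the R choice on
intervals straddling the break.

Dose and damage integrals are additive over concatenated profile
segments whenever the seam is continuous. A genuine step discontinuity
cannot be represented in a single strictly-increasing sampled series —
the seam interval necessarily blends the two temperatures — so the
additivity guarantees (and tests) apply to continuous seams, e.g. a
profile split at a sample and rejoined.

## Estimation

All fits are linear after a transform; ordinary least squares is used
throughout and there is no iterative optimisation to tune, beyond the
1-D breakpoint search described below.

*Per-temperature decay rate.* Survival fractions are clipped to
[10⁻⁴, 1.5] before log fits: control-normalized viability can
legitimately exceed 1 (dropping such wells would bias early time points),
and values at or below the 10⁻⁴ floor are censored — they sit below the
detection limit of a colorimetric assay, and regressing on them flattens
the slope, so they are excluded whenever at least two informative points
remain. Two modes exist:

- `through_origin` forces S(0) = 1 (slope-only regression of ln S on t),
  the convention for the simple Arrhenius arm;
- `free_intercept` fits the continuous hinge ln S = −k·max(0, t − t_d)
  to all points jointly: flat at 0 on the shoulder, linear past it, line
  forced through (t_d, 0). The breakpoint is found by profiling the SSE
  over t_d (closed-form k at fixed t_d; bounded 1-D minimization per
  inter-point interval, with the unconstrained free-intercept line as a
  candidate when its x-intercept precedes all data). When the data show
  no shoulder this reduces to ordinary free-intercept OLS. The hinge was
  chosen over "fit a line to the post-shoulder subset" because, with
  designs that leave only two decaying durations at the mildest
  temperature, subset selection is unstable under noise while the hinge
  lets the plateau points help locate the breakpoint.

A fitted shoulder shorter than the earliest sampled duration is reported
as zero: every observed point already decays, so such an estimate is
extrapolation, not measurement. This censoring also keeps spurious
tens-of-seconds shoulders at high temperatures from contaminating the
delay-line regression.

*Arrhenius coefficients.* OLS of ln k on 1/T; slope → −Eₐ/R, intercept →
ln A. *Delay line.* OLS of t_d on T over temperatures with a non-zero
shoulder estimate; clamped-at-zero estimates are censored observations
("no shoulder seen, so the true delay is below the earliest sampled
duration"), not points on the line. The censored temperatures are
enforced as one-sided constraints: if the unconstrained line predicts a
delay above the censoring bound (the pipeline passes the shortest
sampled duration) at a censored temperature, the line is re-fitted
pinned to the bound at the lowest censored temperature — otherwise two
noisy shoulder estimates can extrapolate a spurious multi-minute
shoulder into temperatures whose survival curves decay from the first
time point, which is the dominant failure mode of the delayed model
under realistic noise. If every estimate is zero the fit degrades to
(m, b) = (0, 0) with a warning; a single non-zero shoulder is
underdetermined and, at the pipeline level, likewise degrades to the
no-delay line with a warning rather than aborting the run.
*Two-state.* OLS of logit C on (T, τ) with survival clipped to
[ε, 1 − ε], ε = 10⁻⁴; exact 0/1 observations are clipped, not dropped.
*R_CEM.* Isoeffect time scales as 1/k(T), so ln t_iso is regressed on
T (°C) over temperatures above the break and R = exp(slope). For pure
Arrhenius kinetics this approaches exp(−Eₐ/(R_gas·T·(T+1))); the exact
reading of how published R values were derived from survival data is not
specified, and this isoeffect-time regression is one defensible choice.

*Model scoring.* RMSE is computed on the percentage scale, pooled across
cell lines and conditions (per-cell-line values are also reported), with
predictions from the isothermal forward model at each condition's
setpoint and duration. Fits run separately per recovery time; parameter
blocks are reported for 24 h by default, when injury is fully expressed.

## Synthetic data

The generator emulates the plate experiment, not the assay chemistry.
One "plate" is a (cell line, setpoint, duration, recovery) combination
with n = 6 wells. True survival follows the delayed Arrhenius law at a
jittered temperature T′ = setpoint + N(0, 0.2 K) drawn once per plate
(bath-accuracy error is plate-level, shared across wells). Three
multiplicative noise terms apply: a lognormal control-normalization
factor shared by the plate (CV 2%, from dividing by the control plate's
optical density), and independent lognormal well factors (CV 5%). All
lognormal factors have unit mean so well averages converge to the
noiseless value (asserted at n = 500 wells within 3 standard errors).
All randomness flows from a single seed through one generator; fixed
seed ⇒ bit-identical datasets.

The 6 h readout multiplies the log-kill by 0.7 (< 1: death not yet fully
expressed); this is phenomenological — the available observation is only
that viability keeps falling between 6 h and 24 h — and the multiplier is
excluded from all quantitative checks. Defaults: setpoints
42.5/44/46/50 °C, durations 3/5/10/15/20/30/45/60 min spanning the 3–60
min design; the duration grid within the published range was fixed once
at values typical for such studies.

Not emulated: thermotolerance induction, cell-cycle effects, plate-edge
effects, and any drift of the assay over time. Passing recovery tests on
these synthetics therefore demonstrates estimator correctness under the
stated noise model, not robustness to every artefact of a real MTT
experiment.

The ablation-periphery generator produces a saturating-exponential rise
from 37 °C toward a 47–51 °C peak (default rise constant 120 s over
10 min), the shape of heating at the edge of an ablation zone; validation
against it uses a reference computed from the generating truth and is
labelled synthetic throughout.

## Pipeline and reporting

`run_analysis` requires ≥ 2 temperatures and ≥ 3 distinct durations per
temperature, runs both fitting arms, the two-state fit and the R_CEM
estimate per cell line and recovery time, and scores all three models.
Fitting errors are re-raised with the offending cell line and setpoint
named. The report is a pydantic model; serialization sorts keys, so
identical inputs give byte-identical JSON, and the published JSON schema
shipped at `thermokin/data/report_schema.json` is generated from the same
model (conformance is checked by re-validation). The analysis
configuration is embedded verbatim in every report for provenance.

For non-isothermal validation the Arrhenius models integrate the full
temperature history. The two-state model is defined only for isothermal
(τ, T) pairs; it is evaluated at the profile's duration and
duration-weighted mean temperature, a deliberately simple convention that
under-weights the damage concentrated near the peak — one reason its
validation error is large, consistent with its poor isothermal fit.

## Problem sizes and numerical conventions

Recovery and ordering experiments in the test suite use 100 seeded
replicates of the single-cell-line design (4 setpoints × 8 durations ×
6 wells); the full three-cell-line study is used in the analysis scripts
and the acceptance script. The hinge breakpoint is resolved to
10⁻⁷ × (longest duration), which recovers noiseless coefficients to
~10⁻⁸ relative. Ω non-negativity and monotonicity are enforced on
construction of every damage result, and survival + injury/100 sums to 1
to within 10⁻¹². Tie-breaks: the CEM43 break comparison is strict (>);
the shoulder floor comparison is strict (<); clipping bounds are
inclusive.

## Known limitations

- The delay-accumulator extension to time-varying profiles is one of
  several defensible generalizations; alternatives (e.g. treating the
  profile as piecewise isothermal) differ on strongly non-isothermal
  histories.
- R_CEM estimation assumes isoeffect times proportional to 1/k, i.e.
  pure first-order kinetics without shoulder; shoulder-bearing lines
  violate this mildly.
- The two-state model's temperature dependence is a single bilinear
  term; it cannot reproduce Arrhenius-like rate scaling, and fits to
  Arrhenius-generated data are structurally poor — this is a property of
  the model, not the fitter.
- CSV round-trips of datasets are exact for well values; setpoints and
  durations traverse a °C/min unit conversion at the file boundary and
  round-trip to ~10⁻¹² relative rather than bit-exactly.
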