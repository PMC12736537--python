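# Methods

## Structural model and units

Both analytes follow one-compartment kinetics with first-order oral
absorption; the metabolite is formed from the parent in a catenary chain
(depot → parent → metabolite) with formation fraction FM. Doses are in mg,
volumes in L, clearances in L/h; concentrations are mg/L internally and
ng/mL (×1000) at every public boundary. Bioavailability is not separable
from trough-only oral data, so F ≡ 1 and all clearances/volumes are
apparent (CL/F, V/F).

Multiple dosing uses closed-form superposition: each exponential term
e^(−λt) acquires the accumulation factor (1−e^(−nλτ))/(1−e^(−λτ)), with
n = ∞ giving the steady-state limit. The metabolite profile is the
standard tri-exponential in {ka, kE, km}. When two rate constants approach
each other the analytic form is singular: the scalar API falls back to ODE
integration (LSODA, rtol 1e-10) below a relative gap of 1e-6, while the
vectorized array code used inside estimation and simulation instead nudges
the colliding constants apart by ~3e-6 relative — an O(1e-6·λt)
perturbation, far below the 1e-4 closed-form/ODE agreement verified in the
tests. The ODE integrator also serves as the independent oracle: the frozen
expected values in the test suite (e.g. female 60 mg day-30 troughs of
251.32 / 238.54 / 489.86 ng/mL for parent / metabolite / active moiety)
were computed with it before the closed forms were written.

"Steady state" is operationalized as the analytic superposition limit; the
30-day once-daily regimen used for simulation is computed as an explicit
finite 30-dose superposition. For the joint model (parent half-life ≈ 6 h
under its printed parameters) the two agree to <1e-6; for the pediatric
model at 59 kg (half-life ≈ 143 h) 30 days is almost exactly the 5
half-lives conventionally accepted as steady state, and the finite trough
sits ~3% (2^−5) below the limit — `steady_state_trough` warns whenever a
finite regimen is shorter than 5 half-lives.

## Model repository conventions

Printed between-subject %CV values are interpreted as the standard
deviation of the log-scale random effect, ω = CV/100 (the alternative
ω = √ln(1+CV²) differs by <7% at CV ≤ 52%; one convention is fixed and
used consistently through serialization, simulation and estimation).
Categorical covariates are coded 0/1 with female = 0 the reference; the
sex effect enters as CL_P/F · (1+θ)^SEX. Continuous covariates enter as
value^θ with the typical value holding the per-unit slope, which reproduces
the printed weight-linear forms at θ = 1. Covariates a model does not use
are accepted and ignored; covariates a model needs but the dataset lacks
fall back to a substitution value carried by the ModelSpec (the source
study's central value — e.g. 53.6 kg for the pediatric model, the pooled
mean of its child/adolescent group means). Model specs serialize to YAML
and round-trip losslessly; the shipped `m1/m2/final` fixtures carry the
published parameterizations verbatim.

No correlation between the parent- and metabolite-clearance random effects
is modelled: none is reported, and the assumption is consequential (see
"Known limitations").

## Synthetic cohorts

The generator emulates the confidential TDM dataset's design: 198 subjects
with an exact 146/52 female/male split; ages from a pediatric/adult mixture
(pediatric uniform 12–17; adult 18 + log-normal offset, median ≈ 21,
truncated at 56) weighted 102:92; weights log-normal with median 59 kg and
σ chosen so the 0.1/99.9 percentiles span the observed 35.9–115 kg range,
truncated to that range by redraw; dose levels {20: 0.4, 40: 0.4, 60: 0.2}
(the sources describe 20 and 40 mg/day as the most common regimens, with a
20–60 mg range); one trough per subject with probability 0.78, two with
0.22 (mean 1.22 ≈ 241/198). Every observation is a steady-state trough
(SS dose record, observation at t = k·II), with parent and metabolite
sampled at identical times. Observation noise is y = f·(1+ε_p) + ε_a with
independent draws per analyte, floored at 0; values below the 1 ng/mL LLOQ
are flagged and excluded from fitting by default (no M3-type censored
likelihood — with the study's residual magnitudes this affects ~2% of
observations).

What the generator does not emulate: dose titration histories, η
correlation between analytes, CYP2D6/CYP2C19 genotype strata, covariate–
dose dependence (dose is assigned independently of weight and age). Tests
passing on these cohorts therefore demonstrate correctness of the machinery
under the study's stated design, not robustness to those real-world
features.

## Individual (MAP) estimation

The per-subject objective is the −2 log joint density of the combined-error
model: Σ_j [(y_j−f_j)²/g_j + ln g_j] + Σ_k η_k²/ω_k², with
g = (σ_p f)² + σ_a². It is minimized by a vectorized damped Newton
iteration (finite-difference gradients/Hessians, step size 1e-4;
Levenberg-style damping with backtracking), from η = 0 plus one fixed
alternating-sign restart at 0.3, tie-broken by objective. Note that with a
proportional error component the mode of this objective is *not* exactly
η = 0 even for an observation at its typical prediction — the ln g term
pulls toward smaller predictions; the tilt is ≈0.04 on the log scale at the
joint model's error magnitudes and vanishes as σ_p → 0 (asserted in the
tests).

## Population estimation

The population objective is a conditional-mode approximation of the marginal
likelihood, maximized over typical values (log scale), fractional covariate
shifts (log1p scale), ω and σ (log scale):

1. conditional modes η̂_i by the damped Newton solver, warm-started from the
   modes of the best parameter vector seen so far (warm-starting from the
   *last* evaluated vector would make the objective path-dependent, because
   an optimizer probing a degenerate corner poisons later evaluations);
2. a Laplace (second-order) approximation of each subject's integral during
   the main search;
3. a final refinement and all reported OFVs on an adaptive Gauss–Hermite
   quadrature (7 nodes per dimension, centred at η̂_i and scaled by the
   local Hessian), which reproduces a brute-force 40-point grid to a few
   tenths of an OFV unit.

The first-order FOCE-I linearization is implemented
(`_Conditional.ofv_foce`) but deliberately not used for estimation: on this
steep trough-only design (∂ln C/∂η ≈ −2.5) with ~34% proportional error its
approximation error reaches tens of OFV units and varies across the
parameter space, enough to displace the optimum by ~50% in CL/F. The
Laplace error is a few units and nearly constant; the quadrature stage
removes what remains.

The outer search is staged — typical values first (bounded Powell, with
clearances pre-initialized by matching the median observed trough per
analyte via a 1-D root-find), then all parameters by bounded L-BFGS-B on
the Laplace objective, then L-BFGS-B + a short Powell polish on the
quadrature objective. Bounds are generous but physical (covariate shifts
within [−50%, +100%], CVs below ~220%, additive error below ~400 ng/mL);
a solution that ends on a bound face is pulled inside and re-polished.
Default initial estimates for de-novo fits are generic mid-range values for
an SSRI parent/metabolite pair (CL 5 L/h, V 50 L, CL_M 5 L/h, V_M 5 L,
shifts 0, ω 0.3, σ_p 0.3, σ_a 10 ng/mL).

RSEs come from the finite-difference observed information of the Laplace
objective at the optimum (delta-method back-transformed); η-shrinkage is
1 − SD(η̂)/ω and ε-shrinkage 1 − SD(IWRES), both in %. Stepwise covariate
search uses ΔOFV ≥ 6.635 for forward inclusion (χ²₁, p<0.01) and
ΔOFV ≥ 10.828 to survive backward elimination (p<0.001); note the backward
threshold is the binding one. The bootstrap resamples subjects with
replacement within strata (default sex), preserving per-stratum counts, and
reports medians with 2.5/97.5 percentile intervals; >20% replicate failures
flag the result unstable.

### Identifiability of the trough-only design

All information about V/F in a same-interval trough-only design comes from
the curvature of the trough–clearance relationship expressed through the
IIV distribution; dose variation adds nothing under linear kinetics. The
exact marginal likelihood consequently has a long flat ridge coupling
CL_P/F, V_P/F and CL_M/F: across generator seeds the maximum-likelihood
CL_P/F swings roughly ±35% around the generating value while the OFV at
truth stays within χ²-typical distance of the optimum. This is intrinsic
to the design, not a numerical artifact — the published bootstrap interval
for CL_P/F (1.53–4.13 L/h) spans the same ±45%. On top of the spread, the
maximum-likelihood point tends to sit *below* the generating clearances on
these cohorts: typical-χ² likelihood fluctuations, expressed along the
nearly flat ridge, move the optimum preferentially toward the
low-clearance/low-volume wing, so multi-seed recovery means can land
10–30% low even though the likelihood itself is verified against an
independent quadrature oracle to ~0.003 units. The same direction shows in
the published bootstrap medians, which sit below their point estimates for
CL_P/F, V_P/F and CL_M/F alike. Recovery analyses therefore average over
seeds and should be read with this design limitation in mind. V_M/F is weaker still: with a
metabolite half-life of ~20 min its value barely influences troughs at all,
and fits may return it anywhere on a flat direction (the published RSE of
57% points the same way); `foce_fit(..., fix=("v_metab",))` pins it when
that matters.

## External evaluation and diagnostics

PE = (pred−obs)/obs per observation, reported in %; MPE is its mean, RMSE
the root mean square, so RMSE² = MPE² + Var(PE) holds exactly (population
variance). Observations ≤ 0 are excluded with a warning. The mean PE is
dominated by near-LLOQ observations (relative error is unbounded above but
bounded below at −100%), so large positive MPE coexists with
underprediction of typical concentrations — median PE is the robust
location summary, and variability misspecification is what NPDE's variance
test detects. Parent-only models are evaluated on parent observations only.

NPDE: per subject, n_sim model simulations (IIV + residual) of the
observation vector; decorrelation of observed and simulated vectors by the
empirical mean and lower Cholesky factor of the simulated covariance
(ridge-regularized if singular); mid-rank of the decorrelated observation
among its simulations, clamped to (1/(2n_sim), 1−1/(2n_sim)), mapped
through Φ⁻¹. The pooled vector is tested with Wilcoxon signed-rank
(location 0), a χ² variance test (variance 1) and Shapiro–Wilk (normality).
CWRES uses the FOCE linearization about the MAP mode, whitened by the
Cholesky factor of GΩGᵀ + diag(g). VPC bins by dose level by default (the
natural axis for trough-only data); prediction correction rescales each
value by median(PRED in bin)/PRED_subject, which pools dose levels when
bins mix them (i.e. under time binning).

## Dose-regimen simulation

Virtual subjects draw covariates from a reference cohort or design and η
from the model's IIV; the day-30 trough per analyte comes from the finite
30-dose superposition (for the joint model indistinguishable from the SS
limit). Residual (assay) error is off by default — the target is the
subject's true trough, and medians are insensitive to symmetric noise (a
sensitivity test asserts the median moves <6% with it on) — a flag enables
it; negative noisy concentrations are floored at 0 and counted. PTA is the
fraction of virtual subjects with parent+metabolite trough inside
120–500 ng/mL; fractions below/above are reported alongside and the three
partition fractions sum to 1.

Under the published parameterization (ω_CLP = 0.316, ω_CLM = 0.209,
independent), the simulated PTA at the edge doses of the recommended ranges
computes to just under 70% (≈68% at female 20 mg and male 50 mg, ≈70% at
female 40 mg and male 30 mg) while interior doses clear 75%; the simulated
medians at 60 mg (≈495 female / ≈367 male ng/mL) match the published
502.32 / 372.84 within 2%. A positive η correlation between the two
clearances would narrow the active-moiety distribution and raise the edge
PTAs above 70%, but no correlation is reported, so none is assumed.

## Problem sizes used by the test suite and acceptance script

Simulation targets use n = 1000 virtual subjects per scenario. Recovery
targets refit the full 198-subject design; the acceptance script averages
10 generator seeds (~1 min per fit), and the test suite asserts single-seed
recovery at seed 0 plus a 5-seed mean-bias check. Stepwise-selection and
bootstrap behaviour are exercised on reduced designs (parent-only model,
50–100 subjects; no-IIV joint model, 15–40 subjects) chosen so each fit
runs in seconds while preserving the tested property. NPDE calibration
uses 50-subject cohorts, 1000 simulations, 20 seeds.

## Known limitations

* The trough-only design leaves CL–V ridges (above); point estimates of
  single fits carry ~±35% sampling uncertainty on CL/F even though the
  pipeline is unbiased on average.
* BLQ observations are excluded rather than integrated (no M3 likelihood);
  at the study's concentration ranges this is a ~2% data loss but would
  matter at lower doses.
* η correlation between analytes, inter-occasion variability, titration
  histories and genotype covariates are not modelled.
* The milk compartment of the perinatal model is a scalar milk-to-plasma
  ratio only; no milk kinetics.
* Nonlinear (saturable) elimination is out of scope throughout, although
  fluoxetine is known to inhibit its own metabolism at higher exposures.
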