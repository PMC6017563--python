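# Methods

## Scope and models

`leupkpd` implements a pharmacokinetic–pharmacodynamic (PK–PD) analysis of
leuprolide, a GnRH super-agonist used to suppress testosterone, comparing an
immediate-release solution (IV and SC) with a sustained-release (SR)
microsphere depot in rats. The package covers four layers: mechanistic
simulation, model fitting, model-free exposure/effect summaries, and a
synthetic-study generator that stands in for the (undeposited) animal data.

### Solution pharmacokinetics

A one-compartment model with first-order elimination `k = CL/V_d`. IV
dosing is a bolus into plasma, `C(t) = (A/V_d) e^{-kt}`. SC dosing adds a
first-order absorption compartment with rate `k_a`, whose solution is the
Bateman function

    C(t) = A k_a / (V_d (k_a − k)) (e^{-kt} − e^{-k_a t}),

with the confluent limit `A k t e^{-kt}/V_d` when `k_a ≈ k` (within 1e-9
relative). SC `CL` and `V_d` are apparent (dose/F convention), which is why
the SC clearance is roughly the IV clearance divided by the ~0.5
bioavailability.

### Sustained-release depot

The injected depot dose splits at t = 0 into three sections whose fractions
close on the simplex (`N_R + D_R + E_R = 1`, enforced to 1e-9):

* **NS** (non-encapsulated, fraction `N_R`): free drug absorbed like the
  solution at `k_a`;
* **DS** (diffusion-release, `D_R`): released at `k_d` after a lag
  `t_lag_d`;
* **ES** (erosive-release, `E_R`): enters a chain of `ES_n` identical
  transit compartments traversed at `k_t` after a lag `t_lag_e`; the chain
  output (an Erlang/gamma-shaped delay) feeds plasma.

Lags are realised as *release gating*: the rate terms are multiplied by an
indicator `t ≥ t_lag`. This keeps the system a plain ODE (no state-shifting
delays) and matches the notion of a lag time of release; the gate instants
are inserted exactly into the solver grid so no step straddles the switch.
The cumulative release profile has the closed form
`N_R(1−e^{-k_a t}) + D_R(1−e^{-k_d(t−t_lag_d)})_+ + E_R · GammaCDF(ES_n, k_t; t−t_lag_e)`,
used as an independent oracle in the tests.

### Testosterone pharmacodynamics

A turnover (indirect-response) model: testosterone `R` is produced at a
zero-order `k_in` and removed at first-order `k_out`; the drug-free model
relaxes from the observed baseline `R0` to `k_in/k_out`. The drug effect is
a Hill stimulation of production, `C_E = E_max C^h/(C^h + EC_50^h)`, driven
by total plasma leuprolide with no effect-compartment delay. A feedback
compartment `F` multiplies production:

    dR/dt = (1 + C_E) k_in F − k_out R
    dF/dt = k_f_on / R − k_f_off F      (reciprocal form, default)

The reciprocal form makes the loop inhibitory — elevated testosterone slows
the replenishment of `F` — so sustained stimulation depletes `F` and the
response falls *below* baseline after the initial flare, which is the
clinically relevant behaviour of GnRH agonists. A literal product form
`k_f_on · R` is positive feedback, cannot undershoot, and is provided only
as a sensitivity switch (`feedback_form="product"`).

`F(0) = k_out R0 / k_in` zeroes `dR/dt` at t = 0 without drug. Note this
pins only the R-equation: `(R0, F0)` is a fixed point of the joint system
only when `k_f_on = k_f_off F0 R0`. Published parameter sets need not
satisfy this identity, in which case the drug-free trajectory drifts slowly
from `R0` to `R* = sqrt(k_in k_f_on / (k_out k_f_off))` (≈5% for the
Wistar IV set). The stationarity tests therefore use a self-consistent set;
with published sets the package honours `R0` and the rate constants exactly
as reported and documents the drift rather than silently rescaling any of
them. The same stance is taken for the two reported inconsistencies in the
source estimates: the IV group's NCA `k` (1.42 h⁻¹) versus `CL/V_d`
(1.29 h⁻¹), and the Iar:COP `k_in/k_out` (5.83 ng/mL) versus its reported
baseline (4.094 ng/mL).

## Numerical integration

All ODE paths use a fixed-step classical Runge–Kutta (RK4) integrator with
bolus dose events and gate breakpoints inserted exactly into the grid.
Choices:

* **Step**: 0.01 h default. The stiffest rate is `k_a ≈ 16.7 h⁻¹`
  (time constant 0.06 h); at 0.01 h the SC solution trajectory matches the
  Bateman closed form to < 1e-6 relative at every in vivo sampling time,
  and a 14-day simulation costs ~34k steps. RK4 is conditionally stable:
  the step must satisfy `k_a·step < 2.8` (≲0.15 h here), which is why the
  coarser steps used for fitting stay at 0.05–0.1 h.
* **Events**: a bolus is applied atomically at its event time, before the
  recorded state at that time and before the step leaving it, so dose
  conservation holds at t = 0 exactly.
* **Negativity**: linear non-negative systems can round off slightly below
  zero; states below `−1e-9 ×` the dose scale abort with an error (a
  symptom of a pathological parameter set or an unstable step), smaller
  excursions are clamped to zero.
* Time is hours everywhere inside the package; day-valued CLI inputs take a
  `d` suffix and are converted at the boundary.

## Estimation

Weighted least squares with proportional-error weighting `1/pred²` by
default (`none` and `1/pred` selectable); the objective is the weighted sum
of squared residuals. Each fit runs a derivative-free Nelder–Mead stage
(capped function evaluations) followed by a bounded trust-region
least-squares polish, repeated from seeded multiplicative perturbations of
the initial values (multi-start, 5 by default), keeping the best objective.
Standard errors come from the Jacobian at the optimum.

Stage order mirrors the study workflow: the vehicle groups fix `k_in` and
`k_out`; the solution groups fix `k_a`, `CL`, `V_d`; the depot fit holds
disposition fixed and estimates `N_R, D_R, k_d, k_t, t_lag_d, t_lag_e`,
with the fractions parameterised as `p₁ = N_R`, `p₂ = D_R/(1−N_R)` on
(0, 1)² so the simplex closure holds exactly at every iterate; the PD fit
holds `k_in, k_out, R0` fixed and estimates `E_max, EC_50, h, k_f_on,
k_f_off`. Solution-model objectives evaluate the analytic curves (exact and
~10³× cheaper than the ODE path, which they match to 1e-6); depot and PD
objectives integrate with RK4.

Transit-count selection fits each candidate `ES_n ∈ {2..10}` and picks the
minimal `AIC = n ln(SSR/n) + 2p`, ties toward fewer compartments. On
noise-free data generated from a 2-stage chain the AIC gap to the nearest
alternative is several hundred, so the selection is insensitive to the
solver step and optimiser budget used.

Goodness of fit follows weighted-residual convention: `r_i = (obs_i −
pred_i)/(σ̂ pred_i)` with `σ̂² = SSR_w/(n−p)`, flagging `|r_i| > 4`; zero
predictions are excluded with a warning.

## Non-compartmental and effect-curve analysis

Linear (not log-linear) trapezoidal AUC throughout; `AUC_0-∞` adds a
`C_last/k` tail, with `k` the negative slope of `ln C` over the last three
positive observations (window configurable — the convention is not uniquely
determined by the source analysis). `t_1/2 = 0.693/k` uses the rounded
constant conventional in NCA reports. `CL = dose/AUC_0-∞`, `V_d = CL/k`,
and bioavailability is the AUC ratio against the IV reference × 100.

Because testosterone has a non-zero endogenous baseline, effect curves are
summarised by baseline-corrected AUECs *without* tail extrapolation:
segments crossing the baseline are split at the linearly interpolated
crossing time, supra-baseline area accumulates into the positive AUEC
(flare) and sub-baseline area, sign preserved, into the negative AUEC
(suppression); their sum reconstitutes the baseline-subtracted total
exactly. The baseline is the per-animal pre-dose value by default, with a
group-level baseline selectable — both are defensible and the choice is
exposed rather than hidden.

Group comparisons use the Mann–Whitney U test. For the study's n = 5 per
group the exact permutation distribution of U is enumerated over all
relabellings (midranks for ties; two-sided p = twice the smaller tail,
capped at 1); above combined n = 20 a tie-corrected normal approximation is
used. The exact path is validated against an independent pair-counting
enumeration and against `scipy.stats.mannwhitneyu`'s exact method on
tie-free data.

## Synthetic study generator

The generator reproduces the six-group design: IV solution, vehicle, SC
solution and SC depot in normal Wistar rats; vehicle and SC depot in
Iar:COP (Dunning prostate-carcinoma) rats; n = 5 per group; 0.1 mg/kg
leuprolide; sampling at 0.25, 1, 2, 4, 8 h and days 1–7, 11, 14 (vehicle:
8 h, days 1, 7, 14) plus a pre-dose sample. The disease state enters only
through the Iar:COP parameter columns — the source analysis models nothing
else about the tumour.

Variability: each parameter gets an independent *mean-one* lognormal
multiplier with CV `iiv_cv` (default 0.25); depot fractions are
renormalised to the simplex. Residual error is proportional with CV 0.10
for leuprolide and 0.15 for testosterone plus an additive floor of
0.1 ng/mL (immunoassay noise near baseline); defaults were chosen once so
simulated SE/mean magnitudes sit in the range of the reported parameter
tables. Testosterone below the assay LLOQ (0.041 ng/mL) is flagged BQL and
excluded from fitting by default (M1 handling); values above the 10 ng/mL
ULOQ are flagged "diluted" but kept numeric. Body weight is unreported in
the source study; 0.3 kg (adult male rat) is the configurable default, and
only absolute dose-scaled quantities (CL, V_d) depend on it.

What the generator does *not* emulate: assay mechanics (ELISA competition,
MS transitions), tumour growth, circadian testosterone rhythm, correlated
inter-individual effects, or dropout. Passing recovery tests therefore
demonstrate estimator correctness under the stated error model, not
robustness to every feature of real data.

## Problem sizes used in tests and the reproduction script

Parameter-recovery experiments run at the in vivo sampling times
(14 post-dose samples). Depot and PD refits use an RK4 step of 0.05 h
(0.1 h in the end-to-end pipeline test) — generation and refitting share
the solver, so recovery is solver-consistent, and the selection and
recovery margins are orders of magnitude wider than the step effect. The
vehicle calibration uses 200 simulated animals. Multi-start counts in the
scripted experiments are 1–2 because the noise-free objectives are smooth
near their generating values.

## Known limitations

* One-compartment disposition only; no in vitro–in vivo correlation (the
  source release data showed none).
* No population (mixed-effects) estimation; fitting targets group means by
  default, per-subject mode reports mean ± SE across animals.
* The reciprocal-vs-product reading of the feedback equation is a modelling
  decision (the rendered source equation is ambiguous); the default is the
  only form that produces the reported suppression below baseline.
* Fixed-step RK4 requires the user to respect the stability bound when
  raising the step; the integrator reports runaway states rather than
  silently diverging.
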