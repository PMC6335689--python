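# Methods

## Model structure and assumptions

The liver is treated as a lumped, spatially homogeneous compartment.  Eleven
state variables evolve per day: hepatocyte fractions Q (quiescent), P
(primed), R (replicating); molecular species IL6, JAK, STAT3, SOCS3, IE, GF,
ECM relative to their intact-organ baselines (= 1); and the relative cell
mass G of the cycling pool.  Functional mass is N = Q + G·(P + R); only the
cycling pool carries hypertrophy, so a trajectory with P = R = 0 has N = Q
regardless of G.

Signalling follows the canonical priming/progression cascade: metabolic
overload per functional cell, M/(N + ε), drives IL-6 release and GF
liberation; IL-6 activates JAK/STAT3 with SOCS3 feedback; the
immediate-early signal IE primes quiescent cells; GF advances primed cells
into replication; restored ECM returns replicating cells to quiescence.
Apoptosis removes cells from all three pools at rate k_ap·σ_ap, where σ_ap
is a tanh switch with midpoint θ_ap and slope β_ap on the inverse per-cell
load (N + ε)/M.  The senescent fraction ε = 0.01 is functional but
non-replicating mass; it bounds the per-cell load at M/ε as N → 0, which is
what keeps failure trajectories integrable.

Seven homeostatic constants k1…k7 are chosen in closed form so that every
molecular balance vanishes at the baseline state (species = 1, N = N_ss =
0.99).  They cancel molecular fluxes only; the apoptosis term
−k_ap·σ_ap(N_ss)·Q remains, and is ~e⁻⁶⁰ for the reference parameters — the
organ is at rest to within the switch tail.  Two structural edge effects
follow from ε > 0 and are accepted rather than patched: (i) the
zero-resection initial condition Q₀ = 1 sits an ε-offset above the rest
state N_ss and relaxes by ~1% over the horizon; (ii) during that relaxation
IE dips below baseline and the unguarded priming flux k_QP·(IE − 1)·Q can
push P a few 10⁻³ negative.  Output states are clipped at zero with a
warning; excursions beyond 5·10⁻³ raise, as they would indicate an
integrator problem rather than this structural feature.

**Time base.** The source material never states the unit of the rate
constants.  Days is the only base consistent with the published rate
magnitudes and multi-year recovery horizons, and is used throughout
(1 year = 365 d; the classification timepoints are 730 d and 912.5 d).

## Integration

`solve_ivp` with BDF, analytic Jacobian, rtol 1e-8, atol 1e-10 (the system
is stiff: ECM turnover under cytokine storm runs ~10⁴/day while recovery
tails evolve over years).  The output grid is the solver's own steps plus
mandatory nodes {0, 730, 912.5} d; interpolation between nodes is monotone
cubic (PCHIP).  tanh arguments are clipped at ±50, which changes nothing at
double precision but avoids overflow warnings.  Halving the tolerances
moves N(730 d) by < 1e-4 in the reference scenario.  Calibration uses
LSODA at rtol 1e-6/atol 1e-8 for speed; fitted optima are re-scored at the
reporting stage by the same residual function.

## Classification rules

* **failure** — mass fraction below 0.1 from two years post-surgery onward
  (or early exit through the absorbing N = 0.05 level);
* **unresponsive** — mass fraction never departs from its post-surgical
  value by more than δ_flat = 0.01 (no published value; 1% of organ mass);
* **normal** — long-term mass fraction within 0.9–1.1;
* **suppressed** — everything else (recovered, short of the window).

The normal/suppressed window is evaluated at the end of the supplied
trajectory.  Classifying a 2.5-year run gives the literal
"0.9–1.1 at 2.5 years" rule; the cohort pipelines default to a 10-year
horizon because the reference parameterization crosses 0.9 only at ~8.5
years — its recovery plateau, not its 2.5-year snapshot, is what the
mode taxonomy describes.  Both conventions are one argument away.

**Threshold of failure.** The scan walks resection levels 5–90% in 1% steps
(1% makes the published threshold percentages exactly representable) and
reports the lowest *failing* level.  Failure here is basin membership: each
level is integrated over a long horizon (default 100 years) with an
absorbing early exit at N = 0.05, and fails if N drops below 0.1 any time
from two years onward.  A two-year snapshot alone misclassifies
slow-collapse patients that spend years above 0.1 before failing — exactly
the cells near the separatrix, including the published "no safe level of
resection" cases, which only reproduce under the basin rule.  The failure
boundary is monotone in the resection level throughout the bistable regime,
so the default scan bisects the grid (O(log n) simulations); `scan="full"`
simulates every level.  Bisection and full scan are asserted to agree in
the tests.

## Virtual-patient cohorts

Cohorts are scrambled-Sobol samples over selected parameters (default
bounds M ∈ [0.5, 25], β_ap ∈ [0.005, 0.12] — wide enough to contain every
published operating point; all published values lie in [1.139, 22] ×
[0.0045, 0.085]), everything else at the reference values; bit-identical
given the seed.  The paired "50 × 50" design crosses two independent 1-D
Sobol axes so each metabolic-load value meets every death-sensitivity
value.  One-at-a-time influence sweeps use log-spaced levels over ten-fold
ranges for the five strongly rescaled parameters {M, k_G, θ_ap, KM_ST3,
κ_JAK} and two-fold otherwise, and classify each parameter by (a) whether
any level fails and (b) whether the spread of the long-term mass fraction
across non-failing levels exceeds δ_sens = 0.05 (no published value), with
the sign of the correlation separating improves/decelerates.  The decision
boundary between normal growth and the other modes is a cubic-polynomial
SVM with the box constraint cross-validated over a log grid on [1, 10⁴].

## Calibration

Observed relative liver volume is equated with the model's mass fraction
N(t).  The fit minimizes

    SSE(p) + λ·[α·‖u‖₁ + (1 − α)·‖u‖₂²],   u = log(p / p_init)

— an elastic net on log-fold-changes from the initial parameter vector, so
sparsity acts on exactly the across-species scale factors one reports.
Defaults λ = 1e-3, α = 0.5 (no published values).  The smoothed L1
(√(u² + δ²) − δ, δ = 1e-4) lets a bounded trust-region least-squares solver
handle the objective; the Jacobian uses forward differences with an
*absolute* step of 1e-3 in u — a relative step degenerates at the log-fold
origin and falls below the ODE-solver noise floor.  Multi-start: the
initial guess plus Sobol points within the search box (ten-fold bounds for
the five strongly rescaled parameters, two-fold otherwise), screened by one
objective evaluation each, best-penalized-objective wins.  A failed
integration scores a large sentinel cost so the optimizer retreats from
pathological corners.

Identifiability shapes the recommended use: with 4–8 volumetry points only
the metabolic load M and mass-growth constant k_G (and, weakly, β_ap) are
practically identifiable; the remaining constants are sloppy directions
that a 33-parameter fit uses to absorb noise.  Recovery scoring therefore
fits the declared significant subset (`SIGNIFICANT_PARAMS`); freeing all 33
remains the default surface with the elastic net shrinking the rest.  A
known limit: on recovery-only series the apoptosis switch stays closed, so
θ_ap carries no signal and stays at its initial value — the across-species
θ_ap rescaling is not recoverable from such data under this formulation.

Allometric alternatives to the full fit map body mass m (grams, from
1000·BMI·height², heights 1.72/1.58 m for male/female) to the load:
M = 23.409·m⁻⁰·¹¹⁸, or M = 47.315·m⁻⁰·¹⁸²⁵ paired with k_G = 6.5675e-4.

## Synthetic data

The generator emulates the statistical structure of post-hepatectomy
volumetry follow-up, which is not redistributable: per-patient ground truth
drawn log-uniformly within two-fold of the reference on {M, k_G, β_ap};
4–8 observations log-spaced over [14, 912.5] d (denser early, as in
clinical follow-up); multiplicative lognormal noise with sd 0.05 (volumetry
error scales with volume); resection uniform on [0.30, 0.70]; BMI ~
N(22.5, 3) truncated at 15 and sex ~ Bernoulli(½) for the allometric path.
Everything is determined by the spec seed.  It does **not** emulate:
irregular per-patient visit schedules beyond count variation, censoring or
dropout, measurement error correlated in time, re-resection, or any
correlation between covariates and model parameters.  Passing recovery
tests therefore demonstrate identifiability under idealized sampling, not
clinical-data performance.

The packaged rodent baseline (`rat_baseline_synthetic.json`) is a labelled
synthetic stand-in: the human reference with the reported direction of the
rat-to-human fold changes inverted (allometric M at 250 g, ten-fold faster
k_G, lower θ_ap, higher KM_ST3/κ_JAK).  It serves only as a calibration
initial guess and a direction-consistency test anchor.

## Problem sizes in the shipped tests

Threshold scans in tests use grid bisection; the cohort topology test uses
400 virtual patients (a scaled-down version of the published 1000-patient
design) and the recovery harness 20 synthetic patients with single-start
subset fits.  The acceptance script runs the five published operating
points as full 86-level scans.

## Known limitations

* No spatial/lobular heterogeneity, no multi-stage hepatectomy protocols,
  no SBML export.
* The separatrix region of the (M, β_ap) plane is numerically delicate:
  trajectories there crawl for decades between basins, and the computed
  threshold at the published transition cell (M = 2.293, β_ap = 0.071) is
  63%, robust to solver choice and tolerance, versus the published 58% —
  a genuine sensitivity of the tipping point to implementation detail at
  the critical transition.  All other published operating points reproduce
  within one grid step.
* No uncertainty quantification on fitted parameters (no profile
  likelihood or bootstrap).
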