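# hepregen

Dynamics of human liver regeneration after partial hepatectomy (PHx), as a
tested Python package: a stiff 11-variable ODE model of hepatocyte state
transitions driven by metabolic load, plus the analyses built on it —
response-mode classification, threshold-of-failure (tipping point) scans,
virtual-patient cohorts over the two critical perioperative parameters, and
elastic-net calibration against liver-volumetry time series.

## Who this is for

Systems biologists and surgical-modelling researchers who want to simulate
patient-specific regeneration outcomes: will a given (virtual) patient
recover fully after removing a fraction of the liver, recover only
partially, or progress to liver failure — and what is the largest resection
that is still safe?

## The model

Hepatocytes occupy three functional states — quiescent (Q), primed (P) and
replicating (R) — coupled to seven molecular species (IL-6, JAK, STAT3,
SOCS3, immediate-early gene product IE, growth factor GF, and extracellular
matrix ECM) and a relative cell mass G capturing hypertrophy of the cycling
pool.  The functional liver mass fraction is

    N = Q + G·(P + R)

and the organ-scale metabolic demand per functional cell is M/(N + ε),
where M is the metabolic load and ε = 0.01 a senescent, non-replicating but
functional fraction that regularizes the near-zero-mass dynamics.  Two tanh
switches close the loop: apoptosis

    σ_ap = ½(1 + tanh((θ_ap − (N+ε)/M) / β_ap))

rises as the per-cell load grows, and requiescence σ_req returns primed
cells to quiescence once GF falls.  Homeostatic flux constants k1…k7 are
derived so the intact organ (all species = 1, N = N_ss = 0.99) is a fixed
point.  Resection of a fraction f sets Q₀ = 1 − f with everything else at
baseline.  Time is measured in days.

The system is bistable over a wide parameter range: a recovery attractor
near full mass coexists with a failure attractor at N = 0, and the smallest
resection whose trajectory enters the failure basin is the patient's
*threshold of failure*.  Raising the metabolic load M or the cell-death
sensitivity β_ap shrinks the recovery basin until no safe level of
resection remains.

## Worked example

```python
import hepregen as h

p = h.id71_optimal()                      # packaged human-fitted parameters
tr = h.simulate_resection(p, 2/3, horizon=912.5)
print(f"N(2.5 y) = {float(tr.mass_at(912.5)):.3f}")

r = h.threshold_of_failure(p.replace(M=4.0))
print(f"threshold at M=4: {r}")

r = h.threshold_of_failure(p.replace(M=22.0))
print(f"threshold at M=22: {r}")
```

prints

```
N(2.5 y) = 0.836
threshold at M=4: 87%
threshold at M=22: none-safe
```

i.e. the reference patient has regained ~84% of preoperative mass 2.5 years
after a two-thirds hepatectomy; a virtual patient with metabolic load
lowered to 4 tolerates up to 86% resection and fails at 87%; and at M = 22
even a 5% resection enters the failure basin.

The same operations are exposed on the command line:

```bash
hepregen simulate --resection 0.667 --horizon 912.5 --out traj.csv
hepregen threshold --grid 0.05:0.90:0.01
hepregen cohort --vary M,beta_ap --n 1000 --resection 0.667 --seed 7 --out modes.csv
hepregen fit --series patient.csv --out fit.json
```

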