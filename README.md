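# cveukit

Quantifying intestinal epithelial turnover from thymine-analog pulse-chase
data along the crypt–villus axis.

The small-intestinal epithelium renews continuously: cells born in the
crypts migrate up the adjacent villi and are shed from the villus tips.
`cveukit` implements the quantitative analysis of this process from
BrdU/IdU pulse-chase experiments scored along one-dimensional
**crypt–villus epithelial units** (CVEUs): columns of cells running from a
crypt base (position 1) to a villus tip (position *L*), each position
scored 1 if labeled, 0 if not. It is aimed at quantitative biologists who
have such positional score data — or who want to study the estimators on
simulated data — and provides:

* a **two-compartment label-propagation model** and its piecewise
  closed-form solutions,
* **nonlinear least-squares fitting** of the model to labeled-cell counts
  per compartment, in a statsmodels-style `Model.fit() -> Results` API,
* derived **kinematics**: cell velocities, crypt production rates and
  crypt-to-tip transit times,
* **Monte Carlo posterior comparison** of production rates across
  experimental groups,
* an **agent-based 1-D simulator** of the CVEU that generates complete
  synthetic experiments for every regime (control, genetically reduced
  proliferation, transient proliferation arrest).

## The model

Let `L_C(t)` and `L_V(t)` be the numbers of labeled cells in the crypt
(positions 1..`N_C`) and villus compartments. After a label pulse,

```
dL_C/dt = δ·L_C·(1 − H(L_C − L_C*))
dL_V/dt = δ·L_C·H(L_C − L_C*) − γ·L_V·H(L_V − L_V*)
```

where `δ` (h⁻¹) is the specific cell proliferation rate in the crypt —
equal to the specific crypt→villus transfer rate, because crypt size is
constant under homeostasis — `γ` (h⁻¹) is the shedding rate at the villus
tip, and `H` is the Heaviside step (H(0) = 1). Transfer begins when the
labeled crypt population reaches the threshold `L_C*` (at time `t1`) and
shedding when the labeled villus population reaches `L_V*` (at `t2`).
Before shedding the solution is piecewise:
exponential crypt growth `L_C = L_C0·e^{δ(t−t0)}` for `t < t1`, then a
crypt plateau at `L_C*` with linear villus accumulation at rate `δ·L_C*`.

Fitting this pre-shedding solution to observed compartment counts (on the
variance-homogenizing scale `log(L+1)`) yields `δ`; with the crypt size
`N_C` estimated from the 2-h labeling profile, the derived kinematics are

* mitotic-pressure velocity at crypt position *x*: `V_x = δ·x`,
* boundary velocity / crypt cell production rate: `V_CV = δ·N_C`,
* crypt transit `ln(N_C)/δ`, villus transit `(L − N_C)/(δ·N_C)`,
* labeled-front velocity on the villus, `V_LF`, by linear regression of
  front position (µm) on time.

Group differences in `V_CV = δ·N_C` are assessed by Monte Carlo: `δ | X`
inverse-gamma, `N_C | X` log-normal (both moment-matched to the estimate
and standard error), 10,000 draws, significance when
`P[V_CV(i) > V_CV(j) | X] > 0.95`.

## Worked example

Simulate a control-duodenum experiment (30 CVEUs at each of 8 sample
times) and run the full pipeline — profiles, boundary estimation,
compartment counts, dilution exclusion, model fit, kinematics:

```python
import tempfile
from cveukit import (RunConfig, run_pipeline, scenario_presets,
                     simulate_cveu, write_simulation)

sim = simulate_cveu(scenario_presets("control_duodenum"), seed=1)
with tempfile.TemporaryDirectory() as d:
    write_simulation(sim, d)
    res = run_pipeline(RunConfig(input_dir=d))
print(res.fit.summary())
```

```
Two-compartment label model (pre-shedding), NLS on log(L+1)
==============================================================
scheme: control       boundary N_C: 20 cells
n residuals used: 8   excluded: 8   RMSE (log scale): 0.0941
--------------------------------------------------------------
parameter     estimate     std err
delta          0.07559      0.0101
t1               2.814        1.12
l_c0             8.034        0.86
t0                   0     (fixed)
l_v0                 0     (fixed)
--------------------------------------------------------------
V_CV = delta*N_C = 1.51 cells/h (crypt cell production rate)
```

The fitted specific proliferation rate (0.0756 h⁻¹) recovers the
generating value (0.0760 h⁻¹); 8 of 16 count records were excluded by the
label-dilution rule. The implied kinematics
(`res.kinematics`) give a crypt transit of 39.6 h and a villus transit of
52.7 h — 92.4 h from crypt base to villus tip.

The same steps are available from the shell via the `cveu` command
(`simulate`, `profile`, `boundary`, `fit`, `velocity`, `sensitivity`,
`compare`, `run`); all inputs and outputs are plain delimited text.

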