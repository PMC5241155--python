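# Methods

## The two-compartment label-propagation model

The crypt–villus epithelial unit (CVEU) is treated as a 1-D column of
cells: crypt positions 1..N_C (all proliferative cells plus some
non-proliferative cells near the top), villus positions N_C+1..L.
Homeostasis fixes the crypt size, so every division is balanced by the
transfer of one cell across the boundary: the specific proliferation rate
δ equals the specific transfer rate. A thymine-analog pulse labels a
subset of crypt cells; labeled counts per compartment, L_C and L_V, then
obey the gated system

    dL_C/dt = δ·L_C·(1 − H(L_C − L_C*))
    dL_V/dt = δ·L_C·H(L_C − L_C*) − γ·L_V·H(L_V − L_V*),   H(0) = 1.

The transfer threshold L_C* encodes the observation that the pulse labels
mid-crypt cells, so there is a delay t1 before labeled cells reach the
boundary; the shedding threshold L_V* encodes the delay t2 before the
labeled front reaches the villus tip. The thresholds and phase times are
linked by L_C* = L_C0·e^{δ(t1−t0)} and L_V* = L_V0 + δ·L_C*·(t2−t1), and
the solution is piecewise: exponential crypt growth, then a crypt plateau
with linear villus accumulation at δ·L_C*, then (after t2) exponential
relaxation of L_V at rate γ toward the balance level δ·L_C*/γ.

**A subtlety of the gated ODE.** Taken literally, the state-dependent
shedding gate produces a Filippov sliding mode: whenever δ·L_C* < γ·L_V*
(the usual situation), the vector field pins L_V at L_V* instead of
letting it relax. The piecewise solution instead latches the gate — once
the labeled front reaches the tip, shed cells stay labeled and shedding
stays on. The package implements the latched reading: `ode_rhs` evaluates
the literal gates by default but accepts an explicit gate state, and the
closed-form/ODE equivalence tests integrate phase-wise with each gate
latched at its threshold event.

Counts are real-valued throughout (they are sums of labeled proportions
averaged over ≥30 CVEUs, not integers).

## From score matrices to model inputs

* **Profiles** — per-position labeled proportion, column means of the 0/1
  score matrix; ragged CVEU lengths are NaN-padded and excluded
  per-position.
* **Boundary** — N_C is the first position above the 2-h profile's peak
  with labeled proportion < 0.01 (default, configurable). Scanning above
  the peak matters: the 2-h profile is also low at the crypt base, and a
  global scan would return a base position.
* **Counts** — sums of proportions at positions 1..N_C (crypt) and
  N_C+1..L (villus), per sample time.
* **Dilution/shedding exclusion** — the analog is diluted below detection
  after ~4–5 divisions, so late crypt counts fall and, because cells
  arriving late on the villus have divided just as often, late villus
  accumulation flattens. Crypt decline onset is the first time from which
  the (3-point-smoothed) count stays below 0.9× its running maximum;
  villus plateau onset is the first split point where the trailing OLS
  slope drops below 10% of the leading slope. By default a crypt decline
  also masks the villus points at those times (dilution is a property of
  the sampling time, not of one compartment). All parameters are exposed
  on `ExclusionPolicy`; manual exclusion lists override the rules.

## Fitting

The pre-shedding solution is fitted to both compartments jointly by
nonlinear least squares on the log(L+1) scale (variance homogenization;
equal weight per residual — the neutral choice). Fixed/free parameters
follow the experimental regime:

| scheme       | fixed               | free              |
|--------------|---------------------|-------------------|
| control      | t0 = 0, L_V0 = 0    | δ, t1, L_C0       |
| omomyc       | t0 = 0, L_V0 = 0    | δ, t1, L_C0       |
| arac_early   | t0 = t1 = 15 h      | δ, L_C0, L_V0     |
| arac_late    | t0 = t1 = 25 h      | δ, L_C0, L_V0     |

The arrest regimes fix t1 = t0 because the labeled front is already on
the villus when those windows begin; with t1 fixed, δ enters only through
the villus slope and may legitimately be estimated negative, so its lower
bound is relaxed below zero there (elsewhere δ > 0, as the exponential
phase requires). The optimizer (trust-region reflective least squares)
restarts from 5 deterministic points spanning δ ∈ [0.01, 0.2] and
t1 ∈ [2, 30]; a soft penalty keeps the fitted crypt plateau within the
crypt's capacity N_C, with a final projection onto the feasible set.
Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹ at the
optimum; the reported RMSE is on the transformed scale.

Kinematics follow from the estimates: V_x = δ·x inside the crypt,
V_CV = δ·N_C at the boundary (also the crypt cell production rate), crypt
transit ∫₁^{N_C} dx/(δx) = ln(N_C)/δ (the lower limit is position 1 —
positions are 1-based and V_x vanishes at x = 0), villus transit
(L − N_C)/(δ·N_C). The labeled-front velocity V_LF is the OLS slope of
front position (µm) on time (h).

Note: total transit times computed this way reproduce the reported
totals, but the villus-only times quoted in the source discussion (49 h
ileum, 60 h duodenum) are not recoverable from the reported parameter
values by (villus cells)/(δ·N_C), which gives ≈41 h and ≈52 h; the
discrepancy is noted and not chased.

## Statistical inference

V_CV = δ·N_C is treated as a product of independent posteriors: δ | X
inverse-gamma, N_C | X log-normal, each moment-matched so the
distribution's mean/sd equal the fit's estimate/se (the matching rule is
the package's choice; round trips are exact). P[V_CV(i) > V_CV(j) | X] is
the fraction of 10,000 paired draws (ties count as not-greater);
significance at 0.95. V_LF | X is normal; draws ≤ 0 are rejected and
redrawn with a logged count (negligible at reported moments). The ratio
V_CV/V_LF estimates epithelial cell density (cells/µm); group differences
are judged by whether the 95% interval of the ratio difference covers
zero. All draws use a seeded `numpy` Generator; identical seeds give
identical results.

The skew of the inverse-gamma × log-normal product matters: at the
reported duodenal estimates the exceedance probability is ≈0.957 (just
significant), where a normal approximation would put it below 0.95.

## The simulator

Each CVEU is a conveyor: every crypt cell divides as a Poisson process at
rate δ; a division at position x inserts the daughter at x+1, shifts all
higher cells up one, and sheds the topmost cell, so crypt occupancy and
column length are exactly conserved. Labels and generation counters pass
to both daughters; a labeled cell scores 0 once its lineage has divided
`detection_limit_generations` times (default 5, matching the observed
4–5-generation detection limit). Arrest windows set the division rate to
zero. Sampling is cross-sectional — at each sample time an independent
cohort of `n_cveu_per_timepoint` (default 30) CVEUs is realized, as in
the tissue, where each time point is a different animal — so sampling
noise is independent across time points (required for honest standard
errors, especially in the arrest regime). Per-CVEU lengths are drawn from
a normal with the regime's mean/sd, truncated at N_C+1.

**Initial label profile.** The pulse labels each crypt position
independently with a trapezoidal probability: a plateau over the lower
and mid crypt (slightly reduced at position 1), a steep fall between 0.60
and 0.78 of the crypt, a sparse tail (20% of plateau) up to N_C−1, and
zero at N_C itself (cells there have completed their final S phase). The
profile is scaled so the expected labeled count matches the observed 2-h
totals per regime. Two features are load-bearing:

* On a conveyor the long-run labeled crypt content equals N_C times the
  labeling probability of the basal lineages, so the plateau must extend
  to the base for the crypt counts to show the observed
  exponential-then-plateau kinetics (a mid-crypt-only bump drains the
  crypt instead).
* The faint tail ending just below N_C makes the labeled proportion first
  drop below the 0.01 criterion at the boundary itself, so the boundary
  estimator recovers N_C from 30 CVEUs.

**Scenario presets** encode the study conditions per regime (δ, N_C, CVEU
length mean/sd, strip cell density, 2-h labeled totals) for control,
Myc-inhibited and Ara-C-treated duodenum and ileum. The Ara-C presets put
the arrest window at (15 h, 25 h) on the analysis clock (time 0 = 2 h
after the label pulse; the cytostatic is given 17 h after the label and
arrests divisions for 10 h), matching the fixed t0 = 15 h (early window)
and t0 = 25 h (late window) fitting schemes. Control/omomyc sample times
default to (0, 8, 13, 18, 23, 28, 34, 40) h: the t = 0 sample anchors the
initial condition and the rest cover the linear villus-accumulation phase
— the threshold model describes the conveyor poorly during the brief
transfer-onset transient (~0–7 h), and sampling that window would bias
the recovered δ downward.

**What the simulator does not emulate.** 2-D/3-D crypt geometry and
neutral drift between crypt lineages; stem-cell hierarchy and
position-dependent cycle times; cell-cycle phase structure (labeling is
instantaneous Bernoulli, not S-phase-duration-weighted); villus
contraction or active migration; measurement error in cell identification.
Passing recovery tests therefore demonstrate that the estimators are
consistent with the model's own assumptions under realistic sampling
noise — not that those assumptions hold in tissue.

## Numerical choices and scales used

* Closed-form/ODE agreement is verified at relative tolerance 1e-6 on 200
  random parameter sets (the oracle integrates at rtol 1e-9 with
  event-located phase switches).
* Recovery checks use the preset study conditions: 30 CVEUs × 8 sample
  times, 20 seeded replicates for the control-duodenum recovery; 5 seeded
  replicates for the arrest regime (early-phase significance flags are
  majority-voted and the resumed rate is taken as the median, which
  de-flakes a per-replicate 2·se criterion without weakening it).
* Boundary-sensitivity sweeps refit at candidate boundaries
  {16, 18, 20, 22, 24}; the stable region is the widest suffix with
  production-rate CV < 10%.
* Degenerate inputs raise: empty matrices, all-zero profiles, boundaries
  out of range, δ ≤ 0 transit times, fewer than 3 usable time points,
  under-determined schemes.

## Known limitations

* The recovered δ carries a small negative structural bias (≈3–5% at the
  control-duodenum conditions) from residual label dilution inside the
  kept window and from the smooth transfer onset that the sharp-threshold
  model approximates; it is well inside the estimator's sampling spread.
* The boundary estimator needs the faint near-boundary labeling tail; on
  data where the 2-h profile truly ends several positions below N_C it
  will underestimate the crypt size (the sensitivity sweep exists to
  diagnose exactly this).
* δ is assumed constant across crypt positions; in tissue, basal cells
  cycle more slowly, so within-crypt velocities V_x = δ·x are coarser
  than the boundary velocity itself.
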