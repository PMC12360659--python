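# Methods

This note documents the model as implemented: its structure, assumptions,
parameter choices, numerical methods, and what the synthetic cohorts can
and cannot show about real patients.

## Circulation

The circulation is a closed lumped-parameter loop of eight compliant
compartments — left ventricle, aorta/systemic arteries, systemic
capillaries, systemic veins, right ventricle, pulmonary arteries,
pulmonary capillaries, pulmonary veins — connected by resistors and
two-state valve elements (aortic, tricuspid-path, pulmonic, mitral-path).
This is the smallest loop that exhibits every quantity the downstream
analytics use (systolic/diastolic/mean arterial pressure, CVP, stroke
volume, total blood volume); cerebral, renal-vascular and tissue
sub-circuits are intentionally absent, so absolute regional hemodynamics
are out of scope.

Each step the network is assembled by modified nodal analysis: resistor
conductances stamp the G block, each pressure source adds a row/column
pair, and each capacitor stamps the backward-Euler conductance
G_C = C/Δt on its endpoint diagonals with a history term ±G_C·ΔP(t) on the
right-hand side. For time-varying compliances (the ventricles) the stamp
uses the new compliance in G and the old compliance in the history term,
which advances the stored charge q = C(t)·ΔP exactly; as a consequence
total blood volume obeys the hemorrhage/transfusion ledger to machine
precision (verified to ~1e−10 mL over full scenarios). The dense system
(11 unknowns in the default loop) is solved by LU factorization; sparsity
is irrelevant at this size.

Valves are resistors with a low forward (0.006 mmHg·s/mL) and a very high
reverse (2000) resistance. Valve states are iterated to consistency
*within* each step (flip any valve whose flow disagrees with its state and
re-solve, at most a handful of passes): with a 0.05 s step, a
one-step-lagged state injects tens of mL of spurious regurgitation per
transition, which materially corrupts stroke volume.

Hemorrhage is a flow sink at the venous node, transfusion a flow source at
the same node; the bleed site is not otherwise specified in the scenario.

## Drivers

Ventricles are time-varying compliances C(t) = 1/E_v(t) with

    E_v(t) = (E_max − E_min)·f(t)/f_max + E_min,
    f(t) = [(t/(α1·T))^n1 / (1+(t/(α1·T))^n1)] · [1/(1+(t/(α2·T))^n2)],

using the classic double-Hill constants α1 = 0.303, α2 = 0.508, n1 = 1.32,
n2 = 21.9 (exposed in config). f has no closed-form maximum; f_max is
computed by dense sampling (1000 points/period) and recomputed whenever the
cardiac period changes. Default elastances (LV E_max 2.6 rescaled at
stabilization, E_min 0.05; RV 0.6/0.045 mmHg/mL) give a stroke volume near
70 mL at the population-default filling pressures.

The respiratory muscle driver falls quadratically from 0 to −P_max over
the inspiratory time I and relaxes exponentially (τ = E/5) over the
expiratory time E; the quadratic branch's signs are fixed by continuity at
t = I (both branches give −P_max) and P(T) = 0. P_max is calibrated at
initialization by a multiplicative fixed-point iteration until a
single-compartment linear lung (compliance 100 mL/cmH2O, airway resistance
0.01 cmH2O·s/mL) achieves the requested tidal volume (7 mL/kg) within 2%.
The lung is not coupled into the blood circuit; its role is (i) pleural
pressure for the baroreceptor transmural inputs and (ii) ventilation for
the CO2 balance.

## Baroreflex

Arterial wall strain follows the sigmoid
ε_w = 1 − (1+e^{−q_w(P−s_w)})/(A+e^{−q_w(P−s_w)}) with q_w = 0.04 /mmHg
and A = 0.5, giving ε_w ∈ [−1, 0], equal to −1/3 at the operating point,
and *increasing* as pressure falls. The carotid input is systolic
pressure; the aortic input is systolic minus pleural pressure. The
operating point adapts toward prevailing systolic pressure with
k_adapt = ln2/(16 h). Strain is filtered by a spring-dashpot element
(k_b = 0.1, τ_b = 0.9 s); the cardiopulmonary receptor low-passes
CVP − P_pleural (τ_cp = 6 s) into a logistic firing rate saturating at
f_cp,max = 20 Hz (half-maximal at the baseline transmural pressure).

Efferent scalings are the simplest monotone law consistent with
negative-feedback direction: scale = 1 + gain·(signal − baseline) for
heart rate, contractility and resistance, and 1 − gain·(…) for venous
unstressed volume, with hard saturations (HR ≤ 2.2×, resistance ≤ 2.5×,
unstressed volume ≥ 0.6×). Because the printed strain law makes the
afferent signal rise when pressure falls, the gain enters with the
opposite sign to a law written for a pressure-tracking signal; only the
direction (pressure drop → HR, contractility, resistance up; unstressed
volume down) is observable. Aortic and carotid strains get equal weights;
the low-pressure signal routes only to resistance and unstressed volume.
Each commanded scale passes through a first-order effector lag
(τ = 8 s): without it the loop (gain ≈ 20 with cycle-latched heart-period
updates and per-cycle systolic measurement) develops a limit cycle at
rest. All reflex ODEs use implicit Euler and are unconditionally stable.

Venous unstressed-volume recruitment is implemented mass-neutrally: the
volume released by lowering V0 is added to the venous capacitor's stressed
charge in the same step.

## Blood gas and lactate

Each chemistry pool satisfies, simultaneously: charge balance
0 = SID − HCO₃⁻ − C_A(0.123·pH − 0.631) − C_PO4(0.309·pH − 0.469) (the
linearized albumin/phosphate model; C_A = 44 on the g/L albumin scale,
C_PO4 = 1.16 mmol/L); CO2 mass balance with dissolved CO2 (α = 0.03
mmol/L/mmHg), bicarbonate and carbamino binding (4·S_CO2·C_Hb, S_CO2 a
rectangular hyperbola with half-saturation 300 mmHg, C_Hb = 2.3 mmol/L
tetramer); O2 mass balance with a Hill saturation (n = 2.7, P50 = 26.8
mmHg Bohr-shifted by 10^{0.48(7.4−pH)}); and pH = 6.1 +
log₁₀(HCO₃⁻/(α·P_CO2)). Given pH, bicarbonate follows in closed form from
charge balance and P_CO2 from Henderson–Hasselbalch, so the system reduces
to one residual in pH, bracketed on [6, 8] and solved by Brent's method to
~1e−12; O2 is an independent bracketed solve per pool. Arterial and venous
pools (venous: +2.5 mmol/L total CO2, reduced total O2) are re-solved
every 5 steps (0.25 s) — pH dynamics are far slower than the 0.05 s
circuit step. Corner cases where no root exists in [6, 8] (strong
alkalosis at low total CO2) raise a structured error; the engine caps its
total CO2 just below the level that would push pH under 6.0, so scenario
runs always remain solvable.

Blood lactate relaxes (τ_L = 60 s, implicit Euler) toward the logistic
hypovolemia target L(V) = 15.5/(1 + 5.4·e^{25(V/V₀−1)}) + 1 mmol/L
(≈3.42 at baseline volume, saturating near 16.5 at severe loss); the
relaxation is the net tissue production/consumption term. Renal clearance
moves lactate mass into the tubules at M_L·C·βγ·J, where
M_L = 10/(1 + 24.5·e^{100(pH/pH₀−1)}) + 1 is the pH-gated multiplier
(≈1.39 at baseline pH, →11 in acidosis), J = 0.2 × cardiac output is the
renal capillary flow, and βγ = 0.25 is a single folded transfer
coefficient. βγ and τ_L were set so that baseline lactate turnover sits on
a minutes scale with a resting concentration near 2 mmol/L and shock
lactate peaks in the 11–14 mmol/L range reported for moderate-to-severe
hemorrhage. The argument of M_L is the pH *ratio* to baseline; an absolute
"pH − 1" argument saturates irrecoverably at physiologic pH. The
blood↔tubule transfer conserves lactate mass exactly (capped at the
available pool).

## Ventilation and CO2 (minimal controller)

Chemoreceptor control is deliberately out of scope; in its place a minimal
single-pool CO2 balance closes the loop between perfusion, ventilation and
pH: d(T_CO2)/dt = (V̇CO2 − k·Q_rel^1.5·(0.6 + 0.4·VE_rel)·P_CO2)/V_blood,
with V̇CO2 = 0.15 mmol/s and k fixed by the baseline steady state
(P_CO2 = 40 mmHg at rest). A proportional controller scales respiration
rate and muscle-pressure amplitude breath-to-breath with the arterial CO2
deviation (gain 4, bounds 0.8–3×), holding the previous breath's I:E
ratio. The elimination term's strong perfusion dependence encodes that CO2
removal requires delivery to the lungs: as cardiac output collapses,
arterial CO2 accumulates despite tachypnea, producing the mixed
metabolic + respiratory acidosis characteristic of severe hemorrhagic
shock. The exponent and ventilation weight were chosen at design time so a
~20% volume deficit yields a predominantly metabolic acidosis (minimum pH
≈ 7.0–7.1) and a ~40% deficit a mixed acidosis (minimum pH ≈ 6.5–6.7),
matching the arterial blood-gas ranges reported for moderate vs. severe
hemorrhage.

## Patients, stabilization and the scenario

The cohort generator emulates a healthy middle-aged population:
independent normal marginals truncated at ±3 SD — age 36.9 y (var 3.1),
weight 69.2 kg (var 13.5), diastolic 72.8 (var 2.1) and systolic 114.3
mmHg (var 1.7), heart rate 71.3 /min (var 2.5), respiration rate 15.5 /min
(var 2.1) — with a 50-50 sex split and a 20 mmHg pulse-pressure floor.
Blood volume is derived from weight and sex (70/65 mL/kg male/female).
The dispersion column is treated as a variance (sd = √var). These are
deliberately narrow, healthy marginals: cohort results say nothing about
comorbid or elderly populations.

Stabilization drives the engine to the patient's targets by a damped
multiplicative iteration: total systemic resistance tracks mean arterial
pressure and LV end-systolic elastance tracks pulse pressure, until
simulated systolic and diastolic are within 2 mmHg (typically ~10
iterations of 4 s settling). Venous unstressed volume then absorbs the
difference between the patient's blood volume and the loop's stressed
volume. Reflex baselines (operating points, filtered strains, firing
rate) are recorded as breath-cycle averages with the afferent filters
running but efferents frozen — breathing shifts the mean pleural pressure,
and baselines recorded at the resting pleural value leave a standing error
that destabilizes the resting loop. Chemistry baselines follow: lactate at
its production/clearance steady state, total CO2 set for P_CO2 = 40 mmHg.

The standard scenario bleeds at a constant rate from t = 0; transfusion
(default: matched to the bleed rate, carrying baseline chemistry) starts
when the 10-minute transit ends; the bleed stops at hemostasis (20 min,
"surgical control"); transfusion stops when blood volume reaches baseline;
the run ends when the shock index falls below 1 after hemostasis, or at
60 min. Severity labels: 100 mL/min moderate, 150 intermediate, 200
severe. The engine steps at 0.05 s; output is decimated to 1 Hz. Execution
order within a step is fixed: heart-driver elastance → blood gas + lactate
→ nervous system (writes resistances/elastances/period/unstressed volume)
→ circuit solve → volume/pressure pushes.

Transient circulatory collapse (possible for the lightest patients at
~50% volume loss) is tolerated: the shock index saturates on a floored
systolic rather than aborting, and such patients recover with continued
transfusion.

## Trajectory analytics

Trajectories are smoothed with a centered moving average (normalized ones
kernel; shrunken symmetric windows at the edges). The default window is
31 samples ≈ 31 s at the 1 Hz output rate: raw curvature locks onto
cardiac/respiratory oscillation rather than the global turning point.
Curvature uses central differences in sample index; because the formula is
parameterization-dependent, both axes are pre-scaled to unit range
(`Trajectory.scaled()`) and the scaling recorded with results. The
maximum-curvature point excludes one window at each end and breaks exact
ties to the earliest index. Convex hulls use scipy's Qhull wrapper;
degenerate (< 3 non-collinear points) inputs raise a structured error.

The severity curve f(BV) = a/(1+e^{b(BV−c)}) + d is fitted by
Levenberg–Marquardt-type nonlinear least squares (|b| bounded by 10;
starting values d = max y, a = min y − max y, c = median BV, b signed from
the trend). The covariance is the Jacobian-based Gauss–Newton covariance
scaled by residual variance; prediction intervals add the residual
variance to the delta-method curve variance g(BV)ᵀ·Cov·g(BV) and use
two-sided normal quantiles. The closed-form inverse
BV = c + ln(a/(y−d) − 1)/b is defined strictly between the asymptotes d
and a + d. The BV axis is whatever the caller supplies (mL here); axis
units are recorded, not rescaled.

## What the synthetic cohorts do and do not show

The generator reproduces the stated population marginals and the scenario
timeline, so passing tests demonstrate internal consistency: conservation
ledgers, negative-feedback directions, severity ordering (higher bleed
rate → lower minimum pH and volume, higher peak lactate and heart rate),
hull separation between severities, and correct statistical behavior of
the fit layer. They do not validate the circuit topology against measured
regional hemodynamics (the reduced loop is a stand-in for a richer
unpublished topology), do not include comorbidities, drugs, temperature
effects or crystalloid-vs-blood composition effects, and the ventilation
controller is a deliberate minimal substitute for full chemoreceptor
dynamics. Lactate kinetics are single-pool; regional (hepatic/muscle)
shuttling is absent.

## Numerical summary

- Global step 0.05 s; chemistry every 5 steps; output 1 Hz.
- Implicit Euler for all reflex/lactate ODEs; backward Euler for the
  circuit; valve states iterated to consistency within the step.
- pH root: Brent on [6, 8], xtol 1e−12; engine caps total CO2 to keep the
  root inside the bracket.
- Stabilization tolerance 2 mmHg on systolic and diastolic; tidal-volume
  calibration 2%.
- Cohort endpoints in `scripts/acceptance.py` use 5 patients per severity
  and complete in a few minutes on one CPU; the test suite's cohort
  fixtures use the same sizes.
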