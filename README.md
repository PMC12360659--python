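# hemoshock

A whole-body, lumped-parameter (0D) simulator of hemorrhagic shock and
resuscitation, with phase-plane analytics that turn simulated vital-sign
trajectories into a clinical severity estimate.

## Who this is for

Researchers in quantitative systems physiology and medical-simulation
developers who need a mechanistic, patient-configurable model of acute
hemorrhage — the coupled response of circulation, baroreflex control,
ventilation and blood acid-base chemistry to blood loss and transfusion —
and a reproducible pipeline from simulated cohorts to a lactate-based
severity curve.

## What is inside

**Simulator.** The circulation is an electrical-circuit analog: eight
compliant compartments (left ventricle, arteries, systemic capillaries,
veins, right ventricle, pulmonary arteries/capillaries/veins) joined by
resistors and two-state valves, assembled each 0.05 s step by modified
nodal analysis (MNA) with backward-Euler compliance stamping (G_C = C/Δt)
and solved by dense LU. The ventricles are time-varying compliances
C(t) = 1/E_v(t) with a double-Hill activation shape

    E_v(t) = (E_max − E_min)·f(t)/f_max + E_min.

Arterial (aortic, carotid) baroreceptors sense systolic pressure through a
sigmoidal wall-strain law with a slowly adapting operating point (≈16 h
half-life); cardiopulmonary receptors low-pass the venous transmural
pressure. Their deviations from stabilization baselines scale heart rate,
contractility, vascular resistance and venous unstressed volume.

Each blood pool carries a Stewart-style strong-ion-difference (SID)
acid-base system solved to its root every step:

    SID = Na⁺ + K⁺ − Cl⁻ − lactate⁻,   pH = 6.1 + log₁₀(HCO₃⁻/(0.03·P_CO2)),

with charge balance, CO2/O2 mass balances and Hill-type hemoglobin
saturation (Bohr-shifted). Hypovolemia drives lactate toward a logistic
target of the blood-volume fraction, L(V) = 15.5/(1 + 5.4·e^{25(V/V₀−1)}) + 1,
and the kidney clears lactate into the tubules at a pH-gated rate.

**Analytics.** Simulated trajectories in a phase plane (e.g. blood volume
vs. lactate) are smoothed with a normalized ones-kernel convolution; the
planar curvature k = |x′y″ − y′x″|/(x′²+y′²)^{3/2} is maximized to locate
the deterioration→recovery turning point; cohort turning points are covered
by convex hulls per hemorrhage severity; and a four-parameter logistic
severity curve f(BV) = a/(1+e^{b(BV−c)}) + d is fitted by nonlinear least
squares with delta-method parameter uncertainty and normal-theory
prediction intervals (`LogisticSeverityModel(...).fit()` →
`LogisticSeverityResults` with `summary()`, `prediction_interval()`,
`invert()`).

## Worked example

```python
import numpy as np
from hemoshock import (PatientProfile, ScenarioConfig, run_scenario,
                       Trajectory, max_curvature_point)

patient = PatientProfile()          # 69.2 kg male, 114.3/72.8 mmHg, HR 71.3
records, recovered = run_scenario(patient, ScenarioConfig(bleed_rate=150.0))

ph  = np.array([r.ph for r in records])
lac = np.array([r.lactate for r in records])
bv  = np.array([r.blood_volume for r in records])
print(f"min pH {ph.min():.3f}, peak lactate {lac.max():.1f} mmol/L, "
      f"min volume {bv.min():.0f} mL")

traj = Trajectory(bv, lac).scaled()
cp = max_curvature_point(traj)
print(f"turning point: BV {cp.x*traj.x_scale:.0f} mL, "
      f"lactate {cp.y*traj.y_scale:.1f} mmol/L")
```

prints

```
min pH 6.998, peak lactate 12.3 mmol/L, min volume 3344 mL
turning point: BV 3344 mL, lactate 11.9 mmol/L
```

The patient bleeds at 150 mL/min for a 10-minute transit, receives matched
whole-blood transfusion on arrival, has the bleed stopped surgically at
20 minutes, and is resuscitated until the shock index (HR/systolic) drops
below 1 — here after 1423 s, with a metabolic acidosis (pH 7.00) at the
nadir of blood volume. The turning point is where the phase-plane
trajectory bends from deterioration to recovery.

Fitting the severity curve to a cohort of turning points:

```python
from hemoshock import fit_logistic
res = fit_logistic(bv_lost, lactate)   # one point per simulated patient
print(res.summary())                   # a, b, c, d with standard errors
lo, hi = res.prediction_interval(bv_lost, level=0.95)
res.invert(15.0)                       # blood volume lost at lactate 15
```

A command-line interface mirrors the library: `hemoshock simulate`,
`cohort`, `analyze`, `fit`, `reproduce-figures` (see `hemoshock --help`).

## Layout

- `src/hemoshock/circuit.py` — MNA assembly, capacitor stamping, LU solve, volume bookkeeping
- `src/hemoshock/drivers.py` — elastance and respiratory-muscle drivers, tidal-volume calibration
- `src/hemoshock/baroreflex.py` — wall strain, adaptation, filters, firing rate, efferent scalings
- `src/hemoshock/bloodgas.py` — SID equilibrium solver, lactate target/clearance kinetics
- `src/hemoshock/engine.py` — the coupled per-step execution (preprocess → process → postprocess)
- `src/hemoshock/scenario.py` — cohort generation, stabilization, hemorrhage timeline
- `src/hemoshock/trajectory.py` — smoothing, curvature, hulls, logistic fit + intervals
- `src/hemoshock/io.py`, `cli.py` — config, CSV/JSON persistence, manifests, CLI

See `docs/methods.md` for the model description, parameter choices and
known limitations.
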