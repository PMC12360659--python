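"""Patient cohorts and the hemorrhage → transit → transfusion timeline.

The cohort generator emulates a healthy middle-aged population: independent
normal marginals (truncated at ±3 SD) for age, weight, diastolic/systolic
pressure, resting heart rate and respiration rate, with a 50–50 sex split.
Defaults are the population statistics the simulator is calibrated against:

    age 36.9 y (var 3.1), weight 69.2 kg (var 13.5),
    diastolic 72.8 mmHg (var 2.1), systolic 114.3 mmHg (var 1.7),
    heart rate 71.3 /min (var 2.5), respiration 15.5 /min (var 2.1).

The standard scenario bleeds the patient at a constant rate from t = 0,
starts whole-blood transfusion when transit ends (default 10 min), stops the
bleed at hemostasis (default 20 min, "surgical intervention"), and continues
resuscitation until the shock index (heart rate / systolic pressure) falls
below 1, or a maximum duration elapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .engine import Engine, EngineParams

__all__ = [
    "PatientProfile",
    "ScenarioConfig",
    "TimeSeriesRecord",
    "Table2Statistics",
    "generate_cohort",
    "stabilize",
    "step_engine",
    "run_scenario",
    "run_cohort",
    "shock_index",
    "SEVERITY_BLEED_RATES",
]

# Clinical severity classes mapped to initial bleed rates (mL/min).
SEVERITY_BLEED_RATES = {"moderate": 100.0, "intermediate": 150.0, "severe": 200.0}

BLOOD_ML_PER_KG = {"male": 70.0, "female": 65.0}


@dataclass
class PatientProfile:
    """Baseline vitals and anthropometrics of one virtual patient."""

    sex: str = "male"
    age: float = 36.9                       # years
    weight: float = 69.2                    # kg
    diastolic_target: float = 72.8          # mmHg
    systolic_target: float = 114.3          # mmHg
    heart_rate_baseline: float = 71.3       # 1/min
    respiration_rate_baseline: float = 15.5 # 1/min
    blood_volume_baseline: float = 0.0      # mL; derived from weight if 0

    def __post_init__(self) -> None:
        if self.systolic_target <= self.diastolic_target:
            raise ValueError("systolic target must exceed diastolic target")
        for name in ("age", "weight", "diastolic_target", "systolic_target",
                     "heart_rate_baseline", "respiration_rate_baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.blood_volume_baseline <= 0:
            self.blood_volume_baseline = BLOOD_ML_PER_KG[self.sex] * self.weight


@dataclass
class Table2Statistics:
    """Mean/variance marginals of the simulated healthy cohort."""

    age: tuple[float, float] = (36.9, 3.1)
    weight: tuple[float, float] = (69.2, 13.5)
    diastolic: tuple[float, float] = (72.8, 2.1)
    systolic: tuple[float, float] = (114.3, 1.7)
    heart_rate: tuple[float, float] = (71.3, 2.5)
    respiration_rate: tuple[float, float] = (15.5, 2.1)


@dataclass
class ScenarioConfig:
    """Hemorrhage–resuscitation timeline and engine step configuration."""

    bleed_rate: float = 100.0        # mL/min
    transit_duration: float = 600.0  # s, bleed-only phase (transport)
    transfusion_start: float = 600.0 # s (defaults to transit end)
    hemostasis_time: float = 1200.0  # s, bleeding stops (surgical control)
    transfusion_rate: float | None = None  # mL/min; None → match bleed rate
    stop_shock_index: float = 1.0
    dt: float = 0.05                 # s
    max_duration: float = 3600.0     # s
    output_interval: float = 1.0     # s between records
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.bleed_rate < 0 or (self.transfusion_rate or 0.0) < 0:
            raise ValueError("rates must be nonnegative")
        if not (self.hemostasis_time >= self.transfusion_start
                >= self.transit_duration or
                self.transfusion_start == self.transit_duration):
            raise ValueError("timeline must be ordered: transit <= transfusion "
                             "<= hemostasis")
        if self.hemostasis_time < self.transfusion_start:
            raise ValueError("hemostasis must not precede transfusion start")

    @property
    def effective_transfusion_rate(self) -> float:
        return self.bleed_rate if self.transfusion_rate is None else self.transfusion_rate


@dataclass
class TimeSeriesRecord:
    """Vitals sampled at the output interval."""

    time: float
    heart_rate: float
    systolic: float
    diastolic: float
    map: float
    cvp: float
    blood_volume: float
    ph: float
    lactate: float
    respiration_rate: float
    shock_index: float


def shock_index(heart_rate: float, systolic: float) -> float:
    """Heart rate over systolic pressure; > 1 flags hemodynamic instability."""
    if systolic <= 0:
        raise ValueError(f"systolic pressure must be > 0, got {systolic}")
    return heart_rate / systolic


def generate_cohort(n: int, seed: int,
                    stats: Table2Statistics | None = None) -> list[PatientProfile]:
    """Draw ``n`` patients with independent truncated-normal marginals.

    Sex is Bernoulli(0.5); each numeric field is normal with the given mean
    and *variance*, truncated at ±3 SD; identical seeds give identical
    cohorts.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    stats = stats or Table2Statistics()
    rng = np.random.default_rng(seed)
    cohort: list[PatientProfile] = []

    def draw(mean_var: tuple[float, float]) -> float:
        mean, var = mean_var
        sd = math.sqrt(var)
        for _ in range(100):
            x = rng.normal(mean, sd)
            if abs(x - mean) <= 3.0 * sd:
                return float(x)
        return mean

    for _ in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        dia = draw(stats.diastolic)
        sys_p = draw(stats.systolic)
        if sys_p <= dia + 20.0:  # keep a physiologic pulse pressure
            sys_p = dia + 20.0
        cohort.append(PatientProfile(
            sex=sex,
            age=draw(stats.age),
            weight=draw(stats.weight),
            diastolic_target=dia,
            systolic_target=sys_p,
            heart_rate_baseline=draw(stats.heart_rate),
            respiration_rate_baseline=draw(stats.respiration_rate),
        ))
    return cohort


def stabilize(patient: PatientProfile,
              params: EngineParams | None = None) -> Engine:
    """Build and stabilize an engine at the patient's resting targets."""
    engine = Engine(patient, params)
    engine.stabilize()
    return engine


def step_engine(engine: Engine, dt: float | None = None) -> Engine:
    """Advance the engine one global step (preprocess → process → postprocess)."""
    if dt is not None and abs(dt - engine.dt) > 1e-12:
        engine.dt = dt
    engine.step()
    return engine


def _record(engine: Engine) -> TimeSeriesRecord:
    # transient circulatory collapse can push the measured systolic to ~0;
    # floor it so the shock index saturates instead of blowing up the run
    sys_p = max(engine.cycle.systolic, 0.1)
    return TimeSeriesRecord(
        time=engine.time,
        heart_rate=engine.heart_rate,
        systolic=sys_p,
        diastolic=engine.cycle.diastolic,
        map=engine.map_pressure,
        cvp=engine.cvp,
        blood_volume=engine.blood_volume,
        ph=engine.ph,
        lactate=engine.c_lactate,
        respiration_rate=engine.respiration_rate,
        shock_index=shock_index(engine.heart_rate, sys_p),
    )


def run_scenario(patient: PatientProfile | Engine, config: ScenarioConfig,
                 params: EngineParams | None = None,
                 ) -> tuple[list[TimeSeriesRecord], bool]:
    """Execute the hemorrhage–resuscitation timeline on one patient.

    Returns the sampled records and a ``recovered`` flag (shock index fell
    below the stop threshold after hemostasis).  Internally the engine steps
    at ``config.dt``; output is decimated to one record per
    ``config.output_interval`` seconds.  Transfusion stops once blood volume
    is restored to baseline, the run once the shock index recovers.
    """
    if isinstance(patient, Engine):
        engine = patient
        if not engine.stabilized:
            engine.stabilize()
    else:
        eng_params = params or EngineParams()
        eng_params.dt = config.dt
        engine = stabilize(patient, eng_params)
    engine.dt = config.dt

    t0 = engine.time
    bleed = config.bleed_rate / 60.0           # mL/s
    tx_rate = config.effective_transfusion_rate / 60.0
    steps_per_record = max(int(round(config.output_interval / config.dt)), 1)
    records: list[TimeSeriesRecord] = [_record(engine)]
    records[0] = TimeSeriesRecord(**{**asdict(records[0]), "time": 0.0})

    recovered = False
    i = 0
    while True:
        t = engine.time - t0
        if t >= config.max_duration:
            break
        engine.bleed_flow = bleed if t < config.hemostasis_time else 0.0
        if (t >= config.transfusion_start
                and engine.blood_volume < engine.blood_volume_baseline):
            engine.transfusion_flow = tx_rate
        else:
            engine.transfusion_flow = 0.0
        engine.step()
        i += 1
        if i % steps_per_record == 0:
            rec = _record(engine)
            rec.time = engine.time - t0
            records.append(rec)
            if (t >= config.hemostasis_time
                    and rec.shock_index < config.stop_shock_index):
                recovered = True
                break
        if config.bleed_rate == 0.0 and t >= config.hemostasis_time:
            recovered = True
            break
    engine.bleed_flow = 0.0
    engine.transfusion_flow = 0.0
    return records, recovered


def severity_study(n: int, bleed_rates: list[float], seed: int,
                   config: ScenarioConfig | None = None,
                   params: EngineParams | None = None,
                   smoothing_window: int = 31) -> dict[float, dict]:
    """Cohort study across severities: minimum pH and phase-plane turning points.

    For each bleed rate, runs the same ``n`` seeded patients through the
    standard scenario and reports the cohort-minimum arterial pH plus each
    patient's maximum-curvature point in the (blood volume, lactate) plane.
    """
    from . import trajectory as tj

    runs = run_cohort(n, bleed_rates, seed, config, params)
    out: dict[float, dict] = {}
    for rate, patients in runs.items():
        min_ph = math.inf
        points = []
        for records in patients:
            ph = min(r.ph for r in records)
            min_ph = min(min_ph, ph)
            bv = np.array([r.blood_volume for r in records])
            lac = np.array([r.lactate for r in records])
            traj = tj.Trajectory(bv, lac).scaled()
            cp = tj.max_curvature_point(traj, window=smoothing_window)
            points.append((cp.x * (traj.x_scale or 1.0),
                           cp.y * (traj.y_scale or 1.0)))
        out[rate] = {"min_ph": min_ph, "points": points, "runs": patients}
    return out


def run_cohort(n: int, bleed_rates: list[float], seed: int,
               config: ScenarioConfig | None = None,
               params: EngineParams | None = None,
               ) -> dict[float, list[list[TimeSeriesRecord]]]:
    """Run ``n`` seeded patients at each bleed rate; same patients per rate."""
    base = config or ScenarioConfig()
    cohort = generate_cohort(n, seed)
    out: dict[float, list[list[TimeSeriesRecord]]] = {}
    for rate in bleed_rates:
        runs = []
        for patient in cohort:
            cfg = ScenarioConfig(**{**asdict(base), "bleed_rate": rate})
            records, _ = run_scenario(patient, cfg, params)
            runs.append(records)
        out[rate] = runs
    return out
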