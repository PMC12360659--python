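"""Cardiac and respiratory drivers.

The ventricles are driven through time-varying elastance

    E_v(t) = (E_max − E_min) · f(t)/f_max + E_min,

with a double-Hill activation shape

    f(t) = [(t/(α1 T))^n1 / (1 + (t/(α1 T))^n1)] · [1 / (1 + (t/(α2 T))^n2)]

over one cardiac period T.  f has no closed-form maximum, so f_max is found
by dense sampling of one period and recomputed whenever T changes.

The lung is driven by a respiratory-muscle pressure waveform that falls
quadratically from 0 to −P_max over the inspiratory time I and decays
exponentially back to 0 over the expiratory time E (time constant τ = E/5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeartDriver",
    "RespiratoryDriver",
    "activation_shape",
    "ventricular_elastance",
    "respiratory_muscle_pressure",
    "calibrate_amplitude",
    "LinearLung",
]

# Classic double-Hill shape constants (systolic rise / relaxation).
ALPHA1_DEFAULT = 0.303
ALPHA2_DEFAULT = 0.508
N1_DEFAULT = 1.32
N2_DEFAULT = 21.9

_FMAX_SAMPLES = 1000


@dataclass
class HeartDriver:
    """Time-varying elastance driver for one ventricle."""

    e_max: float                     # mmHg/mL, end-systolic elastance
    e_min: float                     # mmHg/mL, diastolic elastance
    period: float                    # s, cardiac period T
    alpha1: float = ALPHA1_DEFAULT
    alpha2: float = ALPHA2_DEFAULT
    n1: float = N1_DEFAULT
    n2: float = N2_DEFAULT
    f_max: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if not (self.e_max > self.e_min > 0):
            raise ValueError(f"need E_max > E_min > 0, got {self.e_max}, {self.e_min}")
        if not (0 < self.alpha1 < self.alpha2):
            raise ValueError("need 0 < alpha1 < alpha2")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("Hill exponents must be > 0")
        if self.period <= 0:
            raise ValueError("cardiac period must be > 0")
        if self.f_max <= 0:
            self.recompute_fmax()

    def recompute_fmax(self) -> None:
        """Dense-sample one period for the activation maximum (no closed form)."""
        ts = np.linspace(0.0, self.period, _FMAX_SAMPLES, endpoint=False)
        self.f_max = float(np.max(_shape_array(ts, self)))

    def with_period(self, period: float) -> "HeartDriver":
        return HeartDriver(e_max=self.e_max, e_min=self.e_min, period=period,
                           alpha1=self.alpha1, alpha2=self.alpha2,
                           n1=self.n1, n2=self.n2)


def _shape_array(t: np.ndarray, d: HeartDriver) -> np.ndarray:
    x1 = (t / (d.alpha1 * d.period)) ** d.n1
    x2 = (t / (d.alpha2 * d.period)) ** d.n2
    return (x1 / (1.0 + x1)) * (1.0 / (1.0 + x2))


def activation_shape(t: float, driver: HeartDriver) -> float:
    """Double-Hill activation f(t) ∈ [0, 1]; t is reduced modulo the period."""
    t = float(t) % driver.period
    x1 = (t / (driver.alpha1 * driver.period)) ** driver.n1
    x2 = (t / (driver.alpha2 * driver.period)) ** driver.n2
    return (x1 / (1.0 + x1)) * (1.0 / (1.0 + x2))


def ventricular_elastance(t: float, driver: HeartDriver) -> float:
    """E_v(t) = (E_max − E_min)·f(t)/f_max + E_min, in [E_min, E_max]."""
    f = activation_shape(t, driver)
    return (driver.e_max - driver.e_min) * (f / driver.f_max) + driver.e_min


@dataclass
class RespiratoryDriver:
    """Respiratory-muscle (pleural) pressure driver for one breath."""

    p_max: float                     # cmH2O, amplitude (applied as negative)
    t_resp: float                    # s, total breath time
    ie_ratio: float = 0.5            # inspiratory:expiratory time ratio I/E

    def __post_init__(self) -> None:
        if self.p_max <= 0:
            raise ValueError("P_max must be > 0")
        if self.t_resp <= 0:
            raise ValueError("breath period must be > 0")
        if self.ie_ratio <= 0:
            raise ValueError("I:E ratio must be > 0")
        if self.inspiratory_time >= self.t_resp:
            raise ValueError("inspiratory time must be shorter than the breath")

    @property
    def inspiratory_time(self) -> float:
        return self.t_resp * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def expiratory_time(self) -> float:
        return self.t_resp - self.inspiratory_time

    @property
    def tau(self) -> float:
        """Expiratory relaxation time constant, estimated as E/5."""
        return self.expiratory_time / 5.0


def respiratory_muscle_pressure(t: float, driver: RespiratoryDriver) -> float:
    """Muscle pressure P_musc(t) ≤ 0 over one breath cycle.

    Inspiration (0 < t < I): quadratic from 0 to −P_max,
        P(t) = (P_max/(I·E))·t² − (P_max·T/(I·E))·t.
    Expiration (I < t < T): exponential recovery to 0,
        P(t) = −P_max/(1 − e^(−E/τ)) · (e^(−(t−I)/τ) − e^(−E/τ)),
    continuous at t = I (both branches give −P_max) and zero at t = T.
    """
    T = driver.t_resp
    t = float(t) % T
    I = driver.inspiratory_time
    E = driver.expiratory_time
    if t <= I:
        return (driver.p_max / (I * E)) * t * t - (driver.p_max * T / (I * E)) * t
    tau = driver.tau
    scale = driver.p_max / (1.0 - math.exp(-E / tau))
    return -scale * (math.exp(-(t - I) / tau) - math.exp(-E / tau))


@dataclass
class LinearLung:
    """Single-compartment linear lung: airway resistance + compliance.

    dV/dt = −P_alv/R_aw with P_alv = (V − FRC)/C + ΔP_pl; the muscle driver
    sets ΔP_pl = −|P_musc|.  Advanced by implicit Euler.
    """

    compliance: float = 100.0        # mL/cmH2O
    airway_resistance: float = 0.01  # cmH2O·s/mL
    frc: float = 2400.0              # mL, relaxation volume
    volume: float = 2400.0           # mL, current

    def step(self, p_musc: float, dt: float) -> float:
        """Advance one step under muscle pressure ``p_musc`` (cmH2O, ≤ 0)."""
        # implicit: V' = V + dt*(-( (V'-FRC)/C + p_musc ))/R
        a = dt / (self.airway_resistance * self.compliance)
        self.volume = (self.volume + a * self.frc
                       - (dt / self.airway_resistance) * p_musc) / (1.0 + a)
        return self.volume


def simulate_tidal_volume(driver: RespiratoryDriver, lung: LinearLung,
                          dt: float = 0.05, n_breaths: int = 3) -> float:
    """Tidal volume (mL) achieved over the last of ``n_breaths`` breaths."""
    vmin = vmax = lung.volume
    n_steps = int(round(n_breaths * driver.t_resp / dt))
    settle = int(round((n_breaths - 1) * driver.t_resp / dt))
    for i in range(n_steps):
        t = (i * dt) % driver.t_resp
        v = lung.step(respiratory_muscle_pressure(t, driver), dt)
        if i == settle:
            vmin = vmax = v
        elif i > settle:
            vmin = min(vmin, v)
            vmax = max(vmax, v)
    return vmax - vmin


def calibrate_amplitude(driver: RespiratoryDriver, lung: LinearLung,
                        target_tidal_volume: float, *, dt: float = 0.05,
                        rel_tol: float = 0.02, max_iter: int = 50) -> float:
    """Rescale P_max until the achieved tidal volume is within ``rel_tol``.

    The achieved tidal volume is monotone (≈ linear) in P_max for the linear
    lung, so a multiplicative fixed-point update converges quickly.
    """
    if target_tidal_volume <= 0:
        raise ValueError("target tidal volume must be > 0")
    p_max = driver.p_max
    resid = math.inf
    for _ in range(max_iter):
        trial = RespiratoryDriver(p_max=p_max, t_resp=driver.t_resp,
                                  ie_ratio=driver.ie_ratio)
        probe = LinearLung(compliance=lung.compliance,
                           airway_resistance=lung.airway_resistance,
                           frc=lung.frc, volume=lung.frc)
        achieved = simulate_tidal_volume(trial, probe, dt=dt)
        resid = abs(achieved - target_tidal_volume) / target_tidal_volume
        if resid <= rel_tol:
            return p_max
        p_max *= target_tidal_volume / max(achieved, 1e-9)
    raise RuntimeError(
        f"tidal-volume calibration did not converge in {max_iter} iterations "
        f"(last relative residual {resid:.3g})")
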