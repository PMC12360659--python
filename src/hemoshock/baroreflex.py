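"""Baroreflex: afferent pressure sensing and efferent effector scalings.

High-pressure (aortic, carotid) receptors sense systolic pressure through a
sigmoidal wall-strain relationship

    ε_w = 1 − (1 + exp(−q_w(P − s_w))) / (A + exp(−q_w(P − s_w)))

whose operating point s_w slowly adapts toward the prevailing systolic
pressure (≈16 h half-life).  The strain is low-pass filtered by a
spring–dashpot element (gain k_b, time constant τ_b) before reaching the
central nervous system.  Low-pressure (cardiopulmonary) receptors low-pass
filter the venous transmural pressure CVP − P_pleural (time constant τ_cp)
and convert it to a firing rate through a logistic law saturating at
f_cp,max.

With the published strain law and A = 0.5 the strain lives in [−1, 0] and
*rises* toward 0 as pressure falls, so effector scalings are written
``1 + gain·(signal − baseline)``: a pressure drop yields heart-rate,
contractility and resistance scalings > 1 and an unstressed-volume scaling
< 1 (venous recruitment), each clamped at configurable saturations.  All
reflex ODEs advance by implicit Euler so any timestep is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BaroreceptorState",
    "LowPressureState",
    "EfferentGains",
    "EfferentCommand",
    "wall_strain",
    "adapt_operating_point",
    "filter_strain",
    "low_pressure_signal",
    "efferent_response",
    "K_ADAPT_16H",
]

# Adaptation rate for a 16-hour half-life of operating-point resetting.
K_ADAPT_16H = math.log(2.0) / (16.0 * 3600.0)  # 1/s


@dataclass
class BaroreceptorState:
    """One arterial stretch receptor (aortic arch or carotid sinus)."""

    site: str = "aortic"             # {"aortic" | "carotid"}
    s_w: float = 114.0               # mmHg, operating point (set at stabilization)
    q_w: float = 0.04                # 1/mmHg, steepness of the strain response
    a_ratio: float = 0.5             # max stressed:unstressed cross-section, A
    k_b: float = 0.1                 # dimensionless filter gain
    tau_b: float = 0.9               # s, spring–dashpot time constant
    k_adapt: float = K_ADAPT_16H     # 1/s, operating-point adaptation rate
    eps_w: float = 0.0               # current wall strain
    eps_b: float = 0.0               # filtered (CNS) strain
    eps_b_baseline: float = 0.0      # recorded at stabilization

    def __post_init__(self) -> None:
        if self.q_w <= 0 or self.a_ratio <= 0 or self.tau_b <= 0:
            raise ValueError("q_w, A and tau_b must be > 0")


@dataclass
class LowPressureState:
    """Cardiopulmonary (venous) low-pressure receptor."""

    tau_cp: float = 6.0              # s, low-pass time constant
    f_cp_max: float = 20.0           # Hz, maximum firing rate
    cvp_base: float = 4.0            # mmHg
    p_pleural_base: float = -3.7     # mmHg
    p_cp: float = 0.0                # mmHg, filtered transmural pressure
    f_cp: float = 0.0                # Hz
    f_cp_baseline: float = 0.0       # recorded at stabilization

    def __post_init__(self) -> None:
        if self.tau_cp <= 0 or self.f_cp_max <= 0:
            raise ValueError("tau_cp and f_cp_max must be > 0")


def wall_strain(p_input: float, state: BaroreceptorState) -> float:
    """Sigmoidal wall strain ε_w(P_input).

    ``p_input`` is the systolic pressure for the carotid receptor and the
    systolic-minus-pleural transmural pressure for the aortic receptor.
    """
    e = math.exp(-state.q_w * (p_input - state.s_w))
    return 1.0 - (1.0 + e) / (state.a_ratio + e)


def adapt_operating_point(s_w: float, p_sys: float, dt: float, k_adapt: float,
                          *, method: str = "implicit") -> float:
    """One step of ds_w/dt = k_adapt·(P_sys − s_w); fixed point s_w = P_sys."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if method == "explicit":
        return s_w + dt * k_adapt * (p_sys - s_w)
    return (s_w + dt * k_adapt * p_sys) / (1.0 + dt * k_adapt)


def filter_strain(eps_b: float, eps_w: float, dt: float,
                  state: BaroreceptorState) -> float:
    """Implicit-Euler step of the spring–dashpot dε_b/dt = (k_b ε_w − ε_b)/τ_b."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return (eps_b + (dt / state.tau_b) * state.k_b * eps_w) / (1.0 + dt / state.tau_b)


def low_pressure_signal(state: LowPressureState, cvp: float, p_pleural: float,
                        dt: float) -> tuple[float, float]:
    """Advance the low-pressure filter and firing rate.

    dP_cp/dt = (−P_cp + (CVP − P_pleural))/τ_cp (implicit Euler), then
    f_cp = f_cp,max / (1 + exp((CVP_base − P_pleural,base) − P_cp)).
    At baseline transmural pressure the firing rate is f_cp,max/2.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    transmural = cvp - p_pleural
    p_cp = (state.p_cp + (dt / state.tau_cp) * transmural) / (1.0 + dt / state.tau_cp)
    x = (state.cvp_base - state.p_pleural_base) - p_cp
    f_cp = state.f_cp_max / (1.0 + math.exp(min(x, 60.0)))
    state.p_cp = p_cp
    state.f_cp = f_cp
    return p_cp, f_cp


@dataclass
class EfferentGains:
    """Per-effector gains and saturation bounds for the efferent arm.

    The arterial (strain) signal drives heart rate, contractility, systemic
    resistance and venous unstressed volume; the low-pressure (firing-rate)
    signal is routed only to resistance and unstressed volume.
    """

    heart_rate: float = 20.0
    contractility: float = 15.0
    resistance: float = 20.0
    unstressed_volume: float = 10.0
    resistance_lp: float = 0.5
    unstressed_volume_lp: float = 0.6
    weight_aortic: float = 0.5
    weight_carotid: float = 0.5
    heart_rate_bounds: tuple[float, float] = (0.5, 2.2)
    contractility_bounds: tuple[float, float] = (0.5, 2.0)
    resistance_bounds: tuple[float, float] = (0.4, 2.5)
    unstressed_volume_bounds: tuple[float, float] = (0.6, 1.3)


@dataclass
class EfferentCommand:
    """Multiplicative effector scalings; all exactly 1 at baseline signals."""

    heart_rate_scale: float = 1.0
    contractility_scale: float = 1.0
    resistance_scale: float = 1.0
    unstressed_volume_scale: float = 1.0


def _clip(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else hi if x > hi else x


def efferent_response(aortic: BaroreceptorState, carotid: BaroreceptorState,
                      lp: LowPressureState,
                      gains: EfferentGains | None = None) -> EfferentCommand:
    """Map afferent deviations from their stabilization baselines to scalings.

    Monotone in the signal deviation: a pressure drop (strain signal above
    baseline, firing rate below baseline) raises heart rate, contractility
    and resistance and lowers venous unstressed volume, within saturations.
    """
    g = gains or EfferentGains()
    d_strain = (g.weight_aortic * (aortic.eps_b - aortic.eps_b_baseline)
                + g.weight_carotid * (carotid.eps_b - carotid.eps_b_baseline))
    d_fcp = (lp.f_cp_baseline - lp.f_cp) / lp.f_cp_max  # > 0 when CVP falls

    hr = _clip(1.0 + g.heart_rate * d_strain, *g.heart_rate_bounds)
    con = _clip(1.0 + g.contractility * d_strain, *g.contractility_bounds)
    res = _clip(1.0 + g.resistance * d_strain + g.resistance_lp * d_fcp,
                *g.resistance_bounds)
    uv = _clip(1.0 - g.unstressed_volume * d_strain - g.unstressed_volume_lp * d_fcp,
               *g.unstressed_volume_bounds)
    return EfferentCommand(heart_rate_scale=hr, contractility_scale=con,
                           resistance_scale=res, unstressed_volume_scale=uv)
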