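"""Strong-ion-difference acid–base equilibrium and lactate kinetics.

Each blood compartment carries strong ions (Na⁺, K⁺, Cl⁻, lactate⁻), a
linearized weak-acid pool (albumin-like, Figge coefficients), phosphate,
total CO2 and O2, and hemoglobin with four binding sites.  At every solve
the following system is satisfied simultaneously:

    SID  = C_Na + C_K − (C_Cl + C_lactate)
    0    = SID − C_HCO3 − C_A(0.123·pH − 0.631) − C_PO4(0.309·pH − 0.469)
    0    = T_CO2 − C_CO2 − C_HCO3 − 4·S_CO2·C_Hb
    0    = T_O2 − C_O2 − 4·S_O2·C_Hb
    pH   = 6.1 + log10(C_HCO3 / (α·P_CO2))

The root is found by safeguarded bracketing (Brent) on pH ∈ [6, 8]: given a
trial pH, bicarbonate follows from charge balance, P_CO2 from
Henderson–Hasselbalch, CO2 saturation from a rectangular-hyperbola carbamino
law, and the CO2 mass residual closes the loop.  O2 is solved afterwards on
P_O2 with a Hill saturation whose P50 shifts with pH (Bohr effect).

Hypovolemia drives lactate through a logistic target

    L(V_BV) = 15.5 / (1 + 5.4·exp(25·(V_BV/V_baseline − 1))) + 1   [mmol/L]

toward which blood lactate relaxes first-order, and the kidney clears
lactate into the tubules at a pH-gated rate

    M_L = 10 / (1 + 24.5·exp(100·(pH/pH_baseline − 1))) + 1,
    dM_sub/dt = M_L · C_sub · βγ · J,

with βγ a single configurable transfer coefficient and J the renal
capillary flow.  The blood↔tubule transfer conserves lactate mass exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

__all__ = [
    "CompartmentChemistry",
    "LactateKinetics",
    "ChemistryError",
    "strong_ion_difference",
    "co2_saturation",
    "o2_saturation",
    "equilibrium_residual",
    "solve_equilibrium",
    "lactate_target",
    "renal_clearance_scale",
    "transfer_lactate_to_tubule",
    "relax_lactate",
    "baseline_total_co2",
]

ALPHA_CO2 = 0.03      # mmol/L/mmHg, CO2 solubility
ALPHA_O2 = 0.0014     # mmol/L/mmHg, O2 solubility
PK_HH = 6.1           # Henderson–Hasselbalch pK

# Carbamino CO2: rectangular hyperbola, half-saturation pressure (mmHg).
K_CARBAMINO = 300.0
# O2 Hill saturation: exponent and standard P50 with Bohr shift.
HILL_N_O2 = 2.7
P50_O2 = 26.8         # mmHg at pH 7.4
BOHR_SLOPE = 0.48     # Δlog10(P50)/ΔpH

PH_BRACKET = (6.0, 8.0)


class ChemistryError(ValueError):
    """Equilibrium solve failed (no root in the physiologic pH bracket)."""


@dataclass
class CompartmentChemistry:
    """Ion, weak-acid, gas and hemoglobin state of one blood compartment."""

    c_na: float = 140.0      # mmol/L
    c_k: float = 4.0         # mmol/L
    c_cl: float = 105.0      # mmol/L
    c_lactate: float = 1.0   # mmol/L
    c_a: float = 44.0        # weak-acid total (albumin-equivalent, g/L scale)
    c_po4: float = 1.16      # mmol/L
    c_hb: float = 2.3        # mmol/L hemoglobin tetramer (4 O2/CO2 sites)
    t_co2: float = 25.0      # mmol/L total CO2
    t_o2: float = 9.0        # mmol/L total O2
    # solved state
    c_hbco3: float = 24.0    # mmol/L bicarbonate
    c_co2: float = 1.2       # mmol/L dissolved CO2
    c_o2: float = 0.14       # mmol/L dissolved O2
    s_co2: float = 0.12      # carbamino saturation
    s_o2: float = 0.97       # oxygen saturation
    p_co2: float = 40.0      # mmHg
    p_o2: float = 100.0      # mmHg
    ph: float = 7.4
    alpha: float = ALPHA_CO2

    @property
    def sid(self) -> float:
        return strong_ion_difference(self)


def strong_ion_difference(chem: CompartmentChemistry) -> float:
    """SID = Na⁺ + K⁺ − (Cl⁻ + lactate⁻), mmol/L."""
    return chem.c_na + chem.c_k - (chem.c_cl + chem.c_lactate)


def co2_saturation(p_co2: float) -> float:
    """Carbamino-CO2 hemoglobin saturation (rectangular hyperbola)."""
    if p_co2 <= 0:
        return 0.0
    return p_co2 / (p_co2 + K_CARBAMINO)


def o2_saturation(p_o2: float, ph: float = 7.4) -> float:
    """Hill oxygen saturation with Bohr-shifted P50 (acidosis right-shifts)."""
    if p_o2 <= 0:
        return 0.0
    p50 = P50_O2 * 10.0 ** (BOHR_SLOPE * (7.4 - ph))
    x = (p_o2 / p50) ** HILL_N_O2
    return x / (1.0 + x)


def _weak_acid_charge(ph: float, c_a: float, c_po4: float) -> float:
    return c_a * (0.123 * ph - 0.631) + c_po4 * (0.309 * ph - 0.469)


def equilibrium_residual(ph: float, sid: float, t_co2: float, c_a: float,
                         c_po4: float, c_hb: float,
                         alpha: float = ALPHA_CO2) -> float:
    """CO2-mass residual at trial pH after closed-form back-substitution.

    Bicarbonate comes from charge balance, P_CO2 from Henderson–Hasselbalch;
    the residual is T_CO2 − dissolved − bicarbonate − carbamino.
    """
    c_hbco3 = sid - _weak_acid_charge(ph, c_a, c_po4)
    if c_hbco3 <= 0.0:
        # no bicarbonate possible at this pH: residual is all of T_CO2
        return t_co2
    p_co2 = c_hbco3 / (alpha * 10.0 ** (ph - PK_HH))
    return t_co2 - alpha * p_co2 - c_hbco3 - 4.0 * co2_saturation(p_co2) * c_hb


def solve_equilibrium(chem: CompartmentChemistry) -> CompartmentChemistry:
    """Solve the five-equation acid–base system for its root on pH ∈ [6, 8].

    Returns a new chemistry whose pH, bicarbonate, dissolved/bound CO2 and
    O2 satisfy charge balance, the two mass balances and the
    Henderson–Hasselbalch relation to ≤1e−9 relative residual.
    """
    sid = strong_ion_difference(chem)
    lo, hi = PH_BRACKET
    f_lo = equilibrium_residual(lo, sid, chem.t_co2, chem.c_a, chem.c_po4,
                                chem.c_hb, chem.alpha)
    f_hi = equilibrium_residual(hi, sid, chem.t_co2, chem.c_a, chem.c_po4,
                                chem.c_hb, chem.alpha)
    if f_lo * f_hi > 0:
        raise ChemistryError(
            f"no pH root in [{lo}, {hi}] for SID={sid:.3f}, T_CO2={chem.t_co2:.3f}, "
            f"C_A={chem.c_a:.3f}, C_PO4={chem.c_po4:.3f}, C_Hb={chem.c_hb:.3f} "
            f"(residuals {f_lo:.3e}, {f_hi:.3e})")
    ph = brentq(equilibrium_residual, lo, hi,
                args=(sid, chem.t_co2, chem.c_a, chem.c_po4, chem.c_hb, chem.alpha),
                xtol=1e-12, rtol=8.9e-16)

    c_hbco3 = sid - _weak_acid_charge(ph, chem.c_a, chem.c_po4)
    p_co2 = c_hbco3 / (chem.alpha * 10.0 ** (ph - PK_HH))
    s_co2 = co2_saturation(p_co2)
    c_co2 = chem.alpha * p_co2

    # O2: independent 1D solve on P_O2 given pH (Bohr shift).
    p_o2, s_o2 = _solve_o2(chem.t_o2, chem.c_hb, ph)

    return replace(chem, ph=float(ph), c_hbco3=float(c_hbco3),
                   p_co2=float(p_co2), c_co2=float(c_co2), s_co2=float(s_co2),
                   p_o2=float(p_o2), s_o2=float(s_o2),
                   c_o2=float(ALPHA_O2 * p_o2))


def _solve_o2(t_o2: float, c_hb: float, ph: float) -> tuple[float, float]:
    if t_o2 <= 0:
        return 0.0, 0.0
    if c_hb == 0.0:
        return t_o2 / ALPHA_O2, 0.0

    def resid(p_o2: float) -> float:
        return t_o2 - ALPHA_O2 * p_o2 - 4.0 * o2_saturation(p_o2, ph) * c_hb

    hi = max(200.0, t_o2 / ALPHA_O2)
    if resid(0.0) <= 0:
        return 0.0, 0.0
    p_o2 = brentq(resid, 0.0, hi, xtol=1e-10, rtol=8.9e-16)
    return float(p_o2), o2_saturation(p_o2, ph)


# --- lactate kinetics ------------------------------------------------------

L_AMP = 15.5
L_SCALE = 5.4
L_SLOPE = 25.0
L_OFFSET = 1.0

M_AMP = 10.0
M_SCALE = 24.5
M_SLOPE = 100.0
M_OFFSET = 1.0


def lactate_target(v_bv: float, v_baseline: float) -> float:
    """Hypovolemia-driven lactate target L(V_BV), mmol/L.

    Logistic in the volume fraction: ≈3.42 at baseline volume, saturating
    near 16.5 as blood volume collapses; monotone decreasing in V_BV.
    """
    if v_baseline <= 0:
        raise ValueError("baseline blood volume must be > 0")
    x = L_SLOPE * (v_bv / v_baseline - 1.0)
    return L_AMP / (1.0 + L_SCALE * math.exp(min(x, 700.0))) + L_OFFSET


def renal_clearance_scale(ph_ratio: float) -> float:
    """pH-gated renal clearance multiplier M_L(pH/pH_baseline) ∈ (1, 11).

    ≈1.39 at baseline pH, rising toward 11 during acidosis (the kidney
    clears lactate faster as blood pH falls); monotone decreasing in the
    pH ratio.
    """
    if ph_ratio <= 0:
        raise ValueError("pH ratio must be > 0")
    x = M_SLOPE * (ph_ratio - 1.0)
    return M_AMP / (1.0 + M_SCALE * math.exp(min(x, 700.0))) + M_OFFSET


@dataclass
class LactateKinetics:
    """Renal capillary→tubule lactate mass-transfer bookkeeping."""

    c_sub: float = 1.0               # mmol/L, lactate in the renal capillary
    capillary_volume: float = 100.0  # mL of renal capillary blood
    beta_gamma: float = 1.0          # folded transfer coefficient (dimensionless)
    j_flow: float = 16.0             # mL/s renal capillary flow
    m_sub: float = 0.0               # mmol, accumulated tubule lactate mass
    transferred_total: float = 0.0   # mmol, cumulative blood→tubule transfer


def transfer_lactate_to_tubule(state: LactateKinetics, m_l: float,
                               dt: float) -> tuple[LactateKinetics, float]:
    """Move ΔM = M_L·C_sub·βγ·J·dt (mmol) of lactate into the tubules.

    Flow is in mL/s and concentration in mmol/L, so a 1/1000 volume factor
    converts to mmol.  The transfer is capped at the lactate mass available
    in the capillary; blood + tubule mass is conserved exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    available = state.c_sub * state.capillary_volume / 1000.0  # mmol
    dm = m_l * state.c_sub * state.beta_gamma * state.j_flow * dt / 1000.0
    dm = min(dm, available)
    new_c_sub = (available - dm) * 1000.0 / state.capillary_volume
    new = replace(state, c_sub=new_c_sub, m_sub=state.m_sub + dm,
                  transferred_total=state.transferred_total + dm)
    return new, dm


def relax_lactate(current: float, target: float, dt: float, tau_l: float) -> float:
    """First-order relaxation of blood lactate toward its volume target.

    Implicit Euler: unconditionally stable, exact fixed point at the target,
    and jumps to the target as tau_l → 0.
    """
    if tau_l < 0:
        raise ValueError("tau_l must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if tau_l == 0.0:
        return target
    return (current + (dt / tau_l) * target) / (1.0 + dt / tau_l)


def baseline_total_co2(sid: float, c_a: float, c_po4: float, c_hb: float,
                       p_co2: float = 40.0,
                       alpha: float = ALPHA_CO2) -> tuple[float, float]:
    """Total CO2 and pH consistent with a prescribed baseline P_CO2.

    Used at engine stabilization: finds the pH where charge balance and
    Henderson–Hasselbalch agree at the target P_CO2, then assembles T_CO2.
    """
    def resid(ph: float) -> float:
        c_hbco3 = sid - _weak_acid_charge(ph, c_a, c_po4)
        return ph - (PK_HH + math.log10(max(c_hbco3, 1e-12) / (alpha * p_co2)))

    ph = brentq(resid, *PH_BRACKET, xtol=1e-12)
    c_hbco3 = sid - _weak_acid_charge(ph, c_a, c_po4)
    t_co2 = alpha * p_co2 + c_hbco3 + 4.0 * co2_saturation(p_co2) * c_hb
    return float(t_co2), float(ph)
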