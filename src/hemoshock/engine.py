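"""Coupled cardiopulmonary engine: circuit + drivers + reflexes + chemistry.

The circulation is a reduced closed loop of eight compliant compartments —
left ventricle, aorta/arteries, systemic capillaries, veins, right
ventricle, pulmonary arteries, pulmonary capillaries, pulmonary veins —
joined by resistors and two-state valve elements.  The ventricles are
time-varying compliances C(t) = 1/E_v(t) under the double-Hill elastance
driver.  Hemorrhage is a flow sink at the venous node and transfusion a flow
source at the same node.

Each 0.05 s step executes in a fixed order: (1) preprocess — heart-driver
elastance update, then blood-gas/pH and lactate updates, then the nervous
(baroreflex) update which writes resistances, elastances, heart period and
venous unstressed volume; (2) process — the MNA solve; (3) postprocess —
pressures, flows and stored volumes pushed back onto the compartments.

A minimal ventilation submodel stands in for chemoreceptor control: arterial
total CO2 follows a single-pool mass balance (constant metabolic production;
elimination proportional to P_CO2, to lung perfusion and, more weakly, to
ventilation), and a proportional controller scales respiration rate and
muscle-pressure amplitude with the arterial CO2 deviation from baseline.
Perfusion-limited CO2 elimination is what produces the mixed metabolic +
respiratory acidosis characteristic of severe hemorrhagic shock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import bloodgas, circuit as ckt, drivers
from .baroreflex import (BaroreceptorState, EfferentCommand, EfferentGains,
                         LowPressureState, adapt_operating_point,
                         efferent_response, filter_strain, low_pressure_signal,
                         wall_strain)

__all__ = ["EngineParams", "Engine", "StabilizationError"]

CMH2O_TO_MMHG = 0.7355


class StabilizationError(RuntimeError):
    """Engine failed to reach the requested resting hemodynamics."""


@dataclass
class EngineParams:
    """Tunable physical parameters of the reduced closed loop and submodels."""

    dt: float = 0.05                     # s, global timestep

    # compliances, mL/mmHg
    c_arterial: float = 1.0
    c_sys_cap: float = 6.0
    c_venous: float = 60.0
    c_pulm_art: float = 4.0
    c_pulm_cap: float = 5.0
    c_pulm_ven: float = 8.0

    # resistances, mmHg·s/mL
    r_arterial: float = 0.7              # aorta → systemic capillaries
    r_sys_cap: float = 0.15              # capillaries → veins
    r_venous_return: float = 0.03        # veins → RV (tricuspid path)
    r_pulm: float = 0.08
    r_pulm_ven: float = 0.04
    r_valve_forward: float = 0.006
    r_valve_reverse: float = 2000.0

    # ventricular elastances, mmHg/mL
    e_max_lv: float = 2.6
    e_min_lv: float = 0.05
    e_max_rv: float = 0.6
    e_min_rv: float = 0.045

    # fixed unstressed volumes, mL (venous V0 absorbs the remainder)
    v0_fixed: dict[str, float] = field(default_factory=lambda: {
        "lv": 10.0, "arterial": 160.0, "sys_cap": 300.0, "rv": 10.0,
        "pulm_art": 50.0, "pulm_cap": 90.0, "pulm_ven": 100.0})

    # respiration
    p_pleural_base: float = -3.7         # mmHg
    tidal_volume_per_kg: float = 7.0     # mL/kg target
    lung_compliance: float = 100.0       # mL/cmH2O
    ie_ratio: float = 0.5

    # baroreflex
    gains: EfferentGains = field(default_factory=EfferentGains)
    q_w: float = 0.04
    a_ratio: float = 0.5
    k_b: float = 0.1
    tau_b: float = 0.9
    tau_cp: float = 6.0
    f_cp_max: float = 20.0
    tau_effector: float = 8.0            # s, sympathetic/vagal effector lag
    k_adapt: float = math.log(2.0) / (16.0 * 3600.0)

    # chemistry / lactate
    chem_interval: int = 5               # solve equilibrium every n steps
    tau_lactate: float = 60.0            # s, relaxation toward L(V_BV)
    beta_gamma: float = 0.25
    renal_flow_fraction: float = 0.2     # J = fraction × cardiac output
    c_na: float = 140.0
    c_k: float = 4.0
    c_cl: float = 105.0
    c_a: float = 44.0
    c_po4: float = 1.16
    c_hb: float = 2.3
    p_co2_base: float = 40.0
    venous_co2_offset: float = 2.5       # mmol/L added to venous T_CO2

    # ventilation / CO2 balance
    vco2_production: float = 0.15        # mmol/s whole-body CO2 production
    perfusion_exponent: float = 1.5      # elimination ∝ Q_rel^exponent
    ventilation_weight: float = 0.4      # share of elimination scaling with VE
    g_resp_rate: float = 4.0             # RR gain on CO2 deviation
    resp_rate_bounds: tuple[float, float] = (0.8, 3.0)
    t_co2_bounds: tuple[float, float] = (10.0, 45.0)
    q_rel_bounds: tuple[float, float] = (0.2, 2.0)


@dataclass
class _CycleStats:
    systolic: float = 114.0
    diastolic: float = 73.0
    stroke_volume: float = 70.0
    cardiac_output: float = 83.0  # mL/s


class Engine:
    """One virtual patient: circuit, drivers, reflexes and blood chemistry."""

    def __init__(self, patient, params: EngineParams | None = None):
        self.patient = patient
        self.params = params or EngineParams()
        p = self.params

        self.time = 0.0
        self.dt = p.dt
        self._step_count = 0

        self._build_circuit()

        hr = patient.heart_rate_baseline
        self.heart_period = 60.0 / hr
        self.lv_driver = drivers.HeartDriver(e_max=p.e_max_lv, e_min=p.e_min_lv,
                                             period=self.heart_period)
        self.rv_driver = drivers.HeartDriver(e_max=p.e_max_rv, e_min=p.e_min_rv,
                                             period=self.heart_period)
        self.t_cycle = 0.0
        self.contractility_scale = 1.0
        self.hr_scale = 1.0
        self.resistance_scale = 1.0
        self.uv_scale = 1.0

        rr = patient.respiration_rate_baseline
        self.resp_period = 60.0 / rr
        self.resp_driver = drivers.RespiratoryDriver(p_max=5.0,
                                                     t_resp=self.resp_period,
                                                     ie_ratio=p.ie_ratio)
        self.lung = drivers.LinearLung(compliance=p.lung_compliance)
        self.t_breath = 0.0
        self.rr_scale = 1.0
        self.p_pleural = p.p_pleural_base
        self.respiration_rate = rr

        self.aortic = BaroreceptorState(site="aortic", q_w=p.q_w,
                                        a_ratio=p.a_ratio, k_b=p.k_b,
                                        tau_b=p.tau_b, k_adapt=p.k_adapt)
        self.carotid = BaroreceptorState(site="carotid", q_w=p.q_w,
                                         a_ratio=p.a_ratio, k_b=p.k_b,
                                         tau_b=p.tau_b, k_adapt=p.k_adapt)
        self.lp = LowPressureState(tau_cp=p.tau_cp, f_cp_max=p.f_cp_max,
                                   p_pleural_base=p.p_pleural_base)
        self.reflex_active = False
        self._afferent_only = False
        self.command = EfferentCommand()

        # chemistry state (initialized properly at stabilization)
        self.c_lactate = 1.0
        self.c_lactate_base = 1.0
        self.t_co2 = 25.0
        self.t_co2_base = 25.0
        self.t_o2 = bloodgas.ALPHA_O2 * 100.0 + 4.0 * 0.97 * p.c_hb
        self.ph = 7.4
        self.ph_base = 7.4
        self.p_co2 = p.p_co2_base
        self.arterial = bloodgas.CompartmentChemistry(
            c_na=p.c_na, c_k=p.c_k, c_cl=p.c_cl, c_a=p.c_a, c_po4=p.c_po4,
            c_hb=p.c_hb)
        self.venous = replace(self.arterial)
        self.renal = bloodgas.LactateKinetics(beta_gamma=p.beta_gamma)
        self.lactate_produced = 0.0      # mmol, cumulative net production
        self.lactate_transferred = 0.0   # mmol, cumulative blood→tubule

        # scenario couplings (mL/s)
        self.bleed_flow = 0.0
        self.transfusion_flow = 0.0
        self.total_bled = 0.0
        self.total_transfused = 0.0

        self.cycle = _CycleStats(systolic=patient.systolic_target,
                                 diastolic=patient.diastolic_target)
        self._cyc_max = -math.inf
        self._cyc_min = math.inf
        self._cyc_sv = 0.0
        self.co_base = self.cycle.cardiac_output
        self.blood_volume_baseline = patient.blood_volume_baseline
        self.stabilized = False

    # -- circuit ------------------------------------------------------------
    def _build_circuit(self) -> None:
        p = self.params
        g = ckt.CircuitGraph()
        self.n_gnd = g.add_node("ground", is_ground=True)
        self.n_lv = g.add_node("left_ventricle", pressure=8.0)
        self.n_ao = g.add_node("arteries", pressure=92.0)
        self.n_cap = g.add_node("sys_capillaries", pressure=28.0)
        self.n_ven = g.add_node("veins", pressure=6.5)
        self.n_rv = g.add_node("right_ventricle", pressure=4.0)
        self.n_pa = g.add_node("pulm_arteries", pressure=16.0)
        self.n_pc = g.add_node("pulm_capillaries", pressure=10.0)
        self.n_pv = g.add_node("pulm_veins", pressure=8.0)

        v0 = p.v0_fixed
        self.cap_lv = g.add_capacitor(self.n_lv, self.n_gnd, 1.0 / p.e_min_lv,
                                      label="C_lv", unstressed_volume=v0["lv"])
        self.cap_ao = g.add_capacitor(self.n_ao, self.n_gnd, p.c_arterial,
                                      label="C_arterial",
                                      unstressed_volume=v0["arterial"])
        self.cap_cap = g.add_capacitor(self.n_cap, self.n_gnd, p.c_sys_cap,
                                       label="C_sys_cap",
                                       unstressed_volume=v0["sys_cap"])
        self.cap_ven = g.add_capacitor(self.n_ven, self.n_gnd, p.c_venous,
                                       label="C_venous", unstressed_volume=0.0)
        self.cap_rv = g.add_capacitor(self.n_rv, self.n_gnd, 1.0 / p.e_min_rv,
                                      label="C_rv", unstressed_volume=v0["rv"])
        self.cap_pa = g.add_capacitor(self.n_pa, self.n_gnd, p.c_pulm_art,
                                      label="C_pulm_art",
                                      unstressed_volume=v0["pulm_art"])
        self.cap_pc = g.add_capacitor(self.n_pc, self.n_gnd, p.c_pulm_cap,
                                      label="C_pulm_cap",
                                      unstressed_volume=v0["pulm_cap"])
        self.cap_pv = g.add_capacitor(self.n_pv, self.n_gnd, p.c_pulm_ven,
                                      label="C_pulm_ven",
                                      unstressed_volume=v0["pulm_ven"])

        self.aortic_valve = g.add_valve(self.n_lv, self.n_ao,
                                        p.r_valve_forward, p.r_valve_reverse,
                                        label="aortic_valve")
        self.r_art = g.add_resistor(self.n_ao, self.n_cap, p.r_arterial,
                                    label="R_arterial")
        self.r_cap = g.add_resistor(self.n_cap, self.n_ven, p.r_sys_cap,
                                    label="R_sys_cap")
        self.tricuspid = g.add_valve(self.n_ven, self.n_rv,
                                     p.r_venous_return, p.r_valve_reverse,
                                     label="tricuspid_path")
        self.pulm_valve = g.add_valve(self.n_rv, self.n_pa,
                                      p.r_valve_forward, p.r_valve_reverse,
                                      label="pulmonic_valve")
        self.r_pulm = g.add_resistor(self.n_pa, self.n_pc, p.r_pulm,
                                     label="R_pulm")
        self.r_pv = g.add_resistor(self.n_pc, self.n_pv, p.r_pulm_ven,
                                   label="R_pulm_ven")
        self.mitral = g.add_valve(self.n_pv, self.n_lv,
                                  p.r_valve_forward, p.r_valve_reverse,
                                  label="mitral_path")

        self.hemorrhage_src = g.add_flow_source(self.n_ven, self.n_gnd, 0.0,
                                                label="hemorrhage")
        self.transfusion_src = g.add_flow_source(self.n_gnd, self.n_ven, 0.0,
                                                 label="transfusion")
        self.graph = g
        self._r_art_base = p.r_arterial
        self._r_cap_base = p.r_sys_cap
        self._stab_r_scale = 1.0
        self._stab_e_scale = 1.0
        self._v0_ven_base = 0.0

    # -- public measurements -------------------------------------------------
    @property
    def blood_volume(self) -> float:
        return self.graph.total_stored_volume()

    @property
    def heart_rate(self) -> float:
        return 60.0 / self.heart_period

    @property
    def cvp(self) -> float:
        return self.graph.nodes[self.n_ven].pressure

    @property
    def map_pressure(self) -> float:
        c = self.cycle
        return c.diastolic + (c.systolic - c.diastolic) / 3.0

    # -- stepping ------------------------------------------------------------
    def step(self) -> None:
        """Advance exactly one global timestep (preprocess/process/postprocess)."""
        dt = self.dt
        p = self.params

        # --- preprocess: heart driver -------------------------------------
        e_scale = self.contractility_scale
        lv = self.lv_driver
        rv = self.rv_driver
        e_lv = ((lv.e_max * e_scale - lv.e_min)
                * (drivers.activation_shape(self.t_cycle, lv) / lv.f_max)
                + lv.e_min)
        e_rv = ((rv.e_max * e_scale - rv.e_min)
                * (drivers.activation_shape(self.t_cycle, rv) / rv.f_max)
                + rv.e_min)
        self.cap_lv.compliance = 1.0 / e_lv
        self.cap_rv.compliance = 1.0 / e_rv

        # --- preprocess: respiration --------------------------------------
        p_musc = drivers.respiratory_muscle_pressure(self.t_breath, self.resp_driver)
        self.lung.step(p_musc, dt)
        self.p_pleural = p.p_pleural_base + p_musc * CMH2O_TO_MMHG

        # --- preprocess: blood gas, lactate, CO2 ---------------------------
        self._update_chemistry(dt)

        # --- preprocess: nervous system ------------------------------------
        if self.reflex_active:
            self._update_baroreflex(dt)
            if not self._afferent_only:
                self._apply_efferents(dt)

        # --- process: circuit solve ----------------------------------------
        self.hemorrhage_src.source_value = self.bleed_flow
        self.transfusion_src.source_value = self.transfusion_flow
        solution = self._solve_with_valves(dt)

        # --- postprocess ----------------------------------------------------
        ckt.update_volumes(self.graph, solution, dt)
        self.total_bled += self.bleed_flow * dt
        self.total_transfused += self.transfusion_flow * dt
        self._advance_clocks(dt)
        self.time += dt
        self._step_count += 1

    def _solve_with_valves(self, dt: float, max_passes: int = 8):
        """Solve the step, iterating two-state valves to a consistent state.

        A valve left open while its flow runs backward (or closed while its
        gradient is forward) is flipped and the step re-solved; without this
        the one-step state lag injects large spurious regurgitation at every
        valve transition.
        """
        valves = [e for e in self.graph.elements
                  if e.kind is ckt.ElementKind.VALVE]
        solution = None
        for _ in range(max_passes):
            system = ckt.assemble_mna(self.graph, dt)
            solution = ckt.solve_step(system, self.graph)
            changed = False
            for v in valves:
                grad = (solution.pressures[v.node_a]
                        - solution.pressures[v.node_b])
                want_open = grad > 0.0
                if want_open != v.valve_open:
                    v.valve_open = want_open
                    changed = True
            if not changed:
                break
        return solution

    def _advance_clocks(self, dt: float) -> None:
        pa = self.graph.nodes[self.n_ao].pressure
        self._cyc_max = max(self._cyc_max, pa)
        self._cyc_min = min(self._cyc_min, pa)
        self._cyc_sv += max(self.aortic_valve.last_flow, 0.0) * dt

        self.t_cycle += dt
        if self.t_cycle >= self.heart_period:
            self.t_cycle -= self.heart_period
            self.cycle = _CycleStats(
                systolic=self._cyc_max, diastolic=self._cyc_min,
                stroke_volume=self._cyc_sv,
                cardiac_output=self._cyc_sv / self.heart_period)
            self._cyc_max = -math.inf
            self._cyc_min = math.inf
            self._cyc_sv = 0.0
            # latch the commanded heart period for the next cycle
            new_period = 60.0 / (self.patient.heart_rate_baseline * self.hr_scale)
            if abs(new_period - self.heart_period) > 1e-9:
                self.heart_period = new_period
                self.lv_driver = self.lv_driver.with_period(new_period)
                self.rv_driver = self.rv_driver.with_period(new_period)

        self.t_breath += dt
        if self.t_breath >= self.resp_driver.t_resp:
            self.t_breath -= self.resp_driver.t_resp
            # ventilation controller acts breath-to-breath
            dev = (self.p_co2 - self.params.p_co2_base) / self.params.p_co2_base
            lo, hi = self.params.resp_rate_bounds
            scale = min(max(1.0 + self.params.g_resp_rate * dev, lo), hi)
            self.rr_scale = scale
            rr = self.patient.respiration_rate_baseline * scale
            self.respiration_rate = rr
            p_max = self.resp_driver.p_max
            base_p_max = getattr(self, "_p_max_base", p_max)
            self.resp_driver = drivers.RespiratoryDriver(
                p_max=min(base_p_max * scale, base_p_max * 2.5),
                t_resp=60.0 / rr, ie_ratio=self.params.ie_ratio)

    # -- chemistry ------------------------------------------------------------
    def _update_chemistry(self, dt: float) -> None:
        p = self.params
        v_bv = self.blood_volume
        v_l = max(v_bv, 500.0) / 1000.0

        # lactate: relaxation toward the hypovolemia target (net production)
        target = bloodgas.lactate_target(v_bv, self.blood_volume_baseline)
        before = self.c_lactate
        self.c_lactate = bloodgas.relax_lactate(before, target, dt, p.tau_lactate)
        self.lactate_produced += (self.c_lactate - before) * v_l

        # renal clearance, pH-gated; J follows cardiac output
        q_rel = self._q_rel()
        m_l = bloodgas.renal_clearance_scale(self.ph / self.ph_base)
        self.renal.c_sub = self.c_lactate
        self.renal.j_flow = p.renal_flow_fraction * self.co_base * q_rel
        self.renal.capillary_volume = v_bv  # whole-pool clearance
        self.renal, dm = bloodgas.transfer_lactate_to_tubule(self.renal, m_l, dt)
        self.c_lactate = self.renal.c_sub
        self.lactate_transferred += dm

        # transfused blood carries baseline chemistry (volume restoration)
        if self.transfusion_flow > 0.0:
            dv = self.transfusion_flow * dt / 1000.0  # L
            w = dv / (v_l + dv)
            self.c_lactate += w * (self.c_lactate_base - self.c_lactate)
            self.t_co2 += w * (self.t_co2_base - self.t_co2)

        # single-pool CO2 mass balance with perfusion-limited elimination
        ve_rel = self.rr_scale  # tidal amplitude tracks the same controller
        k_el = p.vco2_production / p.p_co2_base
        elim_factor = (q_rel ** p.perfusion_exponent
                       * (1.0 - p.ventilation_weight
                          + p.ventilation_weight * ve_rel))
        dtco2 = (p.vco2_production - k_el * elim_factor * self.p_co2) / v_l
        lo, hi = p.t_co2_bounds
        # keep the acid-base root inside the physiologic pH bracket: cap
        # total CO2 just below the value that would push pH under 6.0
        sid = p.c_na + p.c_k - (p.c_cl + self.c_lactate)
        hco3_floor = sid - (p.c_a * (0.123 * 6.0 - 0.631)
                            + p.c_po4 * (0.309 * 6.0 - 0.469))
        if hco3_floor > 0.0:
            pco2_floor = hco3_floor / (bloodgas.ALPHA_CO2 * 10.0 ** (6.0 - 6.1))
            t_max = (bloodgas.ALPHA_CO2 * pco2_floor + hco3_floor
                     + 4.0 * bloodgas.co2_saturation(pco2_floor) * p.c_hb)
            hi = min(hi, t_max - 0.5)
        self.t_co2 = min(max(self.t_co2 + dt * dtco2, lo), hi)

        if self._step_count % p.chem_interval == 0:
            self._solve_pools()

    def _q_rel(self) -> float:
        lo, hi = self.params.q_rel_bounds
        q = self.cycle.cardiac_output / max(self.co_base, 1e-9)
        return min(max(q, lo), hi)

    def _solve_pools(self) -> None:
        p = self.params
        self.arterial = bloodgas.solve_equilibrium(replace(
            self.arterial, c_lactate=self.c_lactate, t_co2=self.t_co2,
            t_o2=self.t_o2))
        self.ph = self.arterial.ph
        self.p_co2 = self.arterial.p_co2
        self.venous = bloodgas.solve_equilibrium(replace(
            self.venous, c_lactate=self.c_lactate,
            t_co2=self.t_co2 + p.venous_co2_offset,
            t_o2=max(self.t_o2 - 4.0 * 0.25 * p.c_hb, 0.5)))

    # -- baroreflex -------------------------------------------------------------
    def _update_baroreflex(self, dt: float) -> None:
        sys_p = self.cycle.systolic
        carotid_in = sys_p
        aortic_in = sys_p - self.p_pleural

        for rec, p_in in ((self.aortic, aortic_in), (self.carotid, carotid_in)):
            rec.eps_w = wall_strain(p_in, rec)
            rec.eps_b = filter_strain(rec.eps_b, rec.eps_w, dt, rec)
            rec.s_w = adapt_operating_point(rec.s_w, p_in, dt, rec.k_adapt)
        low_pressure_signal(self.lp, self.cvp, self.p_pleural, dt)
        if not self._afferent_only:
            self.command = efferent_response(self.aortic, self.carotid,
                                             self.lp, self.params.gains)

    def _apply_efferents(self, dt: float) -> None:
        # effector organs respond over seconds: first-order lag on each scale
        cmd = self.command
        a = dt / self.params.tau_effector

        def lag(current: float, target: float) -> float:
            return (current + a * target) / (1.0 + a)

        self.hr_scale = lag(self.hr_scale, cmd.heart_rate_scale)
        self.contractility_scale = lag(self.contractility_scale,
                                       cmd.contractility_scale)
        self.resistance_scale = lag(self.resistance_scale, cmd.resistance_scale)
        uv_scale = lag(self.uv_scale, cmd.unstressed_volume_scale)
        cmd = EfferentCommand(heart_rate_scale=self.hr_scale,
                              contractility_scale=self.contractility_scale,
                              resistance_scale=self.resistance_scale,
                              unstressed_volume_scale=uv_scale)
        self.r_art.resistance = (self._r_art_base * self._stab_r_scale
                                 * cmd.resistance_scale)
        self.r_cap.resistance = (self._r_cap_base * self._stab_r_scale
                                 * cmd.resistance_scale)
        # venous unstressed-volume recruitment: released volume becomes
        # stressed charge on the venous compartment (mass neutral)
        new_v0 = self._v0_ven_base * cmd.unstressed_volume_scale
        dv = self.cap_ven.unstressed_volume - new_v0
        if abs(dv) > 0.0 and self.cap_ven.compliance > 0.0:
            pa, pb = self.cap_ven.previous_pressures
            self.cap_ven.previous_pressures = (pa + dv / self.cap_ven.compliance, pb)
            self.cap_ven.unstressed_volume = new_v0
        self.uv_scale = cmd.unstressed_volume_scale

    # -- stabilization ------------------------------------------------------------
    def stabilize(self, *, max_iter: int = 100, tol_mmhg: float = 2.0) -> None:
        """Iterate systemic resistance and contractility to the patient targets.

        A damped multiplicative Newton-type update drives mean pressure with
        total systemic resistance and pulse pressure with LV end-systolic
        elastance until simulated systolic/diastolic are within ``tol_mmhg``
        of the patient's targets; afferent baselines are then recorded.
        """
        pt = self.patient
        sys_t, dia_t = pt.systolic_target, pt.diastolic_target
        map_t = dia_t + (sys_t - dia_t) / 3.0

        # respiratory amplitude for the requested tidal volume
        target_tv = self.params.tidal_volume_per_kg * pt.weight
        p_max = drivers.calibrate_amplitude(self.resp_driver, self.lung,
                                            target_tv, dt=self.dt)
        self.resp_driver = drivers.RespiratoryDriver(
            p_max=p_max, t_resp=self.resp_period, ie_ratio=self.params.ie_ratio)
        self._p_max_base = p_max

        self.reflex_active = False
        self._settle(4.0)
        converged = False
        sys_m = dia_m = 0.0
        for _ in range(max_iter):
            self._settle(4.0)
            sys_m, dia_m = self.cycle.systolic, self.cycle.diastolic
            if abs(sys_m - sys_t) <= tol_mmhg and abs(dia_m - dia_t) <= tol_mmhg:
                converged = True
                break
            map_m = dia_m + (sys_m - dia_m) / 3.0
            pp_m = max(sys_m - dia_m, 1.0)
            pp_t = sys_t - dia_t
            self._stab_r_scale *= (map_t / max(map_m, 1.0)) ** 0.8
            self._stab_e_scale = min(max(
                self._stab_e_scale * (pp_t / pp_m) ** 0.5, 0.2), 5.0)
            self.r_art.resistance = self._r_art_base * self._stab_r_scale
            self.r_cap.resistance = self._r_cap_base * self._stab_r_scale
            self.lv_driver = drivers.HeartDriver(
                e_max=self.params.e_max_lv * self._stab_e_scale,
                e_min=self.params.e_min_lv, period=self.heart_period)
        if not converged:
            raise StabilizationError(
                f"stabilization did not converge in {max_iter} iterations: "
                f"systolic {sys_m:.1f}/{sys_t:.1f}, diastolic {dia_m:.1f}/{dia_t:.1f}")

        self._record_baselines()
        self.stabilized = True

    def _settle(self, seconds: float) -> None:
        for _ in range(int(round(seconds / self.dt))):
            self.step()

    def _record_baselines(self) -> None:
        p = self.params
        # venous unstressed volume absorbs the remaining patient blood volume
        stressed = self.graph.total_stored_volume() - sum(
            e.unstressed_volume for e in self.graph.capacitors())
        v0_other = sum(p.v0_fixed.values())
        v0_ven = self.patient.blood_volume_baseline - stressed - v0_other
        if v0_ven <= 0:
            raise StabilizationError(
                f"patient blood volume {self.patient.blood_volume_baseline:.0f} mL "
                f"cannot accommodate stressed volume {stressed:.0f} mL")
        self.cap_ven.unstressed_volume = v0_ven
        self.cap_ven.stored_volume += v0_ven  # was built with V0 = 0
        self._v0_ven_base = v0_ven
        self.blood_volume_baseline = self.blood_volume

        sys_b = self.cycle.systolic
        self.co_base = self.cycle.cardiac_output
        # mean pleural pressure over one breath (breathing is always on, so
        # afferent baselines must include its mean, not the resting value)
        n_breath = max(int(round(self.resp_driver.t_resp / self.dt)), 1)
        mean_pl = p.p_pleural_base + CMH2O_TO_MMHG * sum(
            drivers.respiratory_muscle_pressure(i * self.dt, self.resp_driver)
            for i in range(n_breath)) / n_breath
        self.aortic.s_w = sys_b - mean_pl
        self.carotid.s_w = sys_b
        for rec in (self.aortic, self.carotid):
            rec.eps_w = wall_strain(rec.s_w, rec)
            rec.eps_b = rec.k_b * rec.eps_w
        self.lp.cvp_base = self.cvp
        self.lp.p_cp = self.lp.cvp_base - mean_pl
        self.lp.f_cp = self.lp.f_cp_max / 2.0

        # settle the afferent filters against live breathing (no efferents),
        # then freeze their breath-averaged values as the reflex baselines
        self.reflex_active = True
        self._afferent_only = True
        self._settle(4.0 * self.resp_driver.t_resp)
        n_avg = n_breath
        acc_a = acc_c = acc_f = 0.0
        for _ in range(n_avg):
            self.step()
            acc_a += self.aortic.eps_b
            acc_c += self.carotid.eps_b
            acc_f += self.lp.f_cp
        self.aortic.eps_b_baseline = acc_a / n_avg
        self.carotid.eps_b_baseline = acc_c / n_avg
        self.lp.f_cp_baseline = acc_f / n_avg
        self._afferent_only = False
        self.command = EfferentCommand()

        # chemistry baselines: lactate steady state, then T_CO2 at P_CO2 = 40
        j_base = p.renal_flow_fraction * self.co_base
        m_l0 = bloodgas.renal_clearance_scale(1.0)
        k_c = m_l0 * p.beta_gamma * j_base / max(self.blood_volume, 1.0)
        l_target = bloodgas.lactate_target(self.blood_volume,
                                           self.blood_volume_baseline)
        self.c_lactate = l_target / (1.0 + p.tau_lactate * k_c)
        self.c_lactate_base = self.c_lactate
        sid = p.c_na + p.c_k - (p.c_cl + self.c_lactate)
        self.t_co2, self.ph_base = bloodgas.baseline_total_co2(
            sid, p.c_a, p.c_po4, p.c_hb, p.p_co2_base)
        self.t_co2_base = self.t_co2
        self.ph = self.ph_base
        self.p_co2 = p.p_co2_base
        self._solve_pools()
        self.ph_base = self.ph  # solved value (matches prescribed P_CO2)
        self.lactate_produced = 0.0
        self.lactate_transferred = 0.0
        self.renal.m_sub = 0.0
        self.renal.transferred_total = 0.0
        self.total_bled = 0.0
        self.total_transfused = 0.0
        self.reflex_active = True
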