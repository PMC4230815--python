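"""Transient 1-D finite-dose skin penetration simulator.

The model tracks a well-stirred surface vehicle compartment (permeant plus
optional water) on top of two parallel 1-D diffusion domains:

* the **lipid pathway** — stratum corneum lipids (partition/diffusion from
  the neutral-species octanol correlation), then viable epidermis and
  dermis;
* the **polar pathway** — water-filled pores through the stratum corneum
  (small area fraction, hindered aqueous diffusion, carries ionized
  species), opening into its own copy of the viable tissue.

The two domains do not exchange mass, so their summed output is an upper
limit on systemic delivery.  A perfect sink (concentration zero) is enforced
at 2 mm depth, where permeant is credited to the systemic circulation.
Volatile permeant evaporates from the surface through a boundary-layer
mass-transfer coefficient (zero under occlusion).  Repeated applications and
surface-removal (wiping) events are exact integration breakpoints.

The spatial discretization is a conservative finite-volume method of lines
on the water-referenced concentration psi = C/K, which is continuous across
layer interfaces; the stiff cell ODEs are integrated with an implicit BDF
scheme and an analytic Jacobian.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import parameters as P
from .chemprops import (ChemicalRecord, TransportParameters,
                        derive_transport_parameters,
                        vapor_pressure_at_skin_temp)


@dataclass
class ExposureScenario:
    """One dermal application protocol.

    Parameters
    ----------
    chemical : ChemicalRecord
    dose_per_area : float
        Applied permeant dose per application, ug/cm^2.
    area : float
        Application area, cm^2 (used downstream for systemic dose scaling).
    tau : float
        Dosing interval, h (default 24).
    n_applications : int
        Number of repeated applications at interval ``tau``.
    removal_after : float, optional
        Hours after each application at which all surface material is wiped
        off.  ``None`` = no removal.
    occluded : bool
        Covered application site (semi-occluded protocols map to True):
        suppresses evaporation and fully hydrates the SC lipid pathway.
    water_volume_per_area : float
        Co-applied aqueous vehicle volume per application, cm^3/cm^2 of
        skin (0 for neat application).
    duration : float, optional
        Total simulated time, h; defaults to ``n_applications * tau``.
    """

    chemical: ChemicalRecord
    dose_per_area: float
    area: float
    tau: float = P.TAU_DEFAULT
    n_applications: int = 1
    removal_after: Optional[float] = None
    occluded: bool = False
    water_volume_per_area: float = 0.0
    duration: Optional[float] = None

    def __post_init__(self):
        if self.dose_per_area < 0:
            raise ValueError("dose_per_area must be >= 0")
        if self.removal_after is not None and not (
                0.0 < self.removal_after < self.tau):
            raise ValueError("removal_after must lie in (0, tau)")
        if self.water_volume_per_area < 0:
            raise ValueError("water_volume_per_area must be >= 0")
        if self.duration is None:
            self.duration = self.n_applications * self.tau
        if self.duration < self.n_applications * self.tau - 1e-9:
            raise ValueError("duration must cover all applications")

    @property
    def vehicle_load_mg_per_cm2(self) -> float:
        """Total vehicle + permeant load per application, mg/cm^2."""
        water_mg = self.water_volume_per_area * 1000.0  # density 1 g/mL
        return water_mg + self.dose_per_area * 1e-3

    @property
    def is_aqueous(self) -> bool:
        return self.water_volume_per_area > 0.0


@dataclass
class ConditionRules:
    """Resolved application conditions (occlusion/vehicle/hydration)."""

    lipid_hydration: str  # partially_hydrated | fully_hydrated
    polar_hydration: str  # always fully_hydrated
    effective_vapor_pressure: float  # mmHg
    vehicle_model: str  # "neat" | "aqueous"


def apply_condition_rules(scenario: ExposureScenario) -> ConditionRules:
    """Map occlusion and vehicle to hydration state and effective volatility.

    Occlusion zeroes the vapor pressure and fully hydrates the lipid-pathway
    SC.  Open application leaves the stated vapor pressure; the lipid
    pathway is partially hydrated unless the aqueous solvent load reaches
    100 mg/cm^2.  The polar pathway is fully hydrated in all cases.
    """
    rec = scenario.chemical
    if scenario.occluded:
        p_eff = 0.0
        hydration = "fully_hydrated"
    else:
        p_eff = (vapor_pressure_at_skin_temp(rec)
                 if rec.P_vap_pred_32 is not None else 0.0)
        if scenario.is_aqueous and (scenario.vehicle_load_mg_per_cm2
                                    >= P.FULL_HYDRATION_SOLVENT_LOAD):
            hydration = "fully_hydrated"
        else:
            hydration = "partially_hydrated"
    return ConditionRules(
        lipid_hydration=hydration,
        polar_hydration="fully_hydrated",
        effective_vapor_pressure=p_eff,
        vehicle_model="aqueous" if scenario.is_aqueous else "neat",
    )


def make_infinite_dose_scenario(base: ExposureScenario) -> ExposureScenario:
    """Single application of an arbitrarily high dose (1e7 ug/cm^2).

    Keeps the occlusion state and the vehicle *composition* (water:permeant
    volume ratio) of the base scenario; removal steps are dropped.  The
    operation is idempotent.
    """
    if base.dose_per_area > 0:
        ratio = base.water_volume_per_area / (
            base.dose_per_area / (base.chemical.density_or_default * 1e6))
        water = ratio * P.INFINITE_DOSE / (
            base.chemical.density_or_default * 1e6)
    else:
        water = base.water_volume_per_area
    return dataclasses.replace(
        base,
        dose_per_area=P.INFINITE_DOSE,
        n_applications=1,
        removal_after=None,
        water_volume_per_area=water,
        duration=base.duration,
    )


@dataclass
class FluxSeries:
    """Time-resolved output of a skin penetration simulation.

    All per-area quantities are per cm^2 of application area.  ``J_*`` are
    fluxes cleared from the dermis into the systemic circulation
    (ug/(cm^2 h)); ``Q_*`` their running integrals (ug/cm^2).  The
    mass-balance ledger tracks vehicle-resident, evaporated, wiped-off and
    tissue-resident permeant alongside the cleared amounts.
    """

    t: np.ndarray
    J_lipid: np.ndarray
    J_polar: np.ndarray
    Q_lipid: np.ndarray
    Q_polar: np.ndarray
    vehicle_mass: np.ndarray
    evaporated: np.ndarray
    removed: np.ndarray
    sc_content: np.ndarray
    ve_content: np.ndarray
    de_content: np.ndarray
    applied: np.ndarray
    scenario: Optional[ExposureScenario] = None

    @property
    def J_total(self) -> np.ndarray:
        return self.J_lipid + self.J_polar

    @property
    def Q_total(self) -> np.ndarray:
        return self.Q_lipid + self.Q_polar

    def mass_balance_error(self) -> float:
        """Max relative ledger error, |applied - accounted| / applied."""
        accounted = (self.vehicle_mass + self.evaporated + self.removed
                     + self.sc_content + self.ve_content + self.de_content
                     + self.Q_lipid + self.Q_polar)
        mask = self.applied > 0
        if not mask.any():
            return float(np.max(np.abs(accounted)))
        return float(np.max(np.abs(accounted[mask] - self.applied[mask])
                            / self.applied[mask]))

    def vehicle_depletion_fraction(self) -> float:
        """Max fraction of the applied dose lost from the vehicle."""
        total = self.applied[-1]
        if total <= 0:
            return 0.0
        return float(np.max((self.applied - self.vehicle_mass) / total))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t_h": self.t,
            "J_lipid": self.J_lipid,
            "J_polar": self.J_polar,
            "J_total": self.J_total,
            "Q_lipid": self.Q_lipid,
            "Q_polar": self.Q_polar,
            "Q_total": self.Q_total,
            "vehicle_mass": self.vehicle_mass,
            "evaporated": self.evaporated,
            "removed": self.removed,
            "sc_content": self.sc_content,
            "ve_content": self.ve_content,
            "de_content": self.de_content,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

class _Pathway:
    """Finite-volume grid for one diffusion domain (lipid or polar)."""

    def __init__(self, segments):
        # segments: list of (thickness, n_cells, K, D, area_fraction)
        dx, K, D, f = [], [], [], []
        self.layer_slices = []
        start = 0
        for (L, n, K_l, D_l, f_l) in segments:
            dx += [L / n] * n
            K += [K_l] * n
            D += [D_l] * n
            f += [f_l] * n
            self.layer_slices.append(slice(start, start + n))
            start += n
        self.dx = np.array(dx)
        self.K = np.array(K)
        self.D = np.array(D)
        self.f = np.array(f)
        self.n = len(dx)
        dkf = self.D * self.K * self.f
        # interior conductances between cell i and i+1
        self.g = 1.0 / (self.dx[:-1] / (2 * dkf[:-1])
                        + self.dx[1:] / (2 * dkf[1:]))
        self.g_top = 2 * dkf[0] / self.dx[0]
        self.g_bot = 2 * dkf[-1] / self.dx[-1]
        self.cap = self.f * self.K * self.dx  # mass per unit psi

    def interior_matrix(self) -> np.ndarray:
        """Constant tridiagonal part of d(psi)/dt (sink at the bottom)."""
        n = self.n
        A = np.zeros((n, n))
        for i in range(n - 1):
            g = self.g[i]
            A[i, i] -= g / self.cap[i]
            A[i, i + 1] += g / self.cap[i]
            A[i + 1, i + 1] -= g / self.cap[i + 1]
            A[i + 1, i] += g / self.cap[i + 1]
        A[n - 1, n - 1] -= self.g_bot / self.cap[n - 1]
        return A

    def layer_mass(self, psi: np.ndarray, layer: int) -> float:
        s = self.layer_slices[layer]
        return float(np.sum(self.cap[s] * psi[s]))


def _build_pathways(tp: TransportParameters, rules: ConditionRules,
                    n_sc: int, n_ve: int, n_de: int):
    L_sc_lip = (P.L_SC_FULL if rules.lipid_hydration == "fully_hydrated"
                else P.L_SC_PARTIAL)
    L_sc_pol = P.L_SC_FULL  # polar pathway is always fully hydrated
    L_de_lip = P.TOTAL_DEPTH - L_sc_lip - P.L_VE
    L_de_pol = P.TOTAL_DEPTH - L_sc_pol - P.L_VE
    f_pol = tp.f_polar_area
    lipid = _Pathway([
        (L_sc_lip, n_sc, tp.K_sc_lipid_w, tp.D_sc_lipid, 1.0 - f_pol),
        (P.L_VE, n_ve, tp.K_ve_w, tp.D_ve, 1.0),
        (L_de_lip, n_de, tp.K_de_w, tp.D_de, 1.0),
    ])
    polar = _Pathway([
        (L_sc_pol, n_sc, tp.K_polar_w, tp.D_polar, f_pol),
        (P.L_VE, n_ve, tp.K_ve_w, tp.D_ve, 1.0),
        (L_de_pol, n_de, tp.K_de_w, tp.D_de, 1.0),
    ])
    return lipid, polar


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class SolverError(RuntimeError):
    pass


class _Engine:
    """Assembled ODE system for one scenario.

    State vector: [psi_lipid (n), psi_polar (n), M_vehicle, E_evap,
    Q_lipid, Q_polar].
    """

    def __init__(self, scenario: ExposureScenario,
                 tp: TransportParameters, rules: ConditionRules,
                 n_sc: int, n_ve: int, n_de: int):
        self.sc = scenario
        self.tp = tp
        self.rules = rules
        self.lip, self.pol = _build_pathways(tp, rules, n_sc, n_ve, n_de)
        self.nl = self.lip.n
        self.np_ = self.pol.n
        self.n_state = self.nl + self.np_ + 4
        self.iM = self.nl + self.np_
        self.iE = self.iM + 1
        self.iQl = self.iM + 2
        self.iQp = self.iM + 3
        self.s_eff = tp.surface_solubility
        self.rho = scenario.chemical.density_or_default * 1e6  # ug/cm^3
        self.k_evap = tp.k_evap if not scenario.occluded else 0.0
        # constant interior matrix (without surface coupling)
        A = np.zeros((self.n_state, self.n_state))
        A[:self.nl, :self.nl] = self.lip.interior_matrix()
        A[self.nl:self.iM, self.nl:self.iM] = self.pol.interior_matrix()
        # systemic clearance bookkeeping
        A[self.iQl, self.nl - 1] = self.lip.g_bot
        A[self.iQp, self.iM - 1] = self.pol.g_bot
        self.A_base = A

    # --- vehicle thermodynamics -------------------------------------------
    def psi_vehicle(self, M: float, V_w: float):
        """Water-referenced surface concentration and its dM derivative.

        In the neat regime the surface activity is 1 (psi = s_eff)
        regardless of the remaining amount; depletion to zero is handled by
        the integration event that switches to the bare-skin regime.
        """
        if V_w <= 0.0:
            return self.s_eff, 0.0
        Vc = max(M, 0.0) / self.rho
        a = Vc / (Vc + V_w)
        dpsi_dM = (self.s_eff * V_w / (Vc + V_w) ** 2 / self.rho
                   if M > 0 else self.s_eff / (V_w * self.rho))
        return self.s_eff * a, dpsi_dM

    # --- regimes -----------------------------------------------------------
    def rhs_vehicle(self, V_w: float):
        """RHS/Jacobian for the vehicle-present regime."""
        gl, gp = self.lip.g_top, self.pol.g_top
        cl, cp = self.lip.cap[0], self.pol.cap[0]

        def rhs(t, y):
            dy = self.A_base @ y
            psi_v, _ = self.psi_vehicle(y[self.iM], V_w)
            Jl = gl * (psi_v - y[0])
            Jp = gp * (psi_v - y[self.nl])
            Jev = self.k_evap * psi_v
            dy[0] += Jl / cl
            dy[self.nl] += Jp / cp
            dy[self.iM] += -(Jl + Jp + Jev)
            dy[self.iE] += Jev
            return dy

        def jac(t, y):
            J = self.A_base.copy()
            _, dpsi = self.psi_vehicle(y[self.iM], V_w)
            J[0, 0] += -gl / cl
            J[self.nl, self.nl] += -gp / cp
            J[0, self.iM] += gl * dpsi / cl
            J[self.nl, self.iM] += gp * dpsi / cp
            J[self.iM, 0] += gl
            J[self.iM, self.nl] += gp
            J[self.iM, self.iM] += -(gl + gp + self.k_evap) * dpsi
            return J

        return rhs, jac

    def rhs_bare(self):
        """RHS/Jacobian with no surface reservoir (evaporation from SC)."""
        kl = self.lip.f[0] * self.k_evap
        kp = self.pol.f[0] * self.k_evap
        cl, cp = self.lip.cap[0], self.pol.cap[0]
        A = self.A_base.copy()
        A[0, 0] += -kl / cl
        A[self.nl, self.nl] += -kp / cp
        A[self.iE, 0] += kl
        A[self.iE, self.nl] += kp

        def rhs(t, y):
            return A @ y

        def jac(t, y):
            return A

        return rhs, jac


def simulate(scenario: ExposureScenario,
             transport_override: Optional[TransportParameters] = None,
             n_sc: int = P.N_SC, n_ve: int = P.N_VE, n_de: int = P.N_DE,
             points_per_interval: int = 40,
             rtol: float = 1e-6) -> FluxSeries:
    """Run the transient two-pathway penetration simulation.

    Returns a :class:`FluxSeries` on a grid that resolves every application
    and removal event.  Raises :class:`SolverError` on integration failure
    or if concentrations go negative beyond tolerance.
    """
    rules = apply_condition_rules(scenario)
    if transport_override is not None:
        tp = transport_override
    else:
        tp = derive_transport_parameters(
            scenario.chemical, rules.lipid_hydration,
            vapor_pressure_mmHg=rules.effective_vapor_pressure)
    eng = _Engine(scenario, tp, rules, n_sc, n_ve, n_de)

    # event timeline
    events = []  # (time, kind)
    for k in range(scenario.n_applications):
        t_app = k * scenario.tau
        if t_app < scenario.duration - 1e-12 or k == 0:
            events.append((t_app, "apply"))
            if scenario.removal_after is not None:
                events.append((t_app + scenario.removal_after, "remove"))
    events = [e for e in events if e[0] < scenario.duration - 1e-12]
    events.sort()
    breakpoints = sorted({t for t, _ in events} | {scenario.duration})

    y = np.zeros(eng.n_state)
    V_w = 0.0
    removed = 0.0
    applied = 0.0

    ts, ys = [], []
    applied_track, removed_track = [], []

    def record(t_arr, y_arr):
        for t, yy in zip(np.atleast_1d(t_arr),
                         np.atleast_2d(y_arr.T if y_arr.ndim == 2 else y_arr)):
            ts.append(t)
            ys.append(yy.copy())
            applied_track.append(applied)
            removed_track.append(removed)

    event_map = dict()
    for t, kind in events:
        event_map.setdefault(t, []).append(kind)

    atol_psi = max(eng.s_eff * 1e-10, 1e-14)
    t_now = 0.0
    record(t_now, y)
    for t, kinds in sorted(event_map.items()):
        if abs(t - t_now) > 1e-12:
            raise SolverError("event schedule inconsistency")
        for kind in kinds:
            if kind == "apply":
                y[eng.iM] += scenario.dose_per_area
                applied += scenario.dose_per_area
                V_w += scenario.water_volume_per_area
            elif kind == "remove":
                removed += max(y[eng.iM], 0.0)
                y[eng.iM] = 0.0
                V_w = 0.0
        break  # only the t=0 events are handled here; loop below does rest

    # walk segments between breakpoints
    future_events = sorted(tt for tt in event_map if tt > 1e-12)
    seg_bounds = [0.0] + future_events + [scenario.duration]
    seg_bounds = sorted(set(seg_bounds))

    for t0, t1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        y = _integrate_segment(eng, y, V_w, t0, t1, record,
                               points_per_interval, rtol, atol_psi)
        # apply events scheduled at t1
        for kind in event_map.get(t1, []):
            if kind == "apply":
                y[eng.iM] += scenario.dose_per_area
                applied += scenario.dose_per_area
                V_w += scenario.water_volume_per_area
            elif kind == "remove":
                removed += max(y[eng.iM], 0.0)
                y[eng.iM] = 0.0
                V_w = 0.0
        record(t1, y)

    return _assemble(eng, scenario,
                     np.array(ts), np.array(ys),
                     np.array(applied_track), np.array(removed_track))


def _integrate_segment(eng, y, V_w, t0, t1, record, npts, rtol, atol_psi):
    """Integrate [t0, t1], switching to the bare regime if the neat vehicle
    empties mid-segment."""
    remaining = (t0, t1)
    while remaining is not None:
        a, b = remaining
        neat_vehicle = (V_w <= 0.0 and y[eng.iM] > 0.0)
        aqueous = V_w > 0.0
        if neat_vehicle or aqueous:
            rhs, jac = eng.rhs_vehicle(V_w)
            ev = None
            if neat_vehicle:
                def vehicle_empty(t, yy):
                    return yy[eng.iM]
                vehicle_empty.terminal = True
                vehicle_empty.direction = -1
                ev = [vehicle_empty]
        else:
            rhs, jac = eng.rhs_bare()
            ev = None
        t_eval = np.linspace(a, b, max(3, int(np.ceil(npts * (b - a)
                                                      / (t1 - t0 + 1e-12)))))
        atol = np.full(eng.n_state, atol_psi)
        big = max(abs(y[eng.iM]), 1.0)
        atol[eng.iM:] = max(1e-9 * big, 1e-12)
        sol = solve_ivp(rhs, (a, b), y, method="BDF", jac=jac,
                        t_eval=t_eval[1:] if len(t_eval) > 1 else None,
                        events=ev, rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(f"integration failed on [{a}, {b}]: "
                              f"{sol.message}")
        sol_t = np.asarray(sol.t)
        sol_y = np.asarray(sol.y)
        if sol_t.size:
            record(sol_t, sol_y)
        if sol.status == 1:  # vehicle emptied
            t_ev = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            y[eng.iM] = 0.0
            record(t_ev, y)
            remaining = (t_ev, b) if b - t_ev > 1e-10 else None
        else:
            y = sol_y[:, -1].copy() if sol_t.size else y.copy()
            remaining = None
        # guard against spurious negative concentrations
        psi_min = min(y[:eng.iM].min(initial=0.0), 0.0)
        if psi_min < -1e-4 * max(eng.s_eff, 1e-12):
            raise SolverError(f"negative concentration beyond tolerance "
                              f"({psi_min:.3e})")
        y[:eng.iM] = np.maximum(y[:eng.iM], 0.0)
        if y[eng.iM] < 0:
            y[eng.iM] = 0.0
    return y


def _assemble(eng, scenario, t, Y, applied, removed) -> FluxSeries:
    nl, iM, iE, iQl, iQp = eng.nl, eng.iM, eng.iE, eng.iQl, eng.iQp
    psi_l = Y[:, :nl]
    psi_p = Y[:, nl:iM]
    J_lip = eng.lip.g_bot * psi_l[:, -1]
    J_pol = eng.pol.g_bot * psi_p[:, -1]
    sc = np.array([eng.lip.layer_mass(p, 0) for p in psi_l]) + \
        np.array([eng.pol.layer_mass(p, 0) for p in psi_p])
    ve = np.array([eng.lip.layer_mass(p, 1) for p in psi_l]) + \
        np.array([eng.pol.layer_mass(p, 1) for p in psi_p])
    de = np.array([eng.lip.layer_mass(p, 2) for p in psi_l]) + \
        np.array([eng.pol.layer_mass(p, 2) for p in psi_p])
    return FluxSeries(
        t=t,
        J_lipid=J_lip,
        J_polar=J_pol,
        Q_lipid=Y[:, iQl],
        Q_polar=Y[:, iQp],
        vehicle_mass=np.maximum(Y[:, iM], 0.0),
        evaporated=Y[:, iE],
        removed=removed,
        sc_content=sc,
        ve_content=ve,
        de_content=de,
        applied=applied,
        scenario=scenario,
    )
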