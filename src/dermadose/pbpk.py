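"""Generic 15-compartment perfusion-limited PBPK model.

Tissues (adipose, bone, brain, gut, heart, kidney, liver, lung, muscle,
pancreas, prostate, skin, spleen, testes, thymus) are linked by venous and
arterial blood pools; the lung sits in series and carries total cardiac
output, and gut and spleen drain into the liver inlet (portal flow).
Distribution into each tissue is instantaneous (perfusion rate-limited).

Dermally cleared permeant enters the venous pool as a constant infusion.
Elimination is linear hepatic extraction: a fixed fraction (extraction
ratio, default 0.1) of the permeant entering the liver is cleared per pass,
so the systemic clearance referenced to venous blood is
CL = ER x Q_hepatic (default 0.15 L/h/kg) and the steady-state venous
concentration obeys C_ss = R / CL independently of the partition
coefficients.  Blood:plasma ratio is taken as 1, so venous blood and plasma
concentrations coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import parameters as P
from .chemprops import ChemicalRecord, fraction_neutral

TISSUES = tuple(sorted(P.TISSUE_COMPOSITION))


@dataclass
class PBPKPhysiology:
    """Compartment volumes (L/kg) and blood flows (L/h/kg)."""

    volumes: Dict[str, float] = field(
        default_factory=lambda: dict(P.PBPK_VOLUMES))
    flows: Dict[str, float] = field(
        default_factory=lambda: dict(P.PBPK_FLOWS))
    BW: float = P.BW_HUMAN

    def __post_init__(self):
        for name, v in {**self.volumes, **self.flows}.items():
            if v <= 0:
                raise ValueError(f"{name}: volumes and flows must be > 0")
        missing = set(TISSUES) - set(self.volumes)
        if missing:
            raise ValueError(f"missing volumes for {sorted(missing)}")

    @property
    def cardiac_output(self) -> float:
        """Total cardiac output, L/h/kg (carried by the lung)."""
        return sum(v for k, v in self.flows.items() if k != "lung")

    @property
    def hepatic_flow_total(self) -> float:
        """Arterial + portal blood flow into the liver, L/h/kg."""
        return (self.flows["liver_arterial"]
                + sum(self.flows[t] for t in P.PORTAL_TISSUES))

    def validate_flow_balance(self) -> None:
        """Flows must balance at every node (venous = cardiac output)."""
        co = self.cardiac_output
        venous_in = (sum(v for k, v in self.flows.items()
                         if k not in P.PORTAL_TISSUES
                         and k not in ("liver_arterial", "lung"))
                     + self.hepatic_flow_total)
        if abs(venous_in - co) / co > 1e-9:
            raise ValueError("flow balance violated at the venous node")


@dataclass
class PBPKChemicalParams:
    """Chemical-specific PBPK inputs."""

    Kp: Dict[str, float]  # tissue:blood partition coefficients
    fu_plasma: float
    CL_hepatic: float = 0.15  # L/h/kg BW (= ER x hepatic blood flow)

    def __post_init__(self):
        for t, v in self.Kp.items():
            if v <= 0:
                raise ValueError(f"Kp[{t}] must be > 0")
        if self.CL_hepatic < 0:
            raise ValueError("CL_hepatic must be >= 0")


def _fu_tissue(fu_plasma: float) -> float:
    fu_p = max(fu_plasma, 1e-6)
    return 1.0 / (1.0 + P.TISSUE_BINDING_RATIO * (1.0 - fu_p) / fu_p)


def estimate_partition_coefficients(
        rec: ChemicalRecord,
        physiology: Optional[PBPKPhysiology] = None,
        tissue_composition: Optional[Dict[str, tuple]] = None,
        plasma_composition: tuple = P.PLASMA_COMPOSITION,
) -> Dict[str, float]:
    """Tissue:blood partition coefficients from tissue composition.

    Mechanistic composition-based calculation: each tissue is a mix of
    water, neutral lipid and phospholipid; the neutral species (ionization
    at blood pH 7.4) distributes into the lipid fractions according to its
    octanol-water (non-adipose) or vegetable-oil-water (adipose)
    lipophilicity, with phospholipid treated as 30% lipid-like and 70%
    water-like.  Binding is carried by the unbound-fraction ratio
    fu_plasma / fu_tissue.  Deterministic in its inputs.
    """
    if rec.fu_plasma is None:
        raise ValueError("fu_plasma is required")
    comp = tissue_composition or P.TISSUE_COMPOSITION
    f_neu = fraction_neutral(rec.pKa, P.BLOOD_PH)
    logp_eff = rec.logKow + np.log10(max(f_neu, 1e-12))
    p_oct = 10.0 ** logp_eff
    # vegetable oil:water lipophilicity for adipose
    p_oil = 10.0 ** (1.115 * logp_eff - 1.35)
    vw_p, vnl_p, vph_p = plasma_composition
    fu_p = max(rec.fu_plasma, 1e-6)
    fu_t = _fu_tissue(fu_p)

    def _kp(p, comp_t, binding):
        vw, vnl, vph = comp_t
        num = p * (vnl + 0.3 * vph) + (vw + 0.7 * vph)
        den = p * (vnl_p + 0.3 * vph_p) + (vw_p + 0.7 * vph_p)
        return num / den * binding

    out = {}
    for tissue, comp_t in comp.items():
        if tissue == "adipose":
            out[tissue] = _kp(p_oil, comp_t, fu_p)
        else:
            out[tissue] = _kp(p_oct, comp_t, fu_p / fu_t)
    return out


def params_for_chemical(rec: ChemicalRecord,
                        physiology: Optional[PBPKPhysiology] = None,
                        ) -> PBPKChemicalParams:
    phys = physiology or PBPKPhysiology()
    cl = P.HEPATIC_EXTRACTION_RATIO * phys.hepatic_flow_total
    return PBPKChemicalParams(
        Kp=estimate_partition_coefficients(rec, phys),
        fu_plasma=rec.fu_plasma,
        CL_hepatic=cl,
    )


@dataclass
class InfusionResult:
    t: np.ndarray  # h
    concentrations: Dict[str, np.ndarray]  # mg/L per compartment
    C_p_ss: float  # mg/L, steady-state venous plasma concentration
    converged: bool
    last_relative_change: float


def _system_matrices(params: PBPKChemicalParams, phys: PBPKPhysiology):
    """Build A, b of dC/dt = A C + b R for the 17-state linear system."""
    order = list(TISSUES) + ["venous", "arterial"]
    idx = {name: i for i, name in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    V = np.array([phys.volumes[name] for name in order])
    co = phys.cardiac_output
    q_liv = phys.hepatic_flow_total
    er = params.CL_hepatic / q_liv if q_liv > 0 else 0.0
    iv, ia = idx["venous"], idx["arterial"]

    def kp(t):
        return params.Kp[t]

    for t in TISSUES:
        i = idx[t]
        if t == "lung":
            # series element: venous -> lung -> arterial, carries CO
            A[i, iv] += co
            A[i, i] -= co / kp(t)
            A[ia, i] += co / kp(t)
            A[ia, ia] -= co
        elif t == "liver":
            # inlet = hepatic artery + portal outflows; extraction ratio
            # removes a fixed fraction of the *incoming* permeant
            q_ha = phys.flows["liver_arterial"]
            A[i, ia] += (1.0 - er) * q_ha
            for pt in P.PORTAL_TISSUES:
                j = idx[pt]
                A[i, j] += (1.0 - er) * phys.flows[pt] / kp(pt)
            A[i, i] -= q_liv / kp(t)
            A[iv, i] += q_liv / kp(t)
        elif t in P.PORTAL_TISSUES:
            q = phys.flows[t]
            A[i, ia] += q
            A[i, i] -= q / kp(t)
            # outflow routed through the liver (handled above)
        else:
            q = phys.flows[t]
            A[i, ia] += q
            A[i, i] -= q / kp(t)
            A[iv, i] += q / kp(t)
    A[ia, ia] += 0.0
    A[iv, iv] -= co
    A /= V[:, None]
    b = np.zeros(n)
    b[iv] = 1.0 / (24.0 * phys.volumes["venous"])  # R in mg/kg/day -> mg/L/h
    return order, A, b


def steady_state_closed_form(params: PBPKChemicalParams,
                             phys: Optional[PBPKPhysiology] = None,
                             R: float = 0.0) -> Dict[str, float]:
    """Exact steady state of the linear system (solve A C = -b R)."""
    phys = phys or PBPKPhysiology()
    order, A, b = _system_matrices(params, phys)
    if R == 0.0:
        return {name: 0.0 for name in order}
    C = np.linalg.solve(A, -b * R)
    return dict(zip(order, C))


def simulate_infusion(params: PBPKChemicalParams,
                      physiology: Optional[PBPKPhysiology] = None,
                      R: float = 0.0,
                      ss_tol: float = 0.001,
                      max_days: int = 4000) -> InfusionResult:
    """Integrate the PBPK ODEs under constant venous infusion at rate R.

    R is in mg/kg/day.  Integration proceeds in 24 h blocks until the
    venous concentration changes by less than ``ss_tol`` (relative) per
    24 h, then reports C_p,ss.  Raises RuntimeError if steady state is not
    reached within ``max_days`` simulated days.
    """
    if R < 0:
        raise ValueError("infusion rate must be >= 0")
    phys = physiology or PBPKPhysiology()
    phys.validate_flow_balance()
    order, A, b = _system_matrices(params, phys)
    n = len(order)
    y = np.zeros(n)
    if R == 0.0:
        return InfusionResult(np.array([0.0]),
                              {name: np.zeros(1) for name in order},
                              0.0, True, 0.0)

    def rhs(t, yy):
        return A @ yy + b * R

    def jac(t, yy):
        return A

    ts = [0.0]
    ys = [y.copy()]
    iv = order.index("venous")
    rel = np.inf
    t_now = 0.0
    chunk_h = 24.0
    for _ in range(max_days):
        sol = solve_ivp(rhs, (t_now, t_now + chunk_h), y,
                        method="BDF", jac=jac, rtol=1e-8, atol=1e-12,
                        t_eval=np.linspace(t_now + chunk_h / 4,
                                           t_now + chunk_h, 4))
        if not sol.success:
            raise RuntimeError(f"PBPK integration failed: {sol.message}")
        c_prev = y[iv]
        y = sol.y[:, -1].copy()
        ts.extend(sol.t)
        ys.extend(sol.y.T)
        t_now += chunk_h
        if y[iv] > 0:
            rel = abs(y[iv] - c_prev) / y[iv]
            if rel < ss_tol:
                break
    else:
        raise RuntimeError(
            f"no steady state within {max_days} days "
            f"(last relative change {rel:.3e})")
    if rel >= ss_tol:
        raise RuntimeError(
            f"no steady state within {max_days} days "
            f"(last relative change {rel:.3e})")
    ts = np.array(ts)
    Y = np.array(ys)
    conc = {name: Y[:, i] for i, name in enumerate(order)}
    # Aitken acceleration of the chunk-end venous series: the approach to
    # steady state is dominated by the slowest perfusion pole, so the tail
    # is nearly geometric and extrapolates accurately to the limit.
    tail = conc["venous"][-3:] if len(ts) >= 3 else conc["venous"]
    c_ss = float(y[iv])
    if len(tail) == 3:
        d1, d2 = tail[1] - tail[0], tail[2] - tail[1]
        if d1 != 0 and 0 < d2 / d1 < 1:
            r = d2 / d1
            c_ss = float(tail[2] + d2 * r / (1 - r))
    return InfusionResult(ts, conc, c_ss, True, float(rel))


def compute_ecf(C_p_ss: float, human_dermal_dose: float) -> float:
    """Exposure conversion factor: C_p,ss divided by the human dermal dose.

    The caller chooses the denominator convention (ug/cm^2/day or
    mg/kg/day); the returned ECF carries the corresponding reciprocal
    units.
    """
    if human_dermal_dose <= 0:
        raise ValueError("human dermal dose must be positive")
    return C_p_ss / human_dermal_dose


def summary_json(C_p_ss: float, dose_per_area: float, dose_per_kg: float,
                 path=None) -> dict:
    out = {
        "C_p_ss": C_p_ss,
        "ECF_per_area": compute_ecf(C_p_ss, dose_per_area),
        "ECF_per_kg": compute_ecf(C_p_ss, dose_per_kg),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)
    return out
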