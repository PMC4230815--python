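"""Chemical records and derived transport/evaporation parameters.

A :class:`ChemicalRecord` carries the physicochemical identity of a permeant
(molar mass, lipophilicity, ionization, plasma protein binding, vapor
pressures, aqueous solubility, density).  From it the package derives the
layer-by-layer transport parameters the skin simulator needs: stratum
corneum lipid partitioning and diffusion, polar-pathway diffusion, viable
tissue partitioning, and the surface mass-transfer coefficient that governs
evaporation at 32 C under a 0.17 m/s air flow.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from . import parameters as P

Hydration = Literal["partially_hydrated", "fully_hydrated"]

CSV_COLUMNS = [
    "name", "MW", "logKow", "pKa", "pKa_type", "fu_plasma",
    "Pvap_meas_25", "Pvap_pred_25", "Pvap_pred_32", "solubility", "density",
]


@dataclass(frozen=True)
class ChemicalRecord:
    """Physicochemical identity of a permeant.

    Parameters
    ----------
    name : str
    MW : float
        Molar mass, g/mol.
    logKow : float
        log10 octanol-water partition coefficient of the neutral species.
    pKa : sequence of (value, "acid"|"base"), optional
        Ionizable groups; empty for permanently neutral chemicals.
    fu_plasma : float
        Fraction unbound in plasma, in [0, 1].
    P_vap_meas_25, P_vap_pred_25, P_vap_pred_32 : float, optional
        Vapor pressures in mmHg (measured at 25 C, predicted at 25 C,
        predicted at 32 C).
    solubility_water : float, optional
        Aqueous solubility, mg/mL.  ``None`` denotes a water-miscible
        liquid.
    density : float, optional
        Liquid density, g/mL (defaults to 1.0 where needed).
    """

    name: str
    MW: float
    logKow: float
    fu_plasma: float
    pKa: tuple = field(default=())
    P_vap_meas_25: Optional[float] = None
    P_vap_pred_25: Optional[float] = None
    P_vap_pred_32: Optional[float] = None
    solubility_water: Optional[float] = None
    density: Optional[float] = None

    def __post_init__(self):
        if self.MW <= 0:
            raise ValueError(f"{self.name}: MW must be positive")
        if not (0.0 <= self.fu_plasma <= 1.0):
            raise ValueError(f"{self.name}: fu_plasma must be in [0, 1]")
        for v in (self.P_vap_meas_25, self.P_vap_pred_25, self.P_vap_pred_32):
            if v is not None and v < 0:
                raise ValueError(f"{self.name}: vapor pressures must be >= 0")
        for pka, kind in self.pKa:
            if kind not in ("acid", "base"):
                raise ValueError(f"{self.name}: pKa type must be acid|base")

    @property
    def density_or_default(self) -> float:
        return self.density if self.density is not None else 1.0


@dataclass
class TransportParameters:
    """Layer transport parameters driving the two-pathway skin model.

    All partition coefficients are referenced to water; diffusivities are in
    cm^2/h; ``k_evap`` (cm/h) multiplies the water-referenced surface
    concentration to give the evaporative flux and is zero under occlusion.
    """

    K_sc_lipid_w: float
    D_sc_lipid: float
    K_polar_w: float
    D_polar: float
    f_polar_area: float
    K_ve_w: float
    K_de_w: float
    D_ve: float
    D_de: float
    k_evap: float
    fu_tissue: float
    fraction_neutral: float
    surface_solubility: float  # ug/cm^3, water-referenced conc of the pure
    # (or saturated) chemical at the surface

    def __post_init__(self):
        for name in ("K_sc_lipid_w", "K_polar_w", "K_ve_w", "K_de_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("D_sc_lipid", "D_polar", "D_ve", "D_de"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.f_polar_area < 1.0):
            raise ValueError("f_polar_area must lie in (0, 1)")
        if self.k_evap < 0:
            raise ValueError("k_evap must be >= 0")


def vapor_pressure_at_skin_temp(rec: ChemicalRecord) -> float:
    """Vapor pressure at the skin surface temperature (32 C), mmHg.

    When a measured 25 C value exists it is rescaled by the predicted
    32 C / 25 C ratio; otherwise the predicted 32 C value is used directly.
    """
    if rec.P_vap_pred_32 is None:
        raise ValueError(f"{rec.name}: predicted 32 C vapor pressure required")
    if rec.P_vap_meas_25 is not None:
        if rec.P_vap_pred_25 is None or rec.P_vap_pred_25 <= 0:
            # no usable predicted 25 C anchor -> fall back to the 32 C value
            return rec.P_vap_pred_32
        return rec.P_vap_meas_25 * rec.P_vap_pred_32 / rec.P_vap_pred_25
    return rec.P_vap_pred_32


def fraction_neutral(pKa: Sequence, pH: float) -> float:
    """Henderson-Hasselbalch neutral fraction at the given pH."""
    f = 1.0
    for pka, kind in pKa:
        if kind == "acid":
            f *= 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            f *= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return f


def surface_solubility(rec: ChemicalRecord) -> float:
    """Water-referenced concentration of the neat chemical, ug/cm^3.

    For a sparingly soluble chemical this is its aqueous solubility (the
    water-phase concentration in equilibrium with the pure phase at unit
    activity); for a water-miscible liquid it is the density of the pure
    liquid expressed as a concentration.
    """
    if rec.solubility_water is not None:
        return rec.solubility_water * 1000.0  # mg/mL -> ug/cm^3
    return rec.density_or_default * 1e6  # g/mL -> ug/cm^3


def gas_phase_mass_transfer_coefficient(MW: float) -> float:
    """Boundary-layer gas-side mass-transfer coefficient, cm/h."""
    D_air = P.D_AIR_PREF * MW ** P.D_AIR_EXP  # cm^2/s
    Re = P.WIND_SPEED * P.L_CHAR / P.NU_AIR
    Sc = P.NU_AIR / D_air
    Sh = 0.664 * math.sqrt(Re) * Sc ** (1.0 / 3.0)
    return Sh * D_air / P.L_CHAR * 3600.0  # cm/s -> cm/h


def saturated_air_concentration(MW: float, p_vap_mmHg: float) -> float:
    """Saturated vapor concentration in air at 32 C, ug/cm^3."""
    p_atm = p_vap_mmHg / 760.0
    c_mol = p_atm / (P.R_GAS_ATM * P.T_SKIN_K)  # mol/cm^3
    return c_mol * MW * 1e6  # g -> ug


def evaporation_coefficient(rec: ChemicalRecord,
                            p_vap_mmHg: float,
                            f_neutral: float,
                            s_surface: float) -> float:
    """Surface mass-transfer coefficient ``k_evap`` (cm/h).

    Acts on the water-referenced surface concentration: evaporative flux =
    k_evap * psi_surface.  Built from boundary-layer theory (wind 0.17 m/s,
    32 C) with Raoult-type vapor-liquid equilibrium; only the neutral
    species is volatile.
    """
    if p_vap_mmHg == 0.0:
        return 0.0
    k_g = gas_phase_mass_transfer_coefficient(rec.MW)
    c_sat = saturated_air_concentration(rec.MW, p_vap_mmHg)
    return k_g * c_sat * f_neutral / s_surface


def derive_transport_parameters(rec: ChemicalRecord,
                                hydration: Hydration = "partially_hydrated",
                                vapor_pressure_mmHg: Optional[float] = None,
                                ) -> TransportParameters:
    """Derive the complete transport parameter set for one chemical.

    Parameters
    ----------
    rec : ChemicalRecord
    hydration : hydration state of the lipid pathway SC.  Full hydration
        increases lipid-phase diffusivity (factor ``HYDRATION_D_FACTOR``),
        which more than compensates the swollen thickness.
    vapor_pressure_mmHg : effective vapor pressure; defaults to the 32 C
        value from the record.  Pass 0 for an occluded scenario.
    """
    if hydration not in ("partially_hydrated", "fully_hydrated"):
        raise ValueError(f"unknown hydration state: {hydration!r}")
    if rec.MW is None or rec.logKow is None:
        raise ValueError("MW and logKow are required")
    if vapor_pressure_mmHg is None:
        vapor_pressure_mmHg = (vapor_pressure_at_skin_temp(rec)
                               if rec.P_vap_pred_32 is not None else 0.0)
    if vapor_pressure_mmHg < 0:
        raise ValueError("vapor pressure must be >= 0")

    f_neutral = fraction_neutral(rec.pKa, P.SURFACE_PH)
    kow = 10.0 ** rec.logKow

    # SC lipid pathway: only the neutral species partitions into lipids.
    K_sc = max(f_neutral, 1e-12) * kow ** P.KOW_EXP
    D_sc = P.D0_SC_LIPID * 10.0 ** (-P.B_MW * rec.MW)
    if hydration == "fully_hydrated":
        D_sc *= P.HYDRATION_D_FACTOR

    # Polar pathway: free aqueous diffusion, hindered, small area fraction.
    D_free = P.D_AQ_PREF * rec.MW ** (-1.0 / 3.0)
    D_polar = P.POLAR_HINDRANCE * D_free

    # Viable tissue: water + binding; unbound-driven partitioning.
    fu_p = max(rec.fu_plasma, 1e-6)
    fu_t = 1.0 / (1.0 + P.TISSUE_BINDING_RATIO * (1.0 - fu_p) / fu_p)
    K_tissue = P.TISSUE_WATER_FRACTION / fu_t
    D_tissue = P.TISSUE_DIFF_FACTOR * D_free

    s_surf = surface_solubility(rec)
    k_evap = evaporation_coefficient(rec, vapor_pressure_mmHg,
                                     f_neutral, s_surf)

    return TransportParameters(
        K_sc_lipid_w=K_sc,
        D_sc_lipid=D_sc,
        K_polar_w=1.0,
        D_polar=D_polar,
        f_polar_area=P.F_POLAR_AREA,
        K_ve_w=K_tissue,
        K_de_w=K_tissue,
        D_ve=D_tissue,
        D_de=D_tissue,
        k_evap=k_evap,
        fu_tissue=fu_t,
        fraction_neutral=f_neutral,
        surface_solubility=s_surf,
    )


def sc_lipid_permeability(rec: ChemicalRecord,
                          hydration: Hydration = "partially_hydrated") -> float:
    """Thickness-normalized SC lipid permeability K*D/L, cm/h."""
    tp = derive_transport_parameters(rec, hydration, vapor_pressure_mmHg=0.0)
    L = P.L_SC_FULL if hydration == "fully_hydrated" else P.L_SC_PARTIAL
    return tp.K_sc_lipid_w * tp.D_sc_lipid / L


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _record_to_row(rec: ChemicalRecord) -> dict:
    pka_val = rec.pKa[0][0] if rec.pKa else ""
    pka_type = rec.pKa[0][1] if rec.pKa else ""
    return {
        "name": rec.name, "MW": rec.MW, "logKow": rec.logKow,
        "pKa": pka_val, "pKa_type": pka_type, "fu_plasma": rec.fu_plasma,
        "Pvap_meas_25": _blank(rec.P_vap_meas_25),
        "Pvap_pred_25": _blank(rec.P_vap_pred_25),
        "Pvap_pred_32": _blank(rec.P_vap_pred_32),
        "solubility": _blank(rec.solubility_water),
        "density": _blank(rec.density),
    }


def _blank(v):
    return "" if v is None else v


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _row_to_record(row: dict) -> ChemicalRecord:
    pka = ()
    if row.get("pKa") not in (None, ""):
        pka = ((float(row["pKa"]), row["pKa_type"]),)
    return ChemicalRecord(
        name=row["name"],
        MW=float(row["MW"]),
        logKow=float(row["logKow"]),
        fu_plasma=float(row["fu_plasma"]),
        pKa=pka,
        P_vap_meas_25=_opt_float(row.get("Pvap_meas_25")),
        P_vap_pred_25=_opt_float(row.get("Pvap_pred_25")),
        P_vap_pred_32=_opt_float(row.get("Pvap_pred_32")),
        solubility_water=_opt_float(row.get("solubility")),
        density=_opt_float(row.get("density")),
    )


def read_chemicals_csv(path) -> list[ChemicalRecord]:
    with open(path, newline="") as fh:
        return [_row_to_record(row) for row in csv.DictReader(fh)]


def write_chemicals_csv(records: Sequence[ChemicalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        w.writeheader()
        for rec in records:
            w.writerow(_record_to_row(rec))


def read_chemicals_json(path) -> list[ChemicalRecord]:
    rows = json.loads(Path(path).read_text())
    return [_row_to_record(row) for row in rows]


def write_chemicals_json(records: Sequence[ChemicalRecord], path) -> None:
    rows = [_record_to_row(rec) for rec in records]
    Path(path).write_text(json.dumps(rows, indent=2))


def table1_chemicals() -> list[ChemicalRecord]:
    """The nine reference chemicals shipped with the package."""
    path = Path(__file__).parent / "fixtures" / "chemicals_table1.csv"
    return read_chemicals_csv(path)
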