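"""Central parameter tables for the skin penetration and PBPK models.

Every empirical constant used by the package lives here, so that the whole
parameterization can be inspected or swapped without touching solver code.
Units are stated next to each constant.  Lengths are cm, times are hours,
amounts are micrograms, concentrations are ug/cm^3 (== mg/L) unless noted.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Skin geometry
# ---------------------------------------------------------------------------
# Stratum corneum thickness depends on its hydration state: dry/partially
# hydrated SC is ~13 um thick and swells to ~25 um when fully hydrated
# (occlusion, large aqueous doses).  The simulation domain ends at a perfect
# sink 2 mm below the surface (taken as the bottom of the dermis, where
# permeant is cleared into the systemic circulation).
L_SC_PARTIAL = 13e-4  # cm
L_SC_FULL = 25e-4  # cm
L_VE = 100e-4  # cm, viable epidermis
TOTAL_DEPTH = 0.2  # cm, depth of the sink boundary (2 mm)

# Default spatial resolution (cells per layer, method of lines)
N_SC = 20
N_VE = 10
N_DE = 20

# ---------------------------------------------------------------------------
# Stratum corneum lipid pathway
# ---------------------------------------------------------------------------
# Partitioning of the neutral species from water into SC lipids follows the
# classical octanol-based power law K = Kow^KOW_EXP.  Diffusivity in the
# lipid phase decreases log-linearly with molecular weight,
# D = D0 * 10^(-B_MW * MW).  The prefactor is a conservative in-vivo default
# chosen so that the nine reference chemicals reproduce the finite/infinite
# kinetics classes of their original study designs (see docs/methods.md).
KOW_EXP = 0.69  # dimensionless
D0_SC_LIPID = 2.5e-7  # cm^2/h at MW -> 0, partially hydrated SC
B_MW = 0.0061  # 1/(g/mol)
# Full hydration swells the SC and fluidizes the lipid phase; diffusivity is
# scaled up by this factor (net permeability increase ~1.6x once the larger
# thickness is accounted for).
HYDRATION_D_FACTOR = 3.0

# ---------------------------------------------------------------------------
# Polar (aqueous pore) pathway
# ---------------------------------------------------------------------------
# A parallel water-filled pathway through the SC carries hydrophilic and
# ionized permeant.  It occupies a small fraction of the skin surface and
# hinders free aqueous diffusion; below the SC it opens into the full-area
# viable tissue.  The polar pathway is always fully hydrated.
F_POLAR_AREA = 1e-5  # area fraction of the skin surface
POLAR_HINDRANCE = 0.05  # D_pore / D_free

# Free aqueous diffusivity (Stokes-Einstein-type MW correlation, 32 C):
# D_free = D_AQ_PREF * MW^(-1/3)  [cm^2/h]
D_AQ_PREF = 0.116  # cm^2/h (g/mol)^(1/3)

# ---------------------------------------------------------------------------
# Viable epidermis / dermis
# ---------------------------------------------------------------------------
# Viable tissue is treated as water + binding protein: diffusivity is free
# aqueous diffusion reduced by tortuosity/volume exclusion, and the
# tissue/water partition coefficient follows from the unbound fraction.
TISSUE_DIFF_FACTOR = 0.3  # D_tissue / D_free
TISSUE_WATER_FRACTION = 0.68  # volume fraction of water in viable tissue
# Tissue binding-site density relative to plasma (used to derive fu_tissue
# from fu_plasma): fu_t = 1 / (1 + TISSUE_BINDING_RATIO*(1-fu_p)/fu_p)
TISSUE_BINDING_RATIO = 0.5

# Skin surface pH governing ionization in the vehicle and at the SC surface
SURFACE_PH = 5.5

# ---------------------------------------------------------------------------
# Evaporation / environment
# ---------------------------------------------------------------------------
# Fixed simulation environment: skin surface at 32 C with a 0.17 m/s ambient
# air flow.  The gas-side mass transfer coefficient comes from laminar
# flat-plate boundary-layer theory, Sh = 0.664 Re^1/2 Sc^1/3.
T_SKIN_K = 305.15  # K (32 C)
WIND_SPEED = 17.0  # cm/s (0.17 m/s)
L_CHAR = 10.0  # cm, characteristic length of the exposed site
NU_AIR = 0.159  # cm^2/s, kinematic viscosity of air at ~32 C
R_GAS_ATM = 82.057  # cm^3 atm / (mol K)
# Gas diffusivity correlation D_air = D_AIR_PREF * MW^D_AIR_EXP [cm^2/s]
D_AIR_PREF = 2.35
D_AIR_EXP = -0.73

# Aqueous-solvent dose above which the lipid pathway is treated as fully
# hydrated even without occlusion (mg of vehicle per cm^2 of skin).
FULL_HYDRATION_SOLVENT_LOAD = 100.0  # mg/cm^2

# ---------------------------------------------------------------------------
# Infinite-dose convention
# ---------------------------------------------------------------------------
INFINITE_DOSE = 1e7  # ug/cm^2, single application treated as inexhaustible
VEHICLE_DEPLETION_LIMIT = 0.01  # max fractional depletion for a valid
# infinite-dose reference
INFINITE_EQUIVALENCE_TOL = 0.04  # relative flux difference classifying a
# finite-dose run as infinite-equivalent

# ---------------------------------------------------------------------------
# Interspecies dose scaling (body-weight / body-surface-area factors)
# ---------------------------------------------------------------------------
# K_m = BW / BSA per species; the human value corresponds to a 60 kg adult
# with 1.6 m^2 body surface area.
KM_FACTORS = {
    "human": 37.0,
    "rat": 6.0,
    "mouse": 3.0,
    "rabbit": 12.0,
}
BW_HUMAN = 60.0  # kg
BSA_HUMAN = 1.6  # m^2

# ---------------------------------------------------------------------------
# PBPK physiology (reference adult, per kg body weight)
# ---------------------------------------------------------------------------
# 15 perfusion-limited tissue compartments linked by venous and arterial
# blood; the lung carries total cardiac output in series between the venous
# and arterial pools.  Gut and spleen drain into the liver inlet (portal
# flow).  Hepatic blood flow (arterial + portal) totals 1.5 L/h/kg so that a
# hepatic extraction ratio of 0.1 corresponds to a clearance of
# 0.15 L/h/kg BW.
PBPK_VOLUMES = {  # L / kg BW
    "adipose": 0.20,
    "bone": 0.14,
    "brain": 0.020,
    "gut": 0.017,
    "heart": 0.005,
    "kidney": 0.004,
    "liver": 0.026,
    "lung": 0.008,
    "muscle": 0.40,
    "pancreas": 0.001,
    "prostate": 0.0003,
    "skin": 0.037,
    "spleen": 0.002,
    "testes": 0.0005,
    "thymus": 0.0003,
    "venous": 0.045,
    "arterial": 0.022,
}

PBPK_FLOWS = {  # L / h / kg BW (tissue perfusion; lung = cardiac output)
    "adipose": 0.25,
    "bone": 0.25,
    "brain": 0.60,
    "gut": 1.00,
    "heart": 0.20,
    "kidney": 0.85,
    "liver_arterial": 0.35,
    "muscle": 0.85,
    "pancreas": 0.05,
    "prostate": 0.01,
    "skin": 0.25,
    "spleen": 0.15,
    "testes": 0.01,
    "thymus": 0.01,
}

PORTAL_TISSUES = ("gut", "spleen")  # outflow routed through the liver

HEPATIC_EXTRACTION_RATIO = 0.1  # dimensionless; CL = ER * Q_hepatic_total

# Tissue composition for partition-coefficient estimation
# (volume fractions of water, neutral lipid, phospholipid)
TISSUE_COMPOSITION = {
    "adipose": (0.18, 0.790, 0.0020),
    "bone": (0.43, 0.074, 0.0011),
    "brain": (0.77, 0.051, 0.0565),
    "gut": (0.77, 0.049, 0.0163),
    "heart": (0.76, 0.014, 0.0111),
    "kidney": (0.79, 0.021, 0.0162),
    "liver": (0.75, 0.035, 0.0252),
    "lung": (0.81, 0.003, 0.0090),
    "muscle": (0.76, 0.024, 0.0072),
    "pancreas": (0.66, 0.041, 0.0093),
    "prostate": (0.80, 0.009, 0.0044),
    "skin": (0.72, 0.028, 0.0111),
    "spleen": (0.78, 0.021, 0.0136),
    "testes": (0.80, 0.009, 0.0044),
    "thymus": (0.79, 0.017, 0.0092),
}
PLASMA_COMPOSITION = (0.96, 0.0035, 0.0023)
BLOOD_PH = 7.4

# Default dosing interval
TAU_DEFAULT = 24.0  # h
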