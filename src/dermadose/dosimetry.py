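"""Dose scaling and steady-state flux aggregation.

Covers the arithmetic that brackets the skin simulation: animal-to-human
dose conversion by body-surface-area scaling (K_m = BW/BSA factors), the
expression of human dermal doses per unit application area, time-averaged
steady-state fluxes and cumulative amounts over dosing intervals, the
finite/infinite kinetics classification, and the conversion of a dermally
cleared flux into a systemic input dose for the PBPK model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import parameters as P
from .skinsim import FluxSeries


@dataclass(frozen=True)
class SpeciesScaling:
    """Body-weight / body-surface-area scaling factors for one species pair."""

    K_m_animal: float
    K_m_human: float = P.KM_FACTORS["human"]
    BSA_animal: Optional[float] = None
    BSA_human: float = P.BSA_HUMAN
    BW_human: float = P.BW_HUMAN

    def __post_init__(self):
        for v in (self.K_m_animal, self.K_m_human, self.BSA_human,
                  self.BW_human):
            if v <= 0:
                raise ValueError("scaling factors must be positive")
        # the human K_m should be consistent with BW/BSA within 10%
        km_implied = self.BW_human / self.BSA_human
        if abs(km_implied - self.K_m_human) / self.K_m_human > 0.10:
            raise ValueError(
                f"K_m_human={self.K_m_human} inconsistent with "
                f"BW/BSA={km_implied:.2f}")

    @classmethod
    def for_species(cls, species: str) -> "SpeciesScaling":
        try:
            km = P.KM_FACTORS[species]
        except KeyError:
            raise ValueError(f"unknown species: {species!r}") from None
        return cls(K_m_animal=km)


@dataclass
class DosimetryResult:
    """Aggregated dermal dosimetry for one scenario."""

    J_ss_ave: float  # ug/(cm^2 h), average steady-state total flux
    Q_ss_ave: float  # ug/cm^2, cleared over the final dosing interval
    kinetics: str  # "finite" | "infinite"
    systemic_dose: float  # mg/kg/day, PBPK input
    human_dose_per_area: float  # ug/cm^2/day
    n_window: int
    tau: float
    relative_difference: Optional[float] = None  # vs. infinite-dose flux
    mass_balance_error: Optional[float] = None


def animal_dose_per_kg(dose_per_animal_mg: float, BW_animal_kg: float) -> float:
    """Per-animal dose (mg) to mg/kg/day."""
    if BW_animal_kg <= 0:
        raise ValueError("animal body weight must be positive")
    return dose_per_animal_mg / BW_animal_kg


def human_equivalent_dose(animal_dose: float,
                          scaling: SpeciesScaling) -> float:
    """HED (mg/kg/day) by the K_m ratio: HED = dose * K_m_a / K_m_h."""
    return animal_dose * scaling.K_m_animal / scaling.K_m_human


def human_dose_per_area(HED_mg_kg_day: float, BW_human_kg: float,
                        A_human_cm2: float) -> float:
    """Human dermal dose per unit area, ug/cm^2/day."""
    if A_human_cm2 <= 0:
        raise ValueError("application area must be positive")
    return HED_mg_kg_day * BW_human_kg * 1000.0 / A_human_cm2


def total_flux(J_lipid: np.ndarray, J_polar: np.ndarray) -> np.ndarray:
    """Total systemically cleared flux: lipid + polar contributions."""
    J_lipid = np.asarray(J_lipid)
    J_polar = np.asarray(J_polar)
    if J_lipid.shape != J_polar.shape:
        raise ValueError("pathway series are on different grids")
    return J_lipid + J_polar


def total_cumulative(Q_lipid: np.ndarray, Q_polar: np.ndarray) -> np.ndarray:
    """Total cleared amount: lipid + polar contributions."""
    Q_lipid = np.asarray(Q_lipid)
    Q_polar = np.asarray(Q_polar)
    if Q_lipid.shape != Q_polar.shape:
        raise ValueError("pathway series are on different grids")
    return Q_lipid + Q_polar


def _window_average(t: np.ndarray, J: np.ndarray,
                    t_lo: float, t_hi: float) -> float:
    """Trapezoidal time-average of J over [t_lo, t_hi]."""
    if t_lo < t[0] - 1e-9 or t_hi > t[-1] + 1e-9:
        raise ValueError("averaging window lies beyond the series")
    grid = np.unique(np.clip(
        np.concatenate([[t_lo], t[(t > t_lo) & (t < t_hi)], [t_hi]]),
        t_lo, t_hi))
    Jg = np.interp(grid, t, J)
    return float(np.trapezoid(Jg, grid) / (t_hi - t_lo))


def average_ss_flux(series: FluxSeries, tau: float = P.TAU_DEFAULT,
                    n: Optional[int] = None) -> Tuple[float, int]:
    """Average steady-state total flux over the window [n*tau, (n+1)*tau].

    When ``n`` is not given, the last complete dosing interval is used,
    capped at n = 10 (by which point the repeated-dose profiles have become
    periodic; the cap matches the n = 7-10 convention for multi-week
    protocols).  Returns (flux, n).
    """
    t, J = series.t, series.J_total
    n_max = int(np.floor(t[-1] / tau + 1e-9)) - 1
    if n_max < 0:
        raise ValueError("series shorter than one dosing interval")
    if n is None:
        n = min(n_max, 10)
    if (n + 1) * tau > t[-1] + 1e-6:
        raise ValueError(f"window n={n} extends beyond the series")
    return _window_average(t, J, n * tau, (n + 1) * tau), n


def average_ss_cumulative(series: FluxSeries,
                          tau: float = P.TAU_DEFAULT) -> float:
    """Amount cleared over the final dosing interval, ug/cm^2."""
    t = series.t
    if t[-1] < tau - 1e-9:
        raise ValueError("series shorter than one dosing interval")
    Q = series.Q_total
    Q_end = Q[-1]
    Q_start = float(np.interp(t[-1] - tau, t, Q))
    return Q_end - Q_start


class InvalidInfiniteReference(ValueError):
    pass


def classify_kinetics(finite_series: FluxSeries,
                      infinite_series: FluxSeries,
                      tau: float = P.TAU_DEFAULT) -> Tuple[str, float]:
    """Classify a finite-dose run against its infinite-dose reference.

    The reference must show vehicle depletion <= 1% of the applied dose over
    the run, otherwise it is rejected (a larger applied dose is needed).
    The finite run is "infinite"-equivalent when its average steady-state
    flux is within 4% of the infinite-dose value.  Returns
    (classification, relative difference).
    """
    depletion = infinite_series.vehicle_depletion_fraction()
    if depletion > P.VEHICLE_DEPLETION_LIMIT:
        raise InvalidInfiniteReference(
            f"infinite-dose reference depleted by {depletion:.2%} "
            f"(> {P.VEHICLE_DEPLETION_LIMIT:.0%}); increase the applied dose")
    J_fin, _ = average_ss_flux(finite_series, tau)
    J_inf, _ = average_ss_flux(infinite_series, tau)
    if J_inf <= 0:
        return ("infinite" if J_fin <= 0 else "finite",
                0.0 if J_fin <= 0 else np.inf)
    rel = abs(J_fin - J_inf) / J_inf
    kinetics = "infinite" if rel <= P.INFINITE_EQUIVALENCE_TOL else "finite"
    return kinetics, rel


def flux_to_systemic_dose(J_ss_ave: float, A_human_cm2: float,
                          BW_human_kg: float = P.BW_HUMAN) -> float:
    """Average dermal flux to a constant systemic input dose, mg/kg/day."""
    if A_human_cm2 <= 0 or BW_human_kg <= 0:
        raise ValueError("area and body weight must be positive")
    return J_ss_ave * A_human_cm2 * 24.0 / (1000.0 * BW_human_kg)
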