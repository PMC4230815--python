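"""Skin penetration simulator: condition rules, oracles, conservation."""

import numpy as np
import pytest

import dermadose as dd
from dermadose import parameters as P
from dermadose.chemprops import TransportParameters
from dermadose.skinsim import ExposureScenario, apply_condition_rules


def _probe(**kw):
    base = dict(name="probe", MW=100.0, logKow=1.0, fu_plasma=1.0,
                P_vap_pred_32=0.0, solubility_water=1.0, density=1.0)
    base.update(kw)
    return dd.ChemicalRecord(**base)


def _scenario(rec, **kw):
    base = dict(chemical=rec, dose_per_area=100.0, area=100.0)
    base.update(kw)
    return ExposureScenario(**base)


# ---------------------------------------------------------------------------
# Condition rules (occlusion / vehicle / hydration)
# ---------------------------------------------------------------------------

class TestConditionRules:
    def test_occlusion_zeroes_vapor_pressure_and_hydrates(self):
        rec = _probe(P_vap_pred_32=5.0)
        rules = apply_condition_rules(_scenario(rec, occluded=True))
        assert rules.effective_vapor_pressure == 0.0
        assert rules.lipid_hydration == "fully_hydrated"

    def test_open_neat_is_partially_hydrated(self):
        rec = _probe(P_vap_pred_32=5.0)
        rules = apply_condition_rules(_scenario(rec, occluded=False))
        assert rules.effective_vapor_pressure == pytest.approx(5.0)
        assert rules.lipid_hydration == "partially_hydrated"
        assert rules.polar_hydration == "fully_hydrated"

    def test_large_aqueous_dose_fully_hydrates(self):
        rec = _probe()
        # 150 mg/cm^2 of water vehicle -> fully hydrated lipid pathway
        rules = apply_condition_rules(
            _scenario(rec, water_volume_per_area=0.150))
        assert rules.lipid_hydration == "fully_hydrated"

    def test_small_aqueous_dose_stays_partially_hydrated(self):
        rules = apply_condition_rules(
            _scenario(_probe(), water_volume_per_area=0.010))
        assert rules.lipid_hydration == "partially_hydrated"


class TestScenarioValidation:
    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            _scenario(_probe(), dose_per_area=-1.0)

    def test_removal_must_precede_next_application(self):
        with pytest.raises(ValueError):
            _scenario(_probe(), removal_after=30.0, tau=24.0)

    def test_duration_must_cover_applications(self):
        with pytest.raises(ValueError):
            _scenario(_probe(), n_applications=3, duration=24.0)


class TestInfiniteDoseScenario:
    def test_single_high_dose_without_removal(self):
        base = _scenario(_probe(), n_applications=5, removal_after=4.0,
                         duration=120.0)
        inf = dd.make_infinite_dose_scenario(base)
        assert inf.dose_per_area == P.INFINITE_DOSE
        assert inf.n_applications == 1
        assert inf.removal_after is None
        assert inf.duration == base.duration

    def test_idempotent(self):
        base = _scenario(_probe(), water_volume_per_area=0.01)
        once = dd.make_infinite_dose_scenario(base)
        twice = dd.make_infinite_dose_scenario(once)
        assert once == twice

    def test_preserves_vehicle_composition(self):
        base = _scenario(_probe(), dose_per_area=1000.0,
                         water_volume_per_area=0.009)
        inf = dd.make_infinite_dose_scenario(base)
        ratio_base = base.water_volume_per_area / (base.dose_per_area / 1e6)
        ratio_inf = inf.water_volume_per_area / (inf.dose_per_area / 1e6)
        assert ratio_inf == pytest.approx(ratio_base)


# ---------------------------------------------------------------------------
# Simulation oracles
# ---------------------------------------------------------------------------

def _membrane_params(K, D):
    """Degenerate configuration: SC lipid is the only resistance."""
    return TransportParameters(
        K_sc_lipid_w=K, D_sc_lipid=D, K_polar_w=1.0, D_polar=1e-12,
        f_polar_area=1e-12, K_ve_w=1.0, K_de_w=1.0, D_ve=1e3, D_de=1e3,
        k_evap=0.0, fu_tissue=1.0, fraction_neutral=1.0,
        surface_solubility=1000.0)


class TestMembraneOracle:
    """Closed-form single-membrane diffusion with constant surface conc."""

    def test_transient_matches_lag_time_series_solution(self):
        K, D, Cv = 2.0, 1e-5, 1000.0
        rec = _probe()
        sc = ExposureScenario(chemical=rec, dose_per_area=P.INFINITE_DOSE,
                              area=1.0, occluded=True, n_applications=1,
                              duration=48.0)
        L = P.L_SC_FULL
        series = dd.simulate(sc, transport_override=_membrane_params(K, D),
                             n_sc=80, n_ve=4, n_de=4,
                             points_per_interval=200)

        def analytic(t):
            s = np.ones_like(t)
            for n in range(1, 200):
                s += 2 * (-1) ** n * np.exp(-n * n * np.pi ** 2 * D * t
                                            / L ** 2)
            return K * D * Cv / L * s

        J_ss = K * D * Cv / L
        t_lag = L ** 2 / (6 * D)
        mask = series.t > 0.3 * t_lag
        rel = np.abs(series.J_lipid[mask] - analytic(series.t[mask])) / J_ss
        assert rel.max() < 0.01
        assert series.J_lipid[-1] == pytest.approx(J_ss, rel=0.01)

    def test_cumulative_matches_lag_time_asymptote(self):
        """Late-time Q(t) -> (KDC/L) (t - L^2/6D)."""
        K, D, Cv = 1.0, 2e-5, 1000.0
        rec = _probe()
        sc = ExposureScenario(chemical=rec, dose_per_area=P.INFINITE_DOSE,
                              area=1.0, occluded=True, n_applications=1,
                              duration=24.0)
        series = dd.simulate(sc, transport_override=_membrane_params(K, D),
                             n_sc=80, n_ve=4, n_de=4)
        L = P.L_SC_FULL
        J_ss = K * D * Cv / L
        t_lag = L ** 2 / (6 * D)
        expected = J_ss * (series.t[-1] - t_lag)
        assert series.Q_lipid[-1] == pytest.approx(expected, rel=0.01)


class TestConservation:
    def test_zero_dose_yields_zero_everything(self):
        series = dd.simulate(_scenario(_probe(), dose_per_area=0.0,
                                       n_applications=2, duration=48.0))
        assert np.all(series.J_total == 0.0)
        assert np.all(series.Q_total == 0.0)
        assert series.mass_balance_error() < 1e-12

    def test_mass_ledger_closes_with_events_and_evaporation(self):
        # vapor pressure low enough that part of the dose survives to the
        # daily wipe, so evaporation, removal and clearance all appear
        rec = _probe(P_vap_pred_32=0.01, solubility_water=None)
        sc = _scenario(rec, dose_per_area=5000.0, n_applications=4,
                       removal_after=6.0, duration=96.0)
        series = dd.simulate(sc)
        assert series.mass_balance_error() < 5e-3
        assert series.evaporated[-1] > 0.0
        assert series.removed[-1] > 0.0

    def test_cleared_amounts_are_nondecreasing(self):
        sc = _scenario(_probe(), n_applications=3, duration=72.0,
                       removal_after=4.0)
        series = dd.simulate(sc)
        assert np.all(np.diff(series.Q_lipid) >= -1e-12)
        assert np.all(np.diff(series.Q_polar) >= -1e-12)

    def test_flux_is_derivative_of_cumulative(self):
        """dQ/dt == J along the series (quadrature identity)."""
        sc = _scenario(_probe(), dose_per_area=P.INFINITE_DOSE,
                       n_applications=1, duration=48.0, occluded=True)
        series = dd.simulate(sc)
        t, J, Q = series.t, series.J_total, series.Q_total
        # compare increments over the post-transient half of the run, where
        # the output grid resolves J well
        i0 = np.searchsorted(t, 24.0)
        dQ = Q[-1] - Q[i0]
        dQ_trap = np.trapezoid(J[i0:], t[i0:])
        assert dQ_trap == pytest.approx(dQ, rel=0.01)

    def test_grid_convergence_under_refinement(self):
        sc = _scenario(_probe(logKow=2.0), dose_per_area=1000.0,
                       n_applications=3, duration=72.0)
        coarse = dd.simulate(sc, n_sc=20, n_ve=10, n_de=20)
        fine = dd.simulate(sc, n_sc=40, n_ve=20, n_de=40)
        assert fine.Q_total[-1] == pytest.approx(coarse.Q_total[-1],
                                                 rel=0.01)


class TestScenarioOrdering:
    def test_flux_monotone_in_dose(self):
        """Average steady-state flux is non-decreasing in applied dose."""
        rec = _probe(solubility_water=None)
        fluxes = []
        for dose in (200.0, 1000.0, 5000.0):
            sc = _scenario(rec, dose_per_area=dose, n_applications=4,
                           duration=96.0, removal_after=3.0)
            series = dd.simulate(sc)
            J, _ = dd.average_ss_flux(series, n=3)
            fluxes.append(J)
        assert fluxes[0] <= fluxes[1] * (1 + 1e-9)
        assert fluxes[1] <= fluxes[2] * (1 + 1e-9)

    def test_removal_reduces_flux(self):
        rec = _probe()
        with_removal = _scenario(rec, dose_per_area=500.0, n_applications=4,
                                 duration=96.0, removal_after=3.0)
        without = _scenario(rec, dose_per_area=500.0, n_applications=4,
                            duration=96.0)
        J_a, _ = dd.average_ss_flux(dd.simulate(with_removal), n=3)
        J_b, _ = dd.average_ss_flux(dd.simulate(without), n=3)
        assert J_a <= J_b * (1 + 1e-9)

    def test_occlusion_beats_open_for_volatile_chemical(self):
        rec = _probe(P_vap_pred_32=2.0, solubility_water=None)
        base = dict(dose_per_area=1000.0, n_applications=3, duration=72.0)
        J_occ, _ = dd.average_ss_flux(
            dd.simulate(_scenario(rec, occluded=True, **base)), n=2)
        J_open, _ = dd.average_ss_flux(
            dd.simulate(_scenario(rec, occluded=False, **base)), n=2)
        assert J_occ >= J_open
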