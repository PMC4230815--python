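"""Study designs, scenario matrix construction, end-to-end workflow."""

import json

import pytest
from click.testing import CliRunner

import dermadose as dd
from dermadose import cli
from dermadose.scenarios import VARIANTS, scenario_for_dose


class TestStudyFixtures:
    def test_nine_designs_load(self, studies):
        assert len(studies) == 9

    def test_dose_chains_reproduce_published_values(self, studies):
        assert studies["CAP"].dose_per_area(0) == pytest.approx(389.19,
                                                                abs=0.01)
        assert studies["CAP"].dose_per_area(2) == pytest.approx(389.19,
                                                                abs=0.01)
        assert studies["DGMBE"].dose_per_area(0) == pytest.approx(912.16,
                                                                  rel=1e-3)
        assert studies["DMF"].dose_per_area(0) == pytest.approx(20270.27,
                                                               rel=1e-3)

    def test_semi_occluded_maps_to_occluded(self, studies):
        assert studies["DMF"].occluded
        assert studies["MPA"].occluded
        assert not studies["BR"].occluded

    def test_unsorted_doses_rejected(self, studies):
        d = studies["BR"]
        with pytest.raises(ValueError):
            dd.StudyDesign(chemical=d.chemical, species="rat",
                           animal_doses=[400, 50], noael=[False, False],
                           human_areas=[100.0, 100.0], exposure_days=5,
                           removal_after=None, occlusion="unoccluded")


class TestBuildMatrix:
    def test_full_variant_set_emitted(self, studies):
        matrix = dd.build_matrix(studies["CAP"])
        assert set(matrix) == set(VARIANTS)
        assert all(len(v) == 3 for v in matrix.values())

    def test_scenario_b_equals_a_without_removal_step(self, studies):
        # BR has no removal: A and B coincide
        m = dd.build_matrix(studies["BR"])
        assert m["A"] == m["B"]
        # CAP wipes the site 3 h after each application
        m = dd.build_matrix(studies["CAP"])
        assert m["A"][0].removal_after == 3.0
        assert m["B"][0].removal_after is None

    def test_water_dilutions_preserve_permeant_load(self, studies):
        d = studies["DMF"]
        a = scenario_for_dose(d, 0, "A")
        w50 = scenario_for_dose(d, 0, "A_water50")
        w90 = scenario_for_dose(d, 0, "A_water90")
        assert w50.dose_per_area == a.dose_per_area
        assert w90.dose_per_area == a.dose_per_area
        rho = d.chemical.density_or_default * 1e6
        assert w50.water_volume_per_area == \
            pytest.approx(a.dose_per_area / rho)
        assert w90.water_volume_per_area == \
            pytest.approx(9 * a.dose_per_area / rho)

    def test_occlusion_toggles(self, studies):
        d = studies["DGMME"]  # occluded study
        assert scenario_for_dose(d, 0, "A_occluded").occluded
        assert not scenario_for_dose(d, 0, "A_open").occluded
        assert scenario_for_dose(d, 0, "A").occluded

    def test_unknown_variant_rejected(self, studies):
        with pytest.raises(ValueError):
            scenario_for_dose(studies["BR"], 0, "A_frozen")


@pytest.fixture(scope="module")
def me2_result(studies, sim_cache):
    # 2-ME: single dose, 10-day protocol - the cheapest full design
    return dd.run_workflow(studies["2-ME"], _cache=sim_cache)


class TestWorkflow:
    def test_rows_cover_variants_and_doses(self, me2_result):
        assert len(me2_result.results) == len(VARIANTS)
        assert {r.variant for r in me2_result.results} == set(VARIANTS)

    def test_results_carry_mass_balance_and_kinetics(self, me2_result):
        for r in me2_result.results:
            assert r.dosimetry.mass_balance_error < 5e-3
            assert r.dosimetry.kinetics in ("finite", "infinite")

    def test_scenario_b_plasma_concentration_dominates_a(self, me2_result):
        a = me2_result.get("2-ME", "A", 0)
        b = me2_result.get("2-ME", "B", 0)
        assert b.C_p_ss >= a.C_p_ss * (1 - 1e-9)

    def test_cpss_consistent_with_linear_clearance(self, me2_result):
        r = me2_result.get("2-ME", "A", 0)
        expected = r.dosimetry.systemic_dose / (24 * 0.15)
        assert r.C_p_ss == pytest.approx(expected, rel=1e-6)

    def test_ecf_definitions(self, me2_result):
        r = me2_result.get("2-ME", "A", 0)
        assert r.ECF_per_area == pytest.approx(
            r.C_p_ss / r.dosimetry.human_dose_per_area)
        dose_kg = (r.dosimetry.human_dose_per_area * 620.9) / (1000 * 60.0)
        assert r.ECF_per_kg == pytest.approx(r.C_p_ss / dose_kg, rel=1e-6)

    def test_deterministic_end_to_end(self, studies, me2_result):
        again = dd.run_workflow(studies["2-ME"])
        df1 = me2_result.to_dataframe()
        df2 = again.to_dataframe()
        assert df1.equals(df2)

    def test_zero_dose_design_yields_zero_everywhere(self, studies):
        d = studies["2-ME"]
        zero = dd.StudyDesign(
            chemical=d.chemical, species=d.species, animal_doses=[0.0],
            noael=[False], human_areas=[620.9], exposure_days=3,
            removal_after=6.0, occlusion="occluded", vehicle={"type": "none"})
        res = dd.run_workflow(zero, variants=("A", "B"))
        for r in res.results:
            assert r.dosimetry.J_ss_ave == 0.0
            assert r.C_p_ss == 0.0


class TestSyntheticFixtures:
    def test_seed_determinism(self):
        assert dd.generate_fixtures(3) == dd.generate_fixtures(3)
        assert dd.generate_fixtures(3) != dd.generate_fixtures(4)

    def test_coverage_and_validity(self):
        recs = dd.generate_fixtures(11)
        assert any(r.P_vap_pred_32 == 0.0 for r in recs)
        assert any((r.P_vap_pred_32 or 0) > 0 for r in recs)
        for r in recs:  # construction already enforces the invariants
            assert r.MW > 0 and 0 <= r.fu_plasma <= 1
            tp = dd.derive_transport_parameters(r)
            assert tp.K_sc_lipid_w > 0 and tp.D_sc_lipid > 0


class TestCLI:
    def test_convert_dose_command(self):
        runner = CliRunner()
        out = runner.invoke(cli.main, ["convert-dose", "--dose", "64",
                                       "--species", "rat",
                                       "--area", "1600"])
        assert out.exit_code == 0
        payload = json.loads(out.output)
        assert payload["human_dose_ug_cm2_day"] == pytest.approx(389.19,
                                                                 abs=0.01)

    def test_pbpk_ss_command(self):
        runner = CliRunner()
        out = runner.invoke(cli.main, ["pbpk-ss", "--rate", "0.166"])
        assert out.exit_code == 0
        payload = json.loads(out.output)
        assert payload["C_p_ss_mg_L"] == pytest.approx(0.0461, abs=2e-4)

    def test_simulate_skin_command(self, tmp_path):
        cfg = tmp_path / "scenario.json"
        cfg.write_text(json.dumps({
            "chemical": "2-ME", "dose_per_area": 1000.0, "area": 620.9,
            "n_applications": 2, "occluded": True, "duration": 48.0,
        }))
        out_csv = tmp_path / "series.csv"
        runner = CliRunner()
        out = runner.invoke(cli.main, ["simulate-skin", "--config", str(cfg),
                                       "--out", str(out_csv)])
        assert out.exit_code == 0, out.output
        header = out_csv.read_text().splitlines()[0]
        assert header.startswith("t_h,J_lipid,J_polar,J_total")
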