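"""Model core: parameter validation, ODE right-hand sides, and the
linear-balance oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import minipbpk as mp
from minipbpk.model import (derivatives_parent_metabolite,
                            derivatives_single, system_matrix)

state_vals = st.floats(min_value=0.0, max_value=1e8, allow_nan=False)


def _pm_form(spec, form):
    return dataclasses.replace(spec, metabolite_trachea_form=form)


class TestParameterValidation:
    def test_inconsistent_rest_volume_rejected(self):
        with pytest.raises(mp.ParameterError, match="V_rest"):
            mp.PhysiologicalParameters(
                V_total=102.01, V_blood=7.2, V_lung=0.48, V_trachea=0.06,
                V_rest=90.0, Q_co=1181.28, Q_trachea=24.81,
                Q_rest=1156.47)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(mp.ParameterError, match="V_lung"):
            mp.PhysiologicalParameters.from_totals(
                V_total=102.01, V_blood=7.2, V_lung=-0.48, V_trachea=0.06,
                Q_co=1181.28, Q_trachea=24.81)

    def test_negative_partition_rejected(self):
        with pytest.raises(mp.ParameterError, match="K_lung"):
            mp.DispositionParameters(k_a=1, CL_F=1, K_lung=-1,
                                     K_trachea=1, K_rest=1, k_tl=0,
                                     k_lt=0)

    def test_zero_partition_with_flow_is_parameter_error(self, pnd_spec):
        bad = pnd_spec.with_parameters(K_trachea=0.0)
        with pytest.raises(mp.ParameterError, match="K_trachea"):
            system_matrix(bad)

    def test_metabolite_requires_molar_units(self, art_spec):
        with pytest.raises(mp.ConfigurationError, match="molar"):
            dataclasses.replace(art_spec, unit_mode="mass_ng")

    def test_metabolite_present_iff_parent_metabolite(self, pnd_spec):
        with pytest.raises(mp.ConfigurationError, match="metabolite"):
            dataclasses.replace(pnd_spec, kind="parent_metabolite")


class TestDerivatives:
    def test_zero_state_is_equilibrium(self, pnd_spec, art_spec):
        assert not derivatives_single(np.zeros(5), pnd_spec).any()
        assert not derivatives_parent_metabolite(np.zeros(9),
                                                 art_spec).any()

    def test_dose_in_depot_only_feeds_blood(self, pnd_spec):
        D = 1.8e7
        d = derivatives_single(np.array([D, 0, 0, 0, 0.0]), pnd_spec)
        assert d[0] == pytest.approx(-pnd_spec.parent.k_a * D)
        assert d[1] == pytest.approx(pnd_spec.parent.k_a * D)
        assert d[2] == d[3] == d[4] == 0.0

    @given(st.lists(state_vals, min_size=5, max_size=5))
    def test_single_total_change_is_blood_clearance(self, state):
        # total mass can only leave through blood clearance
        spec, _, _ = mp.load_config(mp.builtin_config_path("pyronaridine"))
        state = np.asarray(state)
        d = derivatives_single(state, spec)
        c_blood = state[1] / spec.phys.V_blood
        expected = -c_blood * spec.parent.CL_F * 1000.0
        # the near-zero K_rest produces O(1e7) opposing flux terms, so the
        # cancellation in the sum is limited by floating-point precision
        slack = 1e-12 * np.abs(d).max() + 1e-9
        assert abs(d.sum() - expected) <= max(slack, 1e-9 * abs(expected))

    @given(st.lists(state_vals, min_size=9, max_size=9))
    def test_parent_metabolite_mole_balance_mass_balanced_form(self, state):
        spec, _, _ = mp.load_config(mp.builtin_config_path("artesunate"))
        spec = _pm_form(spec, "mass_balanced")
        state = np.asarray(state)
        d = derivatives_parent_metabolite(state, spec)
        ph = spec.phys
        cb = state[1] / ph.V_blood
        cbm = state[5] / ph.V_blood
        cl = spec.parent.CL_F * 1000.0
        clm = spec.metabolite.CLm_F * 1000.0
        slack = 1e-12 * np.abs(d).max() + 1e-9
        assert abs(d[:5].sum() - (-cb * cl)) <= \
            max(slack, 1e-9 * abs(cb * cl))
        met_expected = cb * cl - cbm * clm
        assert abs(d[5:].sum() - met_expected) <= \
            max(slack, 1e-9 * abs(met_expected))

    @given(st.lists(state_vals, min_size=9, max_size=9))
    def test_printed_trachea_form_has_known_balance_residual(self, state):
        # the printed metabolite trachea equation returns drug to blood
        # through K_trachea_m but drains the trachea through K_lung_m, so
        # the metabolite total gains an extra Q_trachea*(C_t,m/K_t,m -
        # C_l,m/K_l,m) relative to the mass-balanced form
        spec, _, _ = mp.load_config(mp.builtin_config_path("artesunate"))
        state = np.asarray(state)
        d = derivatives_parent_metabolite(state, _pm_form(spec,
                                                          "as_printed"))
        ph, m = spec.phys, spec.metabolite
        cb = state[1] / ph.V_blood
        cbm = state[5] / ph.V_blood
        clm = state[6] / ph.V_lung
        ctm = state[7] / ph.V_trachea
        residual = ph.Q_trachea * (ctm / m.K_trachea_m
                                   - clm / m.K_lung_m)
        expected = (cb * spec.parent.CL_F * 1000.0
                    - cbm * m.CLm_F * 1000.0 + residual)
        slack = 1e-12 * np.abs(d).max() + 1e-9
        assert abs(d[5:].sum() - expected) <= \
            max(slack, 1e-9 * abs(expected))

    def test_conservation_without_clearance(self, pnd_spec):
        spec = pnd_spec.with_parameters(CL_F=0.0)
        regimen = mp.DoseRegimen(dose_per_kg=180.0, body_weight=0.10201,
                                 n_doses=1)
        res = mp.simulate_regimen(spec, regimen, t_end=240.0)
        total = sum(res.amounts[spec.parent_name].values())
        dose = mp.make_dose_schedule(regimen, spec.unit_mode)[0][1]
        assert np.allclose(total, dose, rtol=1e-6)

    def test_metabolite_captures_full_dose_without_its_own_clearance(
            self, art_spec):
        # with CLm/F = 0 every parent mole ends up as metabolite; exact
        # only for the mass-balanced trachea form (the printed form has a
        # small balance residual, asserted elsewhere)
        spec = _pm_form(art_spec.with_parameters(CLm_F=0.0),
                        "mass_balanced")
        regimen = mp.DoseRegimen(dose_per_kg=60.0, body_weight=0.10201,
                                 n_doses=1)
        res = mp.simulate_regimen(spec, regimen, t_end=200.0)
        dose = mp.make_dose_schedule(regimen, spec.unit_mode,
                                     spec.molar_mass)[0][1]
        met_total = sum(res.amounts[spec.metabolite_name].values())
        assert met_total[-1] == pytest.approx(dose, rel=1e-4)


class TestOracles:
    def test_pyronaridine_steady_state_ratios(self, pnd_spec):
        r_l, r_t = mp.steady_state_ratio_oracle(pnd_spec)
        # linear-balance solution; the study reports 25.83 and 12.41
        assert r_l == pytest.approx(25.8250, abs=2e-4)
        assert r_t == pytest.approx(12.3933, abs=2e-4)
        assert r_l == pytest.approx(25.83, rel=0.02)
        assert r_t == pytest.approx(12.41, rel=0.02)

    def test_decoupled_limit_returns_partition_coefficients(self,
                                                            pnd_spec):
        spec = pnd_spec.with_parameters(k_tl=0.0, k_lt=0.0)
        assert mp.steady_state_ratio_oracle(spec) == pytest.approx(
            (spec.parent.K_lung, spec.parent.K_trachea))
        assert mp.integrated_auc_ratio_oracle(spec, "parent") == \
            pytest.approx((spec.parent.K_lung, spec.parent.K_trachea))

    def test_metabolite_decoupled_limit(self, art_spec):
        spec = dataclasses.replace(
            art_spec.with_parameters(k_tl_m=0.0, k_lt_m=0.0),
            metabolite_trachea_form="mass_balanced")
        m = spec.metabolite
        assert mp.integrated_auc_ratio_oracle(spec, "metabolite") == \
            pytest.approx((m.K_lung_m, m.K_trachea_m))

    def test_artesunate_parent_auc_ratios(self, art_spec):
        # independent 2x2 solve of the flow balance gives these values
        # (the printed K_lung = 10.33 dominates; see docs/methods.md)
        r_l, r_t = mp.integrated_auc_ratio_oracle(art_spec, "parent")
        assert r_l == pytest.approx(10.3165, abs=1e-3)
        assert r_t == pytest.approx(1.5720, abs=1e-3)

    def test_dha_ratio_depends_on_trachea_form(self, art_spec):
        r_l, r_t = mp.integrated_auc_ratio_oracle(
            _pm_form(art_spec, "as_printed"), "metabolite")
        # printed form: lung+trachea balances sum to exactly K_lung_m
        assert r_l == pytest.approx(art_spec.metabolite.K_lung_m,
                                    rel=1e-12)
        assert r_t == pytest.approx(0.13639, abs=1e-4)
        r_l2, r_t2 = mp.integrated_auc_ratio_oracle(
            _pm_form(art_spec, "mass_balanced"), "metabolite")
        assert r_l2 == pytest.approx(0.3401, abs=1e-3)
        assert r_t2 == pytest.approx(1.0631, abs=1e-3)

    def test_oracle_matches_long_run_simulation(self, pnd_spec, pnd_14day):
        r_l, r_t = mp.steady_state_ratio_oracle(pnd_spec)
        t0, t1 = 13 * 24.0, 14 * 24.0
        avg = {m: mp.interval_average(pnd_14day, m, "parent", t0, t1)
               for m in ("blood", "lung", "trachea")}
        assert avg["lung"] / avg["blood"] == pytest.approx(r_l, rel=0.005)
        assert avg["trachea"] / avg["blood"] == pytest.approx(r_t,
                                                              rel=0.005)

    def test_degenerate_system_reports_parameters(self, pnd_spec):
        with pytest.raises(mp.ParameterError, match="K_lung"):
            mp.steady_state_ratio_oracle(
                pnd_spec.with_parameters(K_lung=0.0))


class TestBloodPlasmaConversion:
    @pytest.mark.parametrize(
        "value,kbp,direction,expected",
        [(4.0, 0.75, "plasma_to_blood", 3.0),
         (3.0, 0.75, "blood_to_plasma", 4.0),
         (7.3, 1.0, "plasma_to_blood", 7.3)])
    def test_known_conversions(self, value, kbp, direction, expected):
        assert mp.blood_plasma_convert(value, kbp, direction) == \
            pytest.approx(expected)

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_round_trip_is_identity(self, value, kbp):
        blood = mp.blood_plasma_convert(value, kbp, "plasma_to_blood")
        back = mp.blood_plasma_convert(blood, kbp, "blood_to_plasma")
        assert back == pytest.approx(value, rel=1e-12)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(mp.ParameterError):
            mp.blood_plasma_convert(1.0, 0.0)
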