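"""Noncompartmental analysis estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import minipbpk as mp
from minipbpk.nca import pooled_series


def exp_series(k=1.0, c0=100.0, t_end=10.0, dt=0.01):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return mp.ConcentrationSeries(t, c0 * np.exp(-k * t))


class TestAUC:
    def test_triangle_and_constant(self):
        tri = mp.ConcentrationSeries(np.array([0.0, 1.0, 2.0]),
                                     np.array([0.0, 2.0, 0.0]))
        assert mp.auc_trapezoid(tri) == pytest.approx(2.0)
        const = mp.ConcentrationSeries(np.array([0.0, 3.0, 7.0]),
                                       np.array([5.0, 5.0, 5.0]))
        assert mp.auc_trapezoid(const, 0.0, 7.0) == pytest.approx(35.0)

    def test_dense_exponential_matches_closed_form(self):
        k, c0 = 1.7328, 50.0
        s = exp_series(k=k, c0=c0, t_end=10.0 / k, dt=0.01)
        assert mp.auc_trapezoid(s) == pytest.approx(c0 / k, rel=1e-4)

    def test_interpolated_window_endpoints(self):
        s = mp.ConcentrationSeries(np.array([0.0, 2.0]),
                                   np.array([0.0, 4.0]))
        assert mp.auc_trapezoid(s, 0.5, 1.5) == pytest.approx(2.0)

    def test_errors(self):
        s = exp_series()
        with pytest.raises(ValueError, match="exceed"):
            mp.auc_trapezoid(s, 5.0, 5.0)
        with pytest.raises(ValueError, match="beyond"):
            mp.auc_trapezoid(s, 0.0, 99.0)
        single = mp.ConcentrationSeries(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError, match="two points"):
            mp.auc_trapezoid(single)

    @given(st.floats(min_value=0.1, max_value=4.9))
    def test_additivity_at_any_interior_split(self, b):
        s = exp_series(t_end=5.0, dt=0.05)
        whole = mp.auc_trapezoid(s, 0.0, 5.0)
        parts = mp.auc_trapezoid(s, 0.0, b) + mp.auc_trapezoid(s, b, 5.0)
        assert parts == pytest.approx(whole, rel=1e-9)


class TestTerminalHalfLife:
    @given(st.floats(min_value=0.01, max_value=10.0))
    def test_exact_on_noise_free_exponential(self, k):
        s = exp_series(k=k, t_end=8.0 / k, dt=0.2 / k)
        fit = mp.terminal_halflife(s, window=(1.0 / k, 8.0 / k))
        assert fit.k_e == pytest.approx(k, rel=1e-9)
        assert fit.t_half == pytest.approx(np.log(2) / k, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_named_rate_constant(self):
        s = exp_series(k=1.7328)
        fit = mp.terminal_halflife(s, window=(0.5, 10.0))
        assert fit.t_half == pytest.approx(np.log(2) / 1.7328, rel=1e-9)
        assert fit.t_half == pytest.approx(0.4, abs=1e-4)

    def test_artesunate_flip_flop_limit(self, art_spec, art_single_dose):
        # absorption (k_a = 1.74/h) is far slower than elimination, so the
        # terminal slope reflects k_a: t_half -> ln2/1.74 = 0.398 h
        res = art_single_dose
        s = mp.ConcentrationSeries(res.times,
                                   res.concentration("blood", "parent"))
        fit = mp.terminal_halflife(s, window=(1.0, 3.0))
        assert fit.t_half == pytest.approx(np.log(2) / art_spec.parent.k_a,
                                           rel=1e-3)
        assert fit.t_half == pytest.approx(0.4, rel=0.05)

    def test_too_few_points_is_error(self):
        s = mp.ConcentrationSeries(np.array([0.0, 1.0, 2.0, 3.0]),
                                   np.array([8.0, 4.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match=">=3"):
            mp.terminal_halflife(s, window=(1.5, 3.0))

    def test_rising_tail_flagged_not_raised(self):
        s = mp.ConcentrationSeries(np.arange(5.0),
                                   np.array([1.0, 2.0, 4.0, 8.0, 16.0]))
        fit = mp.terminal_halflife(s, window=(0.0, 4.0))
        assert fit.flagged and np.isnan(fit.t_half)


class TestScalarEstimators:
    def test_cmax_tmax_and_tie_break(self):
        s = mp.ConcentrationSeries(np.array([0.0, 1.0, 2.0]),
                                   np.array([0.0, 5.0, 3.0]))
        assert mp.cmax_tmax(s) == (5.0, 1.0)
        tie = mp.ConcentrationSeries(np.array([0.0, 1.0, 2.0]),
                                     np.array([5.0, 5.0, 3.0]))
        assert mp.cmax_tmax(tie) == (5.0, 0.0)  # earliest time wins
        falling = mp.ConcentrationSeries(np.array([0.0, 1.0]),
                                         np.array([9.0, 1.0]))
        assert mp.cmax_tmax(falling) == (9.0, 0.0)

    @pytest.mark.parametrize("auc,tau,expected", [
        (57189.7, 24.0, 2382.9),   # steady-state blood AUC -> C_avg
        (931.4, 24.0, 38.8),
        (0.0, 24.0, 0.0),
    ])
    def test_cavg_worked_values(self, auc, tau, expected):
        assert mp.cavg(auc, tau) == pytest.approx(expected, abs=0.05)

    def test_accumulation_ratio_worked_value(self):
        ar = mp.accumulation_ratio(57189.7, 32508.2)
        assert ar == pytest.approx(1.76, abs=0.005)
        assert round(ar, 1) == 1.8
        assert mp.accumulation_ratio(5.0, 5.0) == 1.0
        with pytest.raises(ValueError):
            mp.accumulation_ratio(1.0, 0.0)

    def test_accumulation_matches_superposition_closed_form(self):
        # one-compartment, first-order: R = 1/(1 - e^{-k tau})
        k, tau = 0.03, 24.0
        t = np.arange(0.0, 40 * tau + 0.025, 0.05)
        ss_c = np.zeros_like(t)
        for j in range(40):
            m = t >= j * tau
            ss_c[m] += np.exp(-k * (t[m] - j * tau))
        s = mp.ConcentrationSeries(t, ss_c)
        auc1 = mp.auc_trapezoid(s, 0.0, tau)
        auc_ss = mp.auc_trapezoid(s, 39 * tau, 40 * tau)
        expected = 1.0 / (1.0 - np.exp(-k * tau))
        assert expected == pytest.approx(1.9484, abs=5e-4)
        assert mp.accumulation_ratio(auc_ss, auc1) == pytest.approx(
            expected, rel=5e-3)

    @pytest.mark.parametrize("tissue,blood,expected", [
        (320.5, 931.4, 0.34), (140.5, 931.4, 0.15)])
    def test_tissue_ratio_from_aucs(self, tissue, blood, expected):
        assert mp.tissue_to_blood_ratio(blood, tissue) == pytest.approx(
            expected, abs=0.005)

    def test_tissue_ratio_identical_series_is_one(self):
        s = exp_series(t_end=5.0, dt=0.1)
        assert mp.tissue_to_blood_ratio(s, s) == pytest.approx(1.0)

    def test_tissue_ratio_disjoint_windows_error(self):
        a = mp.ConcentrationSeries(np.array([0.0, 1.0]),
                                   np.array([1.0, 1.0]))
        b = mp.ConcentrationSeries(np.array([5.0, 6.0]),
                                   np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="overlap"):
            mp.tissue_to_blood_ratio(a, b)


class TestPoolingAndReport:
    def _dataset(self):
        rows = []
        for t, vals in [(0.0, [0, 0]), (1.0, [4.0, 6.0]),
                        (2.0, [2.0, 4.0])]:
            for i, v in enumerate(vals):
                rows.append({"animal_id": f"a{i}", "dose_group": "low",
                             "analyte": "pyronaridine",
                             "matrix": "blood", "time_h": t,
                             "concentration": v, "units": "ng/mL",
                             "bql": False})
        return pd.DataFrame(rows)

    def test_pooled_series_averages_animals(self):
        s = pooled_series(self._dataset(), "pyronaridine", "blood", "low")
        assert np.array_equal(s.times, [0.0, 1.0, 2.0])
        assert np.allclose(s.concentrations, [0.0, 5.0, 3.0])

    def test_bql_handling(self):
        df = self._dataset()
        df.loc[df.index[-1], ["concentration", "bql"]] = [np.nan, True]
        as_zero = pooled_series(df, "pyronaridine", "blood", "low")
        assert as_zero.concentrations[-1] == pytest.approx(1.0)
        dropped = pooled_series(df, "pyronaridine", "blood", "low",
                                bql_as_zero=False)
        assert dropped.concentrations[-1] == pytest.approx(2.0)

    def test_report_consistency_cavg_times_tau_is_auc(self, pnd_14day):
        s = mp.ConcentrationSeries(
            pnd_14day.times, pnd_14day.concentration("blood"),
            matrix="blood", analyte="pyronaridine")
        report = mp.nca_report(s, tau=24.0, last_dose_time=13 * 24.0)
        for label, (lo, hi) in {"day1": (0, 24),
                                "ss": (13 * 24, 14 * 24)}.items():
            assert report.C_avg[label] * (hi - lo) == pytest.approx(
                report.auc[label], rel=1e-12)
        assert report.accumulation == pytest.approx(
            report.auc["ss"] / report.auc["day1"], rel=1e-12)
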