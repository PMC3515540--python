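"""DSC analysis: baseline subtraction, enthalpy integration, non-two-state
deconvolution, reversibility, Kirchhoff regression and thermal-CD Tm."""

import numpy as np
import pytest

from foldstab import (
    SimSpec,
    Thermogram,
    ThermalCDCurve,
    TransitionFit,
    fit_dsc,
    fit_kirchhoff,
    fit_tm_sigmoid,
    gen_dsc,
    gen_kirchhoff_series,
    gen_logistic_series,
    integrate_dHcal,
    per_residue_dcp,
    reversibility_fraction,
    subtract_baseline,
    two_state_excess_cp,
)
from foldstab.constants import R_GAS, celsius_to_kelvin
from foldstab.thermal import model_excess_cp


def grid():
    return np.round(np.arange(15.0, 90.0 + 1e-9, 0.25), 10)


class TestSubtractBaseline:
    def test_straight_line_scan_gives_zero_excess(self):
        g = grid()
        scan = Thermogram(g, 0.8 - 0.003 * g)
        excess = subtract_baseline(scan, (15, 35), (75, 90))
        assert np.max(np.abs(excess.cp)) < 1e-10

    def test_peak_on_sloped_line_recovered(self, sis1_transitions):
        g = grid()
        tr = sis1_transitions[0]
        peak = model_excess_cp(g, [tr])
        scan = Thermogram(g, 0.5 + 0.01 * g + peak)
        excess = subtract_baseline(scan, (15, 35), (80, 90))
        height = two_state_excess_cp(celsius_to_kelvin(tr.Tm_C), tr)
        assert np.max(np.abs(excess.cp - peak)) < 0.01 * height

    def test_overlapping_ranges_rejected(self):
        scan = Thermogram(grid(), np.ones(grid().size))
        with pytest.raises(ValueError):
            subtract_baseline(scan, (30, 50), (30, 50))


class TestIntegrateDHcal:
    def test_zero_excess_integrates_to_zero(self):
        assert integrate_dHcal(Thermogram(grid(), np.zeros(grid().size)), 20, 80) == 0.0

    def test_triangular_peak_closed_form(self):
        g = np.linspace(40.0, 60.0, 201)
        h, w = 10.0, 10.0  # height kcal/mol/K, base width °C
        cp = np.clip(h * (1 - np.abs(g - 50.0) / (w / 2)), 0, None)
        area = integrate_dHcal(Thermogram(g, cp), 40.0, 60.0)
        assert area == pytest.approx(h * w / 2, rel=0.005)

    def test_two_state_peak_area_equals_dHcal(self, sis1_transitions):
        # simulated transition with the wild-type first-transition values
        tr = sis1_transitions[0]
        g = grid()
        area = integrate_dHcal(Thermogram(g, model_excess_cp(g, [tr])), 34.0, 84.0)
        assert area == pytest.approx(154.0, rel=0.01)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            integrate_dHcal(Thermogram(grid(), np.zeros(grid().size)), 60.0, 60.0)


class TestTwoStateExcessCp:
    def test_peak_height_closed_form_at_tm(self):
        tr = TransitionFit(Tm_C=59.0, dH_cal=154.0, dH_vH=154.0)
        tm_k = celsius_to_kelvin(59.0)
        expected = tr.dH_cal * tr.dH_vH / (4 * R_GAS * tm_k**2)
        assert two_state_excess_cp(tm_k, tr) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_far_below_tm(self):
        tr = TransitionFit(Tm_C=59.0, dH_cal=154.0, dH_vH=154.0)
        assert two_state_excess_cp(celsius_to_kelvin(0.0), tr) < 1e-6

    @pytest.mark.parametrize("dh_vh", [30.0, 80.0, 154.0, 300.0])
    def test_integral_equals_calorimetric_enthalpy(self, dh_vh):
        tr = TransitionFit(Tm_C=59.0, dH_cal=100.0, dH_vH=dh_vh)
        t = np.linspace(19.0, 99.0, 4001)  # Tm ± 40 °C
        area = np.trapezoid(two_state_excess_cp(celsius_to_kelvin(t), tr), t)
        assert area == pytest.approx(100.0, rel=0.01)


class TestFitDsc:
    def test_two_transition_noiseless_recovery(self, sis1_transitions):
        scan = gen_dsc(SimSpec("dsc_two_transition", {"transitions": sis1_transitions}, seed=0))[0]
        fit = fit_dsc(scan, n_transitions=2)
        assert abs(fit.transitions[0].Tm_C - 59.0) < 0.1
        assert abs(fit.transitions[1].Tm_C - 67.7) < 0.1
        for got, want in zip(fit.transitions, sis1_transitions):
            assert got.dH_cal == pytest.approx(want.dH_cal, rel=1e-3)
        assert fit.residual_rms < 1e-8

    def test_separated_transitions_full_recovery(self):
        truth = [TransitionFit(50.0, 80.0, 120.0), TransitionFit(70.0, 60.0, 90.0)]
        scan = gen_dsc(SimSpec("dsc_two_transition", {"transitions": truth}, seed=0))[0]
        fit = fit_dsc(scan, n_transitions=2)
        for got, want in zip(fit.transitions, truth):
            assert got.Tm_C == pytest.approx(want.Tm_C, abs=1e-3)
            assert got.dH_cal == pytest.approx(want.dH_cal, rel=1e-3)
            assert got.dH_vH == pytest.approx(want.dH_vH, rel=1e-3)

    def test_single_transition_exact_recovery(self):
        truth = [TransitionFit(59.0, 154.0, 154.0)]
        scan = gen_dsc(SimSpec("dsc_two_transition", {"transitions": truth}, seed=0))[0]
        fit = fit_dsc(scan, n_transitions=1)
        assert fit.transitions[0].Tm_C == pytest.approx(59.0, rel=1e-4)
        assert fit.transitions[0].dH_cal == pytest.approx(154.0, rel=1e-4)

    def test_area_additivity(self, sis1_transitions):
        scan = gen_dsc(SimSpec("dsc_two_transition", {"transitions": sis1_transitions}, seed=0))[0]
        fit = fit_dsc(scan, n_transitions=2)
        # the fitted amplitudes carry the generating total enthalpy, and the
        # measured excess heat in the window equals the sum of the fitted
        # per-transition contributions over the same window
        assert sum(t.dH_cal for t in fit.transitions) == pytest.approx(
            sum(t.dH_cal for t in sis1_transitions), rel=0.01)
        total = integrate_dHcal(scan, 15.0, 90.0)
        per_transition = sum(
            np.trapezoid(model_excess_cp(scan.temp_C, [t]), scan.temp_C)
            for t in fit.transitions
        )
        assert total == pytest.approx(per_transition, rel=0.01)

    def test_zero_transitions_rejected(self):
        scan = Thermogram(grid(), np.ones(grid().size))
        with pytest.raises(ValueError):
            fit_dsc(scan, n_transitions=0)


class TestReversibility:
    def test_identical_scans_fully_reversible(self, sis1_transitions):
        scan = gen_dsc(SimSpec("dsc_two_transition", {"transitions": sis1_transitions}, seed=0))[0]
        ratio, ok = reversibility_fraction(scan, scan)
        assert ratio == pytest.approx(1.0, abs=1e-9)
        assert ok

    def test_scaled_rescan_gives_scale(self, sis1_transitions):
        g = grid()
        peak = model_excess_cp(g, sis1_transitions)
        s1 = Thermogram(g, peak, scan_index=1)
        s2 = Thermogram(g, 0.6 * peak, scan_index=2)
        ratio, ok = reversibility_fraction(s1, s2)
        assert ratio == pytest.approx(0.6, abs=1e-6)
        assert not ok

    def test_flat_rescan_gives_zero(self, sis1_transitions):
        g = grid()
        s1 = Thermogram(g, model_excess_cp(g, sis1_transitions))
        s2 = Thermogram(g, np.zeros(g.size))
        ratio, ok = reversibility_fraction(s1, s2)
        assert ratio == pytest.approx(0.0, abs=1e-9)
        assert not ok

    def test_degenerate_first_scan_rejected(self):
        g = grid()
        flat = Thermogram(g, np.zeros(g.size))
        with pytest.raises(ValueError):
            reversibility_fraction(flat, flat)


class TestKirchhoff:
    def test_constant_enthalpy_gives_zero_dcp(self):
        series = [(50.0, 100.0), (55.0, 100.0), (59.0, 100.0)]
        assert fit_kirchhoff(series).dCp == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered_to_machine_precision(self):
        # 5 collinear pairs with the wild-type first-transition slope
        tm = np.array([51.0, 53.0, 55.0, 57.0, 59.0])
        dh = 154.0 + 4.0 * (tm - 59.0)
        fit = fit_kirchhoff(list(zip(tm, dh)))
        assert fit.dCp == pytest.approx(4.0, rel=1e-12)
        assert fit.dH_ref == pytest.approx(154.0, rel=1e-12)
        assert fit.Tm_ref_C == 59.0

    def test_noisy_line_within_two_se(self):
        series = gen_kirchhoff_series(SimSpec(
            "kirchhoff_line",
            {"dCp": 4.0, "dH_ref": 154.0, "Tm_ref_C": 59.0, "Tm_shifts_C": np.linspace(0, 8, 8)},
            noise_sd=2.0, seed=9,
        ))
        fit = fit_kirchhoff(series)
        assert abs(fit.dCp - 4.0) < 2 * fit.se_dCp

    def test_identical_tm_rank_deficient(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_kirchhoff([(59.0, 100.0), (59.0, 120.0), (59.0, 140.0)])


class TestPerResidueDcp:
    @pytest.mark.parametrize(
        "dcp, n, expected",
        [(4.0, 235, 17.0), (3.8, 252, 15.1), (1.7, 121, 14.0)],
    )
    def test_reference_values(self, dcp, n, expected):
        assert per_residue_dcp(dcp, n) == expected

    def test_roundtrip_identity(self):
        assert per_residue_dcp(4.0, 235) * 235 / 1000 == pytest.approx(4.0, abs=0.05)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            per_residue_dcp(4.0, 0)


class TestFitTmSigmoid:
    def test_exact_logistic_midpoint(self):
        t = np.arange(20.0, 90.0, 0.5)
        y = 1.0 / (1.0 + np.exp(-(t - 60.0) / 2.5))
        fit = fit_tm_sigmoid(ThermalCDCurve(t, y))
        assert fit.midpoint == pytest.approx(60.0, abs=1e-6)

    def test_noisy_trace_within_half_degree(self):
        curve = gen_logistic_series(SimSpec(
            "logistic_series",
            {"lower": 0.0, "upper": 1.0, "midpoint": 60.1, "width": 2.5},
            grid=np.arange(20.0, 90.0, 0.5), noise_sd=0.02, seed=4,
        ), kind="thermal_cd")
        fit = fit_tm_sigmoid(curve)
        assert fit.midpoint == pytest.approx(60.1, abs=0.5)

    def test_missing_upper_plateau_flagged_by_wide_se(self):
        rng = np.random.default_rng(7)
        full = np.arange(20.0, 90.0, 0.5)
        trunc = full[full < 58.0]  # stops below the midpoint
        noise = rng.normal(0, 0.005, full.size)

        def sig(t):
            return 1.0 / (1.0 + np.exp(-(t - 60.0) / 2.5))

        fit_trunc = fit_tm_sigmoid(ThermalCDCurve(trunc, sig(trunc) + noise[: trunc.size]))
        fit_full = fit_tm_sigmoid(ThermalCDCurve(full, sig(full) + noise))
        assert fit_trunc.se_midpoint > 20 * fit_full.se_midpoint
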