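"""Sedimentation standardization, solvent properties, partial specific
volume and logistic oligomer-transition midpoints."""

import numpy as np
import pytest

from foldstab import (
    BufferProps,
    SimSpec,
    classify_oligomer,
    correct_s_to_s20w,
    extrapolate_s0,
    fit_transition_midpoint,
    gen_logistic_series,
    urea_buffer_props,
    vbar_from_sequence,
)
from foldstab.constants import WATER_DENSITY_20C_G_ML, WATER_VISCOSITY_20C_CP


class TestS20wCorrection:
    def test_water_buffer_is_identity(self):
        water = BufferProps(WATER_DENSITY_20C_G_ML, WATER_VISCOSITY_20C_CP)
        assert correct_s_to_s20w(3.6, 0.7263, water) == pytest.approx(3.6, rel=1e-14)

    def test_linear_in_relative_viscosity(self):
        doubled = BufferProps(WATER_DENSITY_20C_G_ML, 2 * WATER_VISCOSITY_20C_CP)
        assert correct_s_to_s20w(3.6, 0.7263, doubled) == pytest.approx(7.2, rel=1e-14)

    def test_hand_evaluated_formula(self):
        # s = 2.0 S, vbar = 0.7263 mL/g, buffer 1.10 g/mL / 1.50 cP:
        # 2.0 * (1.50/1.002) * (1 - 0.7263*0.99823) / (1 - 0.7263*1.10)
        buffer = BufferProps(1.10, 1.50)
        expected = 2.0 * (1.50 / 1.002) * (1 - 0.7263 * 0.99823) / (1 - 0.7263 * 1.10)
        assert correct_s_to_s20w(2.0, 0.7263, buffer) == pytest.approx(expected, rel=1e-14)

    def test_negative_buoyancy_rejected(self):
        with pytest.raises(ValueError, match="buoyancy"):
            correct_s_to_s20w(2.0, 0.95, BufferProps(1.10, 1.50))


class TestExtrapolateS0:
    def test_constant_series(self):
        s0, slope, se = extrapolate_s0([0.25, 0.5, 0.75], [3.6, 3.6, 3.6])
        assert s0 == pytest.approx(3.6)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_intercept(self):
        c = np.array([0.25, 0.5, 0.75])
        s0, slope, _ = extrapolate_s0(c, 3.6 - 0.2 * c)
        assert s0 == pytest.approx(3.6, rel=1e-12)
        assert slope == pytest.approx(-0.2, rel=1e-12)

    def test_two_points_match_closed_form(self):
        s0, slope, se = extrapolate_s0([0.25, 0.75], [3.55, 3.45])
        assert s0 == pytest.approx(3.6, rel=1e-12)
        assert slope == pytest.approx(-0.2, rel=1e-12)

    def test_noisy_points_within_two_se(self):
        rng = np.random.default_rng(2)
        c = np.array([0.25, 0.5, 0.75, 1.0, 1.5])
        s = 3.6 - 0.2 * c + rng.normal(0, 0.02, c.size)
        s0, _, se = extrapolate_s0(c, s)
        assert abs(s0 - 3.6) < 2 * se

    def test_single_concentration_flagged(self):
        s0, slope, se = extrapolate_s0([0.5], [3.5])
        assert s0 == 3.5
        assert np.isinf(se)


class TestUreaBufferProps:
    def test_zero_molar_is_water(self):
        props = urea_buffer_props(0.0, 20.0)
        assert props.density_g_mL == pytest.approx(0.9982, abs=2e-4)
        assert props.viscosity_cP == pytest.approx(1.002, abs=2e-3)

    def test_monotone_in_urea(self):
        molarities = np.linspace(0.0, 8.0, 33)
        dens = [urea_buffer_props(m, 20.0).density_g_mL for m in molarities]
        visc = [urea_buffer_props(m, 20.0).viscosity_cP for m in molarities]
        assert np.all(np.diff(dens) > 0)
        assert np.all(np.diff(visc) > 0)

    def test_five_molar_denser_than_one(self):
        assert (urea_buffer_props(5.0).density_g_mL > urea_buffer_props(1.0).density_g_mL)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            urea_buffer_props(9.5)


class TestVbarFromSequence:
    def test_homopolymer_gives_table_value(self):
        assert vbar_from_sequence("GGGGGG") == pytest.approx(0.64, rel=1e-12)
        assert vbar_from_sequence("AAAA") == pytest.approx(0.74, rel=1e-12)

    def test_two_residue_weighted_mean_by_hand(self):
        # masses 57.0519 (G) / 71.0788 (A), vbars 0.64 / 0.74
        expected = (57.0519 * 0.64 + 71.0788 * 0.74) / (57.0519 + 71.0788)
        assert vbar_from_sequence("GA") == pytest.approx(expected, rel=1e-12)

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vbar_from_sequence("")
        with pytest.raises(ValueError, match="position 3"):
            vbar_from_sequence("GAXPA")

    def test_realistic_sequences_in_physical_range(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            seq = "".join(rng.choice(letters, size=120))
            assert 0.58 <= vbar_from_sequence(seq) <= 0.80


class TestTransitionMidpoint:
    def test_exact_logistic_sis1_like(self):
        x = np.arange(0.0, 6.0001, 0.25)
        y = 3.5 + (2.0 - 3.5) / (1 + np.exp(-(x - 3.4) / 0.25))
        fit = fit_transition_midpoint(x, y)
        assert fit.midpoint == pytest.approx(3.4, abs=1e-6)

    def test_direction_symmetry(self):
        x = np.arange(0.0, 6.0001, 0.25)
        down = 3.5 + (2.0 - 3.5) / (1 + np.exp(-(x - 3.4) / 0.25))
        up = 2.0 + (3.5 - 2.0) / (1 + np.exp(-(x - 3.4) / 0.25))
        f_down, f_up = fit_transition_midpoint(x, down), fit_transition_midpoint(x, up)
        assert f_down.midpoint == pytest.approx(f_up.midpoint, abs=1e-6)
        assert f_down.lower == pytest.approx(f_up.upper, abs=1e-6)

    def test_random_noiseless_midpoints_recovered(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0.0, 6.0, 41)
        for _ in range(50):
            lo, up = rng.uniform(1, 5), rng.uniform(-2, 1)
            mid = rng.uniform(1.0, 5.0)
            width = rng.uniform(0.1, 0.8)
            y = lo + (up - lo) / (1 + np.exp(-(x - mid) / width))
            assert fit_transition_midpoint(x, y).midpoint == pytest.approx(mid, abs=1e-6)

    def test_noisy_logistic_within_tolerance(self):
        series = gen_logistic_series(SimSpec(
            "logistic_series",
            {"lower": 3.5, "upper": 2.0, "midpoint": 3.4, "width": 0.25},
            noise_sd=0.03, seed=6,  # 2% of the 1.5 S amplitude
        ), kind="sed")
        fit = fit_transition_midpoint(series.urea_M, series.s0_20w_S)
        assert fit.midpoint == pytest.approx(3.4, abs=0.15)

    def test_flat_series_is_fit_failure(self):
        x = np.arange(0.0, 6.0001, 0.5)
        with pytest.raises(ValueError, match="flat|converge"):
            fit_transition_midpoint(x, np.full(x.size, 3.5))


class TestClassifyOligomer:
    @pytest.mark.parametrize(
        "mm_obs, mm_monomer, expected",
        [(78.0, 39.0, "dimer"), (39.0, 39.0, "monomer"), (60.0, 39.0, "other")],
    )
    def test_classification(self, mm_obs, mm_monomer, expected):
        assert classify_oligomer(mm_obs, mm_monomer) == expected

    def test_positive_masses_required(self):
        with pytest.raises(ValueError):
            classify_oligomer(-1.0, 39.0)
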