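"""Tangent-line inversion: intercept relations, radius and modulus recovery."""

import dataclasses

import numpy as np
import pytest

import afmtangent as at
from afmtangent.coefficients import DomainError
from afmtangent.curves import PolyFit

# worked bench example: agarose gel, borosilicate sphere
HMAX = 4.32e-7
HCOM = 1.342e-7
S_TANGENT = 0.2505
B_TANGENT = -3.363e-8


def make_polyfit(a, b, c):
    return PolyFit(a=a, b=b, c=c, r_squared=1.0, residual_norm=0.0)


class TestHcomOverHmax:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(0.01, 0.3321), (0.50, 0.3092), (1.00, 0.2803), (5.00, 0.1002)],
    )
    def test_tabulated_values(self, ratio, expected):
        assert round(at.hcom_over_hmax(ratio, at.COEFFS_N6), 4) == expected

    def test_limit_is_one_third_at_small_depth(self):
        # convergence is O(sqrt(ratio)), so evaluate deep into the limit
        assert at.hcom_over_hmax(1e-8, at.COEFFS_N6) == pytest.approx(1 / 3, abs=1e-5)

    def test_hcom_over_radius_approaches_half_at_deep_indentation(self):
        assert 5.0 * at.hcom_over_hmax(5.0, at.COEFFS_N6) == pytest.approx(0.5, abs=0.005)

    def test_strictly_decreasing(self):
        ratios = np.linspace(0.01, 5.0, 500)
        vals = at.hcom_over_hmax(ratios, at.COEFFS_N6)
        assert np.all(np.diff(vals) < 0)

    def test_out_of_domain(self):
        with pytest.raises(DomainError):
            at.hcom_over_hmax(6.0, at.COEFFS_N6)
        with pytest.raises(DomainError):
            at.hcom_over_hmax(0.0, at.COEFFS_N6)


class TestBDimensionless:
    def test_vanishes_at_small_depth(self):
        assert at.b_dimensionless(1e-5, at.COEFFS_N6) == pytest.approx(0.0, abs=1e-7)

    def test_tends_to_minus_half(self):
        assert at.b_dimensionless(5.0, at.COEFFS_N6) == pytest.approx(-0.5, abs=0.005)

    def test_negative_throughout(self):
        ratios = np.linspace(0.01, 5.0, 200)
        assert np.all(at.b_dimensionless(ratios, at.COEFFS_N6) < 0)

    def test_consistent_with_forward_model_tangent(self):
        # b from the tangent of a noiseless model curve equals the
        # dimensionless intercept scaled by 2 E* R^2
        params = at.ContactParameters(E=100e3, v=0.5, R=1e-6)
        hmax = 0.8e-6
        # exact fit coefficients of the three-term law
        a = 4 * at.COEFFS_N3.c[0] * params.E_star * np.sqrt(params.R) / 3
        b = at.COEFFS_N3.c[1] * params.E_star
        c = 2 * at.COEFFS_N3.c[2] * params.E_star / (3 * params.R)
        tl = at.tangent_from_polyfit(make_polyfit(a, b, c), hmax)
        expected = at.b_dimensionless(hmax / params.R, at.COEFFS_N3) * (
            2 * params.E_star * params.R**2
        )
        assert tl.b_intercept == pytest.approx(expected, rel=1e-9)


class TestTangentLine:
    def test_inconsistent_intercept_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            at.TangentLine(S=1.0, b_intercept=0.0, hmax=1.0, Fmax=2.0)

    def test_hcom_is_minus_b_over_S(self):
        tl = at.TangentLine(
            S=S_TANGENT, b_intercept=B_TANGENT, hmax=HMAX,
            Fmax=S_TANGENT * HMAX + B_TANGENT,
        )
        assert tl.hcom == pytest.approx(-B_TANGENT / S_TANGENT, rel=1e-12)


class TestTangentFromPolyfit:
    def test_worked_example_tangent(self):
        fit = make_polyfit(281.0, -23340.0, -1.019e10)
        tl = at.tangent_from_polyfit(fit, HMAX)
        assert tl.S == pytest.approx(S_TANGENT, rel=0.01)
        assert tl.b_intercept == pytest.approx(B_TANGENT, rel=0.02)
        assert tl.hcom == pytest.approx(HCOM, rel=0.02)

    def test_pure_hertz_fit_gives_one_third(self):
        tl = at.tangent_from_polyfit(make_polyfit(281.0, 0.0, 0.0), HMAX)
        assert tl.hcom == pytest.approx(HMAX / 3, rel=1e-12)

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(ValueError, match="stiffness"):
            at.tangent_from_polyfit(make_polyfit(1e-3, -1e6, -1e12), HMAX)


class TestSolveRadius:
    def test_worked_example_radius(self):
        R = at.solve_radius(HCOM, HMAX, at.COEFFS_N3)
        assert R == pytest.approx(0.921e-6, abs=0.005e-6)

    def test_hertz_regime_degenerate(self):
        with pytest.raises(at.DegenerateCurveError):
            at.solve_radius(HMAX / 3, HMAX, at.COEFFS_N3)

    def test_noiseless_round_trip(self):
        params = at.ContactParameters(E=50e3, v=0.5, R=2e-6)
        hmax = 1e-6
        h = np.linspace(0, hmax, 400)
        F = at.polynomial_force(h, params, at.COEFFS_N3)
        fit = at.fit_force_curve(at.ForceCurve(h=h, F=F))
        tl = at.tangent_from_polyfit(fit, hmax)
        R = at.solve_radius(tl.hcom, hmax, at.COEFFS_N3)
        assert R == pytest.approx(2e-6, rel=1e-3)

    def test_too_deep_for_three_term_set_suggests_wide_set(self):
        # hcom/hmax below the three-term floor
        target = at.hcom_over_hmax(4.0, at.COEFFS_N6)
        with pytest.raises(DomainError, match="six-term"):
            at.solve_radius(target * HMAX, HMAX, at.COEFFS_N3)

    def test_invalid_intercept(self):
        with pytest.raises(ValueError):
            at.solve_radius(2 * HMAX, HMAX, at.COEFFS_N3)


class TestSolveModulus:
    def test_worked_example_value_matches_symbolic_oracle(self):
        # independent symbolic evaluation of the intercept relation at the
        # printed S, b, hmax, R, v gives 161834.4 Pa (frozen oracle value)
        tl = at.TangentLine(
            S=S_TANGENT, b_intercept=B_TANGENT, hmax=HMAX,
            Fmax=S_TANGENT * HMAX + B_TANGENT,
        )
        E = at.solve_modulus(tl, 0.921e-6, 0.5, at.COEFFS_N3)
        assert E == pytest.approx(161834.4, rel=1e-6)

    def test_zero_intercept_gives_zero_modulus(self):
        tl = at.TangentLine(S=0.25, b_intercept=0.0, hmax=HMAX, Fmax=0.25 * HMAX)
        assert at.solve_modulus(tl, 1e-6, 0.5, at.COEFFS_N3) == 0.0

    def test_noiseless_round_trip(self):
        params = at.ContactParameters(E=100e3, v=0.5, R=1e-6)
        hmax = 0.5e-6
        h = np.linspace(0, hmax, 300)
        F = at.polynomial_force(h, params, at.COEFFS_N3)
        fit = at.fit_force_curve(at.ForceCurve(h=h, F=F))
        tl = at.tangent_from_polyfit(fit, hmax)
        R = at.solve_radius(tl.hcom, hmax, at.COEFFS_N3)
        E = at.solve_modulus(tl, R, 0.5, at.COEFFS_N3)
        assert E == pytest.approx(100e3, rel=5e-3)


class TestForwardInverseConsistency:
    @pytest.mark.parametrize("ratio", [0.2, 0.5, 1.0, 2.0, 3.5, 4.5])
    def test_analytic_tangent_round_trip_across_depths(self, ratio):
        # tangent quantities from the six-term forward model at hmax,
        # then radius recovery: the inverse pair is the identity
        params = at.ContactParameters(E=100e3, v=0.5, R=1e-6)
        hmax = ratio * params.R
        S = at.contact_stiffness(hmax, params, at.COEFFS_N6)
        Fmax = at.polynomial_force(hmax, params, at.COEFFS_N6)
        hcom = -(Fmax - S * hmax) / S
        R = at.solve_radius(hcom, hmax, at.COEFFS_N6)
        assert R == pytest.approx(params.R, rel=1e-3)


class TestModulusIndependence:
    def test_hcom_ratio_identical_across_moduli(self):
        ratios = []
        for E in (10e3, 100e3, 1000e3):
            params = at.ContactParameters(E=E, v=0.5, R=1e-6)
            hmax = 0.6e-6
            h = np.linspace(0, hmax, 300)
            F = at.polynomial_force(h, params, at.COEFFS_N3)
            tl = at.tangent_from_polyfit(
                at.fit_force_curve(at.ForceCurve(h=h, F=F)), hmax
            )
            ratios.append(tl.hcom / hmax)
        assert max(ratios) - min(ratios) < 1e-9


class TestInverseQuarticMap:
    def test_fit_is_essentially_perfect(self):
        q = at.fit_inverse_quartic(1.32)
        assert round(q.r_squared, 4) == 1.0000

    def test_worked_example_lookup(self):
        # a quartic cannot follow the sqrt-like approach to the Hertz limit
        # to better than ~0.003 here; exact inversion is solve_radius's job
        q = at.fit_inverse_quartic(1.32)
        assert q(HCOM / HMAX) == pytest.approx(0.4691, abs=0.005)

    def test_small_depth_end_approaches_zero(self):
        q = at.fit_inverse_quartic(1.32)
        assert q(at.hcom_over_hmax(0.01, at.COEFFS_N6)) == pytest.approx(0.01, abs=0.01)

    def test_domain_beyond_coefficients_rejected(self):
        with pytest.raises(DomainError):
            at.fit_inverse_quartic(2.0, at.COEFFS_N3)


class TestLookupTable:
    def test_fine_grid_rows_and_values(self):
        table = at.build_lookup_table(0.01, 1.00, 0.01)
        assert len(table) == 100
        lookup = dict(zip(table.hmax_over_R, table.hcom_over_hmax))
        assert lookup[0.01] == 0.3321
        assert lookup[0.50] == 0.3092
        assert lookup[1.00] == 0.2803

    def test_coarse_grid_covers_deep_indentation(self):
        table = at.build_lookup_table(0.05, 5.00, 0.05)
        assert len(table) == 100
        assert table.hcom_over_hmax.iloc[-1] == 0.1002

    def test_second_column_monotone_decreasing(self):
        table = at.build_lookup_table(0.05, 5.00, 0.05)
        assert np.all(np.diff(table.hcom_over_hmax) < 0)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            at.build_lookup_table(0.5, 0.6, 1.0)


class TestNaiveCoefficientPitfall:
    """Reading (E, R) straight off the cubic-fit coefficients is unstable.

    Many (a, b, c) triples produce near-identical curves, so the direct
    coefficient maps amplify noise enormously; the tangent construction,
    built from the same fit, stays stable.
    """

    def test_naive_recovery_unstable_under_noise(self):
        base = at.SimulationSpec(hmax=0.921e-6)  # depth ratio 1.0
        naive_R, tangent_R = [], []
        for seed in range(30):
            spec = dataclasses.replace(base, seed=seed, noise_sd_fraction=0.01)
            curve, truth = at.generate_curve(spec)
            fit = at.fit_force_curve(curve)
            _, Rn = at.naive_coefficient_recovery(fit, 0.5, at.COEFFS_N3)
            naive_R.append(Rn)
            tangent_R.append(at.calibrate_curve(curve).R)
        naive_R = np.asarray(naive_R)
        tangent_R = np.asarray(tangent_R)
        cv_naive = naive_R.std() / naive_R.mean()
        cv_tangent = tangent_R.std() / tangent_R.mean()
        # measured: cv 1.5 vs 0.14; generous margins, same ordering
        assert cv_naive > 0.5
        assert cv_tangent < 0.25
        assert cv_naive > 3 * cv_tangent
        # naive mean is badly biased; tangent mean is not
        assert abs(naive_R.mean() - 0.921e-6) / 0.921e-6 > 0.5
        assert abs(tangent_R.mean() - 0.921e-6) / 0.921e-6 < 0.1

    def test_exact_on_noiseless_model_data(self):
        # the maps are exact when the data actually follow the model
        params = at.ContactParameters(E=120e3, v=0.5, R=1.5e-6)
        h = np.linspace(0, 1e-6, 300)
        F = at.polynomial_force(h, params, at.COEFFS_N3)
        fit = at.fit_force_curve(at.ForceCurve(h=h, F=F))
        E, R = at.naive_coefficient_recovery(fit, 0.5, at.COEFFS_N3)
        assert E == pytest.approx(120e3, rel=1e-6)
        assert R == pytest.approx(1.5e-6, rel=1e-6)
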