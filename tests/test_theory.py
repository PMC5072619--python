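"""Forward theory: structural constants, normal modes, MSD laws, mode-sum oracle."""

import numpy as np
import pytest

from chromdyn import (
    FractalDomainModel,
    dapp_constant_C,
    msd_constant_B,
    scaling_constant_A,
    subdiffusion_exponent,
)

# pi^(5/3) * Gamma(5/3) * sin(pi/3), 30-digit arbitrary-precision evaluation
A_AT_3 = 5.26840296480899207
# Gamma(2)^(1/2) * Gamma(1/2) = sqrt(pi)
B_AT_2_1 = 1.77245385090551603


class TestScalingConstantA:
    def test_ideal_chain_is_pi_squared(self):
        assert scaling_constant_A(2.0) == pytest.approx(np.pi**2, rel=1e-14)

    def test_fractal_globule_value(self):
        assert scaling_constant_A(3.0) == pytest.approx(A_AT_3, rel=1e-14)

    def test_vanishes_toward_straight_line(self):
        vals = [scaling_constant_A(d) for d in (1.2, 1.1, 1.05, 1.01)]
        assert all(v > 0 for v in vals)
        assert np.all(np.diff(vals) < 0)  # monotone toward 0 near d_f = 1

    def test_domain_errors(self):
        for bad in (1.0, 0.5, 3.5):
            with pytest.raises(ValueError):
                scaling_constant_A(bad)
        # permissive mode admits d_f > 3 for flagged sweeps
        assert scaling_constant_A(3.5, strict=False) > 0


class TestMSDConstantB:
    def test_rouse_viscous_value(self):
        assert msd_constant_B(2.0, 1.0) == pytest.approx(B_AT_2_1, rel=1e-14)

    def test_positive_on_grid(self):
        for d_f in (1.2, 1.64, 2.0, 2.62, 3.0):
            for alpha in (0.6, 0.8, 1.0):
                assert msd_constant_B(d_f, alpha) > 0

    def test_matches_mode_sum_short_time_prefactor(self, interior_model):
        """The B grouping is pinned by the numerical mode-sum oracle.

        With the exponential relaxation surrogate, position averaging and
        the CoM excluded, the mode sum at t << tau must equal the closed-form
        power law whose prefactor contains B, to within the discretization
        error of the sum.
        """
        m = interior_model
        tau = m.relaxation_time()
        t = tau * np.logspace(-5, -4, 5)
        num = m.msd_mode_sum(t, max_modes=200000, kernel="exp", include_com=False)
        closed = m.internal_msd_asymptotic(t)
        assert np.allclose(num / closed, 1.0, atol=0.01)


class TestDappConstantC:
    def test_weak_alpha_dependence(self):
        # the constant changes by < 20% across alpha in [0.6, 1.0] at fixed d_f
        for d_f in (1.5, 2.0, 2.5, 3.0):
            vals = [dapp_constant_C(d_f, a) for a in np.linspace(0.6, 1.0, 9)]
            assert max(vals) / min(vals) < 1.20

    def test_positive_and_continuous_on_grid(self):
        grid = [
            dapp_constant_C(d_f, a)
            for d_f in np.linspace(1.2, 3.0, 10)
            for a in np.linspace(0.6, 1.0, 5)
        ]
        assert all(np.isfinite(grid)) and all(v > 0 for v in grid)


class TestSubdiffusionExponent:
    @pytest.mark.parametrize(
        "alpha,d_f,expected",
        [(1.0, 3.0, 0.4), (1.0, 2.0, 0.5), (0.8, 1.6364, 0.44), (0.9, 2.0909, 0.44)],
    )
    def test_known_values(self, alpha, d_f, expected):
        assert subdiffusion_exponent(alpha, d_f) == pytest.approx(expected, abs=2e-5)

    def test_hydrodynamic_variant_ignores_d_f(self):
        assert subdiffusion_exponent(0.9, 1.5, hydrodynamics=True) == pytest.approx(0.6)
        assert subdiffusion_exponent(0.9, 3.0, hydrodynamics=True) == pytest.approx(0.6)


class TestDomainModelValidation:
    def test_rejects_out_of_range_parameters(self):
        good = dict(alpha=0.9, d_f=2.0, n_nucleosomes=100, r_rms=0.3, d_egfp=20.6)
        FractalDomainModel(**good)
        for bad in (
            {"alpha": 0.0},
            {"alpha": 1.2},
            {"d_f": 1.0},
            {"d_f": 3.2},
            {"n_nucleosomes": 1},
            {"r_rms": -0.1},
            {"d_egfp": 0.0},
        ):
            with pytest.raises(ValueError):
                FractalDomainModel(**{**good, **bad})

    def test_effective_bond_length(self):
        m = FractalDomainModel(alpha=1.0, d_f=2.0, n_nucleosomes=10000, r_rms=1.0)
        assert m.b_eff == pytest.approx(0.01)  # N^(-1/2) scaling


class TestNormalModes:
    def test_mode_variance_scalings(self, rouse_model):
        m = rouse_model
        # d_f = 2: variance ~ p^(-2), so doubling p divides by 4
        assert m.mode_variance(2) == pytest.approx(m.mode_variance(1) / 4.0)
        # proportional to <R^2>
        m2 = FractalDomainModel(alpha=1.0, d_f=2.0, n_nucleosomes=200, r_rms=0.6)
        p = np.arange(1, 20)
        assert np.allclose(m2.mode_variance(p), 4.0 * m.mode_variance(p))

    def test_mode_variance_rejects_com(self, rouse_model):
        with pytest.raises(ValueError):
            rouse_model.mode_variance(0)

    def test_stiffness_variance_product_conserved(self, interior_model):
        m = interior_model
        p = np.arange(1, 200)
        prod = m.mode_stiffness(p) * m.mode_variance(p)
        assert np.allclose(prod, 3.0 / (2.0 * m.n_nucleosomes), rtol=1e-12)

    def test_com_mode_has_zero_stiffness(self, interior_model):
        assert interior_model.mode_stiffness(0) == 0.0

    def test_rouse_spring_spectrum(self, rouse_model):
        # d_f = 2: k_p ~ p^2
        p = np.array([1, 2, 4, 8])
        k = rouse_model.mode_stiffness(p)
        assert np.allclose(k / k[0], p.astype(float) ** 2, rtol=1e-12)

    def test_mode_correlation_limits_and_monotonicity(self, interior_model):
        m = interior_model
        t = np.linspace(0.0, 5.0, 21)
        c1 = m.mode_correlation(1, t)
        assert c1[0] == pytest.approx(m.mode_variance(1))
        assert np.all(np.diff(c1) <= 1e-15)
        assert np.all(c1 >= 0)
        # higher modes decay faster (normalized)
        c2 = m.mode_correlation(2, t)
        assert np.all(c2[1:] / c2[0] <= c1[1:] / c1[0] + 1e-12)

    def test_mode_correlation_exponential_at_alpha_one(self, rouse_model):
        m = rouse_model
        tau = m.relaxation_time()
        t = np.array([0.1, 0.5, 1.0]) * tau
        expected = m.mode_variance(3) * np.exp(-(3.0**2) * t / tau)
        assert np.allclose(m.mode_correlation(3, t), expected, rtol=1e-10)


class TestRelaxationTime:
    def test_table_value_interior_alpha08(self):
        # the inversion at alpha = 0.8 (interior fit) published tau = 4.65 s
        m = FractalDomainModel(
            alpha=0.8, d_f=1.6364, n_nucleosomes=5000, r_rms=0.37556, d_egfp=20.6
        )
        assert m.relaxation_time() == pytest.approx(4.65, abs=0.01)

    def test_alpha_one_linearity(self):
        m1 = FractalDomainModel(alpha=1.0, d_f=2.0, n_nucleosomes=1000, r_rms=0.3)
        m2 = FractalDomainModel(alpha=1.0, d_f=2.0, n_nucleosomes=2000, r_rms=0.3)
        assert m2.relaxation_time() == pytest.approx(2.0 * m1.relaxation_time(), rel=1e-12)


class TestMSDLaws:
    def test_com_msd_power_law(self, interior_model):
        from scipy.special import gamma

        m = interior_model
        tau = m.relaxation_time()
        assert m.com_msd(0.0) == 0.0
        expected_at_tau = 2.0 * m.r_sq / (m.scaling_constant * gamma(1 + m.alpha))
        assert m.com_msd(tau) == pytest.approx(expected_at_tau, rel=1e-12)
        t = np.logspace(-3, 1, 30)
        y = m.com_msd(t)
        slope = np.polyfit(np.log(t), np.log(y), 1)[0]
        assert slope == pytest.approx(m.alpha, abs=1e-12)

    def test_internal_msd_exponent_identity(self):
        # log-log slope equals 2 alpha / (2 + d_f) to machine precision
        for alpha in (0.6, 0.8, 1.0):
            for d_f in (1.5, 2.0, 2.8):
                m = FractalDomainModel(alpha=alpha, d_f=d_f, n_nucleosomes=5000, r_rms=0.3)
                t = np.logspace(-4, -1, 20)
                slope = np.polyfit(np.log(t), np.log(m.internal_msd_asymptotic(t)), 1)[0]
                assert slope == pytest.approx(subdiffusion_exponent(alpha, d_f), abs=1e-12)

    def test_internal_msd_equals_dapp_power_law(self, interior_model):
        m = interior_model
        t = np.logspace(-3, 0, 15)
        direct = m.apparent_diffusion_coefficient() * t ** m.subdiffusion_exponent()
        assert np.allclose(m.internal_msd_asymptotic(t), direct, rtol=1e-10)

    def test_dapp_size_scaling(self, interior_model):
        m = interior_model
        m2 = FractalDomainModel(
            alpha=m.alpha,
            d_f=m.d_f,
            n_nucleosomes=m.n_nucleosomes,
            r_rms=np.sqrt(2.0) * m.r_rms,  # doubles <R^2>
            d_egfp=m.d_egfp,
        )
        ratio = m2.apparent_diffusion_coefficient() / m.apparent_diffusion_coefficient()
        assert ratio == pytest.approx(2.0 ** (m.d_f / (2.0 + m.d_f)), rel=1e-12)

    def test_table_dapp_round_trip(self):
        # interior row at alpha = 0.8 rebuilt as a forward model gives back D_app ~ 0.018
        m = FractalDomainModel(
            alpha=0.8, d_f=1.6364, n_nucleosomes=5000, r_rms=0.37556, d_egfp=20.6
        )
        assert m.apparent_diffusion_coefficient() == pytest.approx(0.018, rel=2e-3)
        assert m.subdiffusion_exponent() == pytest.approx(0.44, abs=1e-4)


class TestModeSumOracle:
    def test_zero_at_time_zero(self, interior_model):
        assert interior_model.msd_mode_sum(0.0, max_modes=100) == 0.0

    def test_long_time_plateau_without_com(self, interior_model):
        m = interior_model
        tau = m.relaxation_time()
        p = np.arange(1, 2001)
        plateau = 4.0 * np.sum(m.mode_variance(p))
        val = m.msd_mode_sum(500.0 * tau, max_modes=2000, kernel="exp", include_com=False)
        assert val == pytest.approx(plateau, rel=1e-6)

    def test_short_time_effective_exponent(self, interior_model):
        m = interior_model
        tau = m.relaxation_time()
        t = tau * np.logspace(-5, -4, 6)
        with np.errstate(all="ignore"):
            y = m.msd_mode_sum(t, max_modes=100000, kernel="exp", include_com=False)
        slope = np.polyfit(np.log(t), np.log(y), 1)[0]
        assert slope == pytest.approx(m.subdiffusion_exponent(), abs=0.02)

    def test_asymptotic_agreement_in_validity_window(self, interior_model):
        """Closed form vs brute-force mode sum: 5% up to 0.01 tau, 10% up to 0.05 tau.

        The closed-form short-time law degrades smoothly as the slowest modes
        start to relax; the crossover deviation is ~3% at t = 0.01 tau and
        ~7% at t = 0.05 tau for these parameters.
        """
        m = interior_model
        tau = m.relaxation_time()
        t = tau * np.logspace(-3, np.log10(0.05), 8)
        num = m.msd_mode_sum(t, max_modes=4000, kernel="exp", include_com=False)
        ratio = num / m.internal_msd_asymptotic(t)
        assert np.all(np.abs(ratio[t <= 0.01 * tau] - 1.0) < 0.05)
        assert np.all(np.abs(ratio - 1.0) < 0.10)
        # the deviation is a deficit (the sum lags the pure power law)
        assert np.all(ratio < 1.0)

    def test_fixed_bead_cosine_weights(self, interior_model):
        # the middle bead couples only to even modes; with two modes the odd
        # term vanishes so the fixed-bead sum is below the position average
        m = interior_model
        t = m.relaxation_time() * 0.01
        mid = m.msd_mode_sum(t, bead_index=m.n_nucleosomes / 2, max_modes=2, include_com=False, kernel="exp")
        avg = m.msd_mode_sum(t, bead_index="averaged", max_modes=2, include_com=False, kernel="exp")
        assert mid < avg

    def test_truncation_warning(self, interior_model):
        with pytest.warns(UserWarning, match="truncation"):
            interior_model.msd_mode_sum(1e-5, max_modes=5, kernel="exp")
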