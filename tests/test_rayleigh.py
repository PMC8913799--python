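"""Surface-wave solver: printed-limit checks, symmetry, convergence, caching."""

import numpy as np
import pytest

from nitiwave import (
    NITIParameters,
    NoRootError,
    default_angle_grid,
    rayleigh_curve,
    rayleigh_speed,
    secular_residual,
)
from nitiwave.rayleigh import _upper_speed, fold_angle, speed_profile

KPA = 1e3
RHO = 1000.0
ISO_RAYLEIGH = 0.9553  # incompressible isotropic c_R / sqrt(mu/rho)


@pytest.fixture(scope="module")
def iso():
    return NITIParameters(mu=3 * KPA, G=3 * KPA, delta=0.0, rho=RHO).with_lambda_ratio(1e6)


class TestIsotropicLimit:
    def test_printed_constant_all_angles(self, iso):
        """Isotropic incompressible half-space: c_R = 0.9553*sqrt(mu/rho), flat in theta."""
        cs = np.sqrt(iso.mu / iso.rho)
        speeds = [rayleigh_speed(iso, th) for th in (0.0, 20.0, 45.0, 71.0, 90.0)]
        for v in speeds:
            assert v / cs == pytest.approx(ISO_RAYLEIGH, abs=5e-4)
        assert (max(speeds) - min(speeds)) / np.mean(speeds) < 1e-3

    def test_flat_curve(self, iso):
        curve = rayleigh_curve(iso, alpha=0.0)
        assert np.ptp(curve.speeds) / curve.speeds.mean() < 1e-3
        assert curve.speeds.mean() == pytest.approx(0.9553 * np.sqrt(3.0), abs=2e-3)


class TestAcrossFiberLimit:
    @pytest.mark.parametrize("g_ratio,d_ratio", [(0.5, 0.0), (1.0, 2.0), (3.0, 8.0), (10.0, 20.0)])
    def test_speed_at_90_depends_only_on_mu(self, g_ratio, d_ratio):
        """Across the fibers c_R = 0.9553*sqrt(mu/rho) regardless of G and delta."""
        p = NITIParameters(mu=2 * KPA, G=g_ratio * 2 * KPA, delta=d_ratio * 2 * KPA, rho=RHO)
        ratio = rayleigh_speed(p, 90.0) / np.sqrt(p.mu / p.rho)
        assert ratio == pytest.approx(ISO_RAYLEIGH, abs=5e-4)


class TestFastAxisBounds:
    def test_speed_below_sqrt_G_over_rho(self):
        """The Rayleigh speed never exceeds sqrt(G/rho) in a fast-axis medium."""
        for g_ratio, d_ratio in [(2.0, 1.0), (3.0, 5.0), (5.0, 20.0)]:
            p = NITIParameters(mu=KPA, G=g_ratio * KPA, delta=d_ratio * KPA, rho=RHO)
            cap = np.sqrt(p.G / p.rho)
            prof = speed_profile(g_ratio, d_ratio)
            speeds = np.sqrt(p.mu / p.rho) * prof(np.arange(0.0, 90.1, 5.0))
            assert np.all(speeds < cap)

    def test_strong_delta_approaches_shear_curve(self):
        """As delta/mu grows the Rayleigh curve converges onto the shear curve.

        The floor of the gap is the exact 1 - 0.9553 = 4.5% offset at 90 deg,
        so convergence is asserted as monotone shrinkage toward that floor.
        """
        from nitiwave import shear_speed_closed_form

        thetas = np.arange(0.0, 90.1, 10.0)

        def max_gap(d_ratio):
            p = NITIParameters(mu=KPA, G=3 * KPA, delta=d_ratio * KPA, rho=RHO)
            cr = np.array([rayleigh_speed(p, th) for th in thetas])
            cs = shear_speed_closed_form(p, thetas)
            return np.max(np.abs(cr - cs) / cs)

        g5, g20 = max_gap(5.0), max_gap(20.0)
        assert g20 < g5
        assert g20 <= 0.06  # measured 5.45%; floor is 4.5%

    def test_45_deg_weakly_depends_on_G(self):
        """c_R(45 deg) ~ c_qS(45 deg), independent of G, when delta < 2*(G - mu).

        Under that premise the quasi-shear branch is the slowest coupled
        branch at 45 deg and pins the Rayleigh speed; at G = mu the pure
        shear branch takes over and the independence genuinely breaks.
        """
        speeds = [
            rayleigh_speed(NITIParameters(mu=KPA, G=g * KPA, delta=0.5 * KPA, rho=RHO), 45.0)
            for g in (2.0, 3.0, 5.0)
        ]
        assert (max(speeds) - min(speeds)) / min(speeds) <= 0.02
        # and the value it pins to is the G-free quasi-shear speed
        assert speeds[-1] == pytest.approx(np.sqrt((KPA + 0.5 * KPA / 4) / RHO), rel=0.01)


class TestSolverContract:
    def test_lambda_convergence(self):
        p5 = NITIParameters(mu=2 * KPA, G=6 * KPA, delta=8 * KPA, rho=RHO).with_lambda_ratio(1e5)
        p6 = NITIParameters(mu=2 * KPA, G=6 * KPA, delta=8 * KPA, rho=RHO).with_lambda_ratio(1e6)
        for th in (0.0, 30.0, 60.0, 90.0):
            assert rayleigh_speed(p5, th) == pytest.approx(rayleigh_speed(p6, th), rel=1e-4)

    def test_residual_brackets_root(self, iso):
        """Residual is positive at low speed, negative near the cutoff, ~0 at the root."""
        v_up = _upper_speed(iso, 0.0)
        assert secular_residual(iso, 0.0, 0.2 * v_up) > 0
        assert secular_residual(iso, 0.0, v_up * (1 - 1e-9)) < 0
        root = rayleigh_speed(iso, 0.0)
        scale = abs(secular_residual(iso, 0.0, 0.5 * v_up))
        assert abs(secular_residual(iso, 0.0, root)) < 1e-5 * scale

    def test_residual_even_in_theta(self):
        p = NITIParameters(mu=2 * KPA, G=6 * KPA, delta=8 * KPA, rho=RHO)
        v = 0.8 * _upper_speed(p, 37.0)
        assert secular_residual(p, 37.0, v) == pytest.approx(
            secular_residual(p, -37.0, v), rel=1e-10
        )

    def test_near_cutoff_root_found(self):
        """delta < G regime: the root hugging the quasi-shear cutoff is still found."""
        p = NITIParameters(mu=KPA, G=2.6 * KPA, delta=1 * KPA, rho=RHO)
        v = rayleigh_speed(p, 40.0)
        assert 0 < v <= _upper_speed(p, 40.0) * (1 + 1e-9)

    def test_angle_symmetry(self):
        p = NITIParameters(mu=2 * KPA, G=6 * KPA, delta=8 * KPA, rho=RHO)
        v = rayleigh_speed(p, 25.0)
        assert rayleigh_speed(p, -25.0) == pytest.approx(v, rel=1e-6)
        assert rayleigh_speed(p, 155.0) == pytest.approx(v, rel=1e-6)


class TestCurve:
    def test_default_grid_is_13_angles(self):
        grid = default_angle_grid()
        assert grid.size == 13
        np.testing.assert_allclose(grid, np.arange(-90.0, 91.0, 15.0))

    def test_curve_extremum_at_alpha(self, skin_like_params):
        """With the axis at +10 deg the fast direction shows up near scan angle 10."""
        angles = np.arange(-90.0, 90.1, 5.0)
        curve = rayleigh_curve(skin_like_params, alpha=10.0, angles=angles, method="spline")
        assert angles[np.argmax(curve.speeds)] == pytest.approx(10.0, abs=5.0)

    def test_spline_cache_matches_direct(self, skin_like_params):
        """Cached-profile interpolation error stays under the 0.1% budget."""
        p = skin_like_params
        prof = speed_profile(p.G / p.mu, p.delta / p.mu)
        scale = np.sqrt(p.mu / p.rho)
        for th in (2.3, 17.7, 33.1, 48.9, 62.3, 77.7, 88.1):
            direct = rayleigh_speed(NITIParameters(mu=1.0, G=p.G / p.mu, delta=p.delta / p.mu, rho=1.0), th)
            assert abs(prof(th) - direct) / direct < 1e-3

    def test_fold_angle(self):
        np.testing.assert_allclose(fold_angle([-10.0, 100.0, 180.0, -135.0]), [10.0, 80.0, 0.0, 45.0])

    def test_warm_bracket_matches_cold_scan(self):
        """A warm bracket around the root reproduces the cold-scan solution."""
        p = NITIParameters(mu=2 * KPA, G=6 * KPA, delta=8 * KPA, rho=RHO)
        cold = rayleigh_speed(p, 30.0)
        warm = rayleigh_speed(p, 30.0, bracket=(0.9 * cold, 1.1 * cold))
        assert warm == pytest.approx(cold, rel=1e-7)
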