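"""Moduli inversion: round-trip recovery, LOO-CV, diagnostics."""

import warnings

import numpy as np
import pytest

from conftest import make_noisy_scan
from nitiwave import (
    AngleScan,
    NITIParameters,
    RayleighAnisotropyModel,
    UnidentifiableAxisWarning,
    derived_anisotropy,
    fit_angle_scan,
    loo_cv,
    rayleigh_curve,
)

KPA = 1e3
RHO = 1000.0


def synth_scan(mu_kpa, g_ratio, d_ratio, alpha):
    p = NITIParameters(mu=mu_kpa * KPA, G=g_ratio * mu_kpa * KPA,
                       delta=d_ratio * mu_kpa * KPA, rho=RHO)
    curve = rayleigh_curve(p, alpha=alpha)
    return AngleScan(curve.angles, curve.speeds), p


class TestRoundTrip:
    def test_reference_case(self, noiseless_scan):
        """mu=2, G=6, delta=8 kPa, alpha=10 deg recovered within 1% noiseless."""
        res = RayleighAnisotropyModel(noiseless_scan, rho=RHO).fit()
        assert res.mu == pytest.approx(2 * KPA, rel=0.01)
        assert res.G == pytest.approx(6 * KPA, rel=0.01)
        assert res.delta == pytest.approx(8 * KPA, rel=0.01)
        assert res.alpha == pytest.approx(10.0, abs=0.5)
        assert res.rmse < 1e-4

    # 27 material points with alpha cycled over the three target offsets.
    GRID = [
        (mu, g, d, alpha)
        for i, (mu, g, d) in enumerate(
            (mu, g, d)
            for mu in (1.0, 2.0, 4.0)
            for g in (1.5, 3.0, 6.0)
            for d in (0.5, 3.0, 8.0)
        )
        for alpha in ([-60.0, 10.0, 45.0][i % 3],)
    ]

    @pytest.mark.parametrize("mu,g,d,alpha", GRID)
    def test_recovery_grid(self, mu, g, d, alpha):
        """Noiseless forward->fit identity across the parameter grid."""
        scan, truth = synth_scan(mu, g, d, alpha)
        model = RayleighAnisotropyModel(scan, rho=RHO)
        res = model.fit(n_restarts=2)
        assert res.mu == pytest.approx(truth.mu, rel=0.01)
        assert res.G == pytest.approx(truth.G, rel=0.01)
        assert res.delta == pytest.approx(truth.delta, rel=0.01, abs=0.01 * truth.mu)
        from nitiwave.psoct import compare_axes

        assert compare_axes(res.alpha, alpha) < 1.0
        # no spurious better optimum missed: cost at truth >= cost at optimum
        x_true = np.array([truth.mu / KPA, truth.G / KPA, truth.delta / KPA, alpha])
        cost_true = np.sum(model._residuals(x_true) ** 2)
        x_fit = np.array([res.mu / KPA, res.G / KPA, res.delta / KPA, res.alpha])
        cost_fit = np.sum(model._residuals(x_fit) ** 2)
        assert cost_fit <= cost_true + 1e-10

    def test_alpha_mod_180(self):
        """Scans generated with alpha and alpha + 180 deg fit identically."""
        scan_a, _ = synth_scan(2.0, 3.0, 4.0, 25.0)
        scan_b, _ = synth_scan(2.0, 3.0, 4.0, 205.0)
        np.testing.assert_allclose(scan_a.speeds, scan_b.speeds, rtol=1e-9)
        res = RayleighAnisotropyModel(scan_b, rho=RHO).fit(n_restarts=1)
        assert res.alpha == pytest.approx(25.0, abs=0.5)

    def test_isotropic_scan_warns_unidentifiable(self):
        p = NITIParameters(mu=2 * KPA, G=2 * KPA, delta=0.0, rho=RHO)
        curve = rayleigh_curve(p, alpha=0.0)
        scan = AngleScan(curve.angles, curve.speeds)
        model = RayleighAnisotropyModel(scan, rho=RHO)
        with pytest.warns(UnidentifiableAxisWarning):
            res = model.fit(n_restarts=1)
        assert res.result.shear_anisotropy == pytest.approx(1.0, abs=0.05)
        assert res.result.delta_ratio == pytest.approx(0.0, abs=0.05)

    def test_noisy_monte_carlo_short(self, noiseless_scan):
        """3% speed noise, 20 seeds: median mu error <= 5%, alpha error <= 3 deg.

        (The full 100-seed study runs in the acceptance suite.)
        """
        mu_err, al_err = [], []
        for seed in range(20):
            noisy = make_noisy_scan(noiseless_scan, 0.03, seed)
            res = RayleighAnisotropyModel(noisy, rho=RHO).fit(n_restarts=1)
            mu_err.append(abs(res.mu - 2 * KPA) / (2 * KPA))
            al_err.append(abs((res.alpha - 10.0 + 90.0) % 180.0 - 90.0))
        assert np.median(mu_err) <= 0.05
        assert np.median(al_err) <= 3.0


class TestLOOCV:
    def test_noiseless_loo_zero_spread(self, noiseless_scan):
        """13 folds on a noiseless scan: sd ~ 0, mean = full fit."""
        res = RayleighAnisotropyModel(noiseless_scan, rho=RHO).fit(n_restarts=1).loo()
        r = res.result
        assert r.n_loo_fits == 13
        for name, full in (("mu", r.mu), ("G", r.G), ("delta", r.delta)):
            assert r.loo_sd[name] <= 1e-5 * max(abs(full), KPA)
            assert r.loo_mean[name] == pytest.approx(full, rel=1e-4)
        assert r.loo_sd["alpha"] < 1e-3

    def test_loo_mean_close_to_full_fit_with_noise(self, noiseless_scan):
        noisy = make_noisy_scan(noiseless_scan, 0.02, seed=3)
        res = RayleighAnisotropyModel(noisy, rho=RHO).fit(n_restarts=1).loo()
        r = res.result
        assert r.loo_mean["mu"] == pytest.approx(r.mu, rel=0.05)
        assert abs(r.loo_mean["alpha"] - r.alpha) < 2.0

    def test_loo_sd_tracks_monte_carlo_spread(self, noiseless_scan):
        """LOO sd of alpha has the same order as the seeded-repetition spread."""
        alphas = []
        for seed in range(12):
            noisy = make_noisy_scan(noiseless_scan, 0.03, 100 + seed)
            alphas.append(RayleighAnisotropyModel(noisy, rho=RHO).fit(n_restarts=1).alpha)
        mc_spread = np.std(alphas, ddof=1)
        res = (
            RayleighAnisotropyModel(make_noisy_scan(noiseless_scan, 0.03, 200), rho=RHO)
            .fit(n_restarts=1)
            .loo()
        )
        ratio = res.result.loo_sd["alpha"] / mc_spread
        assert 0.1 < ratio < 10.0

    def test_functional_wrapper_requires_7_points(self, noiseless_scan):
        small = AngleScan(noiseless_scan.angles[:6], noiseless_scan.speeds[:6])
        with pytest.raises(ValueError, match="7"):
            loo_cv(small, rho=RHO)


class TestInterfaces:
    def test_scan_validation(self):
        with pytest.raises(ValueError, match="6 distinct"):
            AngleScan(np.array([0.0, 15, 30, 45, 60.0]), np.full(5, 2.0))
        with pytest.raises(ValueError, match="positive"):
            AngleScan(np.arange(-90.0, 91, 15), np.full(13, -1.0))

    def test_fit_angle_scan_wrapper(self, noiseless_scan):
        fr = fit_angle_scan(noiseless_scan, rho=RHO, n_restarts=1)
        assert fr.mu == pytest.approx(2 * KPA, rel=0.01)
        d = fr.to_dict()
        assert d["EL_over_ET"] == pytest.approx(2.0, rel=0.01)

    def test_derived_anisotropy(self):
        fr = fit_angle_scan(
            AngleScan(*_curve_arrays(NITIParameters(mu=KPA, G=3 * KPA, delta=4 * KPA, rho=RHO))),
            rho=RHO,
            n_restarts=1,
        )
        out = derived_anisotropy(fr)
        assert out["EL_over_ET"] == pytest.approx(2.0, rel=0.02)
        assert out["flags"] == []

    def test_summary_mentions_all_parameters(self, noiseless_scan):
        res = RayleighAnisotropyModel(noiseless_scan, rho=RHO).fit(n_restarts=1)
        text = res.summary()
        for token in ("mu (kPa)", "G (kPa)", "delta (kPa)", "alpha (deg)", "E_L/E_T"):
            assert token in text


def _curve_arrays(p, alpha=0.0):
    c = rayleigh_curve(p, alpha=alpha)
    return c.angles, c.speeds
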