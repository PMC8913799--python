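"""Four-parameter NITI moduli inversion from angle-resolved surface-wave speeds.

The observable is an :class:`AngleScan` — Rayleigh-wave group velocities at a
set of propagation directions in the scan frame (default 13 directions,
−90° to +90° in 15° steps). The model is the angle-dependent NITI Rayleigh
phase-velocity curve, and the fit estimates

* ``mu``    — in-plane shear modulus (Pa),
* ``G``     — out-of-plane shear modulus (Pa),
* ``delta`` — tensile-anisotropy parameter (Pa),
* ``alpha`` — symmetry-axis (fiber) orientation in the scan frame (degrees,
  identified only mod 180° and folded into (−90°, 90°]).

Uncertainty is quantified by leave-one-out cross-validation: N refits each
omitting one angle; the per-parameter mean and standard deviation across
folds are the reported estimate and its spread.

A documented caveat: measured group velocities are fitted against the
phase-velocity curve. For off-symmetry directions in an anisotropic medium
the two can differ; the approach mirrors how nondispersive skin wavefields
are analysed in practice, where the distinction is within measurement noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .material import EngineeringModuli, NITIParameters, engineering_moduli, validate_parameters
from .rayleigh import fold_angle, default_angle_grid, speed_profile

__all__ = [
    "AngleScan",
    "FitResult",
    "RayleighAnisotropyModel",
    "RayleighAnisotropyResults",
    "fit_angle_scan",
    "loo_cv",
    "derived_anisotropy",
    "UnidentifiableAxisWarning",
    "InversionError",
]

#: Default box bounds, kPa and degrees: (mu, G, delta, alpha).
DEFAULT_BOUNDS = ((0.01, 1000.0), (0.01, 1000.0), (0.0, 10000.0), (-90.0, 90.0))

#: The isotropic incompressible Rayleigh-to-shear speed ratio, used to seed
#: the optimizer from the scan's speed extremes.
RAYLEIGH_FACTOR = 0.9553


class InversionError(RuntimeError):
    """Fit did not converge; the best iterate is attached as ``best``."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class UnidentifiableAxisWarning(UserWarning):
    """The scan is too flat for the axis angle alpha to be identifiable."""


def fold_orientation(deg: float) -> float:
    """Fold a 180°-periodic orientation into (−90°, 90°]."""
    a = (float(deg) + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


@dataclass(frozen=True)
class AngleScan:
    """Angle-resolved surface-wave speeds (the inversion's observable)."""

    angles: np.ndarray       # degrees, scan frame
    speeds: np.ndarray       # m/s
    sd: np.ndarray | None = None  # m/s, optional per-angle standard deviation

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        s = np.asarray(self.speeds, dtype=float)
        if a.shape != s.shape or a.ndim != 1:
            raise ValueError("angles and speeds must be matching 1-D arrays")
        if np.unique(a).size < 6:
            raise ValueError(
                f"need >= 6 distinct angles for a 4-parameter fit (got {np.unique(a).size})"
            )
        if not np.all(s > 0):
            raise ValueError("all speeds must be positive")
        sd = self.sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != a.shape:
                raise ValueError("sd must match angles")
            if not np.all(sd > 0):
                raise ValueError("sd values must be positive")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "speeds", s)
        object.__setattr__(self, "sd", sd)

    @classmethod
    def default_grid(cls, speeds, sd=None) -> "AngleScan":
        """Scan on the standard 13-angle grid (−90°:15°:+90°)."""
        return cls(default_angle_grid(), np.asarray(speeds, dtype=float), sd)

    def drop(self, i: int) -> "AngleScan":
        keep = np.arange(self.angles.size) != i
        return AngleScan(
            self.angles[keep],
            self.speeds[keep],
            None if self.sd is None else self.sd[keep],
        )


@dataclass(frozen=True)
class FitResult:
    """Fitted NITI parameters with diagnostics and optional LOO statistics.

    Moduli are in Pa; ``alpha`` in degrees folded into (−90°, 90°].
    ``loo_mean``/``loo_sd`` are dicts keyed by parameter name, populated by
    LOO-CV (the LOO mean is then the reported estimate of record).
    """

    mu: float
    G: float
    delta: float
    alpha: float
    rho: float
    rmse: float
    success: bool
    nfev: int
    message: str = ""
    validity_flags: tuple[str, ...] = ()
    loo_mean: dict | None = None
    loo_sd: dict | None = None
    n_loo_fits: int = 0

    @property
    def params(self) -> NITIParameters:
        return NITIParameters(mu=self.mu, G=self.G, delta=self.delta, rho=self.rho)

    @property
    def shear_anisotropy(self) -> float:
        return self.G / self.mu

    @property
    def delta_ratio(self) -> float:
        return self.delta / self.mu

    @property
    def tensile_anisotropy(self) -> float:
        m = engineering_moduli(self.params)
        return m.E_L / m.E_T

    def to_dict(self) -> dict:
        m = engineering_moduli(self.params)
        return {
            "mu_kPa": self.mu / 1e3,
            "G_kPa": self.G / 1e3,
            "delta_kPa": self.delta / 1e3,
            "alpha_deg": self.alpha,
            "rho_kg_m3": self.rho,
            "G_over_mu": self.shear_anisotropy,
            "delta_over_mu": self.delta_ratio,
            "E_L_kPa": m.E_L / 1e3,
            "E_T_kPa": m.E_T / 1e3,
            "EL_over_ET": m.E_L / m.E_T,
            "rmse_m_s": self.rmse,
            "success": bool(self.success),
            "nfev": int(self.nfev),
            "message": self.message,
            "validity_flags": list(self.validity_flags),
            "loo_mean": self.loo_mean,
            "loo_sd": self.loo_sd,
            "n_loo_fits": int(self.n_loo_fits),
        }


class RayleighAnisotropyModel:
    """Model of angle-dependent Rayleigh speed on a NITI half-space.

    Parameters
    ----------
    scan : AngleScan
        Observed speeds per scan-frame angle.
    rho : float
        Assumed tissue density, kg/m³.
    weighted : bool
        Weight residuals by 1/sd when the scan provides sd.
    delta_nonneg : bool
        Constrain delta >= 0 (fast-axis material). Disabling emits a
        slow-axis warning and opens the lower bound.

    Examples
    --------
    >>> model = RayleighAnisotropyModel(scan, rho=1000.0)
    >>> res = model.fit()
    >>> res = res.loo()          # adds leave-one-out statistics
    >>> print(res.summary())
    """

    def __init__(
        self,
        scan: AngleScan,
        rho: float = 1000.0,
        *,
        weighted: bool = True,
        delta_nonneg: bool = True,
    ):
        if rho <= 0:
            raise ValueError("rho must be positive")
        self.scan = scan
        self.rho = float(rho)
        self.weighted = weighted and scan.sd is not None
        self.delta_nonneg = delta_nonneg
        if not delta_nonneg:
            warnings.warn(
                "slow-axis mode: delta allowed negative; validity constraints may flag the fit",
                stacklevel=2,
            )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dataframe(cls, df, rho: float = 1000.0, **kw) -> "RayleighAnisotropyModel":
        """Build from a DataFrame with columns angle_deg, speed_m_s[, sd_m_s]."""
        from .io import angle_scan_from_dataframe

        return cls(angle_scan_from_dataframe(df), rho=rho, **kw)

    @classmethod
    def from_csv(cls, path, rho: float = 1000.0, **kw) -> "RayleighAnisotropyModel":
        from .io import read_angle_scan

        return cls(read_angle_scan(path), rho=rho, **kw)

    # -- forward model -------------------------------------------------------

    def predict(self, x: np.ndarray, angles=None) -> np.ndarray:
        """Model speeds at scan angles for x = (mu_kPa, G_kPa, delta_kPa, alpha_deg)."""
        mu, G, delta, alpha = x
        if angles is None:
            angles = self.scan.angles
        prof = speed_profile(G / mu, delta / mu)
        theta = fold_angle(np.asarray(angles, dtype=float) - alpha)
        return np.sqrt(mu * 1e3 / self.rho) * prof(theta)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        r = self.predict(x) - self.scan.speeds
        if self.weighted:
            r = r / self.scan.sd
        return r

    def _initial_guess(self) -> np.ndarray:
        s = self.scan
        alpha0 = fold_orientation(s.angles[int(np.argmax(s.speeds))])
        c_min, c_max = float(s.speeds.min()), float(s.speeds.max())
        mu0 = self.rho * (c_min / RAYLEIGH_FACTOR) ** 2 / 1e3   # kPa
        G0 = self.rho * (c_max / RAYLEIGH_FACTOR) ** 2 / 1e3
        return np.array([mu0, max(G0, 1.01 * mu0), mu0, alpha0])

    def _check_identifiability(self) -> None:
        s = self.scan
        spread = float(s.speeds.max() - s.speeds.min())
        floor = 0.01 * float(s.speeds.mean())
        if s.sd is not None:
            floor = max(floor, 2.0 * float(np.median(s.sd)))
        if spread < floor:
            warnings.warn(
                f"speed range {spread:.3g} m/s is below the identifiability floor "
                f"{floor:.3g} m/s: the axis angle alpha is not identifiable",
                UnidentifiableAxisWarning,
                stacklevel=3,
            )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        init: np.ndarray | None = None,
        bounds=DEFAULT_BOUNDS,
        n_restarts: int = 5,
        seed: int | None = 0,
    ) -> "RayleighAnisotropyResults":
        """Bounded least-squares fit of (mu, G, delta, alpha).

        The cost surface is 180°-periodic in alpha, so the fit restarts
        ``n_restarts`` times with alpha jittered by up to ±30° around the
        max-speed heuristic and returns the best optimum.

        Raises
        ------
        InversionError
            If no restart converges; the best iterate is attached.
        """
        self._check_identifiability()
        x0 = np.asarray(init, dtype=float) if init is not None else self._initial_guess()
        lo = np.array([b[0] for b in bounds], dtype=float)
        hi = np.array([b[1] for b in bounds], dtype=float)
        if not self.delta_nonneg:
            lo[2] = -hi[2]
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

        rng = np.random.default_rng(seed)
        jitters = [0.0] + list(rng.uniform(-30.0, 30.0, size=max(0, n_restarts - 1)))
        best = None
        for dj in jitters:
            xi = x0.copy()
            xi[3] = np.clip(fold_orientation(x0[3] + dj), lo[3] + 1e-9, hi[3] - 1e-9)
            try:
                sol = least_squares(
                    self._residuals,
                    xi,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale=np.array([1.0, 1.0, 1.0, 10.0]),
                    xtol=1e-10,
                    ftol=1e-10,
                    gtol=1e-10,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise InversionError("all restarts failed", best=None)
        if not best.success:
            raise InversionError(f"fit did not converge: {best.message}", best=best)
        return self._package(best)

    def _package(self, sol) -> "RayleighAnisotropyResults":
        mu, G, delta, alpha = sol.x
        resid = self.predict(sol.x) - self.scan.speeds
        rmse = float(np.sqrt(np.mean(resid**2)))
        p = NITIParameters(mu=mu * 1e3, G=G * 1e3, delta=delta * 1e3, rho=self.rho)
        flags = tuple(validate_parameters(p))
        fr = FitResult(
            mu=mu * 1e3,
            G=G * 1e3,
            delta=delta * 1e3,
            alpha=fold_orientation(alpha),
            rho=self.rho,
            rmse=rmse,
            success=bool(sol.success),
            nfev=int(sol.nfev),
            message=str(sol.message),
            validity_flags=flags,
        )
        return RayleighAnisotropyResults(self, fr)


class RayleighAnisotropyResults:
    """Results wrapper: estimates, derived anisotropy ratios, LOO-CV, summary."""

    def __init__(self, model: RayleighAnisotropyModel, result: FitResult):
        self.model = model
        self.result = result

    # convenience accessors, kPa / degrees at the interface
    @property
    def mu(self) -> float:
        return self.result.mu

    @property
    def G(self) -> float:
        return self.result.G

    @property
    def delta(self) -> float:
        return self.result.delta

    @property
    def alpha(self) -> float:
        return self.result.alpha

    @property
    def rmse(self) -> float:
        return self.result.rmse

    @property
    def moduli(self) -> EngineeringModuli:
        return engineering_moduli(self.result.params)

    def predict(self, angles=None) -> np.ndarray:
        x = np.array([self.mu / 1e3, self.G / 1e3, self.delta / 1e3, self.alpha])
        return self.model.predict(x, angles=angles)

    def loo(self, max_failed_fraction: float = 0.2) -> "RayleighAnisotropyResults":
        """Leave-one-out cross-validation: N refits, each omitting one angle.

        Returns a new results object whose ``loo_mean``/``loo_sd`` carry the
        per-parameter statistics over the N folds; each fold is warm-started
        at the full fit. Fails only if more than ``max_failed_fraction`` of
        folds fail. Alpha statistics are computed on differences folded
        around the full-fit alpha, so wrap-around near ±90° cannot bias them.
        """
        scan = self.model.scan
        n = scan.angles.size
        warm = np.array([self.mu / 1e3, self.G / 1e3, self.delta / 1e3, self.alpha])
        rows = []
        failures = []
        for i in range(n):
            sub = RayleighAnisotropyModel(
                scan.drop(i),
                rho=self.model.rho,
                weighted=self.model.weighted,
                delta_nonneg=self.model.delta_nonneg,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UnidentifiableAxisWarning)
                    r = sub.fit(init=warm, n_restarts=1).result
            except InversionError as exc:
                failures.append((i, str(exc)))
                continue
            alpha_rel = self.alpha + ((r.alpha - self.alpha + 90.0) % 180.0 - 90.0)
            rows.append((r.mu, r.G, r.delta, alpha_rel))
        if len(failures) > max_failed_fraction * n:
            raise InversionError(
                f"{len(failures)}/{n} LOO folds failed: {failures}", best=self.result
            )
        arr = np.array(rows)
        names = ("mu", "G", "delta", "alpha")
        loo_mean = {k: float(v) for k, v in zip(names, arr.mean(axis=0))}
        loo_sd = {k: float(v) for k, v in zip(names, arr.std(axis=0, ddof=1))}
        loo_mean["alpha"] = fold_orientation(loo_mean["alpha"])
        new = replace(
            self.result, loo_mean=loo_mean, loo_sd=loo_sd, n_loo_fits=len(rows)
        )
        return RayleighAnisotropyResults(self.model, new)

    def summary(self) -> str:
        r = self.result
        m = self.moduli
        lines = [
            "NITI Rayleigh anisotropy fit",
            "=" * 46,
            f"{'n angles':<22}{self.model.scan.angles.size:>10d}",
            f"{'rho (kg/m^3)':<22}{r.rho:>10.1f}",
            f"{'rmse (m/s)':<22}{r.rmse:>10.4f}",
            "-" * 46,
            f"{'mu (kPa)':<22}{r.mu / 1e3:>10.3f}",
            f"{'G (kPa)':<22}{r.G / 1e3:>10.3f}",
            f"{'delta (kPa)':<22}{r.delta / 1e3:>10.3f}",
            f"{'alpha (deg)':<22}{r.alpha:>10.2f}",
            "-" * 46,
            f"{'G/mu':<22}{r.shear_anisotropy:>10.3f}",
            f"{'delta/mu':<22}{r.delta_ratio:>10.3f}",
            f"{'E_L (kPa)':<22}{m.E_L / 1e3:>10.3f}",
            f"{'E_T (kPa)':<22}{m.E_T / 1e3:>10.3f}",
            f"{'E_L/E_T':<22}{m.E_L / m.E_T:>10.3f}",
        ]
        if r.loo_mean is not None:
            lines.append("-" * 46)
            lines.append(f"LOO-CV over {r.n_loo_fits} folds (mean +/- sd):")
            for k, unit, scale in (
                ("mu", "kPa", 1e3), ("G", "kPa", 1e3),
                ("delta", "kPa", 1e3), ("alpha", "deg", 1.0),
            ):
                lines.append(
                    f"{k + ' (' + unit + ')':<22}"
                    f"{r.loo_mean[k] / scale:>10.3f} +/- {r.loo_sd[k] / scale:.3f}"
                )
        if r.validity_flags:
            lines.append("-" * 46)
            lines.append("validity flags:")
            lines.extend(f"  {f}" for f in r.validity_flags)
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Functional wrappers
# ----------------------------------------------------------------------

def fit_angle_scan(
    scan: AngleScan,
    rho: float = 1000.0,
    bounds=DEFAULT_BOUNDS,
    init: np.ndarray | None = None,
    **kw,
) -> FitResult:
    """Fit a scan and return the bare :class:`FitResult`."""
    model = RayleighAnisotropyModel(scan, rho=rho)
    return model.fit(init=init, bounds=bounds, **kw).result


def loo_cv(scan: AngleScan, rho: float = 1000.0, bounds=DEFAULT_BOUNDS, **kw) -> FitResult:
    """Full fit followed by leave-one-out cross-validation statistics."""
    if scan.angles.size < 7:
        raise ValueError("LOO-CV needs at least 7 points")
    model = RayleighAnisotropyModel(scan, rho=rho)
    return model.fit(bounds=bounds, **kw).loo().result


def derived_anisotropy(fit: FitResult) -> dict:
    """Engineering moduli and anisotropy ratios of a fitted parameter set.

    Validity violations are reported as flags, not raised; a delta at the
    default upper bound flags the tensile ratio as bound-limited.
    """
    m = engineering_moduli(fit.params)
    flags = list(validate_parameters(fit.params))
    if fit.delta >= DEFAULT_BOUNDS[2][1] * 1e3 * (1.0 - 1e-9):
        flags.append("delta at upper bound: E_L/E_T is bound-limited")
    return {
        "moduli": m,
        "EL_over_ET": m.E_L / m.E_T,
        "G_over_mu": fit.G / fit.mu,
        "delta_over_mu": fit.delta / fit.mu,
        "flags": flags,
    }
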