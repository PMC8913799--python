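"""Rayleigh surface-wave speed on a NITI half-space via the Stroh formalism.

The free surface is the YZ plane with depth along +X; the material symmetry
axis (fiber direction) is Z and the wave propagates in the surface at angle
θ from it, with unit normal ``n = (0, sin θ, cos θ)`` and depth direction
``m = (1, 0, 0)``. For a trial subsonic speed v the sextic Stroh eigenproblem

    N(v) ξ = p ξ,   ξ = (a, l)

yields six partial waves ``u ∝ a exp(ik(n·x + p m·x − vt))``; the three with
``Im p > 0`` decay into the half-space and ``l`` is their surface-traction
amplitude. The surface impedance ``M(v) = −i L A⁻¹`` (columns of A, L from
the decaying triplet) is Hermitian below the bulk-shear cutoff, positive
definite as v → 0, and loses definiteness exactly at the Rayleigh speed —
so ``Re det M(v)`` is a real residual with a clean sign change at c_R.

Incompressibility is approximated with a large but finite λ (see
``NITIParameters``); convergence of c_R in λ is asserted in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .bulk import christoffel_speeds
from .material import NITIParameters, build_stiffness

__all__ = [
    "NoRootError",
    "RayleighConvergenceError",
    "RayleighCurve",
    "secular_residual",
    "rayleigh_speed",
    "rayleigh_curve",
    "speed_profile",
    "fold_angle",
]

_DEPTH = np.array([1.0, 0.0, 0.0])

#: Default number of trial speeds in the coarse bracket scan.
COARSE_SCAN_POINTS = 200

#: Brent refinement relative tolerance on the speed.
ROOT_RTOL = 1e-8

#: Fractional standoff of the search bracket from the bulk-shear cutoff.
#: Kept tiny: when delta < G the Rayleigh branch hugs the quasi-shear
#: cutoff (c_R ≈ c_qS near 45°) and the root can sit within 1e-7 of it.
UPPER_MARGIN = 1e-12


class NoRootError(RuntimeError):
    """The boundary determinant has no admissible zero in the bracket."""


class RayleighConvergenceError(RuntimeError):
    """Root refinement failed to converge."""


@dataclass(frozen=True)
class RayleighCurve:
    """Angle-resolved Rayleigh speeds with per-angle solver diagnostics."""

    angles: np.ndarray          # degrees, in the caller's (scan) frame
    speeds: np.ndarray          # m/s
    residuals: np.ndarray = field(default=None, repr=False)  # det residual at root
    alpha: float = 0.0          # symmetry-axis offset used, degrees


def fold_angle(theta_deg):
    """Fold propagation angle(s) to [0°, 90°] using c(θ) = c(−θ) = c(180°−θ)."""
    t = np.asarray(theta_deg, dtype=float)
    return np.abs((t + 90.0) % 180.0 - 90.0)


def _stroh_blocks(params: NITIParameters, theta_deg: float):
    """Q, R, T contraction blocks for n(θ) in the sagittal plane, m = depth.

    The blocks are nondimensionalized by μ, and a transverse displacement
    component that decouples exactly (pure SH at the symmetry angles θ = 0°
    and 90°) is dropped: the returned blocks act on the coupled degrees of
    freedom only. Dropping it matters at θ = 90° for G < μ, where the
    decoupled out-of-plane shear branch is slower than the sagittal motion
    and would otherwise falsely truncate the subsonic bracket.
    """
    th = np.deg2rad(theta_deg)
    n = np.array([0.0, np.sin(th), np.cos(th)])
    Ct = build_stiffness(params).as_tensor() / params.mu
    Q = np.einsum("ijkl,j,l->ik", Ct, n, n)
    R = np.einsum("ijkl,j,l->ik", Ct, n, _DEPTH)
    T = np.einsum("ijkl,j,l->ik", Ct, _DEPTH, _DEPTH)
    idx = _coupled_dofs(Q, R, T)
    return Q[np.ix_(idx, idx)], R[np.ix_(idx, idx)], T[np.ix_(idx, idx)], idx


def _coupled_dofs(Q, R, T) -> list[int]:
    """Indices of displacement components coupled to the depth (x) motion."""
    scale = max(np.abs(Q).max(), np.abs(T).max())
    for d in (1, 2):  # only an in-surface transverse component can decouple
        others = [i for i in (0, 1, 2) if i != d]
        coupling = max(
            max(abs(B[i, d]) for B in (Q, R, T) for i in others),
            max(abs(B[d, i]) for B in (Q, R, T) for i in others),
        )
        if coupling < 1e-10 * scale:
            return others
    return [0, 1, 2]


def _residual_from_eig(w: np.ndarray, vec: np.ndarray) -> float:
    """Re det of the Hermitianized surface impedance from one Stroh eigenset."""
    k = w.size // 2
    sel = np.imag(w) > 0.0
    if sel.sum() != k:
        # Grazing/branch-point tie: keep the k largest Im p.
        sel = np.zeros_like(sel)
        sel[np.argsort(np.imag(w))[-k:]] = True
    A = vec[:k, sel]
    L = vec[k:, sel]
    M = -1j * (L @ np.linalg.inv(A))
    M = 0.5 * (M + M.conj().T)
    return float(np.real(np.linalg.det(M)))


def _stroh_N(Q, R, T, rho, v):
    k = Q.shape[0]
    Ti = np.linalg.inv(T)
    N = np.empty((2 * k, 2 * k))
    N[:k, :k] = -Ti @ R.T
    N[:k, k:] = Ti
    N[k:, :k] = R @ Ti @ R.T - Q + rho * v * v * np.eye(k)
    N[k:, k:] = -R @ Ti
    return N


def secular_residual(params: NITIParameters, theta_deg: float, v: float) -> float:
    """Real residual whose zero crossing in v is the Rayleigh speed.

    Built from the determinant of the Hermitian surface-impedance matrix of
    the three decaying Stroh partial waves; positive for v below c_R,
    negative above, continuous within the subsonic bracket. The entries are
    nondimensionalized by μ so magnitudes stay tame at large λ/μ.
    """
    Q, R, T, _ = _stroh_blocks(params, theta_deg)
    rho = params.rho / params.mu
    N = _stroh_N(Q, R, T, rho, v)
    w, vec = np.linalg.eig(N)
    try:
        return _residual_from_eig(w, vec)
    except np.linalg.LinAlgError:
        # Defective eigenbasis at an exact tie: nudge the trial speed.
        N = _stroh_N(Q, R, T, rho, v * (1.0 - 1e-9))
        w, vec = np.linalg.eig(N)
        return _residual_from_eig(w, vec)


def _residuals_batch(params: NITIParameters, theta_deg: float, vs: np.ndarray) -> np.ndarray:
    """Vectorized coarse scan: one batched eig call over all trial speeds."""
    Q, R, T, _ = _stroh_blocks(params, theta_deg)
    rho = params.rho / params.mu
    k = Q.shape[0]
    Ti = np.linalg.inv(T)
    nv = len(vs)
    N = np.empty((nv, 2 * k, 2 * k))
    N[:, :k, :k] = -Ti @ R.T
    N[:, :k, k:] = Ti
    N[:, k:, k:] = -R @ Ti
    base = R @ Ti @ R.T - Q
    N[:, k:, :k] = base[None] + rho * (vs**2)[:, None, None] * np.eye(k)[None]
    w, vec = np.linalg.eig(N)
    out = np.empty(nv)
    for i in range(nv):
        try:
            out[i] = _residual_from_eig(w[i], vec[i])
        except np.linalg.LinAlgError:
            out[i] = secular_residual(params, theta_deg, vs[i] * (1.0 - 1e-9))
    return out


def _upper_speed(params: NITIParameters, theta_deg: float) -> float:
    """Subsonic bracket top: just below the slowest *coupled* bulk branch.

    At the symmetry angles one transverse branch decouples from the sagittal
    problem (pure SH); it is excluded so that e.g. at θ = 90° with G < μ the
    slower out-of-plane shear wave does not truncate the bracket below the
    genuine Rayleigh root.
    """
    from .bulk import christoffel_matrix

    theta = float(fold_angle(theta_deg))
    _, _, _, idx = _stroh_blocks(params, theta)
    gamma = christoffel_matrix(params, theta)
    w, vec = np.linalg.eigh(gamma)
    speeds = np.sqrt(np.clip(w, 0.0, None) / params.rho)
    if len(idx) == 3:
        keep = np.ones(3, dtype=bool)
    else:
        d = ({0, 1, 2} - set(idx)).pop()
        keep = np.abs(vec[d, :]) <= 0.9  # exclude the d-polarized branch
        if keep.sum() != 2:  # degenerate polarizations: fall back to all
            keep = np.ones(3, dtype=bool)
    return (1.0 - UPPER_MARGIN) * float(speeds[keep].min())


def rayleigh_speed(
    params: NITIParameters,
    theta_deg: float,
    *,
    bracket: tuple[float, float] | None = None,
    n_scan: int = COARSE_SCAN_POINTS,
    return_residual: bool = False,
):
    """Rayleigh surface-wave phase speed at angle θ from the symmetry axis.

    Finds the lowest-speed zero of :func:`secular_residual` in
    ``(0, v_upper)`` with ``v_upper`` just below the slowest bulk shear
    branch at θ. A coarse scan brackets the sign change and Brent's method
    refines it to ``ROOT_RTOL`` relative.

    Parameters
    ----------
    bracket : (lo, hi), optional
        Known bracket around the root (e.g. from a neighbouring angle);
        falls back to the full scan if the residual does not change sign
        inside it.

    Raises
    ------
    NoRootError
        If no sign change exists in the subsonic bracket.
    """
    v_up = _upper_speed(params, theta_deg)

    def f(v: float) -> float:
        return secular_residual(params, theta_deg, v)

    lo = hi = None
    if bracket is not None:
        b0 = max(1e-12, min(bracket[0], v_up))
        b1 = min(bracket[1], v_up)
        if b1 > b0 and f(b0) > 0 > f(b1):
            lo, hi = b0, b1
    if lo is None:
        # Linear scan plus a geometric tail into the cutoff: near-degenerate
        # angles put the root within a ~1e-7 sliver below the shear branch.
        vs = np.concatenate([
            np.linspace(0.05 * v_up, v_up * (1.0 - 1e-3), n_scan),
            v_up * (1.0 - np.logspace(-3, -12, 28)),
        ])
        rs = _residuals_batch(params, theta_deg, vs)
        sign_change = np.where((rs[:-1] > 0) & (rs[1:] <= 0))[0]
        if len(sign_change) == 0:
            # Branch merging: over a range of (G/mu, delta/mu, theta) the
            # Rayleigh root degenerates onto the slowest coupled bulk branch
            # (the residual stays positive but vanishes at the cutoff). The
            # physical surface-wave speed is then the cutoff itself.
            scale = abs(rs[len(rs) // 2])
            if 0 <= rs[-1] < 1e-3 * scale:
                if return_residual:
                    return v_up, float(rs[-1])
                return v_up
            kmin = int(np.argmin(np.abs(rs)))
            raise NoRootError(
                f"no surface-wave root below the shear cutoff at theta={theta_deg:g} deg "
                f"(min |residual| {abs(rs[kmin]):.3g} at v={vs[kmin]:.4g} m/s)"
            )
        k = sign_change[0]  # lowest-speed root = fundamental surface mode
        lo, hi = vs[k], vs[k + 1]
    try:
        root = brentq(f, lo, hi, rtol=ROOT_RTOL, maxiter=200)
    except (ValueError, RuntimeError) as exc:
        raise RayleighConvergenceError(
            f"Brent refinement failed at theta={theta_deg:g} deg: {exc}"
        ) from exc
    if return_residual:
        return root, f(root)
    return root


def rayleigh_curve(
    params: NITIParameters,
    alpha: float = 0.0,
    angles=None,
    *,
    method: str = "direct",
) -> RayleighCurve:
    """Rayleigh speeds over a scan-frame angle grid.

    ``alpha`` is the symmetry-axis offset from the scan's zero direction:
    ``speeds[i] = c_R(angles[i] - alpha)``. The default grid is the 13-angle
    acquisition pattern −90°:15°:+90°.

    ``method='direct'`` root-finds every angle; ``method='spline'`` uses the
    cached normalized speed profile (fast path used by the inversion).
    """
    if angles is None:
        angles = default_angle_grid()
    angles = np.asarray(angles, dtype=float)
    material_angles = fold_angle(angles - alpha)
    if method == "spline":
        prof = speed_profile(params.G / params.mu, params.delta / params.mu)
        speeds = np.sqrt(params.mu / params.rho) * prof(material_angles)
        return RayleighCurve(angles, speeds, None, alpha)
    speeds = np.empty(angles.shape)
    residuals = np.empty(angles.shape)
    for i, th in enumerate(material_angles):
        try:
            speeds[i], residuals[i] = rayleigh_speed(params, th, return_residual=True)
        except (NoRootError, RayleighConvergenceError) as exc:
            raise type(exc)(f"at scan angle {angles[i]:g} deg: {exc}") from exc
    return RayleighCurve(angles, speeds, residuals, alpha)


def default_angle_grid() -> np.ndarray:
    """The 13-direction acquisition grid: −90° to +90° in 15° steps."""
    return np.arange(-90.0, 90.1, 15.0)


# ----------------------------------------------------------------------
# Cached normalized speed profile for the inversion fast path.
#
# Dimensional analysis: c_R(θ; μ, G, δ, ρ) = sqrt(μ/ρ) · f(θ; G/μ, δ/μ),
# so one profile per (G/μ, δ/μ) serves every (μ, ρ). The profile is
# computed on a 5° grid in [0°, 90°] with warm-started brackets and
# interpolated with a clamped cubic spline (dc/dθ = 0 at 0° and 90° by
# material symmetry); interpolation error is held under 0.1% by a test.
# ----------------------------------------------------------------------

_PROFILE_GRID = np.arange(0.0, 90.1, 5.0)
_PROFILE_CACHE: dict[tuple[float, float], object] = {}
_PROFILE_CACHE_MAX = 4096


def speed_profile(g_ratio: float, d_ratio: float):
    """Normalized Rayleigh speed profile f(θ) = c_R(θ)/sqrt(μ/ρ).

    Returns a callable spline over θ in [0°, 90°] (callers fold angles
    first). Cached per (G/μ, δ/μ).
    """
    from scipy.interpolate import CubicSpline

    key = (round(float(g_ratio), 12), round(float(d_ratio), 12))
    hit = _PROFILE_CACHE.get(key)
    if hit is not None:
        return hit
    ref = NITIParameters(mu=1.0, G=g_ratio, delta=d_ratio, rho=1.0)
    speeds = np.empty(_PROFILE_GRID.shape)
    prev = None
    for i, th in enumerate(_PROFILE_GRID):
        # Warm bracket from the neighbouring angle; rayleigh_speed falls back
        # to its full coarse scan if the sign change escapes the bracket.
        br = None if prev is None else (0.9 * prev, 1.1 * prev)
        speeds[i] = rayleigh_speed(ref, th, bracket=br)
        prev = speeds[i]
    spline = CubicSpline(_PROFILE_GRID, speeds, bc_type="clamped")
    if len(_PROFILE_CACHE) >= _PROFILE_CACHE_MAX:
        _PROFILE_CACHE.clear()
    _PROFILE_CACHE[key] = spline
    return spline
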