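"""Bulk plane-wave phase velocities in a NITI medium (Christoffel solution).

Propagation is restricted to the sagittal plane containing the symmetry
axis: the unit wave normal is ``n = (0, sin θ, cos θ)`` with the symmetry
axis along Z and depth along X, θ measured from the symmetry axis. Three
branches exist: quasi-longitudinal (near-constant speed for λ ≫ μ),
quasi-shear, and the pure shear wave polarized normal to the sagittal
plane. The shear branches carry the anisotropy (G/μ and δ/μ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .material import NITIParameters, build_stiffness

__all__ = [
    "BulkSpeeds",
    "christoffel_matrix",
    "christoffel_speeds",
    "shear_speed_closed_form",
    "quasi_shear_closed_form",
]

@dataclass(frozen=True)
class BulkSpeeds:
    """Phase speeds of the three bulk branches at angle(s) theta (degrees)."""

    theta: np.ndarray
    c_qL: np.ndarray
    c_qS: np.ndarray
    c_S: np.ndarray


def christoffel_matrix(params: NITIParameters, theta_deg) -> np.ndarray:
    """Christoffel matrices Γ_ik = C_ijkl n_j n_l for n = (0, sin θ, cos θ).

    Returns shape ``(..., 3, 3)`` following the broadcast shape of
    ``theta_deg``.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    n = np.stack([np.zeros_like(th), np.sin(th), np.cos(th)], axis=-1)
    Ct = build_stiffness(params).as_tensor()
    return np.einsum("ijkl,...j,...l->...ik", Ct, n, n)


def christoffel_speeds(params: NITIParameters, theta_deg) -> BulkSpeeds:
    """Solve the Christoffel eigenproblem Γu = ρc²u for the three branches.

    Branches are labelled by polarization: the eigenvector with dominant
    out-of-sagittal-plane (X) component is the pure shear wave; the two
    in-plane branches are quasi-shear (slower) and quasi-longitudinal
    (faster). Eigenvalues are clipped at zero with a tolerance of
    ``1e-9 * lam`` to absorb round-off.
    """
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    gamma = christoffel_matrix(params, theta)
    w, vec = np.linalg.eigh(gamma)
    tol = 1e-9 * params.lam
    if w.min() < -tol:
        raise ValueError(f"Christoffel matrix not positive semidefinite (min eig {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    c = np.sqrt(w / params.rho)

    c_S = np.empty(theta.shape)
    c_qS = np.empty(theta.shape)
    c_qL = np.empty(theta.shape)
    ex = np.abs(vec[..., 0, :])  # |x-component| of each eigenvector
    for idx in np.ndindex(theta.shape):
        # Most x-polarized branch is the pure shear wave; at exact shear
        # degeneracy (isotropic G = mu) any choice gives the same speed.
        which = int(np.argmax(ex[idx]))
        c_S[idx] = c[idx][which]
        others = sorted(c[idx][j] for j in range(3) if j != which)
        c_qS[idx], c_qL[idx] = others

    squeeze = np.isscalar(theta_deg) or np.ndim(theta_deg) == 0
    if squeeze:
        return BulkSpeeds(theta[0], c_qL[0], c_qS[0], c_S[0])
    return BulkSpeeds(theta, c_qL, c_qS, c_S)


def shear_speed_closed_form(params: NITIParameters, theta_deg):
    """Pure shear branch: sqrt((G cos²θ + μ sin²θ)/ρ).

    Exact at any λ — the out-of-plane polarization decouples from the
    longitudinal modes. Reduces to sqrt(G/ρ) along the fibers and
    sqrt(μ/ρ) across them.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    c2 = (params.G * np.cos(th) ** 2 + params.mu * np.sin(th) ** 2) / params.rho
    return np.sqrt(c2)


def quasi_shear_closed_form(params: NITIParameters, theta_deg):
    """Quasi-shear branch in the incompressible limit.

    c_qS(θ) = sqrt((G cos²2θ + (μ + δ/4) sin²2θ)/ρ): 90°-periodic, equal to
    sqrt(G/ρ) along and across the fibers and to sqrt((μ + δ/4)/ρ) at 45°,
    where it is independent of G. Valid only for λ ≫ μ; checked against the
    finite-λ Christoffel solution in the tests.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    c2 = (
        params.G * np.cos(2.0 * th) ** 2
        + (params.mu + params.delta / 4.0) * np.sin(2.0 * th) ** 2
    ) / params.rho
    return np.sqrt(c2)
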