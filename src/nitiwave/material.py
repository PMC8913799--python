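"""Nearly incompressible transversely isotropic (NITI) constitutive model.

Skin dermis is modelled as a transversely isotropic solid whose symmetry
axis follows the dominant collagen-fiber direction (Langer's lines), in the
nearly incompressible regime where the longitudinal Lamé constant λ vastly
exceeds every shear-scale modulus.  Three parameters carry all the in-scope
mechanics:

* ``mu``    — shear modulus in the isotropy (transverse) plane,
* ``G``     — out-of-plane shear modulus (shear involving the symmetry axis),
* ``delta`` — tensile-anisotropy parameter, ``delta = Q2 - 2*Q1``, which sets
  the ratio of the Young's moduli along (E_L) and across (E_T) the fibers.

λ only enforces near-incompressibility; derived moduli are insensitive to it
once ``lam / max(mu, G, |delta|) >= 1e4`` (a convergence test asserts this).
All moduli are stored in Pa, density in kg/m³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NITIParameters",
    "StiffnessMatrix",
    "EngineeringModuli",
    "InvalidParameterError",
    "build_stiffness",
    "engineering_moduli",
    "compliance_oracle",
    "validate_parameters",
]

#: λ is a numerical surrogate for incompressibility; below this ratio the
#: incompressible-limit formulas stop being trustworthy.
MIN_LAMBDA_RATIO = 1e4

#: Default λ multiplier when the user does not pin λ explicitly.
DEFAULT_LAMBDA_RATIO = 1e5

DEFAULT_DENSITY = 1000.0  # kg/m^3, standard soft-tissue assumption


class InvalidParameterError(ValueError):
    """Raised when a NITI parameter set violates a hard invariant."""


@dataclass(frozen=True)
class NITIParameters:
    """Material parameter set driving every solver.

    Parameters
    ----------
    mu : float
        In-plane shear modulus, Pa. Must be positive.
    G : float
        Out-of-plane shear modulus, Pa. Must be positive.
    delta : float
        Tensile-anisotropy parameter ``Q2 - 2*Q1``, Pa. Positive for
        fast-axis materials (stiffer along fibers).
    rho : float, optional
        Mass density, kg/m³ (default 1000).
    lam : float, optional
        Longitudinal Lamé constant λ, Pa. Defaults to
        ``1e5 * max(mu, G, |delta|)``; must keep the material nearly
        incompressible (ratio >= 1e4).
    Q1 : float, optional
        Tensile coupling parameter, Pa (default 0). ``Q2`` is derived as
        ``delta + 2*Q1`` so the identity ``Q2 - 2*Q1 = delta`` is exact;
        in the incompressible limit observables depend on delta only.
    """

    mu: float
    G: float
    delta: float = 0.0
    rho: float = DEFAULT_DENSITY
    lam: float | None = None
    Q1: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        if not self.mu > 0:
            problems.append(f"mu must be > 0 (got {self.mu!r})")
        if not self.G > 0:
            problems.append(f"G must be > 0 (got {self.G!r})")
        if not self.rho > 0:
            problems.append(f"rho must be > 0 (got {self.rho!r})")
        if self.lam is None and not problems:
            scale = max(self.mu, self.G, abs(self.delta))
            object.__setattr__(self, "lam", DEFAULT_LAMBDA_RATIO * scale)
        if self.lam is not None and not problems:
            scale = max(self.mu, self.G, abs(self.delta))
            if self.lam / scale < MIN_LAMBDA_RATIO:
                problems.append(
                    "lam/max(mu, G, |delta|) = "
                    f"{self.lam / scale:.3g} < {MIN_LAMBDA_RATIO:g}: "
                    "outside the nearly incompressible regime"
                )
        if problems:
            raise InvalidParameterError("; ".join(problems))

    @property
    def Q2(self) -> float:
        """Tensile parameter Q2 = delta + 2*Q1 (identity exact)."""
        return self.delta + 2.0 * self.Q1

    def with_lambda_ratio(self, ratio: float) -> "NITIParameters":
        """Copy of the parameters with λ pinned to ``ratio * max(mu, G, |delta|)``."""
        scale = max(self.mu, self.G, abs(self.delta))
        return NITIParameters(self.mu, self.G, self.delta, rho=self.rho,
                              lam=ratio * scale, Q1=self.Q1)


@dataclass(frozen=True)
class StiffnessMatrix:
    """6x6 stiffness matrix in Voigt ordering (11, 22, 33, 23, 13, 12), Pa.

    The symmetry (Z) axis is the 3-direction. Satisfies the transverse
    isotropy identity C12 = C11 - 2*C66.
    """

    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.entries, dtype=float)
        if M.shape != (6, 6):
            raise ValueError(f"stiffness must be 6x6, got {M.shape}")
        if not np.allclose(M, M.T, rtol=0, atol=1e-9 * np.abs(M).max()):
            raise ValueError("stiffness matrix must be symmetric")
        object.__setattr__(self, "entries", M)

    def as_tensor(self) -> np.ndarray:
        """Full 3x3x3x3 stiffness tensor with all minor/major symmetries."""
        return _voigt_to_tensor(self.entries)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.entries, dtype=dtype)


@dataclass(frozen=True)
class EngineeringModuli:
    """Young's moduli and Poisson ratios of the incompressible-limit NITI solid.

    ``E_L`` acts along the fibers (symmetry axis), ``E_T`` across them.
    ``nu_LT`` is exactly 1/2 in the incompressible limit: stress along the
    fibers deforms the isotropy plane equally in all directions.
    """

    E_T: float
    E_L: float
    nu_TT: float
    nu_TL: float
    nu_LT: float

    @property
    def tensile_anisotropy(self) -> float:
        """E_L / E_T, the tensile anisotropy ratio."""
        return self.E_L / self.E_T


_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def _voigt_to_tensor(C6: np.ndarray) -> np.ndarray:
    C = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(_VOIGT_PAIRS):
        for J, (k, l) in enumerate(_VOIGT_PAIRS):
            c = C6[I, J]
            C[i, j, k, l] = C[j, i, k, l] = C[i, j, l, k] = C[j, i, l, k] = c
    return C


def build_stiffness(params: NITIParameters) -> StiffnessMatrix:
    """Assemble the NITI Voigt stiffness matrix.

    Layout (symmetry axis = 3/Z):

    ======  =================
    C11=C22 ``lam + 2*mu``
    C12     ``lam``
    C13=C23 ``lam + Q1``
    C33     ``lam + 2*mu + Q2``
    C44=C55 ``G``
    C66     ``mu``
    ======  =================

    C12 = C11 - 2*C66 holds identically.
    """
    lam, mu, G = params.lam, params.mu, params.G
    Q1, Q2 = params.Q1, params.Q2
    C = np.zeros((6, 6))
    C[0, 0] = C[1, 1] = lam + 2.0 * mu
    C[0, 1] = C[1, 0] = lam
    C[0, 2] = C[2, 0] = C[1, 2] = C[2, 1] = lam + Q1
    C[2, 2] = lam + 2.0 * mu + Q2
    C[3, 3] = C[4, 4] = G
    C[5, 5] = mu
    return StiffnessMatrix(C)


def engineering_moduli(params: NITIParameters) -> EngineeringModuli:
    """Incompressible-limit engineering moduli from (mu, delta).

    E_T = 3μ + μ·δ/(4μ+δ); E_L = 3μ + δ;
    ν_TT = (1 + δ/(4μ+δ))/2; ν_TL = (1 − δ/(4μ+δ))/2; ν_LT = 1/2.

    Neither Young's modulus depends on G. E_T is capped at 4μ as δ → ∞,
    while E_L grows linearly with δ.
    """
    mu, delta = params.mu, params.delta
    denom = 4.0 * mu + delta
    if denom <= 0:
        raise InvalidParameterError(
            f"degenerate denominator 4*mu + delta = {denom:.6g} <= 0"
        )
    r = delta / denom
    return EngineeringModuli(
        E_T=3.0 * mu + mu * r,
        E_L=3.0 * mu + delta,
        nu_TT=0.5 * (1.0 + r),
        nu_TL=0.5 * (1.0 - r),
        nu_LT=0.5,
    )


def compliance_oracle(stiffness: StiffnessMatrix | np.ndarray) -> EngineeringModuli:
    """Engineering moduli read off the inverted stiffness (compliance) matrix.

    Independent of the closed-form route: E_L = 1/S33, E_T = 1/S11,
    ν_TT = −S12/S11, ν_TL = −S31/S11, ν_LT = −S13/S33 (Voigt compliance S).
    Only meaningful in the nearly incompressible regime where the
    incompressible-limit formulas apply; agreement degrades as λ shrinks.
    """
    C = np.asarray(stiffness, dtype=float)
    try:
        S = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular stiffness matrix: {exc}") from exc
    # Guard against a numerically singular but formally invertible input.
    if not np.isfinite(S).all():
        raise np.linalg.LinAlgError("singular stiffness matrix (non-finite inverse)")
    E_T = 1.0 / S[0, 0]
    E_L = 1.0 / S[2, 2]
    return EngineeringModuli(
        E_T=E_T,
        E_L=E_L,
        nu_TT=-S[0, 1] / S[0, 0],
        nu_TL=-S[2, 0] / S[0, 0],
        nu_LT=-S[0, 2] / S[2, 2],
    )


def validate_parameters(params: NITIParameters) -> list[str]:
    """Physical-validity diagnostics for a NITI parameter set.

    Returns an empty list when every constraint holds:
    E_L > E_T/2, E_L > μ, E_T > 2μ, all Poisson ratios positive, and
    (for δ > 0) 3μ < E_T < 4μ. Otherwise names each violated inequality.
    Diagnostic only — never raises for a violation.
    """
    violations: list[str] = []
    mu, delta = params.mu, params.delta
    if 4.0 * mu + delta <= 0:
        return [f"4*mu + delta = {4.0 * mu + delta:.6g} <= 0 (moduli undefined)"]
    m = engineering_moduli(params)
    if not m.E_L > m.E_T / 2.0:
        violations.append(f"E_L = {m.E_L:.6g} <= E_T/2 = {m.E_T / 2.0:.6g}")
    if not m.E_L > mu:
        violations.append(f"E_L = {m.E_L:.6g} <= mu = {mu:.6g}")
    if not m.E_T > 2.0 * mu:
        violations.append(f"E_T = {m.E_T:.6g} <= 2*mu = {2.0 * mu:.6g}")
    for name, nu in (("nu_TT", m.nu_TT), ("nu_TL", m.nu_TL), ("nu_LT", m.nu_LT)):
        if not nu > 0:
            violations.append(f"{name} = {nu:.6g} <= 0")
    if delta > 0:
        if not 3.0 * mu < m.E_T:
            violations.append(f"E_T = {m.E_T:.6g} <= 3*mu = {3.0 * mu:.6g}")
        if not m.E_T < 4.0 * mu:
            violations.append(f"E_T = {m.E_T:.6g} >= 4*mu = {4.0 * mu:.6g}")
    return violations
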