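"""Depth-resolved optic-axis orientation from Poincaré-sphere trajectories.

A linear retarder with physical axis orientation ψ rotates normalized Stokes
vectors about the equatorial Poincaré axis (cos 2ψ, sin 2ψ, 0). As probing
light accumulates round-trip retardance with depth, the measured output
states trace an arc on the sphere whose plane is normal to that axis. The
estimator slides a window of (default) 3 adjacent states along depth, fits
the local plane by singular value decomposition of the centered states, and
reads ψ from the plane normal: ψ = ½·atan2(n_U, n_Q), folded into
(−90°, 90°].

The sign of the normal is fixed by requiring consecutive states to advance
right-handedly about +n (positive retardance), which resolves the ψ vs.
ψ + 90° ambiguity of an unsigned normal. Windows whose states are nearly
collinear (arc below a threshold) are masked invalid — the non-birefringent
case, e.g. the epidermal surface layer.

Only pure retardance is simulated (no diattenuation or depolarization);
that matches the apparent-axis quantity being estimated.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

__all__ = [
    "StokesTrajectory",
    "AxisProfile",
    "AxisMap",
    "simulate_retarder_stack",
    "estimate_axis_profile",
    "depth_averaged_axis",
    "compare_axes",
]

#: Window arc (degrees on the sphere) below which a window is masked invalid.
DEFAULT_COLLINEARITY_DEG = 1.0


def _fold(deg):
    """Fold 180°-periodic orientation(s) into (−90°, 90°]."""
    a = (np.asarray(deg, dtype=float) + 90.0) % 180.0 - 90.0
    return np.where(a == -90.0, 90.0, a)


@dataclass(frozen=True)
class StokesTrajectory:
    """Depth-ordered normalized Stokes states (Q, U, V) on the Poincaré sphere."""

    depths: np.ndarray            # µm, uniform step
    states: np.ndarray = field(repr=False)  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if s.shape != (d.size, 3):
            raise ValueError(f"states shape {s.shape} != (n_depths={d.size}, 3)")
        norms = np.linalg.norm(s, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("states must be unit vectors (tolerance 1e-6)")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "states", s)


@dataclass(frozen=True)
class AxisProfile:
    """Per-depth axis orientation ψ (degrees in (−90°, 90°]) with validity mask."""

    depths: np.ndarray   # µm, window centers
    psi: np.ndarray      # degrees; NaN where invalid
    valid: np.ndarray    # bool mask


@dataclass(frozen=True)
class AxisMap:
    """Depth-averaged axis per lateral position, with validity mask."""

    psi: np.ndarray      # degrees; NaN where masked
    valid: np.ndarray

    def directivity_histogram(self, bins: int = 36):
        """Histogram of valid orientations over (−90°, 90°]."""
        vals = np.asarray(self.psi)[np.asarray(self.valid)]
        return np.histogram(vals, bins=bins, range=(-90.0, 90.0))


def _axis_rotation(psi_deg: float, angle_deg: float) -> np.ndarray:
    """Rotation matrix about the Poincaré axis (cos 2ψ, sin 2ψ, 0)."""
    from scipy.spatial.transform import Rotation

    a = np.deg2rad(2.0 * psi_deg)
    k = np.array([np.cos(a), np.sin(a), 0.0])
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * k).as_matrix()


def simulate_retarder_stack(
    axis_profile_deg,
    retardance_per_step_deg,
    n_steps: int | None = None,
    *,
    input_state=(0.0, 0.0, 1.0),
    dz_um: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> StokesTrajectory:
    """Stokes trajectory through a stack of linear retarder slabs.

    ``axis_profile_deg`` may be a scalar (uniform retarder) or a per-step
    array; likewise ``retardance_per_step_deg`` (the round-trip retardance
    accumulated per depth step). The default input state is circular
    polarization (0, 0, 1). Gaussian noise, when requested, is added to the
    states and re-normalized to the sphere; deterministic given a seed.
    """
    if n_steps is None:
        n_steps = np.size(axis_profile_deg) if np.ndim(axis_profile_deg) else 128
    psi = np.broadcast_to(np.asarray(axis_profile_deg, dtype=float), (n_steps,))
    ret = np.broadcast_to(np.asarray(retardance_per_step_deg, dtype=float), (n_steps,))
    if np.any(ret < 0):
        raise ValueError("retardance per step must be >= 0")
    s = np.asarray(input_state, dtype=float)
    s = s / np.linalg.norm(s)
    states = np.empty((n_steps + 1, 3))
    states[0] = s
    for i in range(n_steps):
        states[i + 1] = _axis_rotation(psi[i], ret[i]) @ states[i]
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        states = states + rng.normal(0.0, noise_sd, size=states.shape)
        states /= np.linalg.norm(states, axis=1, keepdims=True)
    depths = np.arange(n_steps + 1) * dz_um
    return StokesTrajectory(depths, states)


def estimate_axis_profile(
    traj: StokesTrajectory,
    window: int = 3,
    collinearity_deg: float = DEFAULT_COLLINEARITY_DEG,
) -> AxisProfile:
    """Sliding-window plane fit of the Stokes trajectory (SVD).

    For each window of ``window`` adjacent states, the plane through the
    centered states is fitted by SVD; the smallest principal direction is
    the plane normal, signed so the states advance right-handedly about it,
    and ψ = ½·atan2(n_U, n_Q). Windows with arc length below
    ``collinearity_deg`` are masked (non-birefringent tissue).
    """
    s = traj.states
    n = s.shape[0]
    if window < 3:
        raise ValueError("window must be >= 3 states")
    if n < window:
        raise ValueError(f"trajectory has {n} states, needs >= window = {window}")
    n_win = n - window + 1
    psi = np.full(n_win, np.nan)
    valid = np.zeros(n_win, dtype=bool)
    centers = np.empty(n_win)
    for i in range(n_win):
        w = s[i : i + window]
        centers[i] = traj.depths[i : i + window].mean()
        # Arc traversed within the window, degrees.
        dots = np.clip(np.sum(w[:-1] * w[1:], axis=1), -1.0, 1.0)
        arc = np.degrees(np.sum(np.arccos(dots)))
        if arc < collinearity_deg:
            continue
        centered = w - w.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=True)
        normal = vt[-1]
        # Right-handed advance about +normal fixes the sign (ψ vs ψ+90°).
        sense = np.sum(np.cross(w[:-1], w[1:]) @ normal)
        if sense < 0:
            normal = -normal
        psi[i] = _fold(0.5 * np.degrees(np.arctan2(normal[1], normal[0])))
        valid[i] = True
    if not valid.any():
        import warnings

        warnings.warn("all windows masked: trajectory is non-birefringent", stacklevel=2)
    return AxisProfile(depths=centers, psi=psi, valid=valid)


def circular_mean_axis(psi_deg: np.ndarray) -> float:
    """Mean of 180°-periodic orientations via doubled-angle vector averaging."""
    a = np.deg2rad(2.0 * np.asarray(psi_deg, dtype=float))
    return float(_fold(0.5 * np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))))


def depth_averaged_axis(
    profiles,
    depth_range: tuple[float, float] | None = None,
) -> AxisMap:
    """Depth-averaged axis orientation per lateral position.

    ``profiles`` is a sequence (any lateral ordering; arrays are flattened)
    of :class:`AxisProfile`. Within ``depth_range`` (µm, inclusive; default:
    all depths) the circular mean with doubled angles is taken over valid
    windows; positions with no valid window are masked.
    """
    profiles = list(np.asarray(profiles, dtype=object).ravel())
    if not profiles:
        raise ValueError("no profiles given")
    psi_out = np.full(len(profiles), np.nan)
    valid_out = np.zeros(len(profiles), dtype=bool)
    for k, prof in enumerate(profiles):
        sel = prof.valid.copy()
        if depth_range is not None:
            lo, hi = depth_range
            if hi < lo:
                raise ValueError("empty depth range")
            sel &= (prof.depths >= lo) & (prof.depths <= hi)
        if not sel.any():
            continue
        psi_out[k] = circular_mean_axis(prof.psi[sel])
        valid_out[k] = True
    if not valid_out.any():
        raise ValueError("no valid windows in the requested depth range at any position")
    return AxisMap(psi=psi_out, valid=valid_out)


def compare_axes(alpha_deg: float, psi_deg: float) -> float:
    """Acute angle (degrees, [0°, 90°]) between two 180°-periodic orientations."""
    if not (np.isfinite(alpha_deg) and np.isfinite(psi_deg)):
        raise ValueError("both orientations must be finite")
    d = abs(float(alpha_deg) - float(psi_deg)) % 180.0
    return min(d, 180.0 - d)
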