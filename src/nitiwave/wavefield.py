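"""Synthetic surface wavefields and group-velocity estimation.

Emulates the acoustic micro-tapping OCE acquisition: an impulsive line push
launches a near-planar surface wave whose vertical velocity is sampled on a
uniform lateral grid (default 256 positions, 54.7 µm step) at a uniform
frame rate (default 512 frames at 46.5 kHz). The wave packet is kinematic
and nondispersive — a Gaussian-enveloped pulse translating at a fixed group
velocity with optional geometric decay — because the estimation chain, not
full elastodynamics, is the quantity under test here.

Group velocity is recovered as the inverse slope of the arrival-time vs.
position line, with arrival times picked either from the analytic-signal
envelope peak (default) or from cross-correlation lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "Wavefield",
    "GroupVelocityEstimate",
    "SpeedMap",
    "simulate_wavefield",
    "estimate_group_velocity",
    "local_speed_map",
    "NoArrivalError",
    "AliasingError",
]

DEFAULT_DX = 54.7e-6        # m, lateral A-scan step
DEFAULT_FS = 46.5e3         # Hz, frame (A-line) rate
DEFAULT_NX = 256            # lateral positions per M-B scan
DEFAULT_NT = 512            # temporal frames per M-scan
DEFAULT_CENTER_FREQ = 1.5e3  # Hz, pulse center frequency
DEFAULT_BANDWIDTH = 4.0e3    # Hz, -6 dB full bandwidth of the excitation


class NoArrivalError(RuntimeError):
    """No usable arrival could be picked (flat or inconsistent wavefield)."""


class AliasingError(ValueError):
    """Requested pulse band exceeds the Nyquist limit of the time grid."""


@dataclass(frozen=True)
class Wavefield:
    """Space-time map of vertical surface velocity.

    ``v[i, j]`` is the sample at lateral position ``x[i]`` and time ``t[j]``.
    Both grids must be uniform. ``meta`` carries generation settings (seed,
    pulse width) used by downstream defaults.
    """

    x: np.ndarray
    t: np.ndarray
    v: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if v.shape != (x.size, t.size):
            raise ValueError(f"v shape {v.shape} != (n_x={x.size}, n_t={t.size})")
        for name, g in (("x", x), ("t", t)):
            steps = np.diff(g)
            if g.size < 2 or not np.allclose(steps, steps[0], rtol=1e-6, atol=0):
                raise ValueError(f"{name} grid must be uniform")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class GroupVelocityEstimate:
    """Result of the arrival-time linear fit."""

    speed: float              # m/s
    intercept: float          # s, fitted arrival time at x = 0
    r_squared: float          # coefficient of determination of the line
    arrival_times: np.ndarray  # s, one per position used
    positions: np.ndarray      # m, positions used in the fit
    method: str = "envelope"


@dataclass(frozen=True)
class SpeedMap:
    """Moving-kernel local speeds: ``speeds[row, k]`` at ``centers[k]``."""

    centers: np.ndarray        # m, kernel-center positions
    speeds: np.ndarray         # m/s, shape (n_rows, n_x - kernel)
    kernel: int


def gaussian_pulse_sigma(bandwidth: float = DEFAULT_BANDWIDTH) -> float:
    """Envelope std (s) for a Gaussian pulse with the given −6 dB full bandwidth."""
    return np.sqrt(2.0 * np.log(2.0)) / (np.pi * bandwidth)


def simulate_wavefield(
    speed: float,
    *,
    center_freq: float = DEFAULT_CENTER_FREQ,
    bandwidth: float = DEFAULT_BANDWIDTH,
    n_x: int = DEFAULT_NX,
    n_t: int = DEFAULT_NT,
    dx: float = DEFAULT_DX,
    fs: float = DEFAULT_FS,
    t0: float = 5e-4,
    geometric_decay: bool = False,
    x0: float = 1e-3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Wavefield:
    """Kinematic surface wavefield: a pulse translating at ``speed``.

    v(x, t) = s(t − t0 − x/speed), with s a Gaussian-enveloped cosine of the
    given center frequency and −6 dB full bandwidth, optional 1/sqrt(x + x0)
    geometric decay, and additive white Gaussian noise. Deterministic for a
    fixed seed.
    """
    if speed <= 0:
        raise ValueError(f"speed must be > 0 (got {speed})")
    nyquist = fs / 2.0
    if center_freq + bandwidth / 2.0 >= nyquist:
        raise AliasingError(
            f"pulse band {center_freq + bandwidth / 2.0:.0f} Hz exceeds Nyquist {nyquist:.0f} Hz"
        )
    x = np.arange(n_x) * dx
    t = np.arange(n_t) / fs
    sigma = gaussian_pulse_sigma(bandwidth)
    tau = t[None, :] - t0 - x[:, None] / speed
    v = np.exp(-(tau**2) / (2.0 * sigma**2)) * np.cos(2.0 * np.pi * center_freq * tau)
    if geometric_decay:
        v = v / np.sqrt((x[:, None] + x0) / x0)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    meta = {
        "speed": speed,
        "seed": seed,
        "pulse_width_s": 2.0 * sigma,
        "center_freq": center_freq,
        "bandwidth": bandwidth,
        "t0": t0,
    }
    return Wavefield(x, t, v, meta)


def _envelope_arrivals(wf: Wavefield) -> np.ndarray:
    """Sub-sample arrival times from the analytic-signal envelope maximum."""
    env = np.abs(hilbert(wf.v, axis=1))
    peak_amp = env.max(axis=1)
    if peak_amp.max() <= 0 or np.median(peak_amp) < 1e-12 * max(peak_amp.max(), 1.0):
        raise NoArrivalError("wavefield envelope is flat; no arrival to pick")
    idx = np.argmax(env, axis=1)
    arrivals = wf.t[idx].astype(float)
    # 3-point parabolic refinement around the peak sample.
    for i, j in enumerate(idx):
        if 0 < j < env.shape[1] - 1:
            y0, y1, y2 = env[i, j - 1 : j + 2]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                arrivals[i] += 0.5 * (y0 - y2) / denom * wf.dt
    return arrivals


def _xcorr_arrivals(wf: Wavefield) -> np.ndarray:
    """Arrival times (up to a common offset) from lags against the first trace."""
    ref = wf.v[0]
    if not np.any(ref):
        raise NoArrivalError("reference trace is identically zero")
    n_t = wf.t.size
    arrivals = np.empty(wf.x.size)
    for i in range(wf.x.size):
        c = np.correlate(wf.v[i], ref, mode="full")
        j = int(np.argmax(c))
        lag = float(j - (n_t - 1))
        if 0 < j < c.size - 1:
            y0, y1, y2 = c[j - 1 : j + 2]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                lag += 0.5 * (y0 - y2) / denom
        arrivals[i] = lag * wf.dt
    return arrivals


def _fit_line(x: np.ndarray, tt: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, tt, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((tt - pred) ** 2))
    ss_tot = float(np.sum((tt - tt.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), r2


def estimate_group_velocity(
    wf: Wavefield,
    method: str = "envelope",
    *,
    r2_threshold: float = 0.9,
    exclude_near: float | None = None,
) -> GroupVelocityEstimate:
    """Group velocity from the slope of the arrival-time vs. position line.

    Parameters
    ----------
    method : {'envelope', 'cross-correlation'}
        Arrival-time picker. ``'envelope'`` takes the analytic-signal
        envelope maximum with 3-point parabolic sub-sample refinement;
        ``'cross-correlation'`` takes the peak lag against the first trace.
    exclude_near : float, optional
        Distance (m) from the first position to exclude from the fit
        (near-field guard). When None and the wavefield metadata records a
        pulse width, a two-pass fit excludes positions within one
        speed × pulse-width of the source side.

    Raises
    ------
    NoArrivalError
        Flat field, or non-positive fitted slope (wave direction
        inconsistent with increasing x).
    """
    if method == "envelope":
        arrivals = _envelope_arrivals(wf)
    elif method in ("cross-correlation", "xcorr"):
        arrivals = _xcorr_arrivals(wf)
    else:
        raise ValueError(f"unknown method {method!r}")

    x = wf.x
    slope, intercept, r2 = _fit_line(x, arrivals)
    if slope <= 0:
        raise NoArrivalError(
            f"fitted slope {slope:.3g} s/m is not positive; no outgoing wave along +x"
        )

    if exclude_near is None:
        pw = wf.meta.get("pulse_width_s")
        exclude_near = (1.0 / slope) * pw if pw else 0.0
    if exclude_near > 0:
        keep = x - x[0] >= exclude_near
        if keep.sum() >= max(3, x.size // 4):
            slope, intercept, r2 = _fit_line(x[keep], arrivals[keep])
            x, arrivals = x[keep], arrivals[keep]
            if slope <= 0:
                raise NoArrivalError("non-positive slope after near-field exclusion")

    if r2 < r2_threshold:
        warnings.warn(
            f"arrival-time fit quality R^2 = {r2:.3f} below threshold {r2_threshold}",
            stacklevel=2,
        )
    return GroupVelocityEstimate(
        speed=1.0 / slope,
        intercept=intercept,
        r_squared=r2,
        arrival_times=arrivals,
        positions=x,
        method=method,
    )


def local_speed_map(
    fields: Wavefield | list[Wavefield],
    kernel: int = 20,
    stride: int = 1,
    method: str = "envelope",
) -> SpeedMap:
    """Sliding-kernel local speed estimation (scar-type speed mapping).

    Applies :func:`estimate_group_velocity` to every contiguous window of
    ``kernel`` positions; with the default stride of 1 each row of
    ``n_x`` positions yields exactly ``n_x - kernel`` estimates (e.g. 100
    positions with a 20-pixel kernel give 80 speeds).
    """
    if isinstance(fields, Wavefield):
        fields = [fields]
    n_x = fields[0].x.size
    if kernel >= n_x:
        raise ValueError(f"kernel {kernel} must be smaller than n_x = {n_x}")
    starts = range(0, n_x - kernel, stride)
    centers = np.array([fields[0].x[s : s + kernel].mean() for s in starts])
    speeds = np.full((len(fields), len(centers)), np.nan)
    for r, wf in enumerate(fields):
        if wf.x.size != n_x:
            raise ValueError("all rows must share the lateral grid")
        for k, s in enumerate(starts):
            sub = Wavefield(wf.x[s : s + kernel], wf.t, wf.v[s : s + kernel], wf.meta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    est = estimate_group_velocity(sub, method=method, exclude_near=0.0)
                    speeds[r, k] = est.speed
                except NoArrivalError:
                    pass  # leave NaN for windows without a usable arrival
    return SpeedMap(centers=centers, speeds=speeds, kernel=kernel)
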