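"""Synthetic-subject fixture generation tying the full pipeline together.

A synthetic subject mirrors the paired acquisition geometry: 13 surface
wavefields at propagation angles −90°:15°:+90° whose speeds follow the NITI
Rayleigh curve for the ground-truth parameters, plus a PS-OCT Stokes volume
whose dermal optic axis equals the mechanical axis alpha beneath a
non-birefringent surface layer. Every artifact is deterministic given the
manifest seed (per-artifact sub-seeds are spawned from one SeedSequence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    SCHEMA_VERSION,
    read_stokes_volume,
    read_wavefield,
    write_stokes_volume,
    write_wavefield,
)
from .material import NITIParameters
from .psoct import simulate_retarder_stack
from .rayleigh import default_angle_grid, rayleigh_curve
from .wavefield import Wavefield, simulate_wavefield

__all__ = ["SyntheticSubject", "make_fixtures", "load_subject"]

#: Dermal round-trip retardance per depth step, degrees. Deep enough per
#: window to stay far above the collinearity mask.
DERMIS_RETARDANCE = 6.0

#: Non-birefringent surface (epidermis-like) layer: steps with zero retardance.
SURFACE_LAYER_STEPS = 20


@dataclass(frozen=True)
class SyntheticSubject:
    """On-disk synthetic subject: truth, wavefields, PS-OCT volume, manifest."""

    root: Path
    truth: NITIParameters
    alpha: float
    angles: np.ndarray
    speeds: np.ndarray
    wavefield_paths: list[Path]
    volume_path: Path
    manifest_path: Path

    def wavefields(self) -> list[Wavefield]:
        return [read_wavefield(p) for p in self.wavefield_paths]

    def stokes_volume(self):
        return read_stokes_volume(self.volume_path)


def make_fixtures(
    truth: NITIParameters,
    alpha: float,
    out_dir,
    *,
    speed_noise_sd: float = 0.0,
    wavefield_noise_sd: float = 0.0,
    stokes_noise_sd: float = 0.0,
    seed: int = 0,
    n_lateral: int = 8,
    n_depth_steps: int = 120,
) -> SyntheticSubject:
    """Generate a synthetic subject on disk.

    Speeds come from the forward Rayleigh curve at the truth parameters with
    the symmetry axis offset ``alpha``; optional multiplicative Gaussian
    noise (``speed_noise_sd``, relative) perturbs them before wavefield
    synthesis. The PS-OCT volume is an ``n_lateral × n_lateral`` grid of
    retarder-stack trajectories with dermal axis alpha below a
    non-birefringent surface layer.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    angles = default_angle_grid()
    curve = rayleigh_curve(truth, alpha=alpha, angles=angles)
    speeds = curve.speeds.copy()

    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(len(angles) + 2)
    if speed_noise_sd > 0:
        rng = np.random.default_rng(sub[-2])
        speeds = speeds * (1.0 + rng.normal(0.0, speed_noise_sd, size=speeds.shape))

    wf_paths = []
    for i, (ang, c) in enumerate(zip(angles, speeds)):
        wf_seed = int(sub[i].generate_state(1)[0] % (2**31))
        wf = simulate_wavefield(float(c), noise_sd=wavefield_noise_sd, seed=wf_seed)
        p = out / f"wavefield_{int(round(ang)):+04d}deg.h5"
        write_wavefield(wf, p)
        wf_paths.append(p)

    # PS-OCT volume: zero-retardance surface layer, dermal axis = alpha.
    psi_profile = np.full(n_depth_steps, alpha)
    ret_profile = np.full(n_depth_steps, DERMIS_RETARDANCE)
    ret_profile[:SURFACE_LAYER_STEPS] = 0.0
    vol_rng_root = sub[-1].spawn(n_lateral * n_lateral)
    states = np.empty((n_lateral, n_lateral, n_depth_steps + 1, 3))
    depths = None
    for iy in range(n_lateral):
        for ix in range(n_lateral):
            tr_seed = int(vol_rng_root[iy * n_lateral + ix].generate_state(1)[0] % (2**31))
            traj = simulate_retarder_stack(
                psi_profile, ret_profile, n_depth_steps,
                noise_sd=stokes_noise_sd, seed=tr_seed,
            )
            states[iy, ix] = traj.states
            depths = traj.depths
    vol_path = out / "psoct_volume.h5"
    write_stokes_volume(depths, states, vol_path, alpha_truth=alpha,
                        surface_layer_steps=SURFACE_LAYER_STEPS)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "alpha_deg": alpha,
        "truth": {
            "mu_kPa": truth.mu / 1e3,
            "G_kPa": truth.G / 1e3,
            "delta_kPa": truth.delta / 1e3,
            "rho_kg_m3": truth.rho,
        },
        "noise": {
            "speed_noise_sd": speed_noise_sd,
            "wavefield_noise_sd": wavefield_noise_sd,
            "stokes_noise_sd": stokes_noise_sd,
        },
        "angles_deg": angles.tolist(),
        "speeds_m_s": speeds.tolist(),
        "wavefields": [p.name for p in wf_paths],
        "psoct_volume": vol_path.name,
        "psoct": {
            "n_lateral": n_lateral,
            "n_depth_steps": n_depth_steps,
            "dermis_retardance_deg": DERMIS_RETARDANCE,
            "surface_layer_steps": SURFACE_LAYER_STEPS,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return SyntheticSubject(
        root=out, truth=truth, alpha=alpha, angles=angles, speeds=speeds,
        wavefield_paths=wf_paths, volume_path=vol_path, manifest_path=manifest_path,
    )


def load_subject(root) -> SyntheticSubject:
    """Reload a synthetic subject from its manifest."""
    root = Path(root)
    doc = json.loads((root / "manifest.json").read_text())
    t = doc["truth"]
    truth = NITIParameters(
        mu=t["mu_kPa"] * 1e3, G=t["G_kPa"] * 1e3,
        delta=t["delta_kPa"] * 1e3, rho=t["rho_kg_m3"],
    )
    return SyntheticSubject(
        root=root,
        truth=truth,
        alpha=doc["alpha_deg"],
        angles=np.asarray(doc["angles_deg"], float),
        speeds=np.asarray(doc["speeds_m_s"], float),
        wavefield_paths=[root / name for name in doc["wavefields"]],
        volume_path=root / doc["psoct_volume"],
        manifest_path=root / "manifest.json",
    )
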