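"""File formats: angle-scan CSV, fit-result JSON, parameter JSON, HDF5 containers.

All JSON documents carry a ``schema_version`` field. Moduli cross the file
boundary in kPa (and density in kg/m³); in memory everything is Pa.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .inversion import AngleScan, FitResult
from .material import NITIParameters
from .psoct import StokesTrajectory
from .wavefield import Wavefield

__all__ = [
    "SchemaError",
    "read_angle_scan",
    "write_angle_scan",
    "angle_scan_from_dataframe",
    "read_params_json",
    "write_params_json",
    "write_fit_result",
    "read_fit_result",
    "write_wavefield",
    "read_wavefield",
    "write_stokes_volume",
    "read_stokes_volume",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Malformed input file: names the offending column or field."""


# -- angle scans (CSV) -------------------------------------------------------

def angle_scan_from_dataframe(df: pd.DataFrame) -> AngleScan:
    for col in ("angle_deg", "speed_m_s"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    for col in ("angle_deg", "speed_m_s", "sd_m_s"):
        if col in df.columns and not np.issubdtype(
            pd.to_numeric(df[col], errors="coerce").dtype, np.number
        ):
            raise SchemaError(f"non-numeric values in column {col!r}")
        if col in df.columns and pd.to_numeric(df[col], errors="coerce").isna().any():
            raise SchemaError(f"non-numeric cell in column {col!r}")
    sd = df["sd_m_s"].to_numpy(float) if "sd_m_s" in df.columns else None
    return AngleScan(df["angle_deg"].to_numpy(float), df["speed_m_s"].to_numpy(float), sd)


def read_angle_scan(path) -> AngleScan:
    """Read an angle scan CSV (columns angle_deg, speed_m_s[, sd_m_s])."""
    return angle_scan_from_dataframe(pd.read_csv(path, float_precision="round_trip"))


def write_angle_scan(scan: AngleScan, path) -> None:
    data = {"angle_deg": scan.angles, "speed_m_s": scan.speeds}
    if scan.sd is not None:
        data["sd_m_s"] = scan.sd
    # 17 significant digits: binary64 round-trips exactly through text
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# -- parameter JSON ----------------------------------------------------------

def read_params_json(path) -> NITIParameters:
    """Parameter file: {"mu_kPa", "G_kPa", "delta_kPa"[, "rho_kg_m3",
    "lambda_over_mu", "Q1_kPa"]}."""
    doc = json.loads(Path(path).read_text())
    for key in ("mu_kPa", "G_kPa", "delta_kPa"):
        if key not in doc:
            raise SchemaError(f"missing field {key!r}")
    mu = float(doc["mu_kPa"]) * 1e3
    G = float(doc["G_kPa"]) * 1e3
    delta = float(doc["delta_kPa"]) * 1e3
    rho = float(doc.get("rho_kg_m3", 1000.0))
    Q1 = float(doc.get("Q1_kPa", 0.0)) * 1e3
    lam = None
    if "lambda_over_mu" in doc:
        lam = float(doc["lambda_over_mu"]) * mu
    return NITIParameters(mu=mu, G=G, delta=delta, rho=rho, lam=lam, Q1=Q1)


def write_params_json(params: NITIParameters, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "mu_kPa": params.mu / 1e3,
        "G_kPa": params.G / 1e3,
        "delta_kPa": params.delta / 1e3,
        "rho_kg_m3": params.rho,
        "lambda_over_mu": params.lam / params.mu,
        "Q1_kPa": params.Q1 / 1e3,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


# -- fit results (JSON) ------------------------------------------------------

def write_fit_result(fit: FitResult, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **fit.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_fit_result(path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema_version {doc.get('schema_version')!r} != {SCHEMA_VERSION}"
        )
    for key in ("mu_kPa", "G_kPa", "delta_kPa", "alpha_deg", "rho_kg_m3", "rmse_m_s"):
        if key not in doc:
            raise SchemaError(f"missing field {key!r}")
    return FitResult(
        mu=doc["mu_kPa"] * 1e3,
        G=doc["G_kPa"] * 1e3,
        delta=doc["delta_kPa"] * 1e3,
        alpha=doc["alpha_deg"],
        rho=doc["rho_kg_m3"],
        rmse=doc["rmse_m_s"],
        success=doc.get("success", True),
        nfev=doc.get("nfev", 0),
        message=doc.get("message", ""),
        validity_flags=tuple(doc.get("validity_flags", ())),
        loo_mean=doc.get("loo_mean"),
        loo_sd=doc.get("loo_sd"),
        n_loo_fits=doc.get("n_loo_fits", 0),
    )


# -- HDF5 containers ---------------------------------------------------------

def write_wavefield(wf: Wavefield, path) -> None:
    """Wavefield container: datasets x, t, v; attrs dx, dt and meta."""
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=wf.x)
        f.create_dataset("t", data=wf.t)
        f.create_dataset("v", data=wf.v)
        f.attrs["dx"] = wf.dx
        f.attrs["dt"] = wf.dt
        f.attrs["schema_version"] = SCHEMA_VERSION
        for k, val in wf.meta.items():
            if val is not None:
                f.attrs[f"meta_{k}"] = val


def read_wavefield(path) -> Wavefield:
    with h5py.File(path, "r") as f:
        for name in ("x", "t", "v"):
            if name not in f:
                raise SchemaError(f"missing dataset {name!r}")
        meta = {
            k[len("meta_"):]: (v.item() if np.ndim(v) == 0 else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return Wavefield(f["x"][:], f["t"][:], f["v"][:], meta)


def write_stokes_volume(depths: np.ndarray, states: np.ndarray, path, **attrs) -> None:
    """PS-OCT volume: states shaped (n_y, n_x, n_depths+1, 3) plus depth grid."""
    with h5py.File(path, "w") as f:
        f.create_dataset("depths", data=np.asarray(depths, float))
        f.create_dataset("states", data=np.asarray(states, float))
        f.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in attrs.items():
            if v is not None:
                f.attrs[k] = v


def read_stokes_volume(path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        for name in ("depths", "states"):
            if name not in f:
                raise SchemaError(f"missing dataset {name!r}")
        return f["depths"][:], f["states"][:]


def volume_trajectories(depths: np.ndarray, states: np.ndarray):
    """Iterate a (n_y, n_x, n_z, 3) volume as per-position StokesTrajectory."""
    ny, nx = states.shape[:2]
    for iy in range(ny):
        for ix in range(nx):
            yield StokesTrajectory(depths, states[iy, ix])
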