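"""Delimited-text readers and writers for every pipeline file dialect.

All files are comma-separated UTF-8 with a header row, '.' decimals and
'#' comment lines.  Floats are written with repr-level precision so that a
write/read round trip is numerically exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .condensation import RadialProfile
from .laurdan import EmissionSpectrum
from .lattice_model import EnergyParams
from .phasor import FrequencySweep

__all__ = [
    "read_radial_profile",
    "write_radial_profile",
    "read_sweeps",
    "write_sweeps",
    "read_spectrum",
    "write_spectrum",
    "read_spectra_manifest",
    "load_model_config",
    "write_table",
    "write_json",
]

_SWEEP_COLUMNS = [
    "mole_fraction",
    "replicate",
    "frequency_mhz",
    "phase_deg",
    "modulation",
    "rel_err_phase",
    "rel_err_mod",
]


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_radial_profile(path: str | Path, **kwargs) -> RadialProfile:
    """Read a 2-column (r_angstrom, g) radial distribution table."""
    df = _read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "r_angstrom" not in cols or "g" not in cols:
        raise ValueError(f"{path}: expected columns (r_angstrom, g), got {cols}")
    return RadialProfile(df["r_angstrom"].to_numpy(), df["g"].to_numpy(), **kwargs)


def write_radial_profile(profile: RadialProfile, path: str | Path) -> None:
    _write_csv(
        pd.DataFrame({"r_angstrom": profile.r_grid, "g": profile.g_values}), path
    )


def read_sweeps(path: str | Path) -> list[FrequencySweep]:
    """Read a sweep table into one FrequencySweep per (mole fraction, replicate)."""
    df = _read_csv(path)
    missing = [c for c in _SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sweep columns {missing}")
    sweeps = []
    for (x, rep), grp in df.groupby(["mole_fraction", "replicate"], sort=True):
        grp = grp.sort_values("frequency_mhz", ascending=False)
        sweeps.append(
            FrequencySweep(
                frequency_mhz=grp["frequency_mhz"].to_numpy(),
                phase_deg=grp["phase_deg"].to_numpy(),
                modulation=grp["modulation"].to_numpy(),
                rel_err_phase=grp["rel_err_phase"].to_numpy(),
                rel_err_mod=grp["rel_err_mod"].to_numpy(),
                mole_fraction=float(x),
                replicate=int(rep),
            )
        )
    return sweeps


def write_sweeps(sweeps: list[FrequencySweep], path: str | Path) -> None:
    frames = []
    for s in sweeps:
        frames.append(
            pd.DataFrame(
                {
                    "mole_fraction": s.mole_fraction,
                    "replicate": s.replicate,
                    "frequency_mhz": s.frequency_mhz,
                    "phase_deg": s.phase_deg,
                    "modulation": s.modulation,
                    "rel_err_phase": s.rel_err_phase,
                    "rel_err_mod": s.rel_err_mod,
                }
            )
        )
    _write_csv(pd.concat(frames, ignore_index=True), path)


def read_spectrum(
    path: str | Path, blank_path: str | Path | None = None
) -> EmissionSpectrum:
    """Read a (wavelength_nm, intensity) table, optionally with a blank file."""
    df = _read_csv(path)
    if not {"wavelength_nm", "intensity"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns (wavelength_nm, intensity)")
    blank = None
    if blank_path is not None:
        bdf = _read_csv(blank_path)
        if not np.allclose(bdf["wavelength_nm"], df["wavelength_nm"]):
            raise ValueError("blank spectrum grid does not match the sample grid")
        blank = bdf["intensity"].to_numpy()
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), blank=blank
    )


def write_spectrum(spectrum: EmissionSpectrum, path: str | Path) -> None:
    _write_csv(
        pd.DataFrame(
            {"wavelength_nm": spectrum.wavelength, "intensity": spectrum.intensity}
        ),
        path,
    )


def read_spectra_manifest(path: str | Path) -> dict[float, list[EmissionSpectrum]]:
    """Read a manifest (mole_fraction, replicate, spectrum_file[, blank_file]).

    File paths are resolved relative to the manifest's directory.
    """
    base = Path(path).parent
    df = _read_csv(path)
    if not {"mole_fraction", "replicate", "spectrum_file"}.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs mole_fraction, replicate, spectrum_file")
    out: dict[float, list[EmissionSpectrum]] = {}
    for _, row in df.sort_values(["mole_fraction", "replicate"]).iterrows():
        blank = row.get("blank_file")
        blank_path = base / str(blank) if isinstance(blank, str) and blank else None
        spec = read_spectrum(base / str(row["spectrum_file"]), blank_path)
        out.setdefault(float(row["mole_fraction"]), []).append(spec)
    return out


def load_model_config(path: str | Path) -> tuple[EnergyParams, dict]:
    """Load a YAML model config into EnergyParams plus the extra keys.

    Recognized keys: z, eps_ss, eps_us, eps_uu, delta_cluster,
    eps_gs_minus_gu, temperature_K, n_tot, M.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    defaults = EnergyParams()
    params = EnergyParams(
        z=int(raw.get("z", defaults.z)),
        eps_ss=float(raw.get("eps_ss", defaults.eps_ss)),
        eps_us=float(raw.get("eps_us", defaults.eps_us)),
        eps_uu=float(raw.get("eps_uu", defaults.eps_uu)),
        delta_cluster=float(raw.get("delta_cluster", defaults.delta_cluster)),
        eps_gs_minus_gu=float(raw.get("eps_gs_minus_gu", defaults.eps_gs_minus_gu)),
        temperature=float(raw.get("temperature_K", defaults.temperature)),
    )
    extra = {
        "n_tot": float(raw.get("n_tot", 1e4)),
        "M": int(raw.get("M", 12)),
    }
    return params, extra


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table in the standard dialect."""
    _write_csv(df, path)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
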