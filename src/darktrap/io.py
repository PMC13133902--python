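"""Readers and writers for the package's on-disk formats.

Conventions: JSON for structured level data, CSV for series and matrices,
YAML only for run configurations.  Units are spelled out in column names
(energies in eV, frequencies in cm^-1, delays in ps) because silent unit
conversion is the main foreseeable bug class in this domain.  All writers
go through a temp-file-then-rename so a failed run never leaves a partial
output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .energy_levels import LevelDiagram, StateLevel, ThresholdValue
from .kinetics import Transient
from .pe_spectra import PESpectrum2D
from .power_law import PowerSeries
from .rrkm import FrequencySet

__all__ = [
    "FormatError",
    "packaged_diagram_path",
    "read_level_diagram",
    "read_transient_csv",
    "write_transient_csv",
    "read_power_series_csv",
    "write_power_series_csv",
    "read_frequency_csv",
    "write_frequency_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "atomic_write_text",
]

PS = 1e-12  # seconds per picosecond


class FormatError(ValueError):
    """A file does not match its declared schema; message points at the spot."""


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text to path via a temp file + rename (no partial outputs)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def packaged_diagram_path() -> Path:
    """Path to the packaged level-diagram fixture (meta-HBDI numbers)."""
    return Path(__file__).parent / "data" / "level_diagram.json"


def _threshold_map(obj: dict, key: str, path: str) -> dict[str, ThresholdValue]:
    out: dict[str, ThresholdValue] = {}
    for prov, entry in obj.items():
        where = f"{path}/{key}/{prov}"
        if not isinstance(entry, dict) or "value_eV" not in entry:
            raise FormatError(f"{where}: expected an object with 'value_eV'")
        try:
            out[prov] = ThresholdValue(float(entry["value_eV"]), entry.get("provenance", prov))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{where}: {exc}") from exc
    return out


def read_level_diagram(path: str | os.PathLike | None = None) -> LevelDiagram:
    """Load a level diagram from JSON (the packaged fixture by default).

    Schema: ``states`` (list of state objects), ``vde_d0``/``ade_d0``/
    ``vde_d1n`` ({provenance: {value_eV, provenance}}), optional ``meci``.
    Schema violations raise FormatError naming the offending field.
    """
    p = Path(path) if path is not None else packaged_diagram_path()
    with open(p) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{p}: not valid JSON: {exc}") from exc
    for key in ("states", "vde_d0"):
        if key not in raw:
            raise FormatError(f"{p}: missing required key '/{key}'")
    states: dict[str, StateLevel] = {}
    for i, s in enumerate(raw["states"]):
        where = f"{p}:/states/{i}"
        for key in ("label", "species"):
            if key not in s:
                raise FormatError(f"{where}: missing '{key}'")
        if s["label"] in states:
            raise FormatError(f"{where}: duplicate state label {s['label']!r}")
        try:
            states[s["label"]] = StateLevel(
                label=s["label"],
                species=s["species"],
                adiabatic_energy=s.get("adiabatic_energy"),
                vertical_energy=s.get("vertical_energy"),
                oscillator_strength_from_S0=s.get("oscillator_strength_from_S0"),
            )
        except ValueError as exc:
            raise FormatError(f"{where}: {exc}") from exc
    return LevelDiagram(
        states=states,
        vde_d0=_threshold_map(raw["vde_d0"], "vde_d0", str(p)),
        ade_d0=_threshold_map(raw.get("ade_d0", {}), "ade_d0", str(p)),
        vde_d1n=_threshold_map(raw.get("vde_d1n", {}), "vde_d1n", str(p)),
        meci={k: float(v) for k, v in raw.get("meci", {}).items()},
    )


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column '{c}' (have {list(df.columns)})")


def read_transient_csv(path: str | os.PathLike) -> list[Transient]:
    """Transient CSV (columns delay_ps, signal, sigma, channel) -> Transients.

    One Transient per distinct channel value; delays converted to seconds.
    """
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["delay_ps", "signal", "channel"], path)
    out = []
    for channel, grp in df.groupby("channel", sort=False):
        grp = grp.sort_values("delay_ps")
        sigma = grp["sigma"].to_numpy() if "sigma" in grp.columns else None
        try:
            out.append(
                Transient(
                    grp["delay_ps"].to_numpy() * PS,
                    grp["signal"].to_numpy(),
                    sigma,
                    str(channel),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} (channel {channel!r}): {exc}") from exc
    return out


def write_transient_csv(path: str | os.PathLike, transients: list[Transient]) -> None:
    frames = []
    for tr in transients:
        frames.append(
            pd.DataFrame(
                {
                    "delay_ps": tr.delays / PS,
                    "signal": tr.signal,
                    "sigma": tr.sigma if tr.sigma is not None else np.nan,
                    "channel": tr.channel,
                }
            )
        )
    atomic_write_text(path, pd.concat(frames).to_csv(index=False))


def read_power_series_csv(path: str | os.PathLike) -> PowerSeries:
    """Power-series CSV with columns pulse_energy, yield, sigma, wavelength_nm."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["pulse_energy", "yield"], path)
    wl = float(df["wavelength_nm"].iloc[0]) if "wavelength_nm" in df.columns else None
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    try:
        return PowerSeries(df["pulse_energy"].to_numpy(), df["yield"].to_numpy(), sigma, wl)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_power_series_csv(path: str | os.PathLike, series: PowerSeries) -> None:
    df = pd.DataFrame(
        {
            "pulse_energy": series.pulse_energy,
            "yield": series.yield_,
            "sigma": series.uncertainty if series.uncertainty is not None else np.nan,
            "wavelength_nm": series.wavelength_nm,
        }
    )
    atomic_write_text(path, df.to_csv(index=False))


def read_frequency_csv(path: str | os.PathLike, role: str = "minimum") -> FrequencySet:
    """Frequency CSV: one frequency per line under header frequency_cm1."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["frequency_cm1"], path)
    bad = df.index[~(df["frequency_cm1"] > 0)].tolist()
    if bad:
        raise FormatError(f"{path}: non-positive frequency at data row(s) {bad}")
    return FrequencySet(tuple(df["frequency_cm1"].astype(float)), role=role)


def write_frequency_csv(path: str | os.PathLike, freqs: FrequencySet) -> None:
    df = pd.DataFrame({"frequency_cm1": list(freqs.frequencies)})
    atomic_write_text(path, df.to_csv(index=False))


def read_spectrum_csv(path: str | os.PathLike) -> PESpectrum2D:
    """2D spectrum CSV: first row the eKE axis, first column the hv axis."""
    raw = np.loadtxt(path, delimiter=",")
    if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a matrix with axis row and column")
    try:
        return PESpectrum2D(raw[1:, 0], raw[0, 1:], raw[1:, 1:])
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum_csv(path: str | os.PathLike, spec: PESpectrum2D) -> None:
    mat = np.zeros((len(spec.photon_energies) + 1, len(spec.eke) + 1))
    mat[0, 1:] = spec.eke
    mat[1:, 0] = spec.photon_energies
    mat[1:, 1:] = spec.intensity
    rows = [",".join(f"{v:.10g}" for v in row) for row in mat]
    atomic_write_text(path, "\n".join(rows) + "\n")
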