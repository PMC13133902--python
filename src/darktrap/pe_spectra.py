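"""Forward simulation of 2D photoelectron spectra and 1D-cut analysis.

A 2D photoelectron spectrum is intensity over (photon energy hv, electron
kinetic energy eKE).  Given a level diagram, each detachment channel puts a
Gaussian ridge at its energetically determined eKE centre:

    direct_d0      eKE = hv - VDE(D0)              (unit-slope ridge)
    direct_d1n     eKE = hv - VDE(D1n)             (parallel, offset by the gap)
    two_photon_s1  eKE = AEE(S1) + hv - VDE(D0)    (above the direct line)
    low_eke        exp(-eKE / decay)               (statistical emission)
    s3_broadening  extra ridge width inside a resonance photon-energy window

Closed channels (centre <= 0) contribute nothing.  Output is normalized to
unit maximum because absolute electron counts are instrument-dependent.
Gaussian widths stand in for the unmodelled experimental resolution and
vibrational envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_levels import LevelDiagram, MissingStateError

__all__ = ["PESpectrum2D", "ChannelSpec", "simulate_2d", "spectral_cut", "peak_eke"]

CHANNEL_KINDS = ("direct_d0", "direct_d1n", "two_photon_s1", "low_eke", "s3_broadening")


@dataclass(frozen=True)
class ChannelSpec:
    """Configuration of one simulated detachment channel.

    width_eV is the Gaussian ridge width (standard deviation) in eKE;
    decay_eV is the exponential constant of the low-eKE channel;
    hv_window and extra_width_eV configure the resonance broadening.
    """

    kind: str
    amplitude: float = 1.0
    width_eV: float = 0.15
    decay_eV: float = 0.05
    hv_window: tuple[float, float] = (3.6, 3.9)
    extra_width_eV: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}; expected one of {CHANNEL_KINDS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width_eV <= 0 or self.decay_eV <= 0 or self.extra_width_eV <= 0:
            raise ValueError("widths and decay constants must be positive")


@dataclass
class PESpectrum2D:
    """Intensity matrix over (photon energy, eKE), axes strictly increasing.

    intensity has shape (len(photon_energies), len(eke)); channel_masks maps
    channel kind -> that channel's contribution matrix (same shape), kept so
    downstream code can attribute pixels to their generating process.
    """

    photon_energies: np.ndarray
    eke: np.ndarray
    intensity: np.ndarray
    channel_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.photon_energies = np.asarray(self.photon_energies, dtype=float)
        self.eke = np.asarray(self.eke, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.photon_energies) <= 0) or np.any(np.diff(self.eke) <= 0):
            raise ValueError("axes must be strictly increasing")
        if self.intensity.shape != (len(self.photon_energies), len(self.eke)):
            raise ValueError("intensity shape must be (n_hv, n_eke)")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative and finite")


def _ridge_center(kind: str, hv: float, diagram: LevelDiagram, prefer: str) -> float | None:
    """eKE centre of a ridge channel at photon energy hv; None if closed."""
    if kind in ("direct_d0", "s3_broadening"):
        c = hv - diagram.threshold("vde_d0", prefer=prefer)
    elif kind == "direct_d1n":
        c = hv - diagram.threshold("vde_d1n", prefer=prefer)
    elif kind == "two_photon_s1":
        aee = diagram.state("S1").adiabatic_energy
        if aee is None:
            raise MissingStateError("S1 adiabatic energy required for the two-photon channel")
        c = aee + hv - diagram.threshold("vde_d0", prefer=prefer)
    else:
        return None
    return c if c > 0 else None


def simulate_2d(
    diagram: LevelDiagram,
    channels: list[ChannelSpec],
    photon_energies: np.ndarray,
    eke: np.ndarray,
    prefer: str = "measured",
) -> PESpectrum2D:
    """Deterministic forward simulation of the 2D photoelectron spectrum.

    Adds every open channel's profile column by column and normalizes the
    total to unit maximum (channel masks are scaled by the same factor).
    """
    hv_axis = np.asarray(photon_energies, dtype=float)
    eke_axis = np.asarray(eke, dtype=float)
    total = np.zeros((len(hv_axis), len(eke_axis)))
    masks = {c.kind: np.zeros_like(total) for c in channels}
    for spec in channels:
        if spec.amplitude == 0:
            continue
        contrib = np.zeros_like(total)
        if spec.kind == "low_eke":
            profile = spec.amplitude * np.exp(-eke_axis / spec.decay_eV)
            contrib[:, :] = profile[None, :]
        else:
            for i, hv in enumerate(hv_axis):
                center = _ridge_center(spec.kind, hv, diagram, prefer)
                if center is None:
                    continue
                width = spec.width_eV
                if spec.kind == "s3_broadening":
                    lo, hi = spec.hv_window
                    if not (lo <= hv <= hi):
                        continue
                    width = np.hypot(spec.width_eV, spec.extra_width_eV)
                contrib[i, :] = spec.amplitude * np.exp(
                    -((eke_axis - center) ** 2) / (2 * width**2)
                )
        masks[spec.kind] += contrib
        total += contrib
    peak = total.max()
    if peak > 0:
        total /= peak
        for kind in masks:
            masks[kind] /= peak
    return PESpectrum2D(hv_axis, eke_axis, total, masks)


def spectral_cut(spec: PESpectrum2D, hv: float) -> tuple[float, np.ndarray]:
    """1D photoelectron spectrum at the axis column nearest to hv.

    Returns (selected photon energy, intensity row).
    """
    axis = spec.photon_energies
    if hv < axis[0] - 1e-12 or hv > axis[-1] + 1e-12:
        raise IndexError(f"hv = {hv} eV outside the axis range [{axis[0]}, {axis[-1]}] eV")
    i = int(np.argmin(np.abs(axis - hv)))
    return float(axis[i]), spec.intensity[i, :].copy()


def peak_eke(eke_axis: np.ndarray, cut: np.ndarray) -> float:
    """Peak position of a 1D cut by three-point parabolic interpolation.

    Ties between equal maxima resolve to the lowest-eKE peak.  Raises on an
    all-zero cut.
    """
    y = np.asarray(cut, dtype=float)
    x = np.asarray(eke_axis, dtype=float)
    if np.all(y == 0):
        raise ValueError("cannot locate a peak in an all-zero spectrum")
    i = int(np.argmax(y))  # argmax returns the first (lowest-eKE) maximum
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    dx = x[i + 1] - x[i]
    return float(x[i] + delta * dx)
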