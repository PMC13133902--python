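"""Seeded generators for every input the analysis pipeline consumes.

The experimental beamline is replaced by pure functions of (parameters,
seed): pump-probe transients with shot-to-shot noise, laser power series,
harmonic frequency sets standing in for unavailable quantum-chemistry mode
lists, and Poisson-sampled 2D photoelectron maps.  Ground-truth parameters
travel with each synthetic object in its metadata so recovery tests never
re-derive the truth from the noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics
from .kinetics import KineticParams, Transient
from .pe_spectra import PESpectrum2D
from .power_law import PowerSeries
from .rrkm import FrequencySet

__all__ = [
    "NoiseModel",
    "default_transient_delays",
    "generate_transient",
    "generate_power_series",
    "generate_frequency_set",
    "generate_pe_counts",
]

NOISE_KINDS = ("multiplicative_lognormal", "additive_gaussian", "poisson_counts")


@dataclass(frozen=True)
class NoiseModel:
    """Noise law applied to a clean model curve.

    kind selects the law; scale is the lognormal sigma, the Gaussian
    standard deviation (signal units), or the expected total counts at
    unit signal for Poisson sampling.  Identical (kind, scale, seed) give
    bit-identical output.
    """

    kind: str = "multiplicative_lognormal"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, clean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noisy signal and its per-point 1-sigma uncertainty."""
        rng = np.random.default_rng(self.seed)
        clean = np.asarray(clean, dtype=float)
        if self.scale == 0:
            # noiseless: unit weights (any constant gives the same optimum)
            return clean.copy(), np.ones_like(clean)
        if self.kind == "multiplicative_lognormal":
            noisy = clean * rng.lognormal(0.0, self.scale, size=clean.shape)
            sigma = np.abs(clean) * self.scale
        elif self.kind == "additive_gaussian":
            noisy = clean + rng.normal(0.0, self.scale, size=clean.shape)
            sigma = np.full_like(clean, self.scale)
        else:  # poisson_counts
            lam = np.clip(clean * self.scale, 0, None)
            noisy = rng.poisson(lam).astype(float)
            sigma = np.sqrt(np.clip(lam, 1.0, None))
        # guard weights against zero-signal points
        sigma = np.where(sigma > 0, sigma, np.max(sigma) if np.max(sigma) > 0 else 1.0)
        return noisy, sigma


def default_transient_delays(
    t_min_s: float = -0.5e-12,
    t_switch_s: float = 0.5e-12,
    t_max_s: float = 400e-12,
    n_early: int = 15,
    n_late: int = 45,
) -> np.ndarray:
    """The package's standard pump-probe delay grid.

    Linear spacing through the instrument-response region (t_min..t_switch)
    where the fast component lives, then geometric spacing out to t_max for
    the slow component — 60 points in total by default.
    """
    early = np.linspace(t_min_s, t_switch_s, n_early, endpoint=False)
    late = np.geomspace(t_switch_s, t_max_s, n_late)
    return np.concatenate([early, late])


def generate_transient(
    params: KineticParams,
    delays_s: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    channel: str = "prompt",
) -> Transient:
    """Synthetic action transient: kinetic model curve plus noise.

    The true parameters and noise model are stored in the transient's
    metadata under 'truth'.
    """
    if delays_s is None:
        delays_s = default_transient_delays()
    delays_s = np.asarray(delays_s, dtype=float)
    if channel == "prompt":
        clean = kinetics.prompt_signal(params, delays_s)
    elif channel == "delayed":
        clean = kinetics.delayed_signal(params, delays_s)
    else:
        raise ValueError(f"channel must be 'prompt' or 'delayed', got {channel!r}")
    noisy, sigma = noise.apply(clean)
    return Transient(
        delays_s, noisy, sigma, channel,
        metadata={"truth": params, "noise": noise},
    )


def generate_power_series(
    c: float,
    n: float,
    pulse_energies: np.ndarray,
    noise: NoiseModel = NoiseModel(),
    wavelength_nm: float | None = None,
) -> PowerSeries:
    """Synthetic power-dependence series y = c P^n with noise."""
    if n <= 0:
        raise ValueError("photon order n must be positive")
    p = np.asarray(pulse_energies, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pulse energies must be positive")
    clean = c * p**n
    noisy, sigma = noise.apply(clean)
    return PowerSeries(
        p, noisy, sigma, wavelength_nm,
        metadata={"truth": {"c": c, "n": n}, "noise": noise},
    )


def generate_frequency_set(
    n_modes: int = 78,
    range_cm1: tuple[float, float] = (50.0, 3500.0),
    seed: int = 0,
    make_ts: bool = False,
) -> FrequencySet | tuple[FrequencySet, FrequencySet]:
    """Synthetic harmonic frequency set, uniform over range_cm1, sorted.

    The default emulates the vibrational manifold of a ~78-mode chromophore
    whose computed frequencies are not available.  With make_ts=True also
    returns a paired transition-state set: the lowest mode is removed (it
    becomes the reaction coordinate) and the remainder perturbed by a
    seeded +/-10%.
    """
    if n_modes < 2:
        raise ValueError("need at least 2 modes")
    lo, hi = range_cm1
    if lo <= 0 or hi <= lo:
        raise ValueError("frequency range must be positive and increasing")
    rng = np.random.default_rng(seed)
    freqs = np.sort(rng.uniform(lo, hi, size=n_modes))
    minimum = FrequencySet(tuple(freqs), role="minimum")
    if not make_ts:
        return minimum
    remaining = freqs[1:]
    perturbed = remaining * rng.uniform(0.9, 1.1, size=len(remaining))
    ts = FrequencySet(tuple(np.sort(perturbed)), role="transition_state")
    return minimum, ts


def generate_pe_counts(spec: PESpectrum2D, total_counts: float, seed: int = 0) -> PESpectrum2D:
    """Poisson-sampled counting twin of a simulated 2D spectrum.

    The normalized intensity is scaled so its sum equals total_counts in
    expectation, then each pixel is Poisson sampled.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    rng = np.random.default_rng(seed)
    s = spec.intensity.sum()
    lam = spec.intensity * (total_counts / s) if s > 0 else spec.intensity
    counts = rng.poisson(lam).astype(float)
    return PESpectrum2D(spec.photon_energies.copy(), spec.eke.copy(), counts)
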