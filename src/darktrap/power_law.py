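"""Photon-order analysis of laser power dependences.

An n-photon action signal scales as yield = c * P^n with the laser pulse
energy P, so the slope of log(yield) against log(P) is the photon order.
This module estimates that slope by weighted linear regression, classifies
it as one- or two-photon (or ambiguous), and normalizes action spectra by
P^n so that spectra recorded at varying pulse energy become comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PowerSeries",
    "fit_power_exponent",
    "classify_photon_order",
    "normalize_by_power",
]

log = logging.getLogger(__name__)

#: half-width of the photon-order acceptance band around integers; the floor
#: keeps sparse series from over-claiming an order on a tight formal error
AMBIGUITY_FLOOR = 0.15


@dataclass
class PowerSeries:
    """Yield versus laser pulse energy at one wavelength."""

    pulse_energy: np.ndarray
    yield_: np.ndarray
    uncertainty: np.ndarray | None = None
    wavelength_nm: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pulse_energy = np.asarray(self.pulse_energy, dtype=float)
        self.yield_ = np.asarray(self.yield_, dtype=float)
        if np.any(self.pulse_energy <= 0):
            raise ValueError("pulse energies must be positive")
        if len(np.unique(self.pulse_energy)) < 3:
            raise ValueError("need at least 3 distinct pulse energies")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)


def fit_power_exponent(series: PowerSeries) -> tuple[float, float]:
    """Photon order n and its standard error from a log-log regression.

    Zero or negative yields carry no log-domain information and are dropped
    with a logged count.  With per-point uncertainties present the regression
    is weighted by the propagated log-domain errors (sigma_y / y).
    """
    usable = series.yield_ > 0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        log.info("fit_power_exponent: dropped %d non-positive yield points", n_dropped)
    if np.sum(usable) < 3:
        raise ValueError(f"fewer than 3 usable points after dropping {n_dropped} non-positive yields")
    x = np.log(series.pulse_energy[usable])
    y = np.log(series.yield_[usable])
    if series.uncertainty is not None:
        w = (series.yield_[usable] / series.uncertainty[usable]) ** 2
        # weighted least squares: slope of y on x with weights w
        sw = w.sum()
        xb = np.sum(w * x) / sw
        yb = np.sum(w * y) / sw
        sxx = np.sum(w * (x - xb) ** 2)
        slope = np.sum(w * (x - xb) * (y - yb)) / sxx
        resid = y - (yb + slope * (x - xb))
        dof = max(len(x) - 2, 1)
        s2 = np.sum(w * resid**2) / dof
        stderr = np.sqrt(s2 / sxx)
        return float(slope), float(stderr)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def classify_photon_order(
    n: float, sigma_n: float, floor: float = AMBIGUITY_FLOOR
) -> str:
    """'one_photon', 'two_photon', or 'ambiguous' from a fitted exponent.

    The nearest integer m is accepted if |n - m| <= max(2 sigma_n, floor)
    and m is 1 or 2; anything else is ambiguous.
    """
    if sigma_n < 0:
        raise ValueError("sigma_n must be nonnegative")
    m = int(round(n))
    # tiny epsilon keeps boundary values like n = m - 0.15 inside the band
    if m in (1, 2) and abs(n - m) <= max(2.0 * sigma_n, floor) + 1e-12:
        return "one_photon" if m == 1 else "two_photon"
    return "ambiguous"


def normalize_by_power(
    yield_: np.ndarray | float, pulse_energy: np.ndarray | float, n: float
) -> np.ndarray | float:
    """yield / P^n; a series obeying y = c P^n normalizes to the constant c."""
    p = np.asarray(pulse_energy, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pulse energies must be positive")
    out = np.asarray(yield_, dtype=float) / p**n
    return float(out) if np.isscalar(yield_) and np.isscalar(pulse_energy) else out
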