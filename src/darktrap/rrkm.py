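"""RRKM / quasi-equilibrium statistical lifetime of a trapped excited state.

A molecule excited above the adiabatic origin of a bound excited state and
left there by internal conversion carries a microcanonical vibrational
energy E.  If escape to the ground state proceeds over a barrier E0 (the
lowest conical intersection on the pathway out of the excited-state
minimum), quasi-equilibrium theory gives the microcanonical rate

    k(E) = sigma * W_ts(E - E0) / (h * rho(E)),

with W_ts the harmonic sum of states of the transition-state modes (one
fewer than the minimum: the reaction coordinate is removed), rho the
density of states at the minimum, sigma a symmetry factor, and h Planck's
constant.  Sums and densities are obtained by exact Beyer-Swinehart direct
counting of the harmonic manifold on a 1 cm^-1 grid; energies are counted
above the zero-point level.

The thermal machinery averages k(E) over the canonical vibrational-energy
distribution of the stored ground-state ions at temperature T: after a pump
photon hv each ensemble member carries E = Ev + hv - AEE in the excited
state, the survival probability is S(t) = sum_Ev P(Ev) exp(-k(E) t), and
the statistical lifetime is reported as the 1/e crossing of S(t)
(a non-exponential ensemble decay makes any other "lifetime" ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EV_TO_CM1, KB_EV_K, PLANCK_EV_S

__all__ = [
    "FrequencySet",
    "StateCountGrid",
    "RateCurve",
    "ThermalEnsemble",
    "LifetimeResult",
    "count_states",
    "rrkm_rate",
    "rate_curve",
    "thermal_distribution",
    "ensemble_survival",
    "statistical_lifetime",
    "s1_lifetime",
]


@dataclass(frozen=True)
class FrequencySet:
    """Harmonic mode frequencies (cm^-1) of a stationary point.

    role is "minimum" or "transition_state"; a transition-state set has one
    fewer mode than its paired minimum (the reaction coordinate is dropped).
    """

    frequencies: tuple[float, ...]
    role: str = "minimum"

    def __post_init__(self) -> None:
        if len(self.frequencies) == 0:
            raise ValueError("frequency set must contain at least one mode")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("all mode frequencies must be positive")
        if self.role not in ("minimum", "transition_state"):
            raise ValueError(f"role must be 'minimum' or 'transition_state', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class StateCountGrid:
    """Binned harmonic sum of states W(E) and density of states rho(E).

    energies is the left edge of each bin in cm^-1 starting at 0 (measured
    above the zero-point level); W is the cumulative number of vibrational
    states up to and including each bin; rho is states per cm^-1.
    """

    bin_width: float
    energies: np.ndarray
    sum_of_states: np.ndarray
    density_of_states: np.ndarray

    def w_at(self, energy_cm1: float) -> float:
        """W(E) at an energy in cm^-1 (floor binning; 0 below the grid)."""
        if energy_cm1 < 0:
            return 0.0
        idx = int(energy_cm1 / self.bin_width)
        if idx >= len(self.energies):
            raise IndexError(
                f"energy {energy_cm1} cm^-1 beyond the grid maximum "
                f"{self.energies[-1]} cm^-1"
            )
        return float(self.sum_of_states[idx])

    def rho_at(self, energy_cm1: float) -> float:
        """rho(E) in states per cm^-1 at an energy in cm^-1."""
        if energy_cm1 < 0:
            return 0.0
        idx = int(energy_cm1 / self.bin_width)
        if idx >= len(self.energies):
            raise IndexError(
                f"energy {energy_cm1} cm^-1 beyond the grid maximum "
                f"{self.energies[-1]} cm^-1"
            )
        return float(self.density_of_states[idx])


@dataclass(frozen=True)
class RateCurve:
    """Microcanonical rate k(E) on an energy grid (eV above the excited-state
    zero-point level), with the barrier and symmetry factor that produced it."""

    energies_eV: np.ndarray
    k: np.ndarray
    barrier_eV: float
    symmetry_factor: float

    def k_at(self, energy_eV: np.ndarray | float) -> np.ndarray | float:
        """Rate at arbitrary energies by linear interpolation (0 below barrier)."""
        e = np.asarray(energy_eV, dtype=float)
        if np.any(e > self.energies_eV[-1] + 1e-12):
            raise IndexError(
                f"energy beyond the rate grid maximum {self.energies_eV[-1]:.3f} eV"
            )
        out = np.interp(e, self.energies_eV, self.k)
        out = np.where(e < self.barrier_eV, 0.0, out)
        return float(out) if np.isscalar(energy_eV) else out


@dataclass(frozen=True)
class ThermalEnsemble:
    """Canonical vibrational-energy distribution P(Ev) of the stored ions."""

    temperature: float
    energies_cm1: np.ndarray
    probabilities: np.ndarray

    def mean_energy_cm1(self) -> float:
        return float(np.sum(self.energies_cm1 * self.probabilities))


@dataclass(frozen=True)
class LifetimeResult:
    """Statistical lifetime with the survival curve it was read off."""

    tau_s: float
    temperature: float
    excitation_wavelength_nm: float
    times_s: np.ndarray
    survival: np.ndarray


def _direct_count_py(rs: np.ndarray, n_bins: int) -> np.ndarray:
    counts = np.zeros(n_bins)
    counts[0] = 1.0
    for r in rs:
        for i in range(r, n_bins):
            counts[i] += counts[i - r]
    return counts


try:
    from numba import njit

    _direct_count = njit(cache=False)(_direct_count_py)
except ImportError:  # pragma: no cover
    _direct_count = _direct_count_py


def count_states(freqs: FrequencySet, emax_cm1: float, bin_cm1: float = 1.0) -> StateCountGrid:
    """Exact harmonic sum and density of states by Beyer-Swinehart direct count.

    Each frequency is rounded to the nearest nonzero grid multiple; the count
    is exact for the rounded frequencies.  Energies are measured above the
    zero-point level, so W(0) = 1 (the vibrational ground state).
    """
    if bin_cm1 <= 0 or emax_cm1 < bin_cm1:
        raise ValueError("need emax >= bin > 0")
    n_bins = int(np.floor(emax_cm1 / bin_cm1)) + 1
    rs = np.array([max(1, int(round(f / bin_cm1))) for f in freqs.frequencies], dtype=np.int64)
    counts = _direct_count(rs, n_bins)
    w = np.cumsum(counts)
    rho = counts / bin_cm1
    energies = np.arange(n_bins) * bin_cm1
    return StateCountGrid(bin_cm1, energies, w, rho)


#: default width (cm^-1) of the window over which the exact density is
#: averaged before entering a rate; suppresses bin-to-bin shot noise of the
#: direct count without materially biasing smooth densities.
RHO_WINDOW_CM1 = 100.0


def _windowed_rho_cm1(grid: StateCountGrid, e_cm1: float, window_cm1: float) -> float:
    """Density of states (per cm^-1) as a centred window average of the count.

    The window is snapped to whole bins so the counted states and the width
    they are divided by always correspond, whatever the bin size.
    """
    if window_cm1 <= 0:
        return grid.rho_at(e_cm1)
    b = grid.bin_width
    half = window_cm1 / 2.0
    i_lo = max(0, int(np.ceil((e_cm1 - half) / b)))
    i_hi = min(len(grid.energies) - 1, int(np.floor((e_cm1 + half) / b)))
    if i_hi < i_lo:
        return grid.rho_at(e_cm1)
    counts = grid.sum_of_states[i_hi] - (grid.sum_of_states[i_lo - 1] if i_lo > 0 else 0.0)
    width = (i_hi - i_lo + 1) * b
    return counts / width


def rrkm_rate(
    energy_eV: float,
    grid_min: StateCountGrid,
    grid_ts: StateCountGrid,
    barrier_eV: float,
    sigma: float = 1.0,
    rho_window_cm1: float = RHO_WINDOW_CM1,
) -> float:
    """Microcanonical rate k(E) = sigma W_ts(E - E0) / (h rho_min(E)) in s^-1.

    E is the vibrational energy above the minimum's zero-point level;
    returns 0 below the barrier.  rho is the window-averaged exact density
    converted to states per eV; set ``rho_window_cm1=0`` for the raw per-bin
    density.
    """
    if barrier_eV <= 0:
        raise ValueError("barrier must be positive")
    if sigma <= 0:
        raise ValueError("symmetry factor must be positive")
    if energy_eV < barrier_eV:
        return 0.0
    e_cm1 = energy_eV * EV_TO_CM1
    ets_cm1 = (energy_eV - barrier_eV) * EV_TO_CM1
    w_ts = grid_ts.w_at(ets_cm1)
    rho = _windowed_rho_cm1(grid_min, e_cm1, rho_window_cm1) * EV_TO_CM1  # per eV
    if rho == 0.0:
        # no accessible states at this energy on the counted grid
        return 0.0
    return sigma * w_ts / (PLANCK_EV_S * rho)


def rate_curve(
    freqs_min: FrequencySet,
    freqs_ts: FrequencySet,
    barrier_eV: float,
    emax_eV: float,
    sigma: float = 1.0,
    bin_cm1: float = 1.0,
    de_eV: float = 0.002,
    rho_window_cm1: float = RHO_WINDOW_CM1,
) -> RateCurve:
    """k(E) sampled on a uniform energy grid 0..emax_eV (step ``de_eV``)."""
    if len(freqs_ts) != len(freqs_min) - 1:
        raise ValueError(
            "transition-state set must have exactly one fewer mode than the minimum "
            f"({len(freqs_ts)} vs {len(freqs_min)})"
        )
    emax_cm1 = emax_eV * EV_TO_CM1 + 2 * rho_window_cm1 + 100 * bin_cm1
    gmin = count_states(freqs_min, emax_cm1, bin_cm1)
    gts = count_states(freqs_ts, emax_cm1, bin_cm1)
    energies = np.arange(0.0, emax_eV + de_eV / 2, de_eV)
    k = np.array(
        [
            rrkm_rate(e, gmin, gts, barrier_eV, sigma, rho_window_cm1)
            for e in energies
        ]
    )
    return RateCurve(energies, k, barrier_eV, sigma)


def thermal_distribution(
    freqs_s0: FrequencySet,
    temperature: float,
    emax_cm1: float | None = None,
    bin_cm1: float = 1.0,
) -> ThermalEnsemble:
    """Canonical distribution P(Ev) ~ rho_S0(Ev) exp(-Ev / kB T) on the grid.

    T = 0 gives a point mass at Ev = 0.  The default grid maximum is chosen
    so that the truncated Boltzmann tail is negligible (the harmonic mean
    energy plus a generous multiple of kB T per mode).
    """
    if temperature < 0:
        raise ValueError("temperature must be nonnegative")
    if temperature == 0:
        energies = np.array([0.0])
        return ThermalEnsemble(0.0, energies, np.array([1.0]))
    kbt_cm1 = KB_EV_K * temperature * EV_TO_CM1
    if emax_cm1 is None:
        # mean and variance of the canonical harmonic energy fix the grid:
        # 12 standard deviations beyond the mean leaves a negligible tail
        nu = np.asarray(freqs_s0.frequencies)
        nbar = 1.0 / np.expm1(nu / kbt_cm1)
        mean = float(np.sum(nu * nbar))
        var = float(np.sum(nu**2 * nbar * (1.0 + nbar)))
        emax_cm1 = mean + 12.0 * np.sqrt(var) + 5.0 * kbt_cm1 + 20.0 * bin_cm1
    grid = count_states(freqs_s0, emax_cm1, bin_cm1)
    log_p = np.log(np.where(grid.density_of_states > 0, grid.density_of_states, 1.0))
    log_p -= grid.energies / kbt_cm1
    p = np.where(grid.density_of_states > 0, np.exp(log_p - log_p.max()), 0.0)
    p /= p.sum()
    if p[-1] > 1e-10 * p.max():
        raise ValueError("thermal grid too small: distribution not converged at emax")
    return ThermalEnsemble(temperature, grid.energies, p)


def ensemble_survival(
    ensemble: ThermalEnsemble,
    hv_eV: float,
    aee_eV: float,
    rates: RateCurve,
    times_s: np.ndarray,
) -> np.ndarray:
    """Survival S(t) of the photoexcited ensemble in the trapped state.

    Each member with ground-state vibrational energy Ev carries
    E = Ev + hv - AEE in the excited state and decays as exp(-k(E) t);
    S(t) is the probability-weighted average.
    """
    if hv_eV < aee_eV:
        raise ValueError(f"photon {hv_eV} eV cannot reach the state origin at {aee_eV} eV")
    e_excited = ensemble.energies_cm1 / EV_TO_CM1 + (hv_eV - aee_eV)
    k = np.asarray(rates.k_at(e_excited))
    times = np.asarray(times_s, dtype=float)
    return (ensemble.probabilities[None, :] * np.exp(-np.outer(times, k))).sum(axis=1)


def statistical_lifetime(times_s: np.ndarray, survival: np.ndarray) -> float:
    """Lifetime as the 1/e crossing of S(t), by linear interpolation in log S."""
    s = np.asarray(survival, dtype=float)
    t = np.asarray(times_s, dtype=float)
    target = 1.0 / np.e
    below = np.nonzero(s <= target)[0]
    if len(below) == 0 or below[0] == 0:
        raise ValueError(
            "survival curve does not cross 1/e inside the sampled window; "
            "widen the time window"
        )
    i = below[0]
    # monotone linear interpolation in log S between the bracketing samples
    ls0, ls1 = np.log(s[i - 1]), np.log(s[i])
    frac = (-1.0 - ls0) / (ls1 - ls0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def s1_lifetime(
    freqs_min: FrequencySet,
    freqs_ts: FrequencySet,
    barrier_eV: float,
    temperature: float,
    pump_nm: float,
    aee_eV: float,
    sigma: float = 1.0,
    bin_cm1: float = 1.0,
) -> LifetimeResult:
    """Full pipeline: thermal ensemble -> excitation -> k(E) -> S(t) -> tau.

    The ground-state frequencies are reused for the excited-state minimum
    manifold when a separate set is not supplied upstream; callers with
    distinct S0/S1 sets should build the pieces directly.
    """
    from .constants import HC_EV_NM

    hv = HC_EV_NM / pump_nm
    ensemble = thermal_distribution(freqs_min, temperature, bin_cm1=bin_cm1)
    emax = hv - aee_eV + ensemble.energies_cm1[-1] / EV_TO_CM1 + 0.05
    rates = rate_curve(freqs_min, freqs_ts, barrier_eV, emax, sigma=sigma, bin_cm1=bin_cm1)
    e_excited = ensemble.energies_cm1 / EV_TO_CM1 + (hv - aee_eV)
    k = np.asarray(rates.k_at(e_excited))
    k_pos = k[k > 0]
    if len(k_pos) == 0:
        raise ValueError("no ensemble member is above the barrier; lifetime is infinite")
    t_lo = 0.001 / k_pos.max()
    t_hi = 1000.0 / (np.sum(ensemble.probabilities[k > 0] * k_pos) / ensemble.probabilities[k > 0].sum())
    times = np.geomspace(t_lo, t_hi, 400)
    times = np.concatenate([[0.0], times])
    surv = ensemble_survival(ensemble, hv, aee_eV, rates, times)
    tau = statistical_lifetime(times, surv)
    return LifetimeResult(tau, temperature, pump_nm, times, surv)
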