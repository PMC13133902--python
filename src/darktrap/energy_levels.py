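"""Photodetachment channel energetics over a calculated/measured level diagram.

The central object is a :class:`LevelDiagram`: the electronic states of an
anionic chromophore (labelled S0, S1, S2, ... for the anion and D0, D1n, ...
for the neutral radical) together with the detachment thresholds VDE(D0),
ADE(D0) and VDE(D1n).  All energies are in eV relative to the anion S0
minimum.  The operations in this module are the bookkeeping a photoelectron
spectroscopist does on such a diagram: electron kinetic energies (eKE) for
direct and excited-state detachment, binding energies from measured peak
positions, excess vibrational energies after internal conversion, and the
assignment of (photon energy, eKE) pixels to the spectral regions

    i    direct detachment to D0 (eKE = hv - VDE(D0)),
    ii   direct detachment to the excited neutral D1n,
    iii  two-photon detachment via a trapped intermediate state
         (eKE up to AEE + hv - VDE(D0), i.e. above the direct line),
    iv   low-eKE electrons from statistical/thermionic emission,
    v    broadening of the direct ridge inside a resonance window.

Channels that are energetically closed are returned as flagged values, not
exceptions, so a forward simulator can iterate over all channels uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import HC_EV_NM

__all__ = [
    "StateLevel",
    "ThresholdValue",
    "LevelDiagram",
    "Photon",
    "ChannelEnergy",
    "ClosedChannelError",
    "MissingStateError",
    "InconsistentEnergeticsError",
    "photon_energy",
    "photon_wavelength",
    "eke_direct",
    "eke_from_excited",
    "excess_vibrational_energy",
    "binding_energy_from_peak",
    "aee_from_photoelectron",
    "classify_channel",
    "REGION_LABELS",
]

REGION_LABELS = ("i", "ii", "iii", "iv", "v", "unassigned")


class ClosedChannelError(ValueError):
    """The requested process is energetically forbidden."""


class MissingStateError(KeyError):
    """A state label or threshold required for the operation is absent."""


class InconsistentEnergeticsError(ValueError):
    """Input energies violate the energetic ordering they must satisfy."""


@dataclass(frozen=True)
class StateLevel:
    """One electronic state of the anion or the neutral radical.

    Energies are in eV relative to the anion S0 minimum.  The vertical
    energy (at the S0 equilibrium geometry) and the oscillator strength of
    the transition from S0 are optional because not every state has them
    tabulated.
    """

    label: str
    species: str  # "anion" | "neutral"
    adiabatic_energy: float | None = None
    vertical_energy: float | None = None
    oscillator_strength_from_S0: float | None = None

    def __post_init__(self) -> None:
        if self.species not in ("anion", "neutral"):
            raise ValueError(f"species must be 'anion' or 'neutral', got {self.species!r}")
        if (
            self.adiabatic_energy is not None
            and self.vertical_energy is not None
            and self.adiabatic_energy > self.vertical_energy + 1e-12
        ):
            raise ValueError(
                f"state {self.label}: adiabatic energy {self.adiabatic_energy} eV "
                f"exceeds vertical energy {self.vertical_energy} eV"
            )
        if self.label == "S0" and self.adiabatic_energy not in (None, 0, 0.0):
            raise ValueError("S0 defines the energy origin; its adiabatic energy must be 0")
        f = self.oscillator_strength_from_S0
        if f is not None and f < 0:
            raise ValueError(f"oscillator strength must be >= 0, got {f}")


@dataclass(frozen=True)
class ThresholdValue:
    """A detachment threshold with its provenance (calculated or measured)."""

    value_eV: float
    provenance: str  # "calculated" | "measured"

    def __post_init__(self) -> None:
        if self.value_eV <= 0:
            raise ValueError(f"threshold must be positive, got {self.value_eV} eV")
        if self.provenance not in ("calculated", "measured"):
            raise ValueError(f"provenance must be 'calculated' or 'measured', got {self.provenance!r}")


@dataclass
class LevelDiagram:
    """Electronic states plus detachment thresholds of the anion.

    Thresholds are stored as ``{provenance: ThresholdValue}`` mappings so the
    measured (e.g. VDE 2.63 eV) and calculated (2.54 eV) values coexist;
    each operation takes explicit numbers so the caller chooses which.
    """

    states: dict[str, StateLevel] = field(default_factory=dict)
    vde_d0: dict[str, ThresholdValue] = field(default_factory=dict)
    ade_d0: dict[str, ThresholdValue] = field(default_factory=dict)
    vde_d1n: dict[str, ThresholdValue] = field(default_factory=dict)
    #: conical-intersection barrier heights in eV above the S1 minimum
    meci: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prov in set(self.ade_d0) & set(self.vde_d0):
            if self.ade_d0[prov].value_eV > self.vde_d0[prov].value_eV + 1e-12:
                raise ValueError(
                    f"ADE(D0) ({prov}) exceeds VDE(D0) ({prov}): "
                    f"{self.ade_d0[prov].value_eV} > {self.vde_d0[prov].value_eV}"
                )

    def state(self, label: str) -> StateLevel:
        try:
            return self.states[label]
        except KeyError:
            raise MissingStateError(f"state {label!r} not in diagram "
                                    f"(have {sorted(self.states)})") from None

    def threshold(self, name: str, prefer: str = "measured") -> float:
        """Threshold in eV; ``prefer`` provenance, falling back to the other."""
        table = {"vde_d0": self.vde_d0, "ade_d0": self.ade_d0, "vde_d1n": self.vde_d1n}
        try:
            entries = table[name]
        except KeyError:
            raise MissingStateError(f"unknown threshold {name!r}") from None
        if not entries:
            raise MissingStateError(f"threshold {name!r} not present in diagram")
        if prefer in entries:
            return entries[prefer].value_eV
        return next(iter(entries.values())).value_eV


@dataclass(frozen=True)
class Photon:
    """A photon specified by wavelength (nm) or energy (eV); the other derived."""

    wavelength_nm: float
    energy_eV: float

    @classmethod
    def from_wavelength(cls, wavelength_nm: float) -> "Photon":
        return cls(wavelength_nm, photon_energy(wavelength_nm))

    @classmethod
    def from_energy(cls, energy_eV: float) -> "Photon":
        return cls(photon_wavelength(energy_eV), energy_eV)

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.energy_eV <= 0:
            raise ValueError("photon wavelength and energy must be positive")
        if abs(self.energy_eV * self.wavelength_nm / HC_EV_NM - 1.0) > 1e-6:
            raise ValueError("wavelength and energy are inconsistent with hc")


@dataclass(frozen=True)
class ChannelEnergy:
    """An eKE (or internal-energy) result with an open/closed channel flag.

    ``value_eV`` is the signed arithmetic result; ``open`` is False when the
    channel is energetically closed (value <= 0).
    """

    value_eV: float
    open: bool

    def __float__(self) -> float:
        return self.value_eV


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy in eV for a wavelength in nm (E = hc / lambda)."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm} nm")
    return HC_EV_NM / wavelength_nm


def photon_wavelength(energy_eV: float) -> float:
    """Photon wavelength in nm for an energy in eV (inverse of photon_energy)."""
    if energy_eV <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_eV} eV")
    return HC_EV_NM / energy_eV


def eke_direct(hv: float, vde: float) -> ChannelEnergy:
    """eKE for direct one-photon detachment, hv + S0 -> D0 + e-.

    Returns hv - VDE; a non-positive value is flagged closed rather than
    raising, so channel scans stay uniform.
    """
    if hv <= 0 or vde <= 0:
        raise ValueError("photon energy and VDE must be positive")
    value = hv - vde
    return ChannelEnergy(value, value > 0)


def eke_from_excited(aee_state: float, hv: float, vde_neutral: float) -> ChannelEnergy:
    """Maximum eKE for detachment out of an excited anion state.

    An anion trapped in a state of adiabatic excitation energy ``aee_state``
    absorbing a further photon hv can emit electrons with kinetic energy up
    to AEE + hv - VDE.  With ``aee_state = 0`` this reduces to
    :func:`eke_direct`.
    """
    if aee_state < 0 or hv < 0 or vde_neutral < 0:
        raise ValueError("energies must be nonnegative")
    value = aee_state + hv - vde_neutral
    return ChannelEnergy(value, value > 0)


def excess_vibrational_energy(hv_pump: float, aee_state: float) -> float:
    """Vibrational energy left in an excited state populated by internal
    conversion after pumping with ``hv_pump`` (eV above the state's minimum)."""
    if hv_pump < aee_state:
        raise ClosedChannelError(
            f"pump photon {hv_pump} eV cannot reach a state at {aee_state} eV"
        )
    return hv_pump - aee_state


def binding_energy_from_peak(hv_probe: float, eke_peak: float) -> float:
    """Electron binding energy from a measured photoelectron peak, hv - eKE."""
    if eke_peak < 0:
        raise InconsistentEnergeticsError(f"peak eKE must be >= 0, got {eke_peak}")
    if eke_peak > hv_probe:
        raise InconsistentEnergeticsError(
            f"peak eKE {eke_peak} eV exceeds the probe photon energy {hv_probe} eV"
        )
    return hv_probe - eke_peak


def aee_from_photoelectron(vde_d0: float, binding_s1: float) -> float:
    """Adiabatic excitation energy of a trapped state from its measured
    electron binding energy: AEE = VDE(D0) - BE."""
    if binding_s1 > vde_d0:
        raise InconsistentEnergeticsError(
            f"binding energy {binding_s1} eV exceeds VDE(D0) {vde_d0} eV"
        )
    return vde_d0 - binding_s1


def classify_channel(
    hv: float,
    eke: float,
    diagram: LevelDiagram,
    tol: float = 0.1,
    *,
    low_eke_cutoff: float = 0.1,
    broadening_tol: float | None = None,
    s3_window: tuple[float, float] = (3.6, 3.9),
    prefer: str = "measured",
) -> str:
    """Assign a (photon energy, eKE) pixel to a spectral region.

    Deterministic priority order iii > i > ii > v > iv > unassigned:
    two-photon electrons (iii) are defined precisely by exceeding the direct
    line, so they are tested first; the broadened resonance region (v) only
    claims pixels inside its photon-energy window that the sharp direct
    ridge (i) did not.

    Parameters
    ----------
    tol : half-width in eV of the direct ridge assignment bands (i, ii).
    low_eke_cutoff : eKE below which pixels are statistical emission (iv).
    broadening_tol : wider band for region v; defaults to 3 * tol.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if broadening_tol is None:
        broadening_tol = 3.0 * tol
    vde = diagram.threshold("vde_d0", prefer=prefer)
    direct = hv - vde
    if eke > direct + tol:
        return "iii"
    # a direct ridge can only claim pixels when its channel is open
    if direct > 0 and abs(eke - direct) <= tol:
        return "i"
    if diagram.vde_d1n:
        direct_d1n = hv - diagram.threshold("vde_d1n", prefer=prefer)
        if direct_d1n > 0 and abs(eke - direct_d1n) <= tol:
            return "ii"
    lo, hi = s3_window
    if lo <= hv <= hi and abs(eke - direct) <= broadening_tol:
        return "v"
    if eke <= low_eke_cutoff:
        return "iv"
    return "unassigned"
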