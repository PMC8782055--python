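"""Rutherford single-collision cross sections and equivalent-dose arithmetic.

To put different HZE ions (He, Ar, Fe) on a single damage axis, the delivered
absorbed dose is rescaled by the ratio of single-collision elastic cross
sections computed from Rutherford's relation

    sigma = pi * M1 * (Z1 * Z2 * e^2)^2 / (M2 * E) * integral(dT / T^2)

where (M1, Z1) are the projectile mass and charge, (M2, Z2) the target atom,
E the projectile kinetic energy and T the energy transferred in the
collision.  Only ratios of cross sections between ions are physically used
downstream: the target properties, the e^2 constant and the transfer window
all cancel, leaving sigma_a / sigma_b = (M1 Z1^2 / E)_a / (M1 Z1^2 / E)_b
with E in the per-nucleon convention.  Absolute sigma values are therefore
returned in arbitrary units.

The Fe beam is the conventional reference: an "equivalent dose" Phi is the
delivered dose multiplied by the ion's Fe-normalized cross section.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidInputError, InvalidWindowError

__all__ = [
    "IonBeam",
    "TargetMedium",
    "EnergyTransferWindow",
    "rutherford_sigma",
    "normalized_sigma",
    "equivalent_dose",
    "exposure_duration",
    "space_exposure_years",
]


@dataclass(frozen=True)
class IonBeam:
    """An accelerated ion beam as delivered by the facility.

    Parameters
    ----------
    name:
        Ion label, e.g. ``"Fe"``.
    mass_amu:
        Projectile mass M1 in atomic mass units.
    atomic_number:
        Projectile charge number Z1.
    energy_mev_per_nucleon:
        Kinetic energy per nucleon E/A in MeV/n.
    let_kev_per_um:
        Linear energy transfer in keV/um (bookkeeping only; not used in the
        cross-section ratio).
    dose_rate_gy_per_min:
        Facility dose rate in Gy/min, used for irradiation-duration
        arithmetic.  May be ``None`` for beams defined only for
        cross-section work.
    """

    name: str
    mass_amu: float
    atomic_number: int
    energy_mev_per_nucleon: float
    let_kev_per_um: float | None = None
    dose_rate_gy_per_min: float | None = None

    def __post_init__(self) -> None:
        if self.mass_amu <= 0:
            raise InvalidInputError(f"beam {self.name!r}: mass_amu must be > 0")
        if self.atomic_number < 1:
            raise InvalidInputError(f"beam {self.name!r}: atomic_number must be >= 1")
        if self.energy_mev_per_nucleon <= 0:
            raise InvalidInputError(
                f"beam {self.name!r}: energy_mev_per_nucleon must be > 0"
            )

    @property
    def sigma_factor(self) -> float:
        """M1 * Z1^2 / E (E per nucleon) — the part of sigma that differs between ions."""
        return self.mass_amu * self.atomic_number**2 / self.energy_mev_per_nucleon


@dataclass(frozen=True)
class TargetMedium:
    """Target atom (M2, Z2) struck by the projectile."""

    mass_amu: float
    atomic_number: int

    def __post_init__(self) -> None:
        if self.mass_amu <= 0 or self.atomic_number <= 0:
            raise InvalidInputError("target mass and atomic number must be > 0")


@dataclass(frozen=True)
class EnergyTransferWindow:
    """Integration bounds [t_min, t_max] for the transferred energy T (eV)."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_min <= 0:
            raise InvalidInputError("t_min must be > 0")
        if self.t_min >= self.t_max:
            raise InvalidWindowError(
                f"t_min ({self.t_min}) must be strictly below t_max ({self.t_max})"
            )


def default_transfer_window(
    beam: IonBeam, target: TargetMedium, t_min_ev: float = 10.0
) -> EnergyTransferWindow:
    """Default window: 10 eV up to the classical elastic maximum
    T_max = 4 M1 M2 E / (M1 + M2)^2, with E the per-nucleon energy in eV.

    Ratios between ions do not depend on the window; it only fixes the
    arbitrary scale of absolute cross sections.
    """
    e_ev = beam.energy_mev_per_nucleon * 1e6
    t_max = 4 * beam.mass_amu * target.mass_amu * e_ev / (beam.mass_amu + target.mass_amu) ** 2
    return EnergyTransferWindow(t_min_ev, t_max)


def rutherford_sigma(
    beam: IonBeam, target: TargetMedium, window: EnergyTransferWindow
) -> float:
    """Single-collision elastic cross section, arbitrary units.

    Evaluates pi * M1 (Z1 Z2)^2 / (M2 E) * (1/t_min - 1/t_max), i.e. the
    closed form of the 1/T^2 transfer integral, with e^2 absorbed into the
    unit system and E in the per-nucleon convention.  Only ratios between
    two beams are guaranteed physically meaningful.
    """
    import math

    integral = 1.0 / window.t_min - 1.0 / window.t_max
    return (
        math.pi
        * beam.mass_amu
        * (beam.atomic_number * target.atomic_number) ** 2
        / (target.mass_amu * beam.energy_mev_per_nucleon)
        * integral
    )


def normalized_sigma(beam: IonBeam, reference: IonBeam) -> float:
    """Cross-section ratio sigma(beam) / sigma(reference).

    Computed in the ratio form where target properties and the transfer
    window cancel exactly: (M1 Z1^2 / E)_beam / (M1 Z1^2 / E)_ref, E per
    nucleon.  For the study's beams (Ar at 500 MeV/n vs Fe at 500 MeV/n)
    this evaluates to 0.343 -> 0.34 at two decimals.
    """
    return beam.sigma_factor / reference.sigma_factor


def equivalent_dose(dose_gy: float, beam: IonBeam, reference: IonBeam) -> float:
    """Reference-ion-equivalent dose Phi = dose * sigma(beam)/sigma(reference).

    Linear in dose; identity when ``beam`` is the reference.
    """
    if dose_gy < 0:
        raise InvalidInputError("dose_gy must be >= 0")
    return dose_gy * normalized_sigma(beam, reference)


def exposure_duration(dose_gy: float, beam: IonBeam) -> float:
    """Irradiation duration in minutes to deliver ``dose_gy`` at the beam's rate.

    Returns the exact quotient; round to 0.1 min for display (facility logs
    quote durations to one decimal).
    """
    if dose_gy < 0:
        raise InvalidInputError("dose_gy must be >= 0")
    rate = beam.dose_rate_gy_per_min
    if rate is None or rate <= 0:
        raise InvalidInputError(
            f"beam {beam.name!r} needs a positive dose_rate_gy_per_min"
        )
    return dose_gy / rate


def space_exposure_years(
    tolerated_dose_gy: float, flux_lo: float = 0.2, flux_hi: float = 0.5
) -> tuple[float, float]:
    """Years of open-space exposure corresponding to a tolerated dose.

    The ambient galactic-cosmic-ray dose rate in open space is taken as
    0.2-0.5 Gy/year; a tolerated dose D maps to the residence interval
    (D/flux_hi, D/flux_lo).
    """
    if flux_lo <= 0 or flux_hi <= 0:
        raise InvalidInputError("fluxes must be > 0")
    if flux_lo >= flux_hi:
        raise InvalidInputError("flux_lo must be < flux_hi")
    if tolerated_dose_gy < 0:
        raise InvalidInputError("tolerated_dose_gy must be >= 0")
    return tolerated_dose_gy / flux_hi, tolerated_dose_gy / flux_lo
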