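"""Radionuclide constants, source regions, and the sphere-model self-dose factor.

The dose model is the standard local-deposition sphere approximation for a
beta/Auger emitter such as Lu-177: every electron emitted inside a region
deposits its energy in that region, so the absorbed dose per unit
time-integrated activity (the self-dose S factor) is simply the electron
energy released per decay divided by the region mass.  An optional photon
self-absorption table can add the (small) photon contribution as a
mass-dependent fractional increase.

Units are fixed package-wide: time in hours, activity in MBq,
time-integrated activity in MBq*h, mass in grams, dose in mGy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import DomainError

#: decays per MBq*h (1e6 decays/s * 3600 s)
DECAYS_PER_MBQ_H = 3.6e9
#: joules per keV
J_PER_KEV = 1.602176634e-16


def _load_defaults() -> dict[str, str]:
    text = resources.files("lutadose").joinpath("data/lu177_defaults.txt").read_text()
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


_DEFAULTS = _load_defaults()

DEFAULT_DENSITIES = {
    "kidney": float(_DEFAULTS["density.kidney"]),
    "lesion_soft": float(_DEFAULTS["density.lesion_soft"]),
    "lesion_bone": float(_DEFAULTS["density.lesion_bone"]),
}
DEFAULT_GLAND_MASSES = {
    "parotid": float(_DEFAULTS["mass.parotid"]),
    "submandibular": float(_DEFAULTS["mass.submandibular"]),
}
KIDNEY_LIMIT_GY = float(_DEFAULTS["limit.kidney_Gy"])
GLAND_LIMIT_GY = float(_DEFAULTS["limit.salivary_gland_Gy"])


class RegionKind(str, Enum):
    """Kinds of dosimetry source regions handled by the pipeline."""

    KIDNEY = "kidney"
    PAROTID = "parotid"
    SUBMANDIBULAR = "submandibular"
    LESION_BONE = "lesion_bone"
    LESION_SOFT = "lesion_soft"

    @property
    def is_lesion(self) -> bool:
        return self in (RegionKind.LESION_BONE, RegionKind.LESION_SOFT)

    @property
    def is_organ(self) -> bool:
        return not self.is_lesion


ORGAN_KINDS = (RegionKind.KIDNEY, RegionKind.PAROTID, RegionKind.SUBMANDIBULAR)
LESION_KINDS = (RegionKind.LESION_BONE, RegionKind.LESION_SOFT)


def decay_constant(half_life_h: float) -> float:
    """Decay (or clearance) rate constant, per hour, from a half-life in hours."""
    if not half_life_h > 0:
        raise DomainError(f"half-life must be positive, got {half_life_h}")
    return math.log(2.0) / half_life_h


def mass_from_volume(volume_ml: float, density_g_per_ml: float) -> float:
    """Region mass in grams from a segmented volume (ml) and tissue density."""
    if not volume_ml > 0:
        raise DomainError(f"volume must be positive, got {volume_ml}")
    if not density_g_per_ml > 0:
        raise DomainError(f"density must be positive, got {density_g_per_ml}")
    return volume_ml * density_g_per_ml


@dataclass(frozen=True)
class Radionuclide:
    """Physics of the therapy nuclide.

    Parameters
    ----------
    physical_half_life_h:
        Physical half-life, hours.
    electron_energy_per_decay_keV:
        Mean energy of all electron emissions (beta, conversion, Auger)
        per decay, keV; assumed locally deposited.
    photon_dose_fraction_table:
        Optional ``(mass_g, fraction)`` pairs giving the photon self-dose
        as a fraction of the electron self-dose; interpolated log-log in
        mass.  ``None`` disables the photon term.
    """

    name: str = _DEFAULTS["nuclide.name"]
    physical_half_life_h: float = float(_DEFAULTS["nuclide.physical_half_life_h"])
    electron_energy_per_decay_keV: float = float(
        _DEFAULTS["nuclide.electron_energy_per_decay_keV"]
    )
    photon_dose_fraction_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.physical_half_life_h > 0:
            raise DomainError("physical half-life must be positive")
        if not self.electron_energy_per_decay_keV > 0:
            raise DomainError("electron energy per decay must be positive")
        if self.photon_dose_fraction_table is not None:
            table = tuple(tuple(row) for row in self.photon_dose_fraction_table)
            masses = [m for m, _ in table]
            fracs = [f for _, f in table]
            if any(m2 <= m1 for m1, m2 in zip(masses, masses[1:])) or not all(
                m > 0 for m in masses
            ):
                raise DomainError("photon table masses must be positive, strictly increasing")
            if not all(0 <= f < 1 for f in fracs):
                raise DomainError("photon fractions must lie in [0, 1)")
            object.__setattr__(self, "photon_dose_fraction_table", table)

    @property
    def decay_constant_h(self) -> float:
        return decay_constant(self.physical_half_life_h)

    def photon_fraction(self, mass_g: float) -> float:
        """Photon self-dose fraction at a given mass (0 if no table)."""
        if self.photon_dose_fraction_table is None:
            return 0.0
        masses = np.array([m for m, _ in self.photon_dose_fraction_table])
        fracs = np.array([f for _, f in self.photon_dose_fraction_table])
        # log-log interpolation, clamped at the table ends
        return float(
            np.exp(
                np.interp(
                    np.log(mass_g),
                    np.log(masses),
                    np.log(np.maximum(fracs, 1e-300)),
                )
            )
        ) if len(masses) > 1 else float(fracs[0])


LU177 = Radionuclide()


@dataclass(frozen=True)
class SourceRegion:
    """A dosimetry target: an organ at risk or a tumor lesion.

    Mass may be given directly (salivary glands use ICRP reference masses)
    or derived from a segmented volume and a kind-specific default density.
    """

    region_id: str
    kind: RegionKind
    mass_g: float = 0.0
    volume_ml: float | None = None
    density_g_per_ml: float | None = field(default=None)

    def __post_init__(self) -> None:
        kind = RegionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        density = self.density_g_per_ml
        if density is None:
            density = DEFAULT_DENSITIES.get(kind.value)
        mass = self.mass_g
        if self.volume_ml is not None:
            if density is None:
                raise DomainError(
                    f"region kind {kind.value!r} has no default density; give density_g_per_ml"
                )
            mass = mass_from_volume(self.volume_ml, density)
        elif not mass:
            mass = DEFAULT_GLAND_MASSES.get(kind.value, 0.0)
        if not mass > 0:
            raise DomainError(f"region {self.region_id!r}: mass must be positive")
        object.__setattr__(self, "mass_g", float(mass))
        object.__setattr__(self, "density_g_per_ml", density)


def self_dose_factor(region: SourceRegion, nuclide: Radionuclide = LU177) -> float:
    """Sphere-model self-dose S factor in mGy per MBq*h.

    Electrons are assumed fully absorbed in the source region (absorbed
    fraction 1), so ``S = N * E_e / m`` with N the number of decays per
    MBq*h and E_e the mean electron energy per decay.  If the nuclide
    carries a photon self-dose table the factor is multiplied by
    ``1 + photon_fraction(mass)``.
    """
    if not region.mass_g > 0:
        raise DomainError("region mass must be positive")
    energy_j = DECAYS_PER_MBQ_H * nuclide.electron_energy_per_decay_keV * J_PER_KEV
    dose_gy = energy_j / (region.mass_g * 1e-3)
    return dose_gy * 1e3 * (1.0 + nuclide.photon_fraction(region.mass_g))


def default_density(kind: RegionKind | str) -> float | None:
    """Default tissue density for a region kind, or None if mass-based."""
    return DEFAULT_DENSITIES.get(RegionKind(kind).value)


def make_region(
    region_id: str,
    kind: RegionKind | str,
    *,
    mass_g: float | None = None,
    volume_ml: float | None = None,
    density_g_per_ml: float | None = None,
) -> SourceRegion:
    """Convenience constructor applying kind defaults (densities, gland masses)."""
    return SourceRegion(
        region_id=region_id,
        kind=RegionKind(kind),
        mass_g=mass_g or 0.0,
        volume_ml=volume_ml,
        density_g_per_ml=density_g_per_ml,
    )


def sorted_unique(values: Sequence[float]) -> np.ndarray:
    """Strictly increasing array; raises if duplicates present."""
    arr = np.asarray(values, dtype=float)
    srt = np.sort(arr)
    if len(srt) > 1 and np.any(np.diff(srt) <= 0):
        raise DomainError("times must be strictly increasing (no duplicates)")
    return srt
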