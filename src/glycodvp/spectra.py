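"""Wavelength-dependent optical constants of the finger chromophores.

The device records transmissive digital volume pulse (DVP) waveforms at three
wavelengths (465, 525, 615 nm).  Everything downstream -- the ratio equations,
their linear-fractional inverses, and the Beer-Lambert forward simulator --
consumes absorption constants from this module.

Two views of the hemoglobin constants are kept deliberately:

* ``molar_absorption`` -- molar absorption coefficients [M^-1 cm^-1] of
  glycated (HbA1c), oxygenated (HbO) and reduced (HHb) hemoglobin;
* ``absorption`` -- bulk absorption coefficients [cm^-1].  For hemoglobin
  species these equal the molar value scaled by the whole-blood hemoglobin
  concentration ``C_TOT_BLOOD`` = 150/64500 mol/L and are stored as rounded
  literals (so the stored table and the conversion identity can be asserted
  against each other); for water and the lumped dermal "skin baseline" medium
  they are measured directly.

Constants ship as a plain-text CSV (``data/spectra_default.csv``); users may
substitute their own file with the same schema via :meth:`ChromophoreSpectra.from_csv`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "HEMOGLOBIN_SPECIES",
    "MEDIA",
    "C_TOT_BLOOD",
    "WavelengthTriple",
    "BloodComposition",
    "ChromophoreSpectra",
    "load_default_spectra",
]

#: Hemoglobin species resolved by the finger models.
HEMOGLOBIN_SPECIES = ("HbA1c", "HbO", "HHb")

#: Non-hemoglobin media whose bulk absorption is tabulated directly.
MEDIA = ("skin_baseline", "water")

#: Typical whole-blood hemoglobin concentration, 150 g/L over 64500 g/mol [mol/L].
C_TOT_BLOOD = 150.0 / 64500.0


class SpectraLookupError(KeyError):
    """An unknown species/medium or wavelength was requested."""


@dataclass(frozen=True)
class WavelengthTriple:
    """The three device wavelengths (nm).

    ``lambda1``/``lambda2`` form the two ratio numerators; ``lambda3`` is the
    shared denominator channel (the red channel, which transmits most strongly
    through the fingertip).
    """

    lambda1: int = 525
    lambda2: int = 465
    lambda3: int = 615

    def __post_init__(self) -> None:
        if len({self.lambda1, self.lambda2, self.lambda3}) != 3:
            raise ValueError("the three wavelengths must be distinct")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.lambda1, self.lambda2, self.lambda3)


@dataclass(frozen=True)
class BloodComposition:
    """Molar concentrations of the three hemoglobin species [mol/L]."""

    c_hba1c: float
    c_hbo: float
    c_hhb: float
    c_tot: float = C_TOT_BLOOD

    def __post_init__(self) -> None:
        for name in ("c_hba1c", "c_hbo", "c_hhb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.c_hba1c + self.c_hbo + self.c_hhb


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Absorption constants per species/medium per wavelength.

    Parameters
    ----------
    molar_absorption
        ``(species, wavelength_nm) -> M^-1 cm^-1`` for hemoglobin species.
    absorption
        ``(species_or_medium, wavelength_nm) -> cm^-1``; hemoglobin entries are
        the molar values scaled by whole-blood concentration, water/skin
        entries are tabulated directly.
    """

    molar_absorption: Mapping[tuple[str, int], float]
    absorption: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wavelengths = self.wavelengths
        for sp in HEMOGLOBIN_SPECIES:
            for wl in wavelengths:
                if (sp, wl) not in self.molar_absorption:
                    raise ValueError(f"missing molar absorption for ({sp}, {wl})")
        for key, value in {**self.molar_absorption, **self.absorption}.items():
            if not value > 0:
                raise ValueError(f"absorption constant for {key} must be positive")

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted({wl for _, wl in self.molar_absorption}))

    def molar(self, species: str, wavelength: int) -> float:
        """Molar absorption coefficient [M^-1 cm^-1] of a hemoglobin species."""
        try:
            return self.molar_absorption[(species, int(wavelength))]
        except KeyError:
            raise SpectraLookupError(
                f"no molar absorption stored for species={species!r} at {wavelength} nm"
            ) from None

    def bulk(self, species: str, wavelength: int) -> float:
        """Stored bulk absorption coefficient [cm^-1] (any species or medium)."""
        try:
            return self.absorption[(species, int(wavelength))]
        except KeyError:
            raise SpectraLookupError(
                f"no bulk absorption stored for {species!r} at {wavelength} nm"
            ) from None

    def to_absorption_coefficient(
        self, species: str, wavelength: int, c_tot: float = C_TOT_BLOOD
    ) -> float:
        """Convert a hemoglobin molar coefficient to a bulk coefficient [cm^-1].

        ``molar * c_tot``; only valid for hemoglobin species -- water and the
        skin baseline are stored directly and must be read with :meth:`bulk`.
        """
        if species not in HEMOGLOBIN_SPECIES:
            raise ValueError(
                f"{species!r} is not a hemoglobin species; its bulk absorption "
                "is stored directly (use .bulk())"
            )
        if c_tot < 0:
            raise ValueError("c_tot must be non-negative")
        return self.molar(species, wavelength) * c_tot

    @classmethod
    def from_csv(cls, path) -> "ChromophoreSpectra":
        """Load spectra from a CSV with columns
        ``species,wavelength_nm,molar_absorption_M_cm,absorption_cm``.
        Lines starting with ``#`` are comments."""
        molar: dict[tuple[str, int], float] = {}
        bulk: dict[tuple[str, int], float] = {}
        with open(path, newline="") as fh:
            rows = [r for r in fh if not r.lstrip().startswith("#")]
        for row in csv.DictReader(rows):
            key = (row["species"].strip(), int(row["wavelength_nm"]))
            if row["molar_absorption_M_cm"].strip():
                molar[key] = float(row["molar_absorption_M_cm"])
            if row["absorption_cm"].strip():
                bulk[key] = float(row["absorption_cm"])
        return cls(molar_absorption=molar, absorption=bulk)


def load_default_spectra() -> ChromophoreSpectra:
    """The packaged default spectra table (see ``data/spectra_default.csv``)."""
    ref = resources.files("glycodvp.data").joinpath("spectra_default.csv")
    with resources.as_file(ref) as path:
        return ChromophoreSpectra.from_csv(path)
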