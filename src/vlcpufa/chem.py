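"""Free fatty acid chemistry: C:D nomenclature, formulas, masses and ion m/z.

Free (non-esterified) fatty acids with ``carbons`` carbon atoms and
``double_bonds`` C=C double bonds have elemental composition
CnH(2n-2d)O2.  In negative-mode electrospray they are observed as the
deprotonated ion [M-H]-, whose m/z is the neutral monoisotopic mass minus
the mass of a proton.  Collision-induced dissociation of [M-H]- gives a
decarboxylation product (neutral loss of CO2, 43.9898 Da, printed as
"44 Da" at nominal mass) followed by a ladder of CH2 losses spaced
14.0157 Da apart ("14 Da"), which is the fragment signature used to
confirm fatty-acid identity in PRM experiments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "MASS_C",
    "MASS_H",
    "MASS_O",
    "MASS_PROTON",
    "MASS_ELECTRON",
    "MASS_CO2",
    "MASS_CH2",
    "FattyAcidSpecies",
    "parse_species",
    "formula",
    "monoisotopic_mass",
    "average_molar_mass",
    "mz_deprotonated",
    "fragment_mz",
    "ppm_window",
    "grams_to_mol",
    "load_reference_panel",
    "default_panel",
]

# CODATA / IUPAC monoisotopic masses, Da.
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_O = 15.99491461956
MASS_PROTON = 1.00727646688
MASS_ELECTRON = 0.00054857991

# [M-H]- = M - H_atom + electron = M - proton; the two bookkeepings agree
# because proton = H_atom - electron (to ~1.5e-8 Da with these CODATA values,
# far below the 1e-4 Th level that matters at 5 ppm).
assert abs((MASS_H - MASS_ELECTRON) - MASS_PROTON) < 1e-7

MASS_CO2 = MASS_C + 2 * MASS_O
MASS_CH2 = MASS_C + 2 * MASS_H

# IUPAC 2021 standard atomic weights, g/mol — for gravimetric conversions
# (a weighed microgram of standard contains the natural isotope mixture).
WEIGHT_C = 12.011
WEIGHT_H = 1.008
WEIGHT_O = 15.999

_LABEL_RE = re.compile(
    r"^\s*(?P<c>\d+):(?P<d>\d+)"
    r"(?:\s*\((?P<tag>\d+)\))?"
    r"(?:\s*\((?P<is>IS)\))?\s*$"
)

MIN_CARBONS = 12


class SpeciesParseError(ValueError):
    """Raised when a C:D species label cannot be parsed or is chemically invalid."""


@dataclass(frozen=True)
class FattyAcidSpecies:
    """A fatty acid identified by carbon count and number of double bonds.

    ``isomer_tag`` distinguishes chromatographic isomers that share an
    elemental composition (hence an m/z) but elute at different retention
    times, e.g. "(1)" and "(2)".  ``series`` is an optional omega-series
    annotation (n-3 / n-6); it is informational only, since positional
    isomers are not resolvable by mass.
    """

    carbons: int
    double_bonds: int
    isomer_tag: Optional[str] = None
    is_internal_standard: bool = False
    series: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < MIN_CARBONS:
            raise SpeciesParseError(
                f"carbon count {self.carbons} below minimum of {MIN_CARBONS}"
            )
        h = 2 * self.carbons - 2 * self.double_bonds
        if self.double_bonds < 0 or h < 2:
            raise SpeciesParseError(
                f"{self.carbons}:{self.double_bonds} leaves {h} hydrogens; "
                "double-bond count too high"
            )

    @property
    def label(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        if self.isomer_tag:
            base += f" {self.isomer_tag}"
        if self.is_internal_standard:
            base += " (IS)"
        return base

    def __str__(self) -> str:
        return self.label


def parse_species(label: str) -> FattyAcidSpecies:
    """Parse a "C:D" label, e.g. ``"32:6"``, ``"22:5 (2)"``, ``"21:5 (IS)"``."""
    m = _LABEL_RE.match(label)
    if not m:
        raise SpeciesParseError(f"malformed species label {label!r}")
    carbons = int(m.group("c"))
    double_bonds = int(m.group("d"))
    if double_bonds >= carbons:
        raise SpeciesParseError(
            f"label {label!r}: double-bond count {double_bonds} "
            f">= carbon count {carbons}"
        )
    tag = f"({m.group('tag')})" if m.group("tag") else None
    return FattyAcidSpecies(
        carbons=carbons,
        double_bonds=double_bonds,
        isomer_tag=tag,
        is_internal_standard=m.group("is") is not None,
    )


def formula(species: FattyAcidSpecies) -> dict[str, int]:
    """Elemental composition CnH(2n-2d)O2 as {"C": ..., "H": ..., "O": 2}."""
    return {
        "C": species.carbons,
        "H": 2 * species.carbons - 2 * species.double_bonds,
        "O": 2,
    }


def monoisotopic_mass(species: FattyAcidSpecies) -> float:
    """Neutral monoisotopic mass in Da."""
    f = formula(species)
    return f["C"] * MASS_C + f["H"] * MASS_H + f["O"] * MASS_O


def average_molar_mass(species: FattyAcidSpecies) -> float:
    """Average molar mass in g/mol (standard atomic weights)."""
    f = formula(species)
    return f["C"] * WEIGHT_C + f["H"] * WEIGHT_H + f["O"] * WEIGHT_O


def mz_deprotonated(species: FattyAcidSpecies) -> float:
    """m/z of the deprotonated ion [M-H]- in Th."""
    return monoisotopic_mass(species) - MASS_PROTON


def fragment_mz(species: FattyAcidSpecies, n_ch2_losses: int = 0) -> float:
    """m/z of the CO2-loss fragment after ``n_ch2_losses`` further CH2 losses.

    With ``n_ch2_losses=0`` this is the decarboxylation product ion.
    """
    if n_ch2_losses < 0:
        raise ValueError("n_ch2_losses must be >= 0")
    remaining_carbons = species.carbons - 1 - n_ch2_losses
    if remaining_carbons < 2:
        raise ValueError(
            f"{n_ch2_losses} CH2 losses from {species.label} leaves "
            f"{remaining_carbons} carbons"
        )
    mz = mz_deprotonated(species) - MASS_CO2 - n_ch2_losses * MASS_CH2
    if mz < 50.0:
        raise ValueError(f"fragment m/z {mz:.4f} below 50 Th")
    return mz


def ppm_window(mz: float, tolerance_ppm: float) -> tuple[float, float]:
    """Symmetric relative window (low, high) around ``mz`` in Th."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tolerance_ppm < 0:
        raise ValueError("ppm tolerance must be non-negative")
    half = mz * tolerance_ppm * 1e-6
    return mz - half, mz + half


def grams_to_mol(grams: float, species: FattyAcidSpecies) -> float:
    """Moles in a weighed mass of the fatty acid (average molar mass)."""
    if grams < 0:
        raise ValueError("mass must be non-negative")
    return grams / average_molar_mass(species)


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def load_reference_panel() -> pd.DataFrame:
    """Packaged target panel: published m/z and retention-time library.

    Columns: species_label, mz_printed (validation fixture; the calculator
    is authoritative), rt_standard_min, rt_retina_min, role
    (marker | internal_standard | other), plus derived columns species,
    mz_theoretical and expected_rt_min (retina RT, falling back to the
    standard-solution RT).  Rows without a published retention time keep
    expected_rt_min = NaN.
    """
    ref = resources.files("vlcpufa.data").joinpath("reference_panel.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"species_label": str})
    df["mz_printed"] = pd.to_numeric(df["mz_printed"], errors="coerce")
    for col in ("rt_standard_min", "rt_retina_min"):
        df[col] = pd.to_numeric(df[col], errors="coerce")  # "ND" -> NaN
    df["species"] = df["species_label"].map(parse_species)
    df["mz_theoretical"] = df["species"].map(mz_deprotonated)
    df["expected_rt_min"] = df["rt_retina_min"].fillna(df["rt_standard_min"])
    return df


def default_panel() -> pd.DataFrame:
    """Alias for :func:`load_reference_panel` (the packaged default)."""
    return load_reference_panel()


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero, as printed tables use."""
    q = 10.0 ** decimals
    return math.floor(abs(x) * q + 0.5) / q * math.copysign(1.0, x)
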