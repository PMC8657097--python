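"""Radionuclide physical constants and elementary decay arithmetic.

A :class:`Nuclide` bundles the physical half-life and the mean energy
emitted per decay as electrons/positrons (beta spectra plus conversion and
Auger electrons) and as photons.  The electron energy drives the
local-deposition sphere dose; the photon energy is informational.

Constants ship in a small CSV catalog (``data/nuclides.csv``) so that a
user preferring a different decay-data compilation can override them
without touching code.  Default entries follow the ICRP-107 compilation:
Cu-64 (T1/2 = 12.7006 h, 0.121 MeV electrons/decay) and Lu-177
(T1/2 = 159.46 h, 0.147 MeV electrons/decay).

Units: hours for time, MeV per decay for energies, per-hour for decay
constants, everywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

LN2 = math.log(2.0)

#: number of decays per MBq.h of time-integrated activity
DECAYS_PER_MBQ_H = 3.6e9

#: joules per MeV
MEV_TO_J = 1.602e-13


def decay_constant(half_life: float) -> float:
    """Physical decay constant ln(2)/T1/2, in 1/h for T1/2 in hours."""
    if not half_life > 0:
        raise ValueError(f"half_life must be positive, got {half_life!r}")
    return LN2 / half_life


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide with its physical decay data.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Cu-64"``.
    half_life : float
        Physical half-life in hours.
    mean_electron_energy : float
        Mean energy emitted per decay as electrons and positrons
        (beta, conversion, Auger combined), MeV.
    mean_photon_energy : float
        Mean photon energy per decay, MeV (informational).
    """

    name: str
    half_life: float
    mean_electron_energy: float
    mean_photon_energy: float = 0.0

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"half_life must be positive, got {self.half_life!r}")
        if self.mean_electron_energy < 0 or self.mean_photon_energy < 0:
            raise ValueError("emission energies must be non-negative")

    @property
    def lambda_p(self) -> float:
        """Physical decay constant, 1/h."""
        return decay_constant(self.half_life)

    def decay_factor(self, t: float) -> float:
        """Fraction of activity remaining after ``t`` hours, exp(-lambda_p t)."""
        if t < 0:
            raise ValueError(f"t must be non-negative, got {t!r}")
        return math.exp(-self.lambda_p * t)


def load_catalog(path: str | Path | None = None) -> dict[str, Nuclide]:
    """Load a nuclide catalog from CSV.

    The file needs columns ``name, half_life_h, mean_electron_mev,
    mean_photon_mev``.  With ``path=None`` the packaged default catalog
    (Cu-64, Lu-177) is loaded.
    """
    if path is None:
        with resources.as_file(
            resources.files("theradose").joinpath("data/nuclides.csv")
        ) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"name", "half_life_h", "mean_electron_mev", "mean_photon_mev"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"nuclide catalog missing columns: {sorted(missing)}")
    return {
        row["name"]: Nuclide(
            name=row["name"],
            half_life=float(row["half_life_h"]),
            mean_electron_energy=float(row["mean_electron_mev"]),
            mean_photon_energy=float(row["mean_photon_mev"]),
        )
        for _, row in table.iterrows()
    }


def save_catalog(nuclides: dict[str, Nuclide], path: str | Path) -> None:
    """Write a nuclide catalog to CSV in the format `load_catalog` reads."""
    pd.DataFrame(
        [
            {
                "name": n.name,
                "half_life_h": n.half_life,
                "mean_electron_mev": n.mean_electron_energy,
                "mean_photon_mev": n.mean_photon_energy,
            }
            for n in nuclides.values()
        ]
    ).to_csv(path, index=False)


_DEFAULT = load_catalog()

#: Cu-64 with default (ICRP-107 style) constants
CU64: Nuclide = _DEFAULT["Cu-64"]

#: Lu-177 with default constants
LU177: Nuclide = _DEFAULT["Lu-177"]
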