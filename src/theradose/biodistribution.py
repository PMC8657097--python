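"""Organ-level biodistribution data model and arithmetic.

Preclinical biodistribution reports organ uptake as percent of injected
activity per gram of tissue (%IA/g), as mean +/- SD over a group of
animals euthanized at each time point.  For dosimetry those concentrations
are converted to whole-organ normalized activities nA (fraction of the
injected activity in the organ), and a rest-of-body source region is
constructed from the muscle concentration taken as representative of
background uptake:

    nA_remainder = (mouse mass - sum of source-organ masses) * c_muscle

with c_muscle the muscle concentration per gram (%IA/g divided by 100).

%IA/g values from a gamma counter are conventionally decay-corrected to
injection time; the ``decay_corrected`` flag records that convention and
is consumed downstream when physical decay is re-applied before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nuclides import Nuclide


@dataclass(frozen=True)
class OrganMeasurement:
    """Group-level %IA/g for one organ at one time point."""

    organ: str
    time: float  # hours post-injection
    pct_ia_per_g_mean: float
    pct_ia_per_g_sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be non-negative, got {self.time!r}")
        if self.pct_ia_per_g_mean < 0:
            raise ValueError(
                f"pct_ia_per_g_mean must be non-negative, got {self.pct_ia_per_g_mean!r}"
            )
        if self.pct_ia_per_g_sd < 0:
            raise ValueError("pct_ia_per_g_sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass(frozen=True)
class NormalizedActivityPoint:
    """Whole-organ normalized activity nA at one time point (dimensionless)."""

    organ: str
    time: float
    na_mean: float
    na_sd: float = 0.0
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if self.na_mean < 0 or self.na_sd < 0:
            raise ValueError("normalized activity and its SD must be non-negative")
        if self.na_mean > 1:
            raise ValueError(
                f"nA for a single organ cannot exceed 1, got {self.na_mean!r}"
            )


@dataclass
class BiodistributionStudy:
    """A full biodistribution data set with organ masses and study metadata.

    ``organ_masses`` must cover every organ used as a dosimetry source;
    the designated muscle organ may lack a mass (it only contributes a
    per-gram concentration to the remainder construction).
    """

    nuclide: Nuclide
    measurements: list[OrganMeasurement]
    organ_masses: dict[str, float]
    mouse_mass: float
    decay_corrected: bool = True
    muscle_organ: str = "muscle"

    def __post_init__(self) -> None:
        for organ, mass in self.organ_masses.items():
            if not mass > 0:
                raise ValueError(f"organ mass for {organ!r} must be positive")
        total = sum(self.organ_masses.values())
        if not self.mouse_mass > total:
            raise ValueError(
                f"mouse_mass ({self.mouse_mass} g) must exceed the summed "
                f"source-organ masses ({total:.3g} g)"
            )

    # -- convenience accessors -------------------------------------------------

    def organs(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.measurements:
            seen.setdefault(m.organ, None)
        return list(seen)

    def times(self) -> list[float]:
        return sorted({m.time for m in self.measurements})

    def source_organs(self) -> list[str]:
        """Organs that have a mass entry and hence enter TIAC/dose work."""
        return [o for o in self.organs() if o in self.organ_masses]

    def measurement(self, organ: str, time: float) -> OrganMeasurement:
        for m in self.measurements:
            if m.organ == organ and m.time == time:
                return m
        raise KeyError(f"no measurement for organ {organ!r} at t={time} h")

    def rest_of_body_mass(self) -> float:
        return self.mouse_mass - sum(self.organ_masses.values())


def normalized_activity(
    m: OrganMeasurement, mass: float, decay_corrected: bool = True
) -> NormalizedActivityPoint:
    """Convert a %IA/g measurement to whole-organ normalized activity.

    nA = (%IA/g / 100) * organ mass; the SD scales identically.
    """
    if not mass > 0:
        raise ValueError(f"mass for organ {m.organ!r} must be positive, got {mass!r}")
    return NormalizedActivityPoint(
        organ=m.organ,
        time=m.time,
        na_mean=m.pct_ia_per_g_mean / 100.0 * mass,
        na_sd=m.pct_ia_per_g_sd / 100.0 * mass,
        decay_corrected=decay_corrected,
    )


def remainder_activity(
    study: BiodistributionStudy, time: float
) -> NormalizedActivityPoint:
    """Rest-of-body normalized activity at one time point.

    The rest-of-body mass (mouse mass minus all source-organ masses) is
    multiplied by the muscle activity concentration per gram.
    """
    try:
        muscle = study.measurement(study.muscle_organ, time)
    except KeyError as exc:
        raise ValueError(
            f"no muscle ({study.muscle_organ!r}) measurement at t={time} h; "
            "cannot build the remainder"
        ) from exc
    rest_mass = study.rest_of_body_mass()
    return NormalizedActivityPoint(
        organ="remainder",
        time=time,
        na_mean=muscle.pct_ia_per_g_mean / 100.0 * rest_mass,
        na_sd=muscle.pct_ia_per_g_sd / 100.0 * rest_mass,
        decay_corrected=study.decay_corrected,
    )


def group_summary(values) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator; 0 when n = 1) and n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("group_summary requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, int(arr.size)


def normalized_curves(
    study: BiodistributionStudy, include_remainder: bool = True
) -> dict[str, list[NormalizedActivityPoint]]:
    """Per-source-organ normalized time-activity points, plus the remainder.

    Only organs with a mass entry are included (the muscle itself is
    consumed by the remainder construction, not fitted on its own unless
    it carries a mass and is not the designated muscle organ).
    """
    curves: dict[str, list[NormalizedActivityPoint]] = {}
    for organ in study.source_organs():
        if organ == study.muscle_organ:
            continue
        mass = study.organ_masses[organ]
        pts = [
            normalized_activity(m, mass, study.decay_corrected)
            for m in study.measurements
            if m.organ == organ
        ]
        pts.sort(key=lambda p: p.time)
        curves[organ] = pts
    if include_remainder:
        if study.muscle_organ in study.organs():
            curves["remainder"] = [
                remainder_activity(study, t) for t in study.times()
            ]
        else:
            warnings.warn(
                f"no {study.muscle_organ!r} measurements; remainder region omitted",
                stacklevel=2,
            )
    return curves


# -- delimited-table I/O -------------------------------------------------------

BIODIST_COLUMNS = ["organ", "time_h", "pct_ia_per_g", "sd", "n"]


def read_biodistribution(path: str | Path) -> list[OrganMeasurement]:
    """Read a biodistribution table (organ, time_h, pct_ia_per_g, sd, n)."""
    table = pd.read_csv(path)
    missing = set(BIODIST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"biodistribution table missing columns: {sorted(missing)}")
    return [
        OrganMeasurement(
            organ=str(row["organ"]),
            time=float(row["time_h"]),
            pct_ia_per_g_mean=float(row["pct_ia_per_g"]),
            pct_ia_per_g_sd=float(row["sd"]),
            n=int(row["n"]),
        )
        for _, row in table.iterrows()
    ]


def write_biodistribution(
    measurements: list[OrganMeasurement], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "organ": m.organ,
                "time_h": m.time,
                "pct_ia_per_g": m.pct_ia_per_g_mean,
                "sd": m.pct_ia_per_g_sd,
                "n": m.n,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


def read_organ_masses(path: str | Path) -> dict[str, float]:
    """Read an organ-mass table (organ, mass_g)."""
    table = pd.read_csv(path)
    missing = {"organ", "mass_g"} - set(table.columns)
    if missing:
        raise ValueError(f"organ-mass table missing columns: {sorted(missing)}")
    return {str(r["organ"]): float(r["mass_g"]) for _, r in table.iterrows()}


def write_organ_masses(masses: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"organ": o, "mass_g": m} for o, m in masses.items()]
    ).to_csv(path, index=False)
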