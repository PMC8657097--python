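"""Radioimmunoconjugate quality-control formulas.

Three small, assay-level computations:

* chelator-to-antibody ratio (DAR) — the intensity-weighted mean number
  of conjugated chelators over the deconvoluted mass-spectrum peaks,
  sum(n * Int) / sum(Int);
* immunoreactive fraction — percent of activity bound to antigen-coated
  beads out of bead + supernatant activity, with nonspecific tube binding
  subtracted from both the bound compartment and the total (the
  subtraction convention is configurable);
* radiochemical purity — percent of TLC-strip counts in the bound window
  (product stays at the origin, Rf ~ 0) out of bound + free (free label
  migrates to the solvent front, Rf ~ 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SpectrumPeak:
    """One deconvoluted mass-spectrum peak: n attached chelators, intensity."""

    n: int
    intensity: float

    def __post_init__(self) -> None:
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError(f"n must be a non-negative integer, got {self.n!r}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class BeadAssay:
    """Gamma counts from a magnetic-bead binding assay (same live-time basis)."""

    bead_counts: float
    supernatant_counts: float
    tube_counts: float = 0.0

    def __post_init__(self) -> None:
        if min(self.bead_counts, self.supernatant_counts, self.tube_counts) < 0:
            raise ValueError("counts must be non-negative")
        if self.bead_counts + self.supernatant_counts <= 0:
            raise ValueError("bead + supernatant counts must be positive")


@dataclass(frozen=True)
class TlcProfile:
    """A radio-TLC strip profile: (Rf, counts) pairs plus integration windows."""

    rf: tuple[float, ...]
    counts: tuple[float, ...]
    bound_window: tuple[float, float] = (0.0, 0.2)
    free_window: tuple[float, float] = (0.8, 1.0)

    def __post_init__(self) -> None:
        if len(self.rf) != len(self.counts) or not self.rf:
            raise ValueError("rf and counts must be equal-length, non-empty")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(not 0 <= r <= 1 for r in self.rf):
            raise ValueError("Rf values must lie in [0, 1]")
        if any(b >= a for a, b in zip(self.rf[1:], self.rf)):
            raise ValueError("Rf values must be strictly increasing")
        lo1, hi1 = self.bound_window
        lo2, hi2 = self.free_window
        if hi1 > lo2 and hi2 > lo1:
            raise ValueError("bound and free windows must be disjoint")

    def window_counts(self, window: tuple[float, float]) -> float:
        lo, hi = window
        return sum(c for r, c in zip(self.rf, self.counts) if lo <= r <= hi)


def dar(peaks: list[SpectrumPeak]) -> float:
    """Chelator(drug)-to-antibody ratio: sum(n * Int) / sum(Int)."""
    total = sum(p.intensity for p in peaks)
    if total <= 0:
        raise ValueError("at least one peak must have positive intensity")
    return sum(p.n * p.intensity for p in peaks) / total


def immunoreactive_fraction(assay: BeadAssay) -> float:
    """Percent of activity bound to antigen beads, tube binding subtracted.

    100 * (bead - tube) / (bead + supernatant - tube), clipped to [0, 100].
    """
    denom = assay.bead_counts + assay.supernatant_counts - assay.tube_counts
    if denom <= 0:
        raise ValueError(
            "bead + supernatant - tube must be positive; check the tube blank"
        )
    frac = 100.0 * (assay.bead_counts - assay.tube_counts) / denom
    return min(max(frac, 0.0), 100.0)


def radiochemical_purity(profile: TlcProfile) -> tuple[float, float]:
    """Radiochemical purity percent and the fraction of counts outside both windows.

    RCP = 100 * counts(bound window) / counts(bound + free windows).  The
    second return value reports the share of total strip counts falling
    between the windows (ignored by the RCP itself).
    """
    bound = profile.window_counts(profile.bound_window)
    free = profile.window_counts(profile.free_window)
    if bound + free <= 0:
        raise ValueError("no counts in the bound or free windows")
    total = sum(profile.counts)
    outside = (total - bound - free) / total if total > 0 else 0.0
    return 100.0 * bound / (bound + free), outside
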