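"""Monoexponential time-activity kinetics and TIAC integration.

The organ time-activity curve is modelled as nA(t) = a0 * exp(-lambda_eff t)
where lambda_eff is the effective decay constant, the sum of biological
clearance and physical decay.  Fitting therefore operates on *uncorrected*
normalized activities, i.e. data that still carry the physical decay factor
exp(-lambda_p t): decay-corrected input must first pass through
:func:`to_physical_units`.

The time-integrated activity coefficient (TIAC, MBq.h per MBq injected,
formerly "residence time") is the integral of nA over time.  Integration
follows a conditional rule that guards against unrealistic extrapolation
for organs whose curve declines more slowly than physical decay alone
(i.e. rising biological uptake, lambda_eff < lambda_p):

* lambda_eff > lambda_p  ->  analytic integral to infinity, a0/lambda_eff;
* otherwise              ->  the fitted curve is integrated only up to the
  last measured time t_last, and pure physical decay is assumed beyond:
  a0 (1 - exp(-lambda_eff t_last))/lambda_eff
  + a0 exp(-lambda_eff t_last)/lambda_p,
  with the lambda_eff -> 0 limit a0 t_last for the first term.  The same
  closed form is valid for negative lambda_eff (net accumulation).

An uncertainty envelope is propagated by fitting and integrating the
mean, mean+SD and mean-SD series independently.  Curves can also be
rescaled between radionuclides that share the biological kinetics, via
the per-time-point scale factor

    SF(t) = exp(-lambda_p,dest t) / exp(-lambda_p,source t),

which converts uncorrected normalized activities measured with one
nuclide into the activities the same biology would have produced with
the other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .biodistribution import NormalizedActivityPoint
from .nuclides import Nuclide

#: integration branches
BRANCH_INFINITE = "infinite"  # lambda_eff > lambda_p, integral 0->inf
BRANCH_PHYSICAL_TAIL = "physical-tail"  # curve to t_last, physical decay beyond


@dataclass(frozen=True)
class MonoExpFit:
    """Fitted monoexponential nA(t) = a0 exp(-lambda_eff t)."""

    organ: str
    a0: float
    lambda_eff: float  # 1/h; negative means the curve still rises

    def __post_init__(self) -> None:
        if not self.a0 > 0:
            raise ValueError(f"fitted amplitude a0 must be positive, got {self.a0!r}")

    def __call__(self, t):
        return self.a0 * np.exp(-self.lambda_eff * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class TiacResult:
    """TIAC with mean and mean+/-SD envelope, MBq.h/MBq."""

    organ: str
    tiac_mean: float
    tiac_low: float
    tiac_high: float
    branch: str
    t_last: float


@dataclass(frozen=True)
class ExtrapolatedCurve:
    """Normalized activities rescaled from one radionuclide to another."""

    organ: str
    points: tuple[NormalizedActivityPoint, ...]
    sf_values: tuple[float, ...]
    source_nuclide: Nuclide
    dest_nuclide: Nuclide


def to_physical_units(
    points: list[NormalizedActivityPoint], nuclide: Nuclide
) -> list[NormalizedActivityPoint]:
    """Re-apply physical decay to decay-corrected normalized activities.

    Each nA (and its SD) is multiplied by exp(-lambda_p t) and the
    decay-correction flag cleared.  Already-uncorrected input is returned
    unchanged with a warning.
    """
    if points and not points[0].decay_corrected:
        warnings.warn(
            "points are already in physical units (uncorrected); returning as-is",
            stacklevel=2,
        )
        return list(points)
    out = []
    for p in points:
        f = nuclide.decay_factor(p.time)
        out.append(
            replace(p, na_mean=p.na_mean * f, na_sd=p.na_sd * f, decay_corrected=False)
        )
    return out


def _fit_loglinear(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # unweighted least squares on log(y); exact interpolation for 2 points
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return math.exp(intercept), -slope


def _fit_nonlinear(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    a0_init, lam_init = _fit_loglinear(t, y)
    popt, _ = curve_fit(
        lambda tt, a0, lam: a0 * np.exp(-lam * tt),
        t,
        y,
        p0=(a0_init, lam_init),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def fit_monoexp(
    points: list[NormalizedActivityPoint],
    organ: str | None = None,
    scale: str = "log",
) -> MonoExpFit:
    """Fit nA(t) = a0 exp(-lambda_eff t) to uncorrected activity points.

    ``scale="log"`` (default) is an unweighted log-linear regression —
    deterministic and exact for two points; ``scale="linear"`` runs
    nonlinear least squares on the natural scale, initialized from the
    log-linear solution.
    """
    if len(points) < 2:
        raise ValueError("fit_monoexp needs at least 2 points")
    if any(p.decay_corrected for p in points):
        raise ValueError(
            "fit_monoexp expects uncorrected (physical-decay-bearing) points; "
            "apply to_physical_units first"
        )
    t = np.array([p.time for p in points], dtype=float)
    y = np.array([p.na_mean for p in points], dtype=float)
    if len(set(t.tolist())) != len(t):
        raise ValueError("duplicate time points in fit input")
    if np.any(y <= 0):
        raise ValueError("all normalized activities must be positive for fitting")
    if scale == "log":
        a0, lam = _fit_loglinear(t, y)
    elif scale == "linear":
        a0, lam = _fit_nonlinear(t, y)
    else:
        raise ValueError(f"unknown fit scale {scale!r}; use 'log' or 'linear'")
    return MonoExpFit(organ=organ if organ is not None else points[0].organ,
                      a0=a0, lambda_eff=lam)


def integrate_tiac(
    fit: MonoExpFit, nuclide: Nuclide, t_last: float
) -> tuple[float, str]:
    """TIAC (MBq.h/MBq) of a fitted curve under the conditional rule.

    Returns ``(tiac, branch)`` where branch is ``"infinite"`` when the
    closed-form integral to infinity was used (lambda_eff > lambda_p) and
    ``"physical-tail"`` when the curve was truncated at ``t_last`` with a
    physical-decay tail beyond.
    """
    lam_p = nuclide.lambda_p
    if not t_last > 0:
        raise ValueError("t_last must be positive")
    lam = fit.lambda_eff
    if lam > lam_p:
        return fit.a0 / lam, BRANCH_INFINITE
    # 0 -> t_last under the fitted curve; analytic limit at lambda_eff = 0,
    # same closed form valid for lambda_eff < 0 (rising uptake)
    x = lam * t_last
    if abs(x) < 1e-12:
        head = fit.a0 * t_last
    else:
        head = fit.a0 * (-math.expm1(-x)) / lam
    tail = fit.a0 * math.exp(-x) / lam_p
    return head + tail, BRANCH_PHYSICAL_TAIL


def tiac_envelope(
    points: list[NormalizedActivityPoint],
    nuclide: Nuclide,
    t_last: float | None = None,
    scale: str = "log",
) -> TiacResult:
    """TIAC with a mean +/- SD envelope.

    Three independent fit+integration passes run on the mean, mean+SD and
    mean-SD series.  A bound whose series is non-positive anywhere is
    reported as NaN with a warning; the mean is always computed.
    """
    if t_last is None:
        t_last = max(p.time for p in points)
    organ = points[0].organ

    def _one(shift: int) -> tuple[float, str]:
        shifted = [
            replace(p, na_mean=p.na_mean + shift * p.na_sd, na_sd=0.0) for p in points
        ]
        fit = fit_monoexp(shifted, organ=organ, scale=scale)
        return integrate_tiac(fit, nuclide, t_last)

    mean, branch = _one(0)
    bounds = {}
    for label, shift in (("low", -1), ("high", +1)):
        try:
            bounds[label], _ = _one(shift)
        except ValueError:
            warnings.warn(
                f"{organ}: mean{'-' if shift < 0 else '+'}SD series not strictly "
                "positive; envelope bound unavailable",
                stacklevel=2,
            )
            bounds[label] = math.nan
    low, high = bounds["low"], bounds["high"]
    # enforce ordering low <= mean <= high when both bounds exist
    if math.isfinite(low) and math.isfinite(high):
        low, high = min(low, mean, high), max(low, mean, high)
    return TiacResult(
        organ=organ, tiac_mean=mean, tiac_low=low, tiac_high=high,
        branch=branch, t_last=t_last,
    )


def scale_factor(t: float, source: Nuclide, dest: Nuclide) -> float:
    """SF(t) = exp(-lambda_dest t)/exp(-lambda_source t)."""
    return math.exp((source.lambda_p - dest.lambda_p) * t)


def extrapolate_nuclide(
    points: list[NormalizedActivityPoint], source: Nuclide, dest: Nuclide
) -> ExtrapolatedCurve:
    """Rescale uncorrected activities from one radionuclide to another.

    Assumes identical biological kinetics; each nA and SD is multiplied by
    SF(t_m).  Only physical-decay-bearing (uncorrected) data can be
    rescaled this way.
    """
    if any(p.decay_corrected for p in points):
        raise ValueError(
            "extrapolate_nuclide requires uncorrected points: the scale factor "
            "replaces one physical decay factor by another"
        )
    sfs = tuple(scale_factor(p.time, source, dest) for p in points)
    new_points = tuple(
        replace(p, na_mean=p.na_mean * sf, na_sd=p.na_sd * sf)
        for p, sf in zip(points, sfs)
    )
    return ExtrapolatedCurve(
        organ=points[0].organ if points else "",
        points=new_points,
        sf_values=sfs,
        source_nuclide=source,
        dest_nuclide=dest,
    )
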