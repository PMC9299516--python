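"""Concentration dependence of the reactive-cell fraction, with logistic fits.

The fitted response is the fraction of reactive cells (not an amplitude), as
a function of log10 agonist or antagonist concentration.  The model is the
standard four-parameter logistic

    f(c) = bottom + (top − bottom) / (1 + 10^((log10(mid) − log10(c)) · h))

whose midpoint is the EC50 in agonist mode (h > 0) or the IC50 in antagonist
mode (h < 0).  Fitting is unweighted least squares by default; inverse-SEM²
weighting is optional.  A zero-concentration control point cannot live on the
log axis: it is excluded from the fit and, in fixed-bottom mode, anchors the
bottom plateau instead.

The assay itself reports concentration dependence without committing to a
parametric fit; the fit here is a convenience summary on top of the measured
fractions, and non-convergence is reported as a flag, never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError
from .reactivity import ReplicateSummary

__all__ = ["HillFit", "DoseResponseCurve", "build_curve", "fit_hill", "hill_logistic"]


def hill_logistic(log_c: np.ndarray, bottom: float, top: float, log_mid: float,
                  slope: float) -> np.ndarray:
    """Four-parameter logistic in log10 concentration."""
    return bottom + (top - bottom) / (1.0 + np.power(10.0, (log_mid - log_c) * slope))


@dataclass(frozen=True)
class HillFit:
    """Result of a four-parameter logistic fit."""

    bottom: float
    top: float
    midpoint: float  # EC50/IC50 in the concentration units of the input (M)
    hill_slope: float
    converged: bool
    message: str = ""

    def summary(self) -> str:
        status = "converged" if self.converged else f"NOT converged ({self.message})"
        return (
            f"4PL fit [{status}]: bottom={self.bottom:.4g}, top={self.top:.4g}, "
            f"midpoint={self.midpoint:.3g} M, hill_slope={self.hill_slope:.3g}"
        )


@dataclass
class DoseResponseCurve:
    """Measured fraction-reactive points of one compound, plus an optional fit."""

    compound: str
    mode: str  # "agonist" or "antagonist"
    concentrations: list[float]  # strictly positive, sorted ascending (M)
    summaries: list[ReplicateSummary]
    baseline: ReplicateSummary | None = None  # zero-concentration control point
    fit: HillFit | None = None

    @property
    def fractions(self) -> np.ndarray:
        return np.array([s.mean for s in self.summaries])

    @property
    def sems(self) -> np.ndarray:
        return np.array([s.sem for s in self.summaries])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "concentration": self.concentrations,
                "fraction_reactive": self.fractions,
                "sem": self.sems,
                "n_replicates": [s.n_replicates for s in self.summaries],
            }
        )

    def plot(self, ax=None):
        """Plot points ± SEM and, if fitted, the logistic curve (log-x axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.concentrations, self.fractions, yerr=self.sems, fmt="o",
                    capsize=3, label=self.compound)
        if self.fit is not None and self.fit.converged:
            grid = np.logspace(
                math.log10(min(self.concentrations)) - 0.5,
                math.log10(max(self.concentrations)) + 0.5,
                200,
            )
            ax.plot(grid, hill_logistic(np.log10(grid), self.fit.bottom, self.fit.top,
                                        math.log10(self.fit.midpoint), self.fit.hill_slope))
        ax.set_xscale("log")
        ax.set_xlabel("concentration (M)")
        ax.set_ylabel("fraction of reactive cells")
        ax.legend()
        return ax


def build_curve(
    summaries_by_concentration: Mapping[float, ReplicateSummary],
    compound: str = "",
    mode: str = "agonist",
) -> DoseResponseCurve:
    """Assemble a curve from per-concentration replicate summaries.

    Requires at least three strictly positive concentrations; a
    zero-concentration entry, if present, is kept aside as the baseline
    control point.  Duplicate concentration keys cannot occur in a mapping,
    but near-duplicates (within 1 ppm) are rejected explicitly.
    """
    if mode not in ("agonist", "antagonist"):
        raise InputError(f"unknown mode {mode!r}")
    baseline = None
    items: list[tuple[float, ReplicateSummary]] = []
    for conc, summ in summaries_by_concentration.items():
        conc = float(conc)
        if conc < 0:
            raise InputError("concentrations must be non-negative")
        if conc == 0:
            baseline = summ
        else:
            items.append((conc, summ))
    items.sort(key=lambda kv: kv[0])
    concs = [c for c, _ in items]
    for a, b in zip(concs, concs[1:]):
        if b <= a * (1 + 1e-6):
            raise InputError(f"duplicate or unsorted concentration near {a!r}")
    if len(items) < 3:
        raise InputError("need at least 3 positive concentrations for a curve")
    return DoseResponseCurve(
        compound=compound,
        mode=mode,
        concentrations=concs,
        summaries=[s for _, s in items],
        baseline=baseline,
    )


def fit_hill(
    curve: DoseResponseCurve,
    fix_bottom: float | None = None,
    weighted: bool = False,
) -> HillFit:
    """Least-squares four-parameter logistic fit on log10 concentration.

    With ``fix_bottom`` the bottom plateau is held fixed (three free
    parameters, allowed from 3 points); otherwise 4 points are required.  When
    ``weighted`` is true, points are weighted by 1/SEM².  Failures and
    implausible midpoints (outside [min conc / 10, max conc × 10]) are
    reported via ``converged=False``.  The fitted curve is stored on
    ``curve.fit`` and returned.
    """
    x = np.log10(np.asarray(curve.concentrations, dtype=float))
    y = curve.fractions.astype(float)
    n_min = 3 if fix_bottom is not None else 4
    if x.size < n_min:
        raise InputError(f"need at least {n_min} points for this fit")

    sigma = None
    if weighted:
        sems = curve.sems
        if np.any(~np.isfinite(sems)) or np.any(sems <= 0):
            raise InputError("weighted fit requires finite positive SEMs")
        sigma = sems

    span = float(y.max() - y.min())
    if span < 1e-6:
        fit = HillFit(
            bottom=float(y.mean()), top=float(y.mean()), midpoint=float("nan"),
            hill_slope=0.0, converged=False, message="flat response",
        )
        curve.fit = fit
        return fit

    slope0 = 1.0 if curve.mode == "agonist" else -1.0
    mid0 = float(np.median(x))
    try:
        if fix_bottom is not None:
            def model(lc, top, log_mid, slope):
                return hill_logistic(lc, fix_bottom, top, log_mid, slope)

            p0 = [float(y.max()), mid0, slope0]
            popt, _ = curve_fit(model, x, y, p0=p0, sigma=sigma, maxfev=20000)
            bottom, (top, log_mid, slope) = float(fix_bottom), popt
        else:
            p0 = [float(y.min()), float(y.max()), mid0, slope0]
            popt, _ = curve_fit(hill_logistic, x, y, p0=p0, sigma=sigma, maxfev=20000)
            bottom, top, log_mid, slope = popt
    except RuntimeError as exc:
        fit = HillFit(bottom=float("nan"), top=float("nan"), midpoint=float("nan"),
                      hill_slope=float("nan"), converged=False, message=str(exc))
        curve.fit = fit
        return fit

    midpoint = float(10.0**log_mid)
    lo_ok = midpoint >= min(curve.concentrations) / 10.0
    hi_ok = midpoint <= max(curve.concentrations) * 10.0
    converged = bool(lo_ok and hi_ok and np.isfinite(midpoint))
    message = "" if converged else "midpoint outside the supported concentration range"
    if bottom > top:
        # canonicalise so bottom <= top, flipping the slope sign
        bottom, top, slope = top, bottom, -slope
    fit = HillFit(
        bottom=float(bottom), top=float(top), midpoint=midpoint,
        hill_slope=float(slope), converged=converged, message=message,
    )
    curve.fit = fit
    return fit
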