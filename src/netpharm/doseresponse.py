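"""Four-parameter logistic (4PL) dose-response analysis for platelet aggregation.

The inhibition model is

    y(c) = bottom + (top - bottom) / (1 + (c / IC50)^slope)

so aggregation % falls from ``top`` (no drug) to ``bottom`` (full inhibition)
as concentration rises; y(IC50) is the exact midpoint. Fitting is nonlinear
least squares on log-concentration with data-driven initialisation, so the
estimate is deterministic given the data and equivariant under rescaling of
the concentration axis.

Also provides the percent-inhibition summary used for thromboxane (TxB2)
production tables and a two-sample significance test against the
agonist-induced vehicle control (Welch's t by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "FourPLFit",
    "FitError",
    "four_pl",
    "fit_4pl",
    "percent_inhibition",
    "compare_to_control",
    "significance_stars",
]


class FitError(RuntimeError):
    """Raised when a dose-response series cannot support a 4PL fit."""


@dataclass
class DoseResponseSeries:
    """Replicate aggregation-% measurements across concentrations for one compound."""

    compound_id: str
    concentrations: np.ndarray  # uM, one entry per replicate measurement
    responses: np.ndarray  # aggregation %, parallel to concentrations
    agonist: str = "collagen"
    vehicle_mean: float = float("nan")
    vehicle_sd: float = float("nan")

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must be parallel arrays")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ic50: float
    hill_slope: float
    residual_sse: float
    converged: bool


def four_pl(c, bottom, top, ic50, slope):
    """Four-parameter logistic inhibition curve; decreasing in c for slope > 0."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** slope)


def _fit_arrays(conc: np.ndarray, resp: np.ndarray) -> FourPLFit:
    levels = np.unique(conc)
    if levels.size < 4:
        raise FitError(f"need >= 4 distinct concentrations, got {levels.size}")
    means = np.array([resp[conc == c].mean() for c in levels])
    dyn = means.max() - means.min()
    if dyn < 1e-9 * max(1.0, abs(means.max())):
        raise FitError("zero dynamic range: response is flat, IC50 undefined")

    top0 = float(means.max())
    bot0 = float(max(means.min(), 0.0))
    # first concentration whose mean falls below the half-range brackets the IC50
    half = (top0 + bot0) / 2.0
    below = np.nonzero(means <= half)[0]
    ic0 = float(levels[below[0]]) if below.size else float(np.sqrt(levels[0] * levels[-1]))
    logc = np.log10(conc)

    def model(lc, bottom, top, lic50, slope):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (lc - lic50)))

    lo = [0.0, 0.0, np.log10(levels[0]) - 2.0, 0.1]
    hi = [110.0, 110.0, np.log10(levels[-1]) + 2.0, 10.0]
    p0 = [bot0, min(top0, 110.0), np.log10(ic0), 1.0]
    p0 = [min(max(p, l), h) for p, l, h in zip(p0, lo, hi)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, logc, resp, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        converged = True
    except RuntimeError:
        popt, converged = np.array(p0), False
    bottom, top, lic50, slope = popt
    if top < bottom:  # bounds allow it; canonicalise
        bottom, top = top, bottom
    resid = resp - model(logc, *popt)
    fit = FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ic50=float(10.0 ** lic50),
        hill_slope=float(slope),
        residual_sse=float(np.sum(resid**2)),
        converged=bool(converged),
    )
    # an IC50 pushed to the search boundary is not a trustworthy estimate
    if not (levels[0] / 100.0 < fit.ic50 < levels[-1] * 100.0):
        fit.converged = False
    return fit


def fit_4pl(series) -> FourPLFit:
    """Least-squares 4PL fit of a :class:`DoseResponseSeries` (or (conc, resp) pair)."""
    if isinstance(series, DoseResponseSeries):
        return _fit_arrays(series.concentrations, series.responses)
    conc, resp = series
    return _fit_arrays(np.asarray(conc, dtype=float), np.asarray(resp, dtype=float))


def percent_inhibition(agonist_mean: float, treated_mean: float, baseline_mean: float) -> float:
    """Percent inhibition relative to the agonist-vs-baseline window.

    (agonist - treated) / (agonist - baseline) * 100; 0% when treatment does
    nothing, 100% when it restores baseline. Values slightly outside [0, 100]
    (treated beyond either reference) are warned about; negatives are clipped
    to 0.
    """
    if agonist_mean <= baseline_mean:
        raise ValueError("agonist mean must exceed baseline mean")
    val = (agonist_mean - treated_mean) / (agonist_mean - baseline_mean) * 100.0
    if val < 0.0:
        warnings.warn(f"inhibition {val:.2f}% below 0; clipping", stacklevel=2)
        return 0.0
    if val > 100.0:
        warnings.warn(f"inhibition {val:.2f}% exceeds 100%", stacklevel=2)
    return val


def compare_to_control(treated_reps, control_reps, test: str = "welch") -> float:
    """Two-sided p-value for treated vs control replicates.

    ``test="welch"`` (default) is Welch's unequal-variance t-test;
    ``"mannwhitney"`` a rank test. Two identical constant samples give p = 1.
    """
    a = np.asarray(treated_reps, dtype=float)
    b = np.asarray(control_reps, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if test == "welch":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "mannwhitney":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(p)


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.001 thresholds."""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""
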