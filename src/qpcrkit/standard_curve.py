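"""Relative standard curves and amplification-efficiency estimation.

A standard curve is the ordinary least-squares regression of Cq on
log10(relative concentration) over a serial dilution of template.  Its slope
gives the amplification efficiency:

    amp_factor = 10 ** (-1 / slope)          (fold increase per cycle)
    efficiency = (amp_factor - 1) * 100      (%; 100 = perfect doubling)

The x-axis is always log10 of the relative concentration regardless of the
dilution factor used to build the series; the dilution factor only sets the
spacing of the concentration grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


class CurveFitError(ValueError):
    """Raised for degenerate or under-determined dilution designs."""


@dataclass(frozen=True)
class CurveFit:
    """Per-gene standard-curve regression result.

    ``slope`` is in cycles per log10(concentration) unit and must be negative
    for a usable curve (more template -> earlier Cq).  ``efficiency_pct`` and
    ``amp_factor`` are NaN when the fit is invalid (slope >= 0).
    ``cq_range`` is the observed (min, max) Cq of the fitted points and bounds
    the safe range for inverse prediction.
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    amp_factor: float
    n_points: int
    cq_range: tuple
    dilution_factor: float = float("nan")

    @property
    def valid(self) -> bool:
        return self.slope < 0


def efficiency_from_slope(slope: float) -> tuple:
    """Amplification factor and efficiency (%) from a standard-curve slope.

    Returns ``(efficiency_pct, amp_factor)`` with
    ``amp_factor = 10**(-1/slope)`` and ``efficiency_pct = (amp_factor-1)*100``.
    A slope of -1/log10(2) = -3.32193 gives exact doubling (100%).
    """
    if not slope < 0:
        raise ValueError(f"slope must be negative for a valid curve, got {slope}")
    amp_factor = 10.0 ** (-1.0 / slope)
    return (amp_factor - 1.0) * 100.0, amp_factor


def fit_curve(dilutions: pd.DataFrame, gene: str, use: str = "all_points") -> CurveFit:
    """Fit one gene's standard curve by OLS of Cq on log10(rel_conc).

    Parameters
    ----------
    dilutions : DataFrame
        Columns ``gene``, ``rel_conc``, ``cq``.
    use : {"all_points", "per_dilution_mean"}
        Regress on every reaction (default, uses full information) or on the
        mean Cq per dilution level.
    """
    if use not in ("all_points", "per_dilution_mean"):
        raise ValueError(f"use must be 'all_points' or 'per_dilution_mean', got {use!r}")
    sub = dilutions[dilutions["gene"] == gene]
    if sub.empty:
        raise CurveFitError(f"no dilution data for gene {gene!r}")
    if sub["rel_conc"].nunique() < 3:
        raise CurveFitError(
            f"gene {gene!r}: {sub['rel_conc'].nunique()} distinct concentrations; >= 3 required"
        )
    if use == "per_dilution_mean":
        sub = sub.groupby("rel_conc", as_index=False)["cq"].mean().assign(gene=gene)
    x = sub["rel_conc"].map(math.log10).to_numpy(float)
    y = sub["cq"].to_numpy(float)
    if x.std() == 0:
        raise CurveFitError(f"gene {gene!r}: zero variance in log10(concentration)")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    if slope < 0:
        eff_pct, amp = efficiency_from_slope(slope)
    else:
        eff_pct, amp = math.nan, math.nan
    return CurveFit(
        gene=gene,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        efficiency_pct=eff_pct,
        amp_factor=amp,
        n_points=len(sub),
        cq_range=(float(y.min()), float(y.max())),
        dilution_factor=float(dilutions.attrs.get("dilution_factor", math.nan)),
    )


def fit_all_curves(dilutions: pd.DataFrame, use: str = "all_points") -> dict:
    """Fit every gene present in the dilution table; returns gene -> CurveFit."""
    return {g: fit_curve(dilutions, g, use=use) for g in dilutions["gene"].unique()}


def curve_report(fits) -> pd.DataFrame:
    """One row per gene: slope, intercept, R², efficiency and formula string.

    Invalid fits (slope >= 0) keep their row with a ``valid = False`` flag and
    a blank efficiency.  Advisory quality flags (R² >= 0.99, efficiency within
    90–110%) are reported, never enforced.
    """
    fits = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if not fits:
        raise ValueError("curve_report needs at least one fit")
    rows = []
    for f in fits:
        rows.append({
            "gene": f.gene,
            "slope": f.slope,
            "intercept": f.intercept,
            "r_squared": f.r_squared,
            "efficiency_pct": f.efficiency_pct,
            "amp_factor": f.amp_factor,
            "formula": f"Cq = {f.slope:.4f}*log10(conc) + {f.intercept:.4f}",
            "n_points": f.n_points,
            "min_cq": f.cq_range[0],
            "max_cq": f.cq_range[1],
            "valid": f.valid,
            "flag_r_squared": f.r_squared >= 0.99,
            "flag_efficiency": f.valid and 90.0 <= f.efficiency_pct <= 110.0,
        })
    return pd.DataFrame(rows)
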