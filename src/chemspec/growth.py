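"""Growth-curve summaries, MIC determination and LC-MS calibration /
relative quantification.

The MIC rule is explicit: the lowest tested dose whose optical density at
the readout time stays at (or below) blank + threshold, the control having
grown. Calibration is an ordinary least-squares line through (concentration,
peak area) standards, with an optional 1/x weighting for the poor low-end
signal typical of dilute standards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GrowthCurve",
    "CalibrationModel",
    "growth_summary",
    "mic_estimate",
    "fit_calibration",
    "quantify",
]


@dataclass
class GrowthCurve:
    """Optical-density time series for one culture condition."""

    time: np.ndarray
    od: np.ndarray
    pH: int | float | None = None
    dose: float | None = None
    treatment_time: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.shape != self.od.shape:
            raise ValueError("time and od must have equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite values")
        if (self.od < 0).any():
            raise ValueError("od must be non-negative")

    def od_at(self, t: float) -> float:
        """Linearly interpolated OD at time t (clamped to the grid ends)."""
        return float(np.interp(t, self.time, self.od))


def growth_summary(g: GrowthCurve) -> dict:
    """Max OD, time to half-max (linear interpolation between bracketing
    points; NaN when the curve never grows) and trapezoid-rule AUC."""
    if len(g.time) < 3:
        raise ValueError("need at least 3 time points")
    max_od = float(g.od.max())
    auc = float(np.trapezoid(g.od, g.time))
    if max_od == 0:
        return {"max_od": 0.0, "t_half_max": math.nan, "auc": 0.0}
    half = max_od / 2.0
    t_half = math.nan
    above = g.od >= half
    idx = int(np.argmax(above))  # first crossing
    if above[0]:
        t_half = float(g.time[0])
    elif above.any():
        t0, t1 = g.time[idx - 1], g.time[idx]
        y0, y1 = g.od[idx - 1], g.od[idx]
        t_half = float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))
    return {"max_od": max_od, "t_half_max": t_half, "auc": auc}


def mic_estimate(
    curves,
    od_threshold: float = 0.05,
    blank: float = 0.0,
    at_time: float | None = None,
) -> float:
    """Lowest tested dose whose OD at ``at_time`` (default: final point) is
    at or below ``blank + od_threshold``.

    Requires a dose-0 control that grows above the cutoff. Returns
    ``float('inf')`` when every dose still grows (MIC above the tested
    range). Raising ``od_threshold`` can only lower (never raise) the MIC.
    """
    by_dose: dict[float, GrowthCurve] = {}
    for c in curves:
        if c.dose is None:
            raise ValueError("every curve needs a dose annotation")
        by_dose[float(c.dose)] = c
    if 0.0 not in by_dose:
        raise ValueError("no dose-0 control curve")
    doses = sorted(by_dose)
    cutoff = blank + od_threshold

    def endpoint(c: GrowthCurve) -> float:
        return c.od_at(at_time) if at_time is not None else float(c.od[-1])

    if endpoint(by_dose[0.0]) <= cutoff:
        raise ValueError("no growth in control: MIC undefined")
    for d in doses:
        if d == 0.0:
            continue
        if endpoint(by_dose[d]) <= cutoff:
            return d
    return math.inf


@dataclass
class CalibrationModel:
    """Straight-line peak-area response: area = slope·conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    conc_range: tuple
    residuals: pd.DataFrame | None = None

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("calibration needs >= 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


def fit_calibration(conc, area, weighted: bool = False) -> CalibrationModel:
    """Least-squares calibration line with residual table.

    ``weighted=True`` fits 1/x-weighted least squares (each point weighted
    by 1/concentration), the usual remedy when low-concentration standards
    have proportionally noisier signal.
    """
    conc = np.asarray(conc, dtype=float)
    area = np.asarray(area, dtype=float)
    if conc.shape != area.shape or conc.ndim != 1:
        raise ValueError("conc and area must be equal-length vectors")
    if len(np.unique(conc)) < 2:
        raise ValueError("all concentrations equal: slope undefined")
    if weighted:
        if (conc <= 0).any():
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / conc
        sw = np.sqrt(w)
        A = np.column_stack([sw * conc, sw])
        coef, *_ = np.linalg.lstsq(A, sw * area, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        fitted = slope * conc + intercept
        ss_res = float(np.sum(w * (area - fitted) ** 2))
        mean_w = float(np.sum(w * area) / np.sum(w))
        ss_tot = float(np.sum(w * (area - mean_w) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = scipy.stats.linregress(conc, area)
        slope, intercept = float(fit.slope), float(fit.intercept)
        fitted = slope * conc + intercept
        r2 = float(fit.rvalue**2)
    resid = pd.DataFrame(
        {"concentration": conc, "area": area, "fitted": fitted, "residual": area - fitted}
    )
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=len(conc),
        conc_range=(float(conc.min()), float(conc.max())),
        residuals=resid,
    )


def quantify(model: CalibrationModel, areas, biomass_norm=None) -> pd.DataFrame:
    """Invert the calibration: concentration = (area − intercept)/slope.

    Values landing below the lowest standard are flagged
    ``below_working_range`` (extrapolation into the region where the
    instrument response is unreliable). ``biomass_norm`` optionally divides
    each concentration by a per-sample normaliser.
    """
    if model.slope <= 0:
        raise ValueError("non-positive calibration slope")
    areas = np.asarray(areas, dtype=float)
    if (areas < 0).any():
        raise ValueError("areas must be >= 0")
    conc = (areas - model.intercept) / model.slope
    out = pd.DataFrame({"area": areas, "concentration": conc})
    out["below_working_range"] = conc < model.conc_range[0]
    if biomass_norm is not None:
        norm = np.asarray(biomass_norm, dtype=float)
        if norm.shape != areas.shape:
            raise ValueError("biomass_norm length mismatch")
        if (norm <= 0).any():
            raise ValueError("biomass normaliser must be positive")
        out["normalized"] = conc / norm
    return out
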