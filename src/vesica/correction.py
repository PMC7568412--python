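"""Filling dependence of wall thickness and the filling-corrected ratio.

Wall thickness depends strongly on bladder filling, so longitudinal
comparisons must remove it.  Two tools do that here:

* ``fit_power_law`` / ``plateau_onset`` characterise the thickness-volume
  relationship t(V) = c * V**p (log-log ordinary least squares) and locate
  the filling volume above which the fitted curve stays within a relative
  tolerance of its interval mean ("plateau", the reproducible measurement
  condition).
* ``bwt_ratio`` implements the baseline-normalised, filling-corrected
  thickness ratio.  Rescaling each thickness to a reference volume via
  t_ref = t * (2R / 2R_ref) and normalising to baseline makes the
  reference radius cancel:

      ratio = (BWT(t) * 2R(t)) / (BWT(t0) * 2R(t0))

  For a spherical bladder with t proportional to 1/R, the product BWT*2R is
  filling-invariant, so an unirradiated bladder has ratio 1 regardless of
  how full it happens to be at either scan — this links the thickness-vs-
  volume law to the longitudinal correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .laws import power_interval_mean

__all__ = [
    "PowerLawFit",
    "PlateauResult",
    "RatioSeries",
    "bwt_ratio",
    "fit_power_law",
    "plateau_onset",
    "build_ratio_series",
    "DEFAULT_PLATEAU_TOLERANCE",
]

#: Default relative tolerance defining the plateau (the reported maximum
#: in-plateau variation is about 15%).
DEFAULT_PLATEAU_TOLERANCE = 0.15


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log OLS fit t = c * V**p."""

    coefficient: float
    exponent: float
    log_rse: float
    n: int

    def thickness(self, volume_ml):
        """Fitted thickness (mm) at the given volume(s)."""
        v = np.asarray(volume_ml, dtype=float)
        out = self.coefficient * v**self.exponent
        return float(out) if np.isscalar(volume_ml) else out

    def interval_mean(self, lo: float, hi: float) -> float:
        return power_interval_mean(self.coefficient, self.exponent, lo, hi)


@dataclass(frozen=True)
class PlateauResult:
    """Plateau detection outcome.

    ``onset_ml`` is the smallest grid volume V* such that the fitted curve
    stays within ``tolerance`` of its [V*, Vmax] interval mean; ``found``
    is False (and onset is None) when no such volume exists below Vmax.
    """

    found: bool
    onset_ml: float | None
    plateau_mean_mm: float | None
    max_rel_deviation: float | None
    tolerance: float


def bwt_ratio(bwt_t: float, diam_t: float, bwt_t0: float, diam_t0: float) -> float:
    """Baseline-normalised filling-corrected thickness ratio.

    ``(bwt_t * diam_t) / (bwt_t0 * diam_t0)``; the reference radius of the
    underlying volume correction cancels exactly, so it takes no parameter.
    """
    vals = (bwt_t, diam_t, bwt_t0, diam_t0)
    if any(v <= 0 or not np.isfinite(v) for v in vals):
        raise ValueError("all thicknesses and diameters must be positive")
    return (bwt_t * diam_t) / (bwt_t0 * diam_t0)


def fit_power_law(volumes, thicknesses) -> PowerLawFit:
    """Ordinary least squares of log(t) on log(V).

    A multiplicative noise model on thickness is additive on the log scale,
    which is why the fit runs there (and why it interpolates noiseless
    power-law data exactly).
    """
    v = np.asarray(volumes, dtype=float)
    t = np.asarray(thicknesses, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("volumes and thicknesses must be 1D of equal length")
    if v.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(v <= 0) or np.any(t <= 0):
        raise ValueError("volumes and thicknesses must be positive")
    lx, ly = np.log(v), np.log(t)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    dof = max(v.size - 2, 1)
    rse = float(np.sqrt(np.sum(resid**2) / dof))
    return PowerLawFit(
        coefficient=float(np.exp(intercept)),
        exponent=float(slope),
        log_rse=rse,
        n=int(v.size),
    )


def plateau_onset(
    fit: PowerLawFit,
    volume_range_ml: tuple[float, float],
    tolerance: float = DEFAULT_PLATEAU_TOLERANCE,
    grid_step_ml: float = 0.01,
) -> PlateauResult:
    """Locate the plateau onset of a fitted thickness curve.

    Scans candidate onsets V* on a grid of step ``grid_step_ml`` from Vmin
    to Vmax; V* is accepted when the fitted thickness, evaluated on the
    grid over [V*, Vmax], deviates from its (closed-form) interval mean by
    at most ``tolerance`` everywhere.  A curve too steep to settle returns
    a "no plateau" result rather than raising.
    """
    vmin, vmax = volume_range_ml
    if not (0 < vmin < vmax):
        raise ValueError("need 0 < Vmin < Vmax")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    grid = np.arange(vmin, vmax + grid_step_ml / 2.0, grid_step_ml)
    grid[-1] = min(grid[-1], vmax)
    t_grid = fit.thickness(grid)
    for i, v0 in enumerate(grid[:-1]):
        mean = fit.interval_mean(float(v0), vmax)
        dev = float(np.max(np.abs(t_grid[i:] - mean)) / mean)
        if dev <= tolerance:
            return PlateauResult(
                found=True,
                onset_ml=float(v0),
                plateau_mean_mm=mean,
                max_rel_deviation=dev,
                tolerance=tolerance,
            )
    return PlateauResult(
        found=False,
        onset_ml=None,
        plateau_mean_mm=None,
        max_rel_deviation=None,
        tolerance=tolerance,
    )


@dataclass
class RatioSeries:
    """Baseline measurements and per-day corrected ratios for one rat."""

    rat_id: str
    group: str
    baseline_day: int
    bwt_t0_mm: float
    diam_t0_mm: float
    days: list[int]
    bwt_mm: list[float]
    diam_mm: list[float]
    ratios: list[float]
    below_plateau: list[bool]


def build_ratio_series(
    measurements: pd.DataFrame,
    plateau_onset_ml: float = 1.5,
    baseline_day: int | None = None,
) -> pd.DataFrame:
    """Per-rat corrected ratios from a long measurement table.

    ``measurements`` needs columns ``rat_id, group, day, bwt_mm, diam_mm``
    and optionally ``volume_mL`` (used to flag scans acquired below the
    plateau onset, where the 1/R correction extrapolates outside its
    validated regime — those rats stay in the analysis, flagged).  The
    baseline is the row at ``baseline_day`` (default: smallest day).
    Ratios are canonically computed from ventral-side measurements; pass in
    ventral rows only (a ``side`` column, if present, must be uniform).

    Returns one row per rat and follow-up day with columns
    ``rat_id, group, day, bwt_t0, diam_t0, bwt_t, diam_t, ratio,
    below_plateau_flag``.
    """
    req = {"rat_id", "group", "day", "bwt_mm", "diam_mm"}
    missing = req - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    if "side" in measurements.columns:
        sides = set(measurements["side"].unique())
        if len(sides) > 1:
            raise ValueError(
                "mixed sides in measurement table; the corrected ratio is "
                "defined per side (canonically ventral)"
            )
    if baseline_day is None:
        baseline_day = int(measurements["day"].min())
    rows = []
    for rat_id, sub in measurements.groupby("rat_id", sort=True):
        base = sub[sub["day"] == baseline_day]
        if base.empty:
            raise ValueError(f"rat {rat_id!r}: no baseline (day {baseline_day}) measurement")
        b = base.iloc[0]
        for _, r in sub[sub["day"] != baseline_day].sort_values("day").iterrows():
            ratio = bwt_ratio(r["bwt_mm"], r["diam_mm"], b["bwt_mm"], b["diam_mm"])
            below = bool(
                "volume_mL" in sub.columns
                and np.isfinite(r.get("volume_mL", np.nan))
                and r["volume_mL"] < plateau_onset_ml
            )
            rows.append(
                {
                    "rat_id": rat_id,
                    "group": r["group"],
                    "day": int(r["day"]),
                    "bwt_t0": float(b["bwt_mm"]),
                    "diam_t0": float(b["diam_mm"]),
                    "bwt_t": float(r["bwt_mm"]),
                    "diam_t": float(r["diam_mm"]),
                    "ratio": float(ratio),
                    "below_plateau_flag": below,
                }
            )
    columns = [
        "rat_id", "group", "day", "bwt_t0", "diam_t0",
        "bwt_t", "diam_t", "ratio", "below_plateau_flag",
    ]
    return pd.DataFrame(rows, columns=columns)
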