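"""Synthetic longitudinal cohorts and filling-series datasets.

Two generators live here:

``generate_filling_series``
    Repeated thickness measurements of unirradiated bladders across a range
    of filling volumes (the data behind the thickness-vs-volume curve).

``generate_cohort``
    A longitudinal irradiation experiment: a control group and irradiated
    groups scanned at baseline (day -1) and at follow-up days 4 and 28.
    Radiation-induced wall thickening is modelled as a per-rat, per-day
    multiplicative effect on the filling law; the effect multiplier is
    drawn from a log-normal distribution moment-matched to the target
    group mean and SD (ratios are positive and right-skewed, which the
    published min-max ranges also suggest).

Determinism: every random draw comes from a substream derived from the
root seed and the (group, rat, timepoint) indices, so enlarging a group
does not reshuffle the draws of existing rats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .laws import MAX_FILLING_ML, ThicknessLaw

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "TimepointRecord",
    "RatRecord",
    "DEFAULT_GROUPS",
    "BASELINE_DAY",
    "lognormal_params",
    "generate_cohort",
    "generate_filling_series",
    "simulate_measurements",
    "cohort_to_frame",
    "sphere_equivalent_diameter_mm",
]

#: Day label of the pre-irradiation scan.
BASELINE_DAY = -1

# Substream tags: keep draw streams for distinct purposes disjoint.
_STREAM_COHORT = 0
_STREAM_MEASURE = 1
_STREAM_RENDER = 2


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Invert (mean, sd) on the natural scale to log-normal (mu, sigma).

    With ``sigma**2 = ln(1 + sd**2/mean**2)`` and
    ``mu = ln(mean) - sigma**2/2`` the resulting log-normal has exactly the
    requested first two moments.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Analytic mean and SD of a log-normal with parameters (mu, sigma)."""
    mean = np.exp(mu + sigma**2 / 2.0)
    sd = mean * np.sqrt(np.expm1(sigma**2))
    return float(mean), float(sd)


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm: label, size, nominal dose and effect calibration.

    ``effect_by_day`` maps a follow-up day to the (mean, sd) of the thickening
    multiplier on that day (dimensionless ratio scale; 1 = no change).
    """

    label: str
    n: int
    dose_gy: tuple[float, float] | None
    effect_by_day: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for day, (mean, sd) in self.effect_by_day.items():
            if mean <= 0:
                raise ValueError(f"{self.label} day {day}: effect mean must be > 0")
            if sd < 0:
                raise ValueError(f"{self.label} day {day}: effect SD must be >= 0")


#: Default calibration: group sizes, dose ranges and per-day effect
#: multipliers matching the published corrected-ratio statistics.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("control", 6, None, {4: (0.94, 0.13), 28: (0.94, 0.10)}),
    GroupSpec("25-30Gy", 9, (25.0, 30.0), {4: (1.32, 0.41), 28: (1.30, 0.21)}),
    GroupSpec("35-40Gy", 9, (35.0, 40.0), {4: (1.47, 0.29), 28: (1.90, 0.83)}),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated longitudinal experiment.

    ``measurement_cv`` is the per-scan multiplicative noise CV on thickness;
    ``diameter_cv`` the (much smaller) CV on the area-derived mean diameter.
    Imaging fillings are drawn uniformly from ``filling_range_ml`` — the
    "full bladder" protocol keeps scans inside the plateau.
    ``n_impaired_high_dose`` optionally gives that many rats of the last
    group a low residual capacity (filling below the plateau) at the last
    follow-up day, emulating radiation-impaired reservoirs.
    """

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    days: tuple[int, ...] = (4, 28)
    baseline_day: int = BASELINE_DAY
    measurement_cv: float = 0.08
    diameter_cv: float = 0.01
    filling_range_ml: tuple[float, float] = (1.8, 2.8)
    impaired_filling_range_ml: tuple[float, float] = (0.8, 1.4)
    n_impaired_high_dose: int = 0
    law: ThicknessLaw = field(default_factory=ThicknessLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_cv < 0 or self.diameter_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        lo, hi = self.filling_range_ml
        if not (0 < lo <= hi <= MAX_FILLING_ML):
            raise ValueError(
                f"filling range must lie within (0, {MAX_FILLING_ML}] mL"
            )
        if not self.groups:
            raise ValueError("at least one group is required")
        for g in self.groups:
            missing = [d for d in self.days if d not in g.effect_by_day]
            if missing:
                raise ValueError(f"group {g.label}: no effect for days {missing}")


@dataclass
class TimepointRecord:
    """True state and measurement slots of one rat at one scan."""

    day: int
    volume_ml: float
    multiplier: float
    t_ventral_mm: float
    t_dorsal_mm: float
    bwt_measured_mm: float | None = None
    diam_measured_mm: float | None = None


@dataclass
class RatRecord:
    """One animal: identity, arm and its per-timepoint entries."""

    rat_id: str
    group: str
    dose_gy: float | None
    group_index: int
    rat_index: int
    timepoints: list[TimepointRecord]

    @property
    def baseline(self) -> TimepointRecord:
        return self.timepoints[0]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def sphere_equivalent_diameter_mm(volume_ml: float) -> float:
    """Diameter (mm) of a sphere of the given volume (mL = cm^3)."""
    if volume_ml < 0:
        raise ValueError("volume must be >= 0")
    return 2.0 * 10.0 * (3.0 * volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)


def generate_cohort(config: CohortConfig) -> list[RatRecord]:
    """Draw a full cohort of :class:`RatRecord` per the configuration.

    Per rat and timepoint: a filling volume uniform on the configured range,
    an effect multiplier (1 at baseline, log-normal on follow-up days) and
    the resulting true ventral/dorsal thicknesses
    ``t = M * law.thickness(V)``.
    """
    law = config.law
    records: list[RatRecord] = []
    last_group = len(config.groups) - 1
    last_day = max(config.days) if config.days else None
    for gi, group in enumerate(config.groups):
        for ri in range(group.n):
            rng_dose = _rng(config.seed, _STREAM_COHORT, gi, ri)
            dose = None
            if group.dose_gy is not None:
                dose = float(rng_dose.uniform(*group.dose_gy))
            tps: list[TimepointRecord] = []
            for ti, day in enumerate((config.baseline_day, *config.days)):
                rng = _rng(config.seed, _STREAM_COHORT, gi, ri, ti)
                filling = config.filling_range_ml
                impaired = (
                    gi == last_group
                    and group.dose_gy is not None
                    and ri < config.n_impaired_high_dose
                    and day == last_day
                )
                if impaired:
                    filling = config.impaired_filling_range_ml
                volume = float(rng.uniform(*filling))
                if day == config.baseline_day:
                    mult = 1.0
                else:
                    mean, sd = group.effect_by_day[day]
                    mu, sigma = lognormal_params(mean, sd)
                    mult = float(rng.lognormal(mu, sigma))
                tv = mult * law.ventral_thickness(volume)
                td = mult * law.dorsal_thickness(volume)
                tps.append(TimepointRecord(day, volume, mult, tv, td))
            records.append(
                RatRecord(
                    rat_id=f"{group.label}-r{ri:03d}",
                    group=group.label,
                    dose_gy=dose,
                    group_index=gi,
                    rat_index=ri,
                    timepoints=tps,
                )
            )
    return records


def simulate_measurements(
    records: Sequence[RatRecord], config: CohortConfig
) -> list[RatRecord]:
    """Fill measurement slots with multiplicative Gaussian noise.

    This is the fast bookkeeping route (no pixels): measured thickness is
    the true ventral thickness times ``1 + cv*z`` and the measured mean
    diameter is the sphere-equivalent diameter of the true volume times
    ``1 + diameter_cv*z``.  The pixel route lives in :mod:`vesica.pipeline`.
    """
    out = []
    for rat in records:
        tps = []
        for ti, tp in enumerate(rat.timepoints):
            rng = _rng(config.seed, _STREAM_MEASURE, rat.group_index, rat.rat_index, ti)
            z_t, z_d = rng.standard_normal(2)
            bwt = tp.t_ventral_mm * max(1.0 + config.measurement_cv * z_t, 0.05)
            diam = sphere_equivalent_diameter_mm(tp.volume_ml) * max(
                1.0 + config.diameter_cv * z_d, 0.05
            )
            tps.append(replace(tp, bwt_measured_mm=bwt, diam_measured_mm=diam))
        out.append(replace(rat, timepoints=tps))
    return out


def cohort_to_frame(records: Sequence[RatRecord]) -> pd.DataFrame:
    """Flatten rat records to the cohort table (one row per rat x scan)."""
    rows = []
    for rat in records:
        for tp in rat.timepoints:
            rows.append(
                {
                    "rat_id": rat.rat_id,
                    "group": rat.group,
                    "dose_Gy": rat.dose_gy,
                    "day": tp.day,
                    "volume_mL": tp.volume_ml,
                    "t_ventral_mm": tp.t_ventral_mm,
                    "t_dorsal_mm": tp.t_dorsal_mm,
                    "multiplier": tp.multiplier,
                    "bwt_meas_mm": tp.bwt_measured_mm,
                    "diam_meas_mm": tp.diam_measured_mm,
                }
            )
    return pd.DataFrame(rows)


def generate_filling_series(
    law: ThicknessLaw,
    n_rats: int,
    volumes_per_rat: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Thickness-vs-volume table for unirradiated rats.

    Each rat is "scanned" at every volume in ``volumes_per_rat``; ventral
    and dorsal true thicknesses follow the law, measured values carry
    multiplicative Gaussian noise of CV ``noise_cv``.

    Returns a frame with columns
    ``rat_id, volume_mL, side, t_true_mm, t_meas_mm``.
    """
    volumes = np.asarray(list(volumes_per_rat), dtype=float)
    if volumes.size == 0:
        raise ValueError("volumes_per_rat must not be empty")
    if np.any(volumes <= 0) or np.any(volumes > MAX_FILLING_ML):
        raise ValueError(f"volumes must lie within (0, {MAX_FILLING_ML}] mL")
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rows = []
    for ri in range(n_rats):
        rng = _rng(seed, _STREAM_COHORT, ri)
        noise = rng.standard_normal((volumes.size, 2))
        for vi, v in enumerate(volumes):
            for si, side in enumerate(("ventral", "dorsal")):
                t_true = (
                    law.ventral_thickness(v) if side == "ventral" else law.dorsal_thickness(v)
                )
                t_meas = t_true * max(1.0 + noise_cv * noise[vi, si], 0.05)
                rows.append(
                    {
                        "rat_id": f"filling-r{ri:03d}",
                        "volume_mL": float(v),
                        "side": side,
                        "t_true_mm": float(t_true),
                        "t_meas_mm": float(t_meas),
                    }
                )
    return pd.DataFrame(rows)
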