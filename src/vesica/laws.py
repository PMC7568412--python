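"""Bladder wall thickness as a function of filling volume.

The bladder wall thins as the organ fills.  For a near-spherical bladder
whose wall cross-section is conserved while the lumen dilates, the mean
wall thickness scales like the inverse lumen radius, i.e.

    t(V) = c * V**p,   p = -1/3.

Above roughly 1.5 mL of filling the curve is flat enough that the mean
ventral thickness is effectively constant (~0.30 mm in adult female
Fischer rats, varying by less than about 15% across the 1.5-3.0 mL
interval).  :class:`ThicknessLaw` encodes this ventral law together with
a dorsal deficit: the dorsal wall reads systematically thinner (gravity
compresses it against the dependent tissues in supine imaging), with the
deficit shrinking as the bladder distends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThicknessLaw",
    "ventral_thickness",
    "dorsal_thickness",
    "calibrated_coefficient",
    "power_interval_mean",
    "DEFAULT_EXPONENT",
    "DEFAULT_COEFFICIENT",
    "MIN_FILLING_ML",
    "MAX_FILLING_ML",
    "PLATEAU_RANGE_ML",
    "PLATEAU_MEAN_MM",
]

#: Exponent of the filling law (inverse cube root of volume).
DEFAULT_EXPONENT = -1.0 / 3.0

#: Smallest filling volume (mL) the model is exercised at ("empty" bladder
#: still holds residual urine) and largest physiological filling.
MIN_FILLING_ML = 0.2
MAX_FILLING_ML = 3.0

#: Plateau of the thickness-volume curve: interval and its mean thickness.
PLATEAU_RANGE_ML = (1.5, 3.0)
PLATEAU_MEAN_MM = 0.30


def power_interval_mean(
    coefficient: float, exponent: float, lo: float, hi: float
) -> float:
    """Closed-form mean of ``c * V**p`` over the volume interval [lo, hi]."""
    if not (0 < lo < hi):
        raise ValueError(f"invalid volume interval [{lo}, {hi}]")
    if exponent == -1.0:
        integral = coefficient * np.log(hi / lo)
    else:
        q = exponent + 1.0
        integral = coefficient * (hi**q - lo**q) / q
    return float(integral / (hi - lo))


def calibrated_coefficient(
    exponent: float = DEFAULT_EXPONENT,
    plateau_mean_mm: float = PLATEAU_MEAN_MM,
    plateau_range_ml: tuple[float, float] = PLATEAU_RANGE_ML,
) -> float:
    """Scale ``c`` such that the law's mean over the plateau interval is
    ``plateau_mean_mm``."""
    unit_mean = power_interval_mean(1.0, exponent, *plateau_range_ml)
    return plateau_mean_mm / unit_mean


#: Default scale, calibrated so the [1.5, 3.0] mL interval mean is 0.30 mm.
DEFAULT_COEFFICIENT = calibrated_coefficient()


def _check_volume(volume_ml):
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("filling volume must be positive and finite (mL)")
    return v


@dataclass(frozen=True)
class ThicknessLaw:
    """Ventral filling law ``t(V) = c * V**p`` with a dorsal deficit.

    Parameters
    ----------
    coefficient:
        Scale ``c`` in mm * mL**(-p); the thickness at V = 1 mL.
    exponent:
        Power ``p`` (<= 0); -1/3 reproduces the inverse-cube-root thinning.
    dorsal_deficit_max:
        Fractional deficit of the dorsal wall at the minimum filling
        (0.2 mL); decays linearly to zero at ``dorsal_deficit_zero_volume``.
    dorsal_deficit_zero_volume:
        Filling (mL) at which dorsal and ventral thickness coincide.
    """

    coefficient: float = DEFAULT_COEFFICIENT
    exponent: float = DEFAULT_EXPONENT
    dorsal_deficit_max: float = 0.20
    dorsal_deficit_zero_volume: float = MAX_FILLING_ML

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("coefficient must be > 0")
        if self.exponent > 0:
            raise ValueError("exponent must be <= 0 (wall thins with filling)")
        if not 0 <= self.dorsal_deficit_max < 1:
            raise ValueError("dorsal_deficit_max must be in [0, 1)")
        if self.dorsal_deficit_zero_volume <= MIN_FILLING_ML:
            raise ValueError(
                "dorsal_deficit_zero_volume must exceed the minimum filling "
                f"({MIN_FILLING_ML} mL)"
            )

    def ventral_thickness(self, volume_ml):
        """Ventral wall thickness (mm) at the given filling volume(s)."""
        v = _check_volume(volume_ml)
        out = self.coefficient * v**self.exponent
        return float(out) if np.isscalar(volume_ml) else out

    def dorsal_deficit(self, volume_ml):
        """Fractional dorsal deficit at the given filling volume(s)."""
        v = _check_volume(volume_ml)
        span = self.dorsal_deficit_zero_volume - MIN_FILLING_ML
        frac = self.dorsal_deficit_max * (self.dorsal_deficit_zero_volume - v) / span
        out = np.clip(frac, 0.0, self.dorsal_deficit_max)
        return float(out) if np.isscalar(volume_ml) else out

    def dorsal_thickness(self, volume_ml):
        """Dorsal wall thickness (mm): ventral reduced by the deficit."""
        return self.ventral_thickness(volume_ml) * (1.0 - self.dorsal_deficit(volume_ml))

    def interval_mean(self, lo: float, hi: float) -> float:
        """Mean ventral thickness over a volume interval (closed form)."""
        return power_interval_mean(self.coefficient, self.exponent, lo, hi)


def ventral_thickness(law: ThicknessLaw, volume_ml):
    """Functional form of :meth:`ThicknessLaw.ventral_thickness`."""
    return law.ventral_thickness(volume_ml)


def dorsal_thickness(law: ThicknessLaw, volume_ml):
    """Functional form of :meth:`ThicknessLaw.dorsal_thickness`."""
    return law.dorsal_thickness(volume_ml)
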