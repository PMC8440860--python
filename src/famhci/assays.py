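"""Colorimetric assay computations.

Nitrite quantification against a sodium-nitrite standard curve (Griess
reaction read at 540 nm) and arginase activity in U/L from a urea
absorbance readout at 430 nm.  The standard curve is an ordinary
least-squares line — the Griess response is linear over the assay range —
and its inversion clips negative concentrations at zero (with a warning)
and warns when extrapolating beyond the fitted span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "nitrite_concentration",
    "arginase_activity",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS line absorbance = intercept + slope * concentration."""

    slope: float
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]


def fit_standard_curve(
    standards: Sequence[tuple[float, float]],
) -> StandardCurve:
    """Fit an OLS standard curve to (concentration, absorbance) points.

    Requires at least two distinct concentrations.  With two points the
    result is the interpolating line (r² = 1).
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (concentration, absorbance) pairs")
    conc, ab = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("all standard concentrations are equal")
    slope, intercept = np.polyfit(conc, ab, 1)
    resid = ab - (intercept + slope * conc)
    ss_res = float(resid @ resid)
    ss_tot = float(((ab - ab.mean()) ** 2).sum())
    if ss_tot == 0 or ss_res <= 1e-12 * max(ss_tot, 1.0):
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def nitrite_concentration(absorbance, curve: StandardCurve):
    """Invert the standard curve: (absorbance - intercept) / slope, in µM.

    Negative concentrations are clipped to 0 with a warning; values outside
    the fitted concentration span raise an extrapolation warning.
    Accepts scalars or arrays.
    """
    if not abs(curve.slope) > 1e-12:
        raise ValueError("standard curve slope is zero; cannot invert")
    conc = (np.asarray(absorbance, dtype=float) - curve.intercept) / curve.slope
    scalar = conc.ndim == 0
    conc = np.atleast_1d(conc)
    if (conc < 0).any():
        warnings.warn("negative concentration clipped to 0", stacklevel=2)
        conc = np.clip(conc, 0.0, None)
    lo, hi = curve.concentration_range
    if ((conc < lo) | (conc > hi)).any():
        warnings.warn(
            "concentration outside the fitted standard range (extrapolation)",
            stacklevel=2,
        )
    return float(conc[0]) if scalar else conc


def arginase_activity(
    a430_sample: float,
    a430_blank: float,
    urea_standard: tuple[float, float],
    reaction_time_min: float,
    sample_volume_ml: float,
) -> float:
    """Arginase activity in U/L (1 U produces 1 µmol ornithine per minute).

    ``urea_standard`` is (µmol, AU) for the urea calibrator; the kit's 1:1
    urea:ornithine stoichiometry converts urea generated to ornithine.
    Activity = urea µmol / (time · volume), volume expressed in liters.
    """
    std_umol, std_au = urea_standard
    if reaction_time_min <= 0 or sample_volume_ml <= 0:
        raise ValueError("reaction time and sample volume must be > 0")
    if std_au <= 0 or std_umol <= 0:
        raise ValueError("urea standard must have positive µmol and AU")
    au_per_umol = std_au / std_umol
    urea_umol = (a430_sample - a430_blank) / au_per_umol
    return urea_umol / reaction_time_min / (sample_volume_ml / 1000.0)
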