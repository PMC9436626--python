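"""Linear calibration, LOD/LOQ from signal-to-noise, and external-standard
quantification (ESM).

The external standard method quantifies each analyte against its own
calibration line ``area = slope * conc + intercept``; mass fractions are
``W = conc * extract_volume / sample_mass`` in mg per g of dried powder
(default extraction: 20.0 mL of solvent per 0.5 g of powder).

LOD and LOQ are the concentrations whose predicted peak height reaches a
signal-to-noise ratio of 3 and 10 respectively, so LOQ/LOD = 10/3 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_EXTRACT_VOLUME_ML = 20.0
DEFAULT_SAMPLE_MASS_G = 0.5


@dataclass
class CalibrationCurve:
    analyte_id: str
    slope: float  # area per (mg/mL)
    intercept: float  # area
    r2: float
    linear_range: tuple[float, float]  # mg/mL
    lod: float = float("nan")  # mg/mL
    loq: float = float("nan")  # mg/mL

    def predict_conc(self, area: float) -> float:
        return (area - self.intercept) / self.slope


def fit_calibration(conc, area, analyte_id: str = "") -> CalibrationCurve:
    """Ordinary least squares of area on concentration.

    Requires >= 3 distinct concentration levels; r2 is the squared
    Pearson correlation of the fit.
    """
    conc = np.asarray(conc, dtype=float)
    area = np.asarray(area, dtype=float)
    if conc.shape != area.shape:
        raise ValueError("conc and area must have equal length")
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    if np.ptp(conc) == 0:
        raise ValueError("zero concentration variance")
    fit = stats.linregress(conc, area)
    return CalibrationCurve(
        analyte_id=analyte_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        linear_range=(float(conc.min()), float(conc.max())),
    )


def lod_loq(noise_sd: float, height_slope: float) -> tuple[float, float]:
    """LOD and LOQ in mg/mL from baseline noise and the height response.

    ``height_slope`` is peak height per unit concentration; the LOD is
    the concentration whose predicted height equals 3 * noise_sd, the
    LOQ the one reaching 10 * noise_sd, hence loq = (10/3) * lod.
    """
    if height_slope <= 0:
        raise ValueError("height slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lod = 3.0 * noise_sd / height_slope
    loq = 10.0 * noise_sd / height_slope
    return lod, loq


def lod_by_dilution_search(
    noise_sd: float,
    height_at_conc,
    conc_hi: float,
    snr_target: float = 3.0,
    tol: float = 1e-9,
) -> float:
    """Alternative LOD: bisection for the concentration whose simulated
    peak height reaches ``snr_target * noise_sd``.

    ``height_at_conc`` maps a concentration to a peak height and must be
    monotone increasing.  Provided for cross-checking the closed-form
    slope-based estimate on nonlinear or empirical height models.
    """
    if noise_sd == 0:
        return 0.0
    target = snr_target * noise_sd
    lo, hi = 0.0, float(conc_hi)
    if height_at_conc(hi) < target:
        raise ValueError("search bracket too low: S/N target not reached")
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if height_at_conc(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def esm_quantify(
    curve: CalibrationCurve,
    area: float,
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_ML,
    sample_mass: float = DEFAULT_SAMPLE_MASS_G,
) -> float:
    """Mass fraction W_ES (mg/g) from a sample peak area.

    conc = (area - intercept) / slope; W = conc * volume / mass.
    A negative implied concentration (a blank or sub-intercept area) is
    clipped to zero with a warning rather than raising.
    """
    if extract_volume <= 0 or sample_mass <= 0:
        raise ValueError("extract volume and sample mass must be positive")
    conc = curve.predict_conc(area)
    if conc < 0:
        warnings.warn(
            f"{curve.analyte_id or 'analyte'}: implied concentration "
            f"{conc:.4g} mg/mL below zero; clipped to 0",
            stacklevel=2,
        )
        conc = 0.0
    return conc * extract_volume / sample_mass
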