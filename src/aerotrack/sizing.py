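"""Rayleigh-scattering photometric sizing.

Particles much smaller than the illumination wavelength scatter with an
intensity proportional to the sixth power of their diameter, so a
single calibration constant k (photons per nm⁶ and mJ) links measured
brightness to size:  I = k d⁶.  Calibration uses monodisperse
polystyrene size standards; the fit is performed in sixth-root space,
where the law is a straight line through the origin, and a
free-exponent power-law fit is stored alongside as a diagnostic of the
d⁶ scaling.  Sizing is only attempted inside a configurable window
(default 40–125 nm): below it the signal drowns in background, above it
the detector's linear range is exhausted.

Clusters — several nebulizer droplets dried into one particle — are
brighter than monomers (a dimer is 2^(1/3) larger, hence 4× brighter)
and are flagged by their diameter relative to the monomer mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import AerotrackError
from .simulate import IlluminationProfile


@dataclass(frozen=True)
class SizeStandard:
    """One monodisperse calibration standard."""

    nominal_diameter_nm: float
    diameter_sd_nm: float = 0.0
    variation_coefficient_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.nominal_diameter_nm <= 0:
            raise AerotrackError("standard diameter must be positive")


#: The instrument's calibration standards (diameter ± sd in nm).
DEFAULT_STANDARDS = (
    SizeStandard(41, 4), SizeStandard(60, 4, 17.0),
    SizeStandard(70, 3, 10.4), SizeStandard(81, 3, 11.7),
    SizeStandard(100, 3, 7.8), SizeStandard(120, 3, 3.6),
)


@dataclass
class RayleighCalibration:
    """Fitted brightness↔diameter relation I = k d⁶.

    ``free_exponent`` and ``free_exponent_se`` store the diagnostic
    unconstrained power-law fit; the sizing itself always uses the
    fixed exponent 6.
    """

    k: float
    sizing_window_nm: Tuple[float, float] = (40.0, 125.0)
    free_exponent: Optional[float] = None
    free_exponent_se: Optional[float] = None
    free_amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise AerotrackError("calibration constant k must be positive")


def correct_illumination(
    brightness: float,
    position_um: Sequence[float],
    profile: IlluminationProfile,
    pulse_energy_mj: float,
    floor: float = 0.1,
) -> float:
    """Rescale a brightness to beam-center illumination and 1 mJ.

    Returns ``brightness / (relative_intensity × pulse_energy)``; NaN
    when the local relative illumination is below ``floor`` (such
    records are unsizable — the correction would amplify noise).
    """
    if pulse_energy_mj <= 0:
        raise AerotrackError("pulse_energy_mj must be positive")
    rel = profile.relative_intensity(position_um)
    if rel < floor:
        return float("nan")
    return brightness / (rel * pulse_energy_mj)


def standard_mean_brightness(values: Sequence[float],
                             trim: float = 0.05) -> float:
    """Trimmed-mean brightness of one calibration standard.

    A 5% symmetric trim resists residual ghosts (low tail) and
    clusters (high tail) in the per-particle brightness sample.
    """
    from scipy.stats import trim_mean
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise AerotrackError("no brightness values")
    return float(trim_mean(v, trim))


def fit_calibration(
    standards: Sequence[Tuple[float, float]],
    sizing_window_nm: Tuple[float, float] = (40.0, 125.0),
) -> RayleighCalibration:
    """Fit the calibration constant from (diameter, mean brightness) pairs.

    The sixth root of the normalized intensity is linear in diameter
    with zero intercept, so the least-squares slope through the origin
    gives k^(1/6):  m = Σ d·I^(1/6) / Σ d².  A log–log regression with
    free exponent is fitted as a diagnostic and stored, never used for
    sizing.
    """
    if len(standards) < 2:
        raise AerotrackError("calibration needs at least 2 standards")
    d = np.array([s[0] for s in standards], dtype=float)
    i = np.array([s[1] for s in standards], dtype=float)
    if np.any(d <= 0) or np.any(i <= 0):
        raise AerotrackError("diameters and intensities must be positive")
    y = i ** (1.0 / 6.0)
    slope = float(np.dot(d, y) / np.dot(d, d))
    k = slope ** 6

    # free-exponent diagnostic: log I = log a + n log d
    logd, logi = np.log(d), np.log(i)
    A = np.column_stack([logd, np.ones_like(logd)])
    coef, res, *_ = np.linalg.lstsq(A, logi, rcond=None)
    n_exp, log_a = float(coef[0]), float(coef[1])
    if len(d) > 2 and res.size:
        s2 = float(res[0]) / (len(d) - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        se = float(math.sqrt(cov[0, 0]))
    else:
        se = 0.0
    return RayleighCalibration(k=k, sizing_window_nm=tuple(sizing_window_nm),
                               free_exponent=n_exp, free_exponent_se=se,
                               free_amplitude=math.exp(log_a))


def estimate_diameter(
    normalized_brightness: float,
    calibration: RayleighCalibration,
    saturated: bool = False,
) -> Optional[float]:
    """Invert the d⁶ law:  d = (I / k)^(1/6), in nm.

    Returns None (unsizable) for saturated records, non-positive or NaN
    brightness, and diameters outside the sizing window.
    """
    if saturated:
        return None
    if not np.isfinite(normalized_brightness) or normalized_brightness <= 0:
        return None
    d = (normalized_brightness / calibration.k) ** (1.0 / 6.0)
    lo, hi = calibration.sizing_window_nm
    if not lo <= d <= hi:
        return None
    return float(d)


def estimate_monomer_mode(diameters: Sequence[float],
                          n_bins: int = 40) -> float:
    """Mode of the diameter histogram, used as the monomer diameter."""
    d = np.asarray([x for x in diameters if np.isfinite(x)], dtype=float)
    if d.size == 0:
        raise AerotrackError("no sizable records to estimate the monomer mode")
    counts, edges = np.histogram(d, bins=n_bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def flag_clusters(
    diameters: Sequence[float],
    monomer_mode_nm: Optional[float] = None,
    cutoff_factor: float = 1.15,
) -> np.ndarray:
    """Flag particles whose diameter betrays a multi-monomer cluster.

    A dimer is 2^(1/3) ≈ 1.26× the monomer diameter; the default
    cutoff 1.15 sits midway between monomer and dimer.  Returns a
    boolean array aligned with the input (NaN entries are False).
    """
    d = np.asarray(diameters, dtype=float)
    if monomer_mode_nm is None:
        monomer_mode_nm = estimate_monomer_mode(d[np.isfinite(d)])
    if monomer_mode_nm <= 0:
        raise AerotrackError("monomer_mode_nm must be positive")
    with np.errstate(invalid="ignore"):
        flags = d > cutoff_factor * monomer_mode_nm
    flags[~np.isfinite(d)] = False
    return flags
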