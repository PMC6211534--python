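"""Particle-beam characterization.

An aerodynamic lens focuses the aerosol into a narrow beam whose
transverse density profile is Gaussian at every distance from the
injector tip.  The evolution of the profile width with distance follows
a Gaussian-beam envelope

    w(z) = w0 sqrt(1 + ((z - z0) / zR)^2),      theta = w0 / (2 zR),

parameterized by the waist w0 (FWHM), the focus distance z0 and the
far-field divergence half-angle theta (FWHM convention throughout).
The waist, focus distance and divergence each follow power laws in the
lens entrance pressure; exponents are measured by log–log regression.

The module also turns per-frame particle counts into areal number
densities, estimates the injection yield (particles out of the injector
per particle supplied in solution) and predicts X-ray hit ratios from
the measured density and a nominal focus area π (FWHM/2)².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .core import AerotrackError
from .units import (fwhm_to_sigma, per_ml_to_per_um3, sigma_to_fwhm,
                    ul_per_min_to_um3_per_s)


@dataclass(frozen=True)
class GaussianProfile:
    """Maximum-likelihood Gaussian fit of a transverse position sample."""

    center_um: float
    sigma_um: float
    n: int

    @property
    def fwhm_um(self) -> float:
        return sigma_to_fwhm(self.sigma_um)


@dataclass
class BeamModel:
    """Gaussian-beam envelope of the particle beam (FWHM convention)."""

    waist_fwhm_um: float
    focus_distance_mm: float
    divergence_mrad: float  # far-field half-angle of the FWHM envelope
    widths: Optional[List[Tuple[float, float, float]]] = None  # (z, fwhm, se)
    covariance: Optional[np.ndarray] = None

    def width_at(self, z_mm: float) -> float:
        z_r = self.waist_fwhm_um / (2.0 * self.divergence_mrad)  # mm
        return self.waist_fwhm_um * math.sqrt(
            1.0 + ((z_mm - self.focus_distance_mm) / z_r) ** 2)


@dataclass(frozen=True)
class ScalingLawFit:
    """Power law y = amplitude · p^exponent from log–log regression."""

    quantity: str
    amplitude: float
    exponent: float
    exponent_se: float


@dataclass(frozen=True)
class DensityRecord:
    """Areal density of the particle beam under one condition."""

    areal_density_per_um2: float
    beam_cross_section_um2: float
    mean_speed_m_s: float
    entrance_pressure_mbar: float
    injector_distance_mm: float


def transverse_profile(positions_um: Sequence[float],
                       min_count: int = 50) -> GaussianProfile:
    """Fit a Gaussian to unbinned transverse particle positions.

    The maximum-likelihood Gaussian fit to an unbinned sample is the
    sample mean and (biased) standard deviation; histograms are for
    display only.
    """
    x = np.asarray(positions_um, dtype=float)
    if x.size < min_count:
        raise AerotrackError(
            f"transverse profile needs >= {min_count} positions, got {x.size}")
    sigma = float(x.std(ddof=0))
    if sigma == 0.0:
        raise AerotrackError("degenerate profile: all positions identical")
    return GaussianProfile(center_um=float(x.mean()), sigma_um=sigma,
                           n=int(x.size))


def _envelope(z, w0, z0, z_r):
    return w0 * np.sqrt(1.0 + ((z - z0) / z_r) ** 2)


def fit_gaussian_beam(
    z_mm: Sequence[float],
    fwhm_um: Sequence[float],
    fwhm_se_um: Optional[Sequence[float]] = None,
) -> BeamModel:
    """Least-squares fit of the Gaussian-beam envelope to width data.

    Needs at least 4 distances spanning the focus.  The divergence is
    reported as the far-field half-angle of the FWHM envelope,
    theta = w0 / (2 zR) (µm/mm = mrad).
    """
    z = np.asarray(z_mm, dtype=float)
    w = np.asarray(fwhm_um, dtype=float)
    if z.size < 4:
        raise AerotrackError("Gaussian-beam fit needs >= 4 distances")
    i_min = int(np.argmin(w))
    span = max(float(z.max() - z.min()), 1e-6)
    p0 = (float(w[i_min]), float(z[i_min]), span / 2.0)
    sigma = None if fwhm_se_um is None else np.asarray(fwhm_se_um, float)
    try:
        popt, pcov = optimize.curve_fit(
            _envelope, z, w, p0=p0, sigma=sigma,
            bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000)
    except RuntimeError as exc:
        resid = _envelope(z, *p0) - w
        raise AerotrackError(
            f"Gaussian-beam fit did not converge (initial residual RMS "
            f"{float(np.sqrt(np.mean(resid ** 2))):.3g} µm)") from exc
    w0, z0, z_r = map(float, popt)
    widths = [(float(zi), float(wi),
               float(si) if sigma is not None else 0.0)
              for zi, wi, si in zip(z, w, sigma if sigma is not None else np.zeros_like(z))]
    return BeamModel(waist_fwhm_um=w0, focus_distance_mm=z0,
                     divergence_mrad=w0 / (2.0 * z_r),
                     widths=widths, covariance=pcov)


def fit_scaling_law(pressures_mbar: Sequence[float],
                    values: Sequence[float],
                    quantity: str = "") -> ScalingLawFit:
    """Log–log linear regression of a quantity against entrance pressure."""
    p = np.asarray(pressures_mbar, dtype=float)
    y = np.asarray(values, dtype=float)
    if p.size < 3:
        raise AerotrackError("scaling-law fit needs >= 3 pressures")
    if np.any(p <= 0) or np.any(y <= 0):
        raise AerotrackError("pressures and values must be positive")
    res = stats.linregress(np.log(p), np.log(y))
    return ScalingLawFit(quantity=quantity,
                         amplitude=float(math.exp(res.intercept)),
                         exponent=float(res.slope),
                         exponent_se=float(res.stderr))


def areal_density(total_count: float, area_um2: float,
                  n_frames: int = 1) -> float:
    """Mean particles per µm² per frame in a counting region."""
    if area_um2 <= 0:
        raise AerotrackError("region area must be positive")
    if n_frames < 1:
        raise AerotrackError("need at least one frame")
    return total_count / (area_um2 * n_frames)


def peak_areal_density(mean_count_per_frame: float,
                       axial_length_um: float,
                       sigma_transverse_um: float) -> float:
    """Peak column density of an axisymmetric Gaussian beam, per µm².

    ``mean_count_per_frame`` particles observed in an axial window of
    length L spread over a transverse Gaussian of width σ have a line
    density λ = n/L and a peak column density λ / (sqrt(2π) σ).
    """
    if axial_length_um <= 0 or sigma_transverse_um <= 0:
        raise AerotrackError("lengths must be positive")
    lam = mean_count_per_frame / axial_length_um
    return lam / (math.sqrt(2.0 * math.pi) * sigma_transverse_um)


def injection_yield(
    peak_density_per_um2: float,
    sigma_transverse_um: float,
    mean_speed_m_s: float,
    concentration_per_ml: float,
    flow_rate_ul_min: float,
) -> float:
    """Fraction of supplied particles that emerge in the vacuum beam.

    Outflow is the peak volumetric density times the effective beam
    cross-section 2π σ² times the particle speed (for an axisymmetric
    Gaussian beam this equals the exact flux integral); the peak
    volumetric density follows from the measured peak column density as
    n_v = σ_a / (sqrt(2π) σ).  Inflow is concentration × sample flow
    rate.  A yield above 1 is unphysical and indicates a calibration
    error; it is returned as-is with a warning.
    """
    if min(sigma_transverse_um, mean_speed_m_s, concentration_per_ml,
           flow_rate_ul_min) <= 0:
        raise AerotrackError("injection_yield requires positive inputs")
    if peak_density_per_um2 < 0:
        raise AerotrackError("density must be non-negative")
    n_v_peak = peak_density_per_um2 / (math.sqrt(2.0 * math.pi)
                                       * sigma_transverse_um)  # /µm³
    cross_section = 2.0 * math.pi * sigma_transverse_um ** 2   # µm²
    speed_um_s = mean_speed_m_s * 1e6
    outflow = n_v_peak * cross_section * speed_um_s            # /s
    inflow = (per_ml_to_per_um3(concentration_per_ml)
              * ul_per_min_to_um3_per_s(flow_rate_ul_min))     # /s
    y = outflow / inflow
    if y > 1.0:
        import warnings
        warnings.warn(f"injection yield {y:.3g} > 1 is unphysical; check "
                      "density calibration", stacklevel=2)
    return y


def predict_hit_ratio(areal_density_per_um2: float,
                      focus_fwhm_um: float) -> float:
    """Predicted fraction of X-ray pulses hitting at least one particle.

    Assumes the nominal focus area π (FWHM/2)² matches the region
    intense enough to produce measurable diffraction; hit ratio =
    areal density × focus area, reported capped at 1.
    """
    if areal_density_per_um2 < 0:
        raise AerotrackError("density must be non-negative")
    if focus_fwhm_um <= 0:
        raise AerotrackError("focus FWHM must be positive")
    ratio = areal_density_per_um2 * math.pi * (focus_fwhm_um / 2.0) ** 2
    return min(ratio, 1.0)
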