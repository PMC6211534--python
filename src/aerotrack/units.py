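"""Centralized unit conversions and width conventions.

Internally the physics code works in SI; instrument-facing values are
expressed in the units the lab uses (µm, mm, mbar, nm, µs, mJ).  Every
conversion lives here so that round-trip identities can be tested in one
place.
"""

from __future__ import annotations

import math

#: FWHM of a Gaussian divided by its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Molar gas constant, J/(mol K).
R_GAS: float = 8.314462618


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full width at half maximum to a Gaussian sigma."""
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    """Convert a Gaussian sigma to a full width at half maximum."""
    return sigma * FWHM_PER_SIGMA


def mbar_to_pa(p_mbar: float) -> float:
    return p_mbar * 100.0


def pa_to_mbar(p_pa: float) -> float:
    return p_pa / 100.0


def um_to_m(x_um: float) -> float:
    return x_um * 1e-6


def m_to_um(x_m: float) -> float:
    return x_m * 1e6


def mm_to_m(x_mm: float) -> float:
    return x_mm * 1e-3


def m_to_mm(x_m: float) -> float:
    return x_m * 1e3


def nm_to_m(x_nm: float) -> float:
    return x_nm * 1e-9


def m_to_nm(x_m: float) -> float:
    return x_m * 1e9


def us_to_s(t_us: float) -> float:
    return t_us * 1e-6


def s_to_us(t_s: float) -> float:
    return t_s * 1e6


def ml_to_um3(v_ml: float) -> float:
    """Millilitres to cubic micrometres (1 ml = 1e12 µm³)."""
    return v_ml * 1e12


def ul_per_min_to_um3_per_s(q_ul_min: float) -> float:
    """Microlitres per minute to cubic micrometres per second."""
    return q_ul_min * 1e9 / 60.0


def per_ml_to_per_um3(c_per_ml: float) -> float:
    """Number concentration per millilitre to per cubic micrometre."""
    return c_per_ml / 1e12
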