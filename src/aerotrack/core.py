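"""Shared domain types for the imaging pipeline.

The instrument records double-exposure frames of laser-illuminated
aerosol particles on their way from an aerodynamic-lens injector into
vacuum.  These containers carry pixel data together with the acquisition
metadata (laser pulses, injector distance, entrance pressure) that the
downstream analysis stages need.

Coordinate conventions
----------------------
Image coordinates are 0-based ``(row, col)`` with the origin at the
center of the top-left pixel.  The object-plane y axis is the particle
beam (vertical) axis and increases downstream, i.e. with increasing row;
the x axis increases with column.  A single configured scalar
(``pixel_scale_object_um``) maps pixels to object-plane micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


class AerotrackError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(AerotrackError):
    """Invalid instrument configuration or frame metadata."""


@dataclass(frozen=True)
class CameraModel:
    """Sensor geometry and photometric response of the sCMOS camera.

    Parameters
    ----------
    n_pixels_x, n_pixels_y : int
        Sensor dimensions in pixels (columns, rows).
    pixel_pitch_um : float
        Physical pixel pitch on the sensor, µm.
    quantum_efficiency : float
        Fraction of incident photons converted to signal, in (0, 1].
    saturation_level : float
        Full-well signal in photons; pixel values clip here.
    dark_noise_sigma : float
        RMS dark-noise fluctuation, photons/pixel.
    background_rate : float
        Mean stray-light background, photons per pixel and per mJ of
        laser pulse energy.
    pixel_scale_object_um : float
        Object-plane size of one pixel, µm/pixel, set by the microscope
        magnification.
    """

    n_pixels_x: int = 2048
    n_pixels_y: int = 2048
    pixel_pitch_um: float = 6.5
    quantum_efficiency: float = 0.8
    saturation_level: float = 30700.0
    dark_noise_sigma: float = 1.3
    background_rate: float = 0.12
    pixel_scale_object_um: float = 1.14

    def __post_init__(self) -> None:
        for name in ("n_pixels_x", "n_pixels_y", "pixel_pitch_um",
                     "saturation_level", "dark_noise_sigma",
                     "background_rate", "pixel_scale_object_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"CameraModel.{name} must be positive")
        if not 0.0 < self.quantum_efficiency <= 1.0:
            raise ConfigurationError("quantum_efficiency must be in (0, 1]")
        if self.saturation_level <= self.dark_noise_sigma:
            raise ConfigurationError(
                "saturation_level must exceed dark_noise_sigma")

    @property
    def shape(self) -> Tuple[int, int]:
        """Array shape ``(rows, cols)`` of a frame from this camera."""
        return (self.n_pixels_y, self.n_pixels_x)


@dataclass(frozen=True)
class LaserModel:
    """Illumination laser parameters.

    ``pulse_delay_us`` is the inter-pulse delay of the dual-flash mode;
    ``beam_axis_angle_deg`` is the angle between the laser axis and the
    microscope axis (recorded as metadata, no parallax correction is
    applied because the dominant, vertical velocity component is
    perpendicular to both axes).
    """

    wavelength_nm: float = 532.0
    pulse_energy_mj: float = 50.0
    pulse_delay_us: float = 0.5
    spot_fwhm_mm: float = 0.5
    beam_axis_angle_deg: float = 25.0

    def __post_init__(self) -> None:
        if self.spot_fwhm_mm <= 0:
            raise ConfigurationError("spot_fwhm_mm must be positive")
        if self.pulse_delay_us <= 0:
            raise ConfigurationError(
                "pulse_delay_us must be positive for dual-pulse mode")


@dataclass
class Frame:
    """One camera exposure plus its acquisition metadata."""

    pixels: np.ndarray
    camera: CameraModel
    laser: LaserModel
    injector_distance_mm: float = 0.0
    entrance_pressure_mbar: float = 0.0
    frame_id: str = ""

    def n_saturated(self) -> int:
        """Number of pixels at or above the camera saturation level."""
        return int(np.count_nonzero(self.pixels >= self.camera.saturation_level))


@dataclass
class Particle:
    """Ground-truth particle used by the synthetic-frame generator.

    ``position_um`` and ``velocity_m_s`` are 3-vectors (x, y, z) in the
    object frame; only x (transverse) and y (beam axis, downstream
    positive) are rendered.  A cluster of ``n_monomers`` droplets dried
    into one particle has diameter ``monomer × n^(1/3)`` by volume
    conservation.
    """

    diameter_nm: float
    position_um: Tuple[float, float, float]
    velocity_m_s: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    mass_density_kg_m3: float = 1050.0
    n_monomers: int = 1

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ConfigurationError("diameter_nm must be positive")
        if self.n_monomers < 1:
            raise ConfigurationError("n_monomers must be >= 1")


@dataclass
class PeakRecord:
    """A single detected spot."""

    centroid: Tuple[float, float]  # (row, col), pixels
    brightness: float = 0.0        # integrated photons
    n_pixels_above_threshold: int = 0
    saturated: bool = False
    ghost: bool = False
    proximity_excluded: bool = False
    partial: bool = False          # integration disk clipped by frame edge
    frame_id: str = ""

    @property
    def usable(self) -> bool:
        return not (self.ghost or self.proximity_excluded)


@dataclass
class TrackRecord:
    """A paired double-flash detection.

    ``displacement_um`` is the object-plane displacement vector
    (dx, dy); ``velocity_m_s`` its magnitude over the pulse delay.
    Unpaired detections have ``second_peak is None`` and velocity
    ``None``.
    """

    first_peak: PeakRecord
    second_peak: Optional[PeakRecord] = None
    displacement_um: Optional[Tuple[float, float]] = None
    velocity_m_s: Optional[float] = None
    diameter_estimate_nm: Optional[float] = None
    cluster_flag: bool = False

    @property
    def paired(self) -> bool:
        return self.second_peak is not None


def pixels_to_object_coords(
    centroid: Tuple[float, float],
    camera: CameraModel,
    reference: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[float, float]:
    """Map a pixel centroid to object-plane coordinates in µm.

    Parameters
    ----------
    centroid : (row, col)
        Pixel coordinates; must lie within the frame bounds.
    camera : CameraModel
        Supplies the object-plane pixel scale.
    reference : (row, col)
        Pixel that maps to the object-plane origin.

    Returns
    -------
    (x_um, y_um)
        x along columns, y along rows (downstream positive).
    """
    row, col = centroid
    if not (-0.5 <= row <= camera.n_pixels_y - 0.5
            and -0.5 <= col <= camera.n_pixels_x - 0.5):
        raise AerotrackError(f"centroid {centroid!r} outside frame bounds")
    s = camera.pixel_scale_object_um
    return ((col - reference[1]) * s, (row - reference[0]) * s)


def object_to_pixel_coords(
    position_um: Tuple[float, float],
    camera: CameraModel,
    reference: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[float, float]:
    """Inverse of :func:`pixels_to_object_coords` (no bounds check)."""
    x, y = position_um
    s = camera.pixel_scale_object_um
    return (y / s + reference[0], x / s + reference[1])


def validate_frame(frame: Frame) -> Frame:
    """Check a frame against its camera model.

    Verifies the pixel-array shape, non-negativity, and that no value
    exceeds the saturation level.  Nothing is clipped; the saturated
    pixel count is available via :meth:`Frame.n_saturated`.
    """
    if not isinstance(frame.pixels, np.ndarray) or frame.pixels.ndim != 2:
        raise ConfigurationError("frame.pixels must be a 2-D array")
    if frame.pixels.shape != frame.camera.shape:
        raise ConfigurationError(
            f"frame shape {frame.pixels.shape} does not match camera "
            f"{frame.camera.shape}")
    if np.any(frame.pixels < 0):
        raise ConfigurationError("frame contains negative pixel values")
    if np.any(frame.pixels > frame.camera.saturation_level):
        raise ConfigurationError(
            "frame contains pixel values above the saturation level")
    return frame
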