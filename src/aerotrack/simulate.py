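"""Synthetic double-exposure frame generator.

Forward model of the Rayleigh-scattering microscope: each particle
scatters ``k · d⁶ · pulse_energy · illumination`` photons per flash,
rendered as a pixel-integrated 2-D Gaussian point-spread function.  The
generator reproduces the instrument's photometric chain — Gaussian
illumination profile, Poisson stray-light background proportional to
the total pulse energy, Gaussian dark noise, sensor saturation, optional
back-reflection ghost spots and Poisson-occupancy particle clusters —
so that every downstream analysis stage can be validated against known
ground truth.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the scene, so identical seeds give bit-identical frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erf

from .core import (AerotrackError, CameraModel, ConfigurationError, Frame,
                   LaserModel, Particle, object_to_pixel_coords)
from .units import fwhm_to_sigma

#: Diameter (nm) above which the Rayleigh d⁶ scaling becomes inaccurate
#: for 532 nm illumination.
RAYLEIGH_LIMIT_NM = 200.0

#: Default calibration constant, photons/(nm⁶ mJ): chosen so a 40 nm
#: polystyrene sphere at full illumination scatters 157 photons per
#: 50 mJ pulse, matching the instrument's measured photometry.
DEFAULT_K = 157.0 / (40.0 ** 6 * 50.0)


@dataclass(frozen=True)
class IlluminationProfile:
    """Gaussian illumination of the object plane by the laser spot.

    Relative intensity is 1 at the center and 0.5 at one half-FWHM from
    the center.
    """

    fwhm_mm: float = 0.5
    center_um: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ConfigurationError("illumination fwhm_mm must be positive")

    def relative_intensity(self, position_um: Sequence[float]) -> float:
        """Relative illumination (0, 1] at an object-plane position."""
        x, y = position_um[0], position_um[1]
        cx, cy = self.center_um
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        fwhm_um = self.fwhm_mm * 1000.0
        return float(math.exp(-4.0 * math.log(2.0) * r2 / fwhm_um ** 2))


@dataclass
class SceneSpec:
    """Full description of one synthetic double-exposure scene."""

    particles: List[Particle] = field(default_factory=list)
    k: float = DEFAULT_K
    psf_sigma_px: float = 2.0
    pulse_energies_mj: Tuple[float, float] = (25.0, 25.0)
    pulse_delay_us: float = 0.5
    illumination: IlluminationProfile = field(default_factory=IlluminationProfile)
    ghost_offset_px: Optional[Tuple[float, float]] = None
    ghost_intensity_fraction: float = 0.1
    cluster_occupancy_mean: Optional[float] = None
    background: bool = True
    dark_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError("calibration constant k must be positive")
        if self.psf_sigma_px <= 0:
            raise ConfigurationError("psf_sigma_px must be positive")
        if not 0.0 <= self.ghost_intensity_fraction < 1.0:
            raise ConfigurationError(
                "ghost_intensity_fraction must be in [0, 1)")


def expected_spot_photons(
    d_p_nm: float,
    k: float = DEFAULT_K,
    pulse_energy_mj: float = 1.0,
    illumination: float = 1.0,
) -> float:
    """Expected integrated photon count of one particle in one flash.

    Rayleigh scattering: intensity scales with the sixth power of the
    particle diameter and linearly with pulse energy and local
    illumination.  Valid for diameters up to ~200 nm at 532 nm; a
    warning is issued above that.
    """
    if d_p_nm <= 0 or k <= 0 or pulse_energy_mj <= 0 or illumination <= 0:
        raise AerotrackError("expected_spot_photons requires positive inputs")
    if d_p_nm > RAYLEIGH_LIMIT_NM:
        warnings.warn(
            f"diameter {d_p_nm:g} nm exceeds the Rayleigh regime "
            f"(~{RAYLEIGH_LIMIT_NM:g} nm); d^6 scaling is approximate",
            stacklevel=2)
    return k * d_p_nm ** 6 * pulse_energy_mj * illumination


def _add_gaussian_spot(image: np.ndarray, row: float, col: float,
                       photons: float, sigma: float) -> None:
    """Add a pixel-integrated Gaussian spot in place.

    The per-pixel value is the separable product of erf differences, so
    the spot integral equals ``photons`` up to window truncation (the
    window spans ±6σ, keeping truncation below 1e-8).
    """
    ny, nx = image.shape
    half = int(math.ceil(6.0 * sigma))
    r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
    c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
    r0, r1 = max(r0, 0), min(r1, ny)
    c0, c1 = max(c0, 0), min(c1, nx)
    if r0 >= r1 or c0 >= c1:
        return
    denom = sigma * math.sqrt(2.0)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    wr = 0.5 * (erf((rows + 0.5 - row) / denom) - erf((rows - 0.5 - row) / denom))
    wc = 0.5 * (erf((cols + 0.5 - col) / denom) - erf((cols - 0.5 - col) / denom))
    image[r0:r1, c0:c1] += photons * np.outer(wr, wc)


def render_frame(
    scene: SceneSpec,
    camera: CameraModel,
    rng: Optional[np.random.Generator] = None,
    frame_id: str = "synthetic",
    injector_distance_mm: float = 0.0,
    entrance_pressure_mbar: float = 0.0,
) -> Tuple[Frame, pd.DataFrame]:
    """Render one double-exposure frame and its ground-truth table.

    Each particle is drawn once per flash at its position advanced by
    ``velocity × pulse_delay`` for the second flash, with brightness
    from :func:`expected_spot_photons` at the local illumination.
    Ghost spots (back-reflections) are added at a fixed pixel offset
    when their intensity would exceed the dark noise.  Background is
    Poisson with mean ``background_rate × total pulse energy``; dark
    noise is additive Gaussian.  The result is clipped to
    ``[0, saturation_level]``.

    Returns the frame and a DataFrame with one row per particle per
    flash (position, rendered photons, visibility flag).
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    ny, nx = camera.shape
    image = np.zeros((ny, nx), dtype=np.float64)
    sigma = scene.psf_sigma_px
    delay_s = scene.pulse_delay_us * 1e-6
    scale = camera.pixel_scale_object_um

    truth_rows = []
    for pid, p in enumerate(scene.particles):
        for flash, energy in enumerate(scene.pulse_energies_mj):
            dt = flash * delay_s
            x = p.position_um[0] + p.velocity_m_s[0] * dt * 1e6
            y = p.position_um[1] + p.velocity_m_s[1] * dt * 1e6
            row, col = object_to_pixel_coords((x, y), camera)
            illum = scene.illumination.relative_intensity((x, y))
            photons = expected_spot_photons(p.diameter_nm, scene.k,
                                            energy, illum)
            visible = (-0.5 <= row <= ny - 0.5) and (-0.5 <= col <= nx - 0.5)
            if visible:
                _add_gaussian_spot(image, row, col, photons, sigma)
                if (scene.ghost_offset_px is not None
                        and scene.ghost_intensity_fraction * photons
                        > camera.dark_noise_sigma):
                    _add_gaussian_spot(
                        image,
                        row + scene.ghost_offset_px[0],
                        col + scene.ghost_offset_px[1],
                        scene.ghost_intensity_fraction * photons, sigma)
            truth_rows.append(dict(
                particle_id=pid, flash=flash, x_um=x, y_um=y,
                row_px=row, col_px=col, diameter_nm=p.diameter_nm,
                n_monomers=p.n_monomers, photons=photons,
                speed_m_s=float(np.hypot(p.velocity_m_s[0],
                                         p.velocity_m_s[1])),
                visible=visible))

    total_energy = sum(scene.pulse_energies_mj)
    if scene.background and camera.background_rate * total_energy > 0:
        image += rng.poisson(camera.background_rate * total_energy,
                             size=image.shape)
    if scene.dark_noise and camera.dark_noise_sigma > 0:
        image += rng.normal(0.0, camera.dark_noise_sigma, size=image.shape)
    np.clip(image, 0.0, camera.saturation_level, out=image)

    laser = LaserModel(pulse_energy_mj=total_energy,
                       pulse_delay_us=scene.pulse_delay_us,
                       spot_fwhm_mm=scene.illumination.fwhm_mm)
    frame = Frame(pixels=image, camera=camera, laser=laser,
                  injector_distance_mm=injector_distance_mm,
                  entrance_pressure_mbar=entrance_pressure_mbar,
                  frame_id=frame_id)
    truth = pd.DataFrame(truth_rows, columns=[
        "particle_id", "flash", "x_um", "y_um", "row_px", "col_px",
        "diameter_nm", "n_monomers", "photons", "speed_m_s", "visible"])
    return frame, truth


def sample_cluster_sizes(
    n: int,
    occupancy_mean: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw monomer counts per dried droplet (zero-truncated Poisson).

    Droplets from the nebulizer contain a Poisson-distributed number of
    particles; empty droplets produce nothing, so observed clusters
    follow the zero-truncated distribution.  A cluster of n monomers
    has diameter ``monomer_diameter × n^(1/3)``.
    """
    if occupancy_mean <= 0:
        raise AerotrackError("occupancy_mean must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    p0 = math.exp(-occupancy_mean)
    u = rng.uniform(p0, 1.0, size=n)
    counts = stats.poisson.ppf(u, occupancy_mean).astype(int)
    return np.maximum(counts, 1)


def cluster_diameter(monomer_nm: float, n_monomers: np.ndarray | int) -> np.ndarray:
    """Diameter of an n-monomer cluster by volume conservation."""
    return monomer_nm * np.asarray(n_monomers, dtype=float) ** (1.0 / 3.0)


@dataclass(frozen=True)
class BeamScaling:
    """Power-law scaling of the particle-beam envelope with entrance
    pressure, used as the ground truth of pressure-scan simulations.

    At pressure p the Gaussian-beam parameters are
    ``w0 = w0_ref (p/p_ref)^waist_exponent`` (waist FWHM, µm),
    ``z0 = z0_ref (p/p_ref)^focus_exponent`` (focus distance, mm) and
    ``theta = theta_ref (p/p_ref)^divergence_exponent`` (far-field
    half-angle of the FWHM envelope, mrad).
    """

    w0_ref_um: float = 30.0
    z0_ref_mm: float = 2.5
    theta_ref_mrad: float = 15.0
    p_ref_mbar: float = 1.0
    waist_exponent: float = -1.5
    focus_exponent: float = -0.5
    divergence_exponent: float = -1.0

    def params_at(self, p_mbar: float) -> Tuple[float, float, float]:
        r = p_mbar / self.p_ref_mbar
        return (self.w0_ref_um * r ** self.waist_exponent,
                self.z0_ref_mm * r ** self.focus_exponent,
                self.theta_ref_mrad * r ** self.divergence_exponent)

    def width_at(self, p_mbar: float, z_mm: float) -> float:
        """FWHM (µm) of the beam at injector distance z under the
        Gaussian-beam envelope w(z) = w0 sqrt(1 + ((z-z0)/zR)^2)."""
        w0, z0, theta = self.params_at(p_mbar)
        z_r = w0 / (2.0 * theta)  # µm / mrad = mm
        return w0 * math.sqrt(1.0 + ((z_mm - z0) / z_r) ** 2)


def generate_pressure_scan(
    beam: BeamScaling,
    pressures_mbar: Sequence[float],
    distances_mm: Sequence[float],
    n_particles: int = 200,
    diameter_nm: float = 100.0,
    rho_p_kg_m3: float = 1050.0,
    speed_noise: float = 0.0,
    seed: int = 0,
    jet_model: bool = True,
    render: bool = False,
    camera: Optional[CameraModel] = None,
    scene_template: Optional[SceneSpec] = None,
) -> Tuple[pd.DataFrame, List[Tuple[Frame, pd.DataFrame]]]:
    """Simulate a pressure/distance scan of the particle beam.

    For every (pressure, distance) condition, transverse particle
    positions are drawn from a Gaussian whose FWHM follows the
    Gaussian-beam envelope of ``beam``, and axial speeds come from the
    free-jet drag model (or a constant 20 m/s when ``jet_model`` is
    False).  Returns a ground-truth DataFrame with columns
    ``pressure_mbar, distance_mm, x_um, speed_m_s, fwhm_true_um`` and,
    when ``render`` is set, one rendered frame per condition.
    """
    if len(pressures_mbar) == 0 or len(distances_mm) == 0:
        raise AerotrackError("pressure and distance lists must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    frames: List[Tuple[Frame, pd.DataFrame]] = []

    speed_cache = {}
    if jet_model:
        from . import jet as _jet
        gas = _jet.GasProperties.helium()
        geom = _jet.InjectorGeometry()

    for p in pressures_mbar:
        for z in distances_mm:
            fwhm = beam.width_at(p, z)
            sig = fwhm_to_sigma(fwhm)
            if jet_model:
                key = (p, z)
                if key not in speed_cache:
                    flow = _jet.FreeJetFlow(
                        stagnation_pressure_mbar=p, gas=gas, geometry=geom)
                    res = _jet.propagate_particle(
                        v0_m_s=1.0, d_p_nm=diameter_nm,
                        rho_p_kg_m3=rho_p_kg_m3, flow=flow,
                        x_end_mm=max(z, flow.x_start_mm * 1.01))
                    speed_cache[key] = float(res.v_m_s[-1])
                base_speed = speed_cache[key]
            else:
                base_speed = 20.0
            x = rng.normal(0.0, sig, size=n_particles)
            speeds = base_speed * (1.0 + speed_noise
                                   * rng.standard_normal(n_particles))
            for xi, vi in zip(x, speeds):
                rows.append(dict(pressure_mbar=p, distance_mm=z,
                                 x_um=float(xi), speed_m_s=float(vi),
                                 fwhm_true_um=fwhm))
            if render:
                if camera is None:
                    raise AerotrackError("render=True requires a camera")
                template = scene_template or SceneSpec()
                cx = camera.n_pixels_x / 2.0 * camera.pixel_scale_object_um
                cy = camera.n_pixels_y / 2.0 * camera.pixel_scale_object_um
                particles = [
                    Particle(diameter_nm=diameter_nm,
                             position_um=(cx + xi, cy, 0.0),
                             velocity_m_s=(0.0, vi, 0.0),
                             mass_density_kg_m3=rho_p_kg_m3)
                    for xi, vi in zip(x, speeds)]
                scene = replace(template, particles=particles,
                                seed=int(rng.integers(2 ** 31)))
                frames.append(render_frame(
                    scene, camera,
                    frame_id=f"p{p:g}_z{z:g}",
                    injector_distance_mm=z, entrance_pressure_mbar=p))

    truth = pd.DataFrame(rows)
    return truth, frames
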