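"""Spot detection and photometry on microscope frames.

Detection follows the difference-of-Gaussians scheme: the frame is
blurred with a small and a large Gaussian kernel, the difference image
is thresholded, each isolated cluster of supra-threshold pixels becomes
one candidate peak, and the peak position is the intensity-weighted
center of mass of the selected pixels.  Brightness is the sum of raw
pixel values within a 10-pixel radius of the centroid.  Two spurious
classes are flagged rather than silently dropped: back-reflection
ghosts (a faint duplicate at a constant image offset) and peaks closer
than 21 px to a neighbour, whose integration disks would overlap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import AerotrackError, CameraModel, Frame, PeakRecord


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection stage.

    ``threshold`` applies to the signed DoG image (positive lobes).
    ``min_separation`` uses a strict "closer than" rule: peaks at
    exactly the separation are kept.  Note 21 px < 2 × 10 px, so two
    kept peaks may still have marginally overlapping integration disks.
    """

    sigma_small: float = 3.0
    sigma_large: float = 6.0
    threshold: float = 1.0
    integration_radius: float = 10.0
    min_separation: float = 21.0
    connectivity: int = 1  # 1 = 4-connectivity, 2 = 8-connectivity
    ghost_offset_px: Optional[Tuple[float, float]] = None
    ghost_tolerance: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_small < self.sigma_large:
            raise AerotrackError("need 0 < sigma_small < sigma_large")
        if self.integration_radius <= 0:
            raise AerotrackError("integration_radius must be positive")
        if self.connectivity not in (1, 2):
            raise AerotrackError("connectivity must be 1 (4-conn) or 2 (8-conn)")


def dog_filter(image: np.ndarray, sigma_small: float,
               sigma_large: float) -> np.ndarray:
    """Difference of Gaussians: small-σ blur minus large-σ blur.

    Linear in the input and zero on constant images.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise AerotrackError("dog_filter expects a 2-D image")
    if not 0 < sigma_small < sigma_large:
        raise AerotrackError("need 0 < sigma_small < sigma_large")
    return (ndimage.gaussian_filter(image, sigma_small)
            - ndimage.gaussian_filter(image, sigma_large))


def find_peaks(dog_image: np.ndarray, threshold: float,
               connectivity: int = 1) -> List[np.ndarray]:
    """Cluster supra-threshold pixels into candidate peaks.

    Returns one ``(n_i, 2)`` array of (row, col) pixel indices per
    connected component of ``dog_image > threshold``.
    """
    if threshold <= 0:
        raise AerotrackError("threshold must be positive")
    mask = dog_image > threshold
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    clusters = []
    if n:
        # ndimage.value_indices groups pixel coordinates per label
        idx = ndimage.value_indices(labels, ignore_value=0)
        for lab in range(1, n + 1):
            rr, cc = idx[lab]
            clusters.append(np.column_stack([rr, cc]))
    return clusters


def centroid(cluster: np.ndarray, weights: np.ndarray) -> Tuple[float, float]:
    """Intensity-weighted center of mass of a pixel cluster."""
    cluster = np.asarray(cluster, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if cluster.size == 0:
        raise AerotrackError("empty cluster")
    total = weights.sum()
    if total <= 0:
        raise AerotrackError("cluster weights must sum to a positive value")
    r = float(np.dot(cluster[:, 0], weights) / total)
    c = float(np.dot(cluster[:, 1], weights) / total)
    return (r, c)


def integrate_brightness(
    raw: np.ndarray,
    center: Tuple[float, float],
    radius: float = 10.0,
    saturation_level: Optional[float] = None,
    background_annulus: Optional[Tuple[float, float]] = None,
) -> Tuple[float, bool, bool]:
    """Sum raw pixel values within ``radius`` of a centroid.

    Returns ``(brightness, partial, saturated)``: ``partial`` is set
    when the disk is clipped by the frame edge, ``saturated`` when any
    pixel inside the disk reaches ``saturation_level``.

    ``background_annulus=(r_in, r_out)`` optionally subtracts the
    median pixel value of the annulus, times the disk pixel count
    (off by default: the stray-light background is part of the
    calibrated photometry).
    """
    ny, nx = raw.shape
    row, col = center
    if not (-0.5 <= row <= ny - 0.5 and -0.5 <= col <= nx - 0.5):
        raise AerotrackError(f"centroid {center!r} outside frame")
    r_geom = radius if background_annulus is None else background_annulus[1]
    r0 = int(np.floor(row - r_geom))
    r1 = int(np.ceil(row + r_geom)) + 1
    c0 = int(np.floor(col - r_geom))
    c1 = int(np.ceil(col + r_geom)) + 1
    partial = (int(np.floor(row - radius)) < 0
               or int(np.floor(col - radius)) < 0
               or int(np.ceil(row + radius)) + 1 > ny
               or int(np.ceil(col + radius)) + 1 > nx)
    r0c, r1c = max(r0, 0), min(r1, ny)
    c0c, c1c = max(c0, 0), min(c1, nx)
    rr, cc = np.mgrid[r0c:r1c, c0c:c1c]
    dist2 = (rr - row) ** 2 + (cc - col) ** 2
    mask = dist2 <= radius ** 2
    window = raw[r0c:r1c, c0c:c1c]
    brightness = float(window[mask].sum())
    if background_annulus is not None:
        r_in, r_out = background_annulus
        ann = (dist2 > r_in ** 2) & (dist2 <= r_out ** 2)
        if np.any(ann):
            brightness -= float(np.median(window[ann])) * int(mask.sum())
    saturated = bool(saturation_level is not None
                     and np.any(window[mask] >= saturation_level))
    return brightness, partial, saturated


def filter_proximity(peaks: Sequence[PeakRecord],
                     min_separation: float = 21.0) -> List[PeakRecord]:
    """Flag every peak with a neighbour strictly closer than the
    minimum separation; exclusion is mutual."""
    pos = np.array([p.centroid for p in peaks], dtype=float)
    n = len(peaks)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(pos[i] - pos[j])))
            if d < min_separation:
                peaks[i].proximity_excluded = True
                peaks[j].proximity_excluded = True
    return list(peaks)


def estimate_ghost_offset(
    peaks_by_frame: Iterable[Sequence[PeakRecord]],
    max_offset: float = 50.0,
    min_pairs: int = 20,
) -> Tuple[float, float]:
    """Estimate the constant back-reflection offset across many frames.

    For every ordered bright→faint peak pair within ``max_offset``, the
    integer-rounded displacement is tallied; the modal displacement is
    the ghost offset.  Raises when fewer than ``min_pairs`` candidate
    pairs are available.
    """
    votes: Counter = Counter()
    n_pairs = 0
    for peaks in peaks_by_frame:
        for i, a in enumerate(peaks):
            for j, b in enumerate(peaks):
                if i == j or b.brightness >= a.brightness:
                    continue
                dr = b.centroid[0] - a.centroid[0]
                dc = b.centroid[1] - a.centroid[1]
                if abs(dr) <= max_offset and abs(dc) <= max_offset:
                    votes[(round(dr), round(dc))] += 1
                    n_pairs += 1
    if n_pairs < min_pairs:
        raise AerotrackError(
            f"ghost-offset estimation needs >= {min_pairs} candidate pairs, "
            f"got {n_pairs}")
    (dr, dc), _ = votes.most_common(1)[0]
    return (float(dr), float(dc))


def filter_ghosts(
    peaks: Sequence[PeakRecord],
    offset: Tuple[float, float],
    tolerance: float = 2.0,
) -> List[PeakRecord]:
    """Flag the fainter member of every peak pair whose displacement
    matches the ghost offset within tolerance.

    Equal-brightness ties are broken by flagging the member displaced
    along the offset direction (the putative reflection).
    """
    if len(peaks) == 0:
        raise AerotrackError("filter_ghosts requires at least one peak")
    off = np.asarray(offset, dtype=float)
    for i, a in enumerate(peaks):
        for j, b in enumerate(peaks):
            if i == j:
                continue
            disp = np.array(b.centroid) - np.array(a.centroid)
            if np.hypot(*(disp - off)) <= tolerance:
                if b.brightness < a.brightness:
                    b.ghost = True
                elif b.brightness == a.brightness:
                    b.ghost = True  # b sits at +offset from a
    return list(peaks)


def suggest_threshold(dog_image: np.ndarray, n_sigma: float = 5.0) -> float:
    """Suggest a detection threshold as μ + nσ of the DoG image.

    Meant to be evaluated on a particle-free region; with particles
    present it is biased high and remains conservative.
    """
    return float(dog_image.mean() + n_sigma * dog_image.std())


def detect_frame(frame: Frame, config: DetectionConfig) -> List[PeakRecord]:
    """Run the full detection chain on one frame.

    DoG filter → threshold clustering → DoG-weighted centroid → raw
    brightness integration → saturation, proximity and (if an offset is
    configured) ghost flagging.
    """
    dog = dog_filter(frame.pixels, config.sigma_small, config.sigma_large)
    clusters = find_peaks(dog, config.threshold, config.connectivity)
    peaks: List[PeakRecord] = []
    for cluster in clusters:
        w = dog[cluster[:, 0], cluster[:, 1]]
        cen = centroid(cluster, w)
        brightness, partial, saturated = integrate_brightness(
            frame.pixels, cen, config.integration_radius,
            saturation_level=frame.camera.saturation_level)
        peaks.append(PeakRecord(
            centroid=cen, brightness=brightness,
            n_pixels_above_threshold=len(cluster),
            saturated=saturated, partial=partial,
            frame_id=frame.frame_id))
    filter_proximity(peaks, config.min_separation)
    if config.ghost_offset_px is not None and peaks:
        filter_ghosts(peaks, config.ghost_offset_px, config.ghost_tolerance)
    return peaks
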