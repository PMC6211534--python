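"""Pair first- and second-flash detections and compute velocities.

A double-exposure frame contains two images of every moving particle.
Which image belongs to which flash is not recoverable from a single
exposure, so pairing relies on a flow-direction prior (the particle
beam points downstream, i.e. along increasing row) and a displacement
ceiling set by the laser-spot extent over the pulse delay.  Matching is
mutual-nearest-neighbour among admissible pairs; speeds are reported as
magnitudes with the direction given by the prior.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AerotrackError, CameraModel, PeakRecord, TrackRecord


def max_measurable_speed(spot_fwhm_mm: float, pulse_delay_us: float) -> float:
    """Velocity ceiling of the dual-flash geometry in m/s.

    The two images of one particle must both fall inside the laser
    spot, so the largest measurable displacement is the spot FWHM:
    e.g. a 0.5 mm spot over a 0.5 µs delay permits up to 1000 m/s.
    """
    if pulse_delay_us <= 0:
        raise AerotrackError("pulse_delay_us must be positive")
    return spot_fwhm_mm * 1e-3 / (pulse_delay_us * 1e-6)


def pair_flashes(
    peaks: Sequence[PeakRecord],
    camera: CameraModel,
    pulse_delay_us: float,
    max_speed_m_s: float = 1000.0,
    flow_direction: Tuple[float, float] = (1.0, 0.0),
    brightness_ratio_gate: Optional[float] = None,
) -> List[TrackRecord]:
    """Match double-flash peak pairs within one frame.

    Parameters
    ----------
    peaks : sequence of PeakRecord
        Should already be ghost/proximity filtered; flagged peaks are
        ignored.
    camera : CameraModel
        Supplies the pixel→µm scale.
    pulse_delay_us : float
        Inter-pulse delay.
    max_speed_m_s : float
        Gate on displacement magnitude (``max_speed × delay``).
    flow_direction : (row, col) unit vector
        Admissible displacements must have a positive component along
        this direction (default: downstream, increasing row).
    brightness_ratio_gate : float, optional
        When set, the two flash images must have a brightness ratio
        (brighter/fainter) at most this value to pair; off by default
        because unequal pulse energies produce unequal brightness.

    Returns
    -------
    list of TrackRecord
        One record per matched pair plus one unpaired record (velocity
        ``None``) per leftover peak.
    """
    if pulse_delay_us <= 0:
        raise AerotrackError("pulse_delay_us must be positive")
    usable = [p for p in peaks if p.usable]
    n = len(usable)
    scale = camera.pixel_scale_object_um
    max_disp_um = max_speed_m_s * pulse_delay_us  # m/s × µs = µm
    flow = np.asarray(flow_direction, dtype=float)
    flow = flow / np.linalg.norm(flow)

    pos = np.array([p.centroid for p in usable], dtype=float)
    # admissible displacement matrix: disp[i, j] = peak j relative to i
    best_fwd = np.full(n, -1, dtype=int)   # i -> nearest admissible j
    best_bwd = np.full(n, -1, dtype=int)   # j -> nearest admissible i
    dist_fwd = np.full(n, np.inf)
    dist_bwd = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            disp_px = pos[j] - pos[i]
            if float(disp_px @ flow) <= 0:
                continue
            d_um = float(np.hypot(*disp_px)) * scale
            if d_um > max_disp_um or d_um == 0.0:
                continue
            if brightness_ratio_gate is not None:
                b = sorted((usable[i].brightness, usable[j].brightness))
                if b[0] <= 0 or b[1] / b[0] > brightness_ratio_gate:
                    continue
            if d_um < dist_fwd[i]:
                dist_fwd[i], best_fwd[i] = d_um, j
            if d_um < dist_bwd[j]:
                dist_bwd[j], best_bwd[j] = d_um, i

    tracks: List[TrackRecord] = []
    matched = set()
    for i in range(n):
        j = best_fwd[i]
        if j >= 0 and best_bwd[j] == i and i not in matched and j not in matched:
            disp_px = pos[j] - pos[i]
            disp_um = (float(disp_px[1]) * scale, float(disp_px[0]) * scale)
            speed = float(np.hypot(*disp_um)) / pulse_delay_us  # µm/µs = m/s
            tracks.append(TrackRecord(
                first_peak=usable[i], second_peak=usable[j],
                displacement_um=disp_um, velocity_m_s=speed))
            matched.update((i, j))
    for i in range(n):
        if i not in matched:
            tracks.append(TrackRecord(first_peak=usable[i]))
    return tracks


def tracks_to_dataframe(tracks: Sequence[TrackRecord],
                        **metadata) -> pd.DataFrame:
    """Flatten TrackRecords into a tidy table (one row per record)."""
    rows = []
    for t in tracks:
        row = dict(
            row1=t.first_peak.centroid[0], col1=t.first_peak.centroid[1],
            brightness1=t.first_peak.brightness,
            saturated=t.first_peak.saturated,
            paired=t.paired,
            frame_id=t.first_peak.frame_id,
        )
        if t.paired:
            row.update(row2=t.second_peak.centroid[0],
                       col2=t.second_peak.centroid[1],
                       brightness2=t.second_peak.brightness,
                       dx_um=t.displacement_um[0],
                       dy_um=t.displacement_um[1],
                       velocity_m_s=t.velocity_m_s)
            row["saturated"] = t.first_peak.saturated or t.second_peak.saturated
        else:
            row.update(row2=np.nan, col2=np.nan, brightness2=np.nan,
                       dx_um=np.nan, dy_um=np.nan, velocity_m_s=np.nan)
        row["diameter_nm"] = (np.nan if t.diameter_estimate_nm is None
                              else t.diameter_estimate_nm)
        row["cluster_flag"] = t.cluster_flag
        row.update(metadata)
        rows.append(row)
    return pd.DataFrame(rows)


def speed_statistics(
    tracks: pd.DataFrame,
    by: Sequence[str] = ("injector_distance_mm", "entrance_pressure_mbar"),
) -> pd.DataFrame:
    """Mean, std and count of paired-track speeds per condition group.

    Groups without any paired track are dropped (with a warning via the
    empty result's absence); feeds the jet-model fitting stage.
    """
    keys = [k for k in by if k in tracks.columns]
    paired = tracks[tracks["velocity_m_s"].notna()]
    if paired.empty:
        raise AerotrackError("no paired tracks to summarize")
    if not keys:
        g = paired["velocity_m_s"]
        return pd.DataFrame([dict(mean_speed_m_s=g.mean(),
                                  std_speed_m_s=g.std(ddof=1) if len(g) > 1 else 0.0,
                                  n=len(g))])
    out = (paired.groupby(list(keys))["velocity_m_s"]
           .agg(mean_speed_m_s="mean",
                std_speed_m_s=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                n="count")
           .reset_index())
    return out
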