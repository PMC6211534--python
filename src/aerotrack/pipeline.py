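"""End-to-end orchestration: simulate → detect → track → size → beamfit.

The pipeline is deliberately thin: every stage is a library call, and
per-stage artifacts (frames, peak and track tables, fitted models) are
written to the output directory so a failed stage leaves partial
results behind for inspection.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import beam as beam_mod
from . import detect as detect_mod
from . import io as io_mod
from . import sizing as sizing_mod
from . import velocimetry as velo_mod
from .core import CameraModel, ConfigurationError, Particle
from .simulate import DEFAULT_K, IlluminationProfile, SceneSpec, render_frame

log = logging.getLogger("aerotrack")


def _build_scene_frames(cfg: Dict[str, Any], camera: CameraModel,
                        rng: np.random.Generator):
    sc = cfg.get("scene", {})
    n_frames = int(sc.get("n_frames", 10))
    n_particles = int(sc.get("n_particles", 5))
    diameter = float(sc.get("diameter_nm", 70.0))
    speed = float(sc.get("speed_m_s", 30.0))
    delay = float(sc.get("pulse_delay_us", 0.5))
    energies = tuple(sc.get("pulse_energies_mj", (25.0, 25.0)))
    beam_sigma_um = float(sc.get("beam_sigma_um",
                                 camera.n_pixels_x
                                 * camera.pixel_scale_object_um / 12.0))
    k = float(sc.get("k", DEFAULT_K))
    fov_x = camera.n_pixels_x * camera.pixel_scale_object_um
    fov_y = camera.n_pixels_y * camera.pixel_scale_object_um
    illum = IlluminationProfile(center_um=(fov_x / 2.0, fov_y / 2.0))
    frames, truths = [], []
    for i in range(n_frames):
        particles = []
        for _ in range(n_particles):
            x = fov_x / 2.0 + rng.normal(0.0, beam_sigma_um)
            y = rng.uniform(0.15, 0.75) * fov_y
            particles.append(Particle(
                diameter_nm=diameter, position_um=(x, y, 0.0),
                velocity_m_s=(0.0, speed, 0.0)))
        scene = SceneSpec(particles=particles, k=k,
                          pulse_energies_mj=energies, pulse_delay_us=delay,
                          illumination=illum,
                          seed=int(rng.integers(2 ** 31)))
        frame, truth = render_frame(scene, camera, frame_id=f"frame{i:04d}")
        frames.append(frame)
        truth["frame_id"] = frame.frame_id
        truths.append(truth)
    return frames, pd.concat(truths, ignore_index=True), illum, k, delay


def run_pipeline(config: Dict[str, Any], out_dir: str | Path,
                 seed: int = 0) -> Dict[str, Any]:
    """Run the simulation-backed pipeline and write per-stage artifacts.

    Returns a report dict with per-stage counts; deterministic for a
    fixed seed and config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    report: Dict[str, Any] = {"seed": seed, "stages": {}}

    camera = io_mod.camera_from_config(config)
    sc = config.get("scene", {})
    if "pulse_delay_us" in config.get("tracking", {}):
        pass
    t0 = time.perf_counter()
    frames, truth, illum, k, delay = _build_scene_frames(config, camera, rng)
    io_mod.write_frames(out / "frames.tiff", frames)
    truth.to_csv(out / "truth.csv", index=False)
    report["stages"]["simulate"] = {
        "n_frames": len(frames), "n_truth_rows": len(truth),
        "seconds": round(time.perf_counter() - t0, 3)}
    log.info("simulate: %d frames", len(frames))

    t0 = time.perf_counter()
    det_cfg = detect_mod.DetectionConfig(**config.get("detection", {}))
    peaks_by_frame = {f.frame_id: detect_mod.detect_frame(f, det_cfg)
                      for f in frames}
    peaks_df = io_mod.peaks_to_dataframe(peaks_by_frame)
    peaks_df.to_csv(out / "peaks.csv", index=False)
    n_peaks = sum(len(v) for v in peaks_by_frame.values())
    report["stages"]["detect"] = {
        "n_peaks": n_peaks,
        "n_excluded": int(peaks_df["proximity_excluded"].sum()
                          + peaks_df["ghost"].sum()) if n_peaks else 0,
        "seconds": round(time.perf_counter() - t0, 3)}
    log.info("detect: %d peaks", n_peaks)

    t0 = time.perf_counter()
    trk = config.get("tracking", {})
    if "pulse_delay_us" in trk:
        delay = float(trk["pulse_delay_us"])
    if delay is None or delay <= 0:
        raise ConfigurationError("tracking requires a positive pulse delay")
    all_tracks = []
    for f in frames:
        tracks = velo_mod.pair_flashes(
            peaks_by_frame[f.frame_id], camera, delay,
            max_speed_m_s=float(trk.get("max_speed_m_s", 1000.0)))
        df = velo_mod.tracks_to_dataframe(
            tracks, injector_distance_mm=f.injector_distance_mm,
            entrance_pressure_mbar=f.entrance_pressure_mbar)
        all_tracks.append(df)
    tracks_df = pd.concat(all_tracks, ignore_index=True)
    report["stages"]["track"] = {
        "n_tracks": int(tracks_df["paired"].sum()),
        "n_unpaired": int((~tracks_df["paired"]).sum()),
        "seconds": round(time.perf_counter() - t0, 3)}
    log.info("track: %d paired", int(tracks_df["paired"].sum()))

    t0 = time.perf_counter()
    sz = config.get("sizing", {})
    cal = sizing_mod.RayleighCalibration(
        k=float(sz.get("k", k)),
        sizing_window_nm=tuple(sz.get("sizing_window_nm", (40.0, 125.0))))
    energy_per_flash = sum(sc.get("pulse_energies_mj", (25.0, 25.0))) / 2.0
    diameters = []
    for _, r in tracks_df.iterrows():
        pos = ((r["col1"]) * camera.pixel_scale_object_um,
               (r["row1"]) * camera.pixel_scale_object_um)
        norm = sizing_mod.correct_illumination(
            r["brightness1"], pos, illum, energy_per_flash)
        d = sizing_mod.estimate_diameter(norm, cal,
                                         saturated=bool(r["saturated"]))
        diameters.append(np.nan if d is None else d)
    tracks_df["diameter_nm"] = diameters
    sized = np.asarray(diameters, dtype=float)
    if np.isfinite(sized).any():
        flags = sizing_mod.flag_clusters(sized)
        tracks_df["cluster_flag"] = flags
    tracks_df.to_csv(out / "tracks.csv", index=False)
    report["stages"]["size"] = {
        "n_sized": int(np.isfinite(sized).sum()),
        "n_clusters": int(tracks_df["cluster_flag"].sum()),
        "seconds": round(time.perf_counter() - t0, 3)}

    t0 = time.perf_counter()
    paired = tracks_df[tracks_df["paired"]]
    beam_report: Dict[str, Any] = {}
    x_um = paired["col1"].to_numpy() * camera.pixel_scale_object_um
    if x_um.size >= 50:
        prof = beam_mod.transverse_profile(x_um)
        beam_report["profile_fwhm_um"] = prof.fwhm_um
        beam_report["profile_center_um"] = prof.center_um
    if paired["velocity_m_s"].notna().any():
        beam_report["mean_speed_m_s"] = float(paired["velocity_m_s"].mean())
    io_mod.write_model_json(out / "beam.json", beam_report)
    report["stages"]["beamfit"] = {
        **beam_report, "seconds": round(time.perf_counter() - t0, 3)}

    io_mod.write_model_json(out / "report.json", report)
    return report
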