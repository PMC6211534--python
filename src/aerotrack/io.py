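"""Reading and writing the pipeline's on-disk formats.

Frames travel as 16-bit grayscale TIFF (multi-page stacks allowed),
particle and track tables as headered CSV, fitted models as JSON and
configuration as YAML.  Frame metadata that TIFF does not carry
(pulse energies, delay, injector distance, pressure) lives in the
config/dataset YAML and is re-attached on load.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CameraModel, ConfigurationError, Frame, LaserModel


def load_config(path: str | Path) -> Dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    return cfg


def camera_from_config(cfg: Dict[str, Any]) -> CameraModel:
    return CameraModel(**cfg.get("camera", {}))


def laser_from_config(cfg: Dict[str, Any]) -> LaserModel:
    return LaserModel(**cfg.get("laser", {}))


def write_frames(path: str | Path, frames: Sequence[Frame]) -> None:
    """Write frames as a multi-page 16-bit TIFF stack.

    Photon values are rounded; the camera saturation level is assumed
    to fit in uint16 (it does for the default 30 700).
    """
    stack = np.stack([np.clip(np.rint(f.pixels), 0, 65535).astype(np.uint16)
                      for f in frames])
    tifffile.imwrite(str(path), stack)


def read_frames(
    path: str | Path,
    camera: CameraModel,
    laser: Optional[LaserModel] = None,
    injector_distance_mm: float = 0.0,
    entrance_pressure_mbar: float = 0.0,
) -> List[Frame]:
    """Read a TIFF stack and attach acquisition metadata."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    laser = laser or LaserModel()
    frames = []
    for i, page in enumerate(data):
        frames.append(Frame(
            pixels=page.astype(np.float64), camera=camera, laser=laser,
            injector_distance_mm=injector_distance_mm,
            entrance_pressure_mbar=entrance_pressure_mbar,
            frame_id=f"{Path(path).stem}[{i}]"))
    return frames


def peaks_to_dataframe(peaks_by_frame: Dict[str, Sequence]) -> pd.DataFrame:
    rows = []
    for frame_id, peaks in peaks_by_frame.items():
        for p in peaks:
            rows.append(dict(
                frame_id=frame_id, row=p.centroid[0], col=p.centroid[1],
                brightness=p.brightness,
                n_pixels=p.n_pixels_above_threshold,
                saturated=p.saturated, ghost=p.ghost,
                proximity_excluded=p.proximity_excluded, partial=p.partial))
    return pd.DataFrame(rows, columns=[
        "frame_id", "row", "col", "brightness", "n_pixels", "saturated",
        "ghost", "proximity_excluded", "partial"])


def dataframe_to_peaks(df: pd.DataFrame) -> Dict[str, List]:
    from .core import PeakRecord
    out: Dict[str, List] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["frame_id"]), []).append(PeakRecord(
            centroid=(float(r["row"]), float(r["col"])),
            brightness=float(r["brightness"]),
            n_pixels_above_threshold=int(r["n_pixels"]),
            saturated=bool(r["saturated"]), ghost=bool(r["ghost"]),
            proximity_excluded=bool(r["proximity_excluded"]),
            partial=bool(r.get("partial", False)),
            frame_id=str(r["frame_id"])))
    return out


class _ModelEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            d = dataclasses.asdict(o)
            d.pop("model", None)  # callables are not serializable
            return d
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_model_json(path: str | Path, payload: Any) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, cls=_ModelEncoder, indent=2)


def read_model_json(path: str | Path) -> Any:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
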