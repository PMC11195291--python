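"""Reading and writing movies, time courses and fit tables.

Stimulus movies are stored as 4-D NIfTI (X x Y x 1 x T) with the degree
calibration and frame duration in the header zooms, plus a JSON sidecar
carrying the same metadata losslessly.  Time-course matrices go to 2-D NIfTI
(units x T) or TSV (time x units); fit tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from logprf.stimulus import FieldGrid, StimulusMovie

__all__ = [
    "save_movie",
    "load_movie",
    "save_timecourses",
    "load_timecourses",
    "save_fits",
    "load_fits",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_movie(movie: StimulusMovie, path: str | Path) -> Path:
    """Write a movie as X x Y x 1 x T NIfTI plus a JSON sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(movie.frames[:, :, None, :])
    affine = np.diag([movie.grid.deg_per_px, movie.grid.deg_per_px, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((movie.grid.deg_per_px, movie.grid.deg_per_px, 1.0,
                          movie.frame_duration_s))
    img.header.set_xyzt_units("unknown", "sec")
    nib.save(img, str(path))
    sidecar = {
        "deg_per_px": movie.grid.deg_per_px,
        "frame_duration_s": movie.frame_duration_s,
        "label": movie.label,
        "height_px": movie.grid.height_px,
        "width_px": movie.grid.width_px,
        "axes": "height x width x 1 x time",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_movie(path: str | Path) -> StimulusMovie:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError(f"expected X x Y x 1 x T movie, got shape {data.shape}")
    frames = data[:, :, 0, :]
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        meta = json.loads(sidecar_file.read_text())
        deg_per_px = float(meta["deg_per_px"])
        frame_duration = float(meta["frame_duration_s"])
        label = meta.get("label", "fixed")
    else:
        zooms = img.header.get_zooms()
        deg_per_px = float(zooms[0])
        frame_duration = float(zooms[3])
        label = "fixed"
    if np.all(np.isin(np.unique(frames), (0, 1))):
        frames = frames.astype(np.uint8)
    grid = FieldGrid(width_px=frames.shape[1], height_px=frames.shape[0],
                     deg_per_px=deg_per_px)
    return StimulusMovie(frames=frames, grid=grid,
                         frame_duration_s=frame_duration, label=label)


def save_timecourses(data: np.ndarray, dt: float, path: str | Path) -> Path:
    """Write a (units, T) matrix: TSV holds time x units, NIfTI units x T."""
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if path.suffix == ".tsv":
        frame = pd.DataFrame(
            data.T, columns=[f"unit_{i}" for i in range(data.shape[0])]
        )
        frame.insert(0, "time_s", np.arange(data.shape[1]) * dt)
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        img = nib.Nifti1Image(data.astype(np.float32), np.eye(4))
        img.header.set_zooms((1.0, dt))
        nib.save(img, str(path))
        _sidecar_path(path).write_text(json.dumps({"dt_s": dt}))
    return path


def load_timecourses(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a time-course matrix; returns ((units, T) array, dt seconds)."""
    path = Path(path)
    if path.suffix == ".tsv":
        frame = pd.read_csv(path, sep="\t")
        if "time_s" in frame.columns:
            t = frame.pop("time_s").to_numpy()
            dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        else:
            dt = 1.0
        return frame.to_numpy().T, dt
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        dt = float(json.loads(sidecar_file.read_text())["dt_s"])
    else:
        zooms = img.header.get_zooms()
        dt = float(zooms[1]) if len(zooms) > 1 else 1.0
    return np.atleast_2d(data), dt


def save_fits(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def load_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
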