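"""Reading and writing of movies, Doppler series, maps and tables.

Movies and Doppler series go to HDF5 (complex data) with their acquisition
metadata as attributes; 2-D maps to float TIFF; traces, epochs, bootstrap
curves and animal tables to CSV; ground truth and reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .doppler import DopplerSeries
from .synthetic import CompoundMovie

__all__ = [
    "save_movie", "load_movie", "save_doppler", "load_doppler",
    "save_map_tiff", "save_trace_csv", "save_json",
]


def save_movie(path: str | Path, movie: CompoundMovie, **metadata) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=movie.frames, compression="gzip")
        d.attrs["frame_rate"] = movie.frame_rate
        d.attrs["pixel_pitch"] = movie.pixel_pitch
        d.attrs["t0"] = movie.t0
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata, default=_jsonable)


def load_movie(path: str | Path) -> CompoundMovie:
    with h5py.File(path, "r") as f:
        d = f["frames"]
        return CompoundMovie(
            frames=d[...],
            frame_rate=float(d.attrs["frame_rate"]),
            pixel_pitch=float(d.attrs["pixel_pitch"]),
            t0=float(d.attrs["t0"]),
        )


def save_doppler(path: str | Path, series: DopplerSeries, **metadata) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("images", data=series.images, compression="gzip")
        f.create_dataset("timestamps", data=series.timestamps)
        for k in ("block_size", "n_removed", "rate", "pixel_pitch"):
            d.attrs[k] = getattr(series, k)
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata, default=_jsonable)


def load_doppler(path: str | Path) -> DopplerSeries:
    with h5py.File(path, "r") as f:
        d = f["images"]
        return DopplerSeries(
            images=d[...],
            timestamps=f["timestamps"][...],
            block_size=int(d.attrs["block_size"]),
            n_removed=int(d.attrs["n_removed"]),
            rate=float(d.attrs["rate"]),
            pixel_pitch=float(d.attrs["pixel_pitch"]),
        )


def save_map_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, np.float32))


def save_trace_csv(path: str | Path, times: np.ndarray,
                   values: np.ndarray, value_name: str = "value") -> None:
    pd.DataFrame({"time_s": times, value_name: values}).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))
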