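"""Reading and writing movies and tables in the package's on-disk formats.

Movies travel as multi-frame TIFF with a YAML sidecar holding the
acquisition metadata (frame rate, um/px, stimulus window); all tables are
CSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import Movie

__all__ = ["write_movie", "read_movie", "write_table", "read_table"]


def write_movie(path, movie: Movie, extra_meta: dict | None = None) -> None:
    """Write a multi-frame TIFF plus a ``<path>.yaml`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float32))
    meta = {
        "frame_rate_hz": float(movie.frame_rate),
        "px_size_um": float(movie.px_size),
        "n_frames": int(movie.n_frames),
        "stimulus_frames": [9, 16],
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_movie(path) -> Movie:
    """Read a multi-frame TIFF and its YAML sidecar back into a Movie."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    frame_rate, px_size = 4.0, 4.0
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        frame_rate = float(meta.get("frame_rate_hz", frame_rate))
        px_size = float(meta.get("px_size_um", px_size))
    return Movie(data=np.asarray(data, dtype=float), frame_rate=frame_rate, px_size=px_size)


def write_table(path, table: pd.DataFrame, index: bool = False) -> None:
    table.to_csv(path, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)
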