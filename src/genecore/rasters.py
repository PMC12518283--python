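"""Minimal ESRI ASCII grid I/O.

One variable per file; header keys ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value followed by whitespace-separated rows, top row first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_esri_ascii(
    grid: np.ndarray,
    path: str | Path,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
) -> None:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be two-dimensional")
    out = grid.copy()
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {float(xllcorner)!r}\n"
        f"yllcorner {float(yllcorner)!r}\n"
        f"cellsize {float(cellsize)!r}\n"
        f"NODATA_value {float(nodata)!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Returns (grid with NaN at nodata cells, header metadata dict)."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        }:
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in meta or "nrows" not in meta:
        raise ValueError(f"{path}: missing ncols/nrows header")
    values = np.array(" ".join(lines[i:]).split(), dtype=float)
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    if values.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} cells, found {values.size}")
    grid = values.reshape(nrows, ncols)
    nodata = meta.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid, meta
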