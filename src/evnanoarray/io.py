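"""File formats: height maps (ASCII grid, float TIFF) and the CSV tables.

Two height-map dialects are supported:

* ``ascii_grid`` — ``#``-prefixed header lines (``rows``, ``cols``,
  ``pixel_size_nm``, ``units=nm``) followed by whitespace-separated rows
  of heights; lossless at >= 6 significant digits.
* ``float_tiff`` — 32-bit float TIFF in nm with a JSON sidecar
  (``<path>.json``) carrying ``pixel_size_nm``, ``rows``, ``cols`` and
  any extra metadata (seed, render config).

Proprietary instrument formats (JPK, Bruker) are out of scope; convert
to one of these dialects first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import HeightMap

__all__ = [
    "read_height_map",
    "write_height_map",
    "write_layout_csv",
    "read_layout_csv",
    "write_truth_csv",
    "write_particle_csv",
    "read_particle_csv",
]

_REQUIRED_HEADER = ("rows", "cols", "pixel_size_nm", "units")

PARTICLE_COLUMNS = [
    "particle_id", "x_nm", "y_nm", "major_nm", "minor_nm", "d_nm", "h_nm",
    "ar", "D_nm", "class", "spot_id", "border_flag",
]


def _read_ascii(path: Path) -> HeightMap:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty height-map file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
            elif "=" in body:
                key, _, val = body.partition("=")
            else:
                continue
            header[key.strip()] = val.strip()
        else:
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}: unparsable data on line {lineno}") from exc
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise ValueError(f"{path}: header missing required field '{key}'")
    if header["units"] != "nm":
        raise ValueError(f"{path}: unsupported units '{header['units']}' (expected nm)")
    nrow, ncol = int(header["rows"]), int(header["cols"])
    if len(rows) != nrow:
        raise ValueError(f"{path}: header declares {nrow} rows, found {len(rows)}")
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise ValueError(f"{path}: row {i} has {len(row)} values, expected {ncol}")
    meta = {k: v for k, v in header.items() if k not in _REQUIRED_HEADER}
    return HeightMap(np.array(rows, dtype=float), float(header["pixel_size_nm"]), meta)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_tiff(path: Path) -> HeightMap:
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: missing JSON sidecar with pixel_size_nm ({sidecar})")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_nm" not in meta:
        raise ValueError(f"{sidecar}: sidecar lacks pixel_size_nm")
    pixel = float(meta.pop("pixel_size_nm"))
    meta.pop("rows", None), meta.pop("cols", None)
    return HeightMap(np.asarray(data, dtype=float), pixel, meta)


def read_height_map(path: str | Path, format: str | None = None) -> HeightMap:
    """Read a height map; ``format`` is ``ascii_grid``/``float_tiff`` or
    inferred from the suffix (.tif/.tiff -> TIFF, else ASCII)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "float_tiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if format == "ascii_grid":
        return _read_ascii(path)
    if format == "float_tiff":
        return _read_tiff(path)
    raise ValueError(f"unknown height-map format '{format}'")


def write_height_map(hmap: HeightMap, path: str | Path, format: str | None = None) -> Path:
    """Write a height map in the chosen dialect; returns the path."""
    path = Path(path)
    if format is None:
        format = "float_tiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if format == "ascii_grid":
        nrow, ncol = hmap.shape
        lines = [
            f"# rows: {nrow}",
            f"# cols: {ncol}",
            f"# pixel_size_nm: {hmap.pixel_size_nm:.9g}",
            "# units: nm",
        ]
        lines += [f"# {k}: {v}" for k, v in sorted(hmap.metadata.items())]
        body = "\n".join(" ".join(f"{v:.9g}" for v in row) for row in hmap.heights)
        path.write_text("\n".join(lines) + "\n" + body + "\n")
    elif format == "float_tiff":
        tifffile.imwrite(path, hmap.heights.astype(np.float32))
        sidecar = {
            "pixel_size_nm": hmap.pixel_size_nm,
            "rows": hmap.shape[0],
            "cols": hmap.shape[1],
        }
        sidecar.update(hmap.metadata)
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True, default=str))
    else:
        raise ValueError(f"unknown height-map format '{format}'")
    return path


# ---------------------------------------------------------------------------
# CSV tables

def write_layout_csv(layout, path: str | Path) -> Path:
    path = Path(path)
    layout.to_frame().to_csv(path, index=False)
    return path


def read_layout_csv(path: str | Path):
    from .synthetic import NanospotLayout

    return NanospotLayout.from_frame(pd.read_csv(path, comment="#"))


def write_truth_csv(truth, path: str | Path) -> Path:
    path = Path(path)
    truth.particles_frame().to_csv(path, index=False)
    return path


def write_particle_csv(particles, path: str | Path, header_comment: str | None = None) -> Path:
    """Write the detected-particle table (one row per particle)."""
    from .detect import particles_to_frame

    path = Path(path)
    frame = particles_to_frame(particles)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
    return path


def read_particle_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in PARTICLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: particle table missing columns {missing}")
    return frame
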