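"""File formats: PGM/PNG stimuli with JSON sidecars, raster CSV, configs.

Images are stored as ordinary greyscale files (0 = black, 255 = white, or
maxval-1 PGM with 0/1) plus a ``<name>.json`` sidecar carrying the inner
size ``n``, margin ``m``, polarity tag and label, so a written stimulus
round-trips to an equal in-memory value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .izhikevich import SpikeRaster
from .network import NetworkConfig
from .stimuli import BinaryImage

__all__ = [
    "load_config",
    "raster_frame",
    "read_image",
    "save_config",
    "write_image",
    "write_rasters_csv",
]


def _sidecar_path(path: Union[str, Path]) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_image(img: BinaryImage, path: Union[str, Path], ascii_pgm: bool = False) -> None:
    """Write a stimulus as PGM or PNG (by extension) plus a JSON sidecar.

    ``ascii_pgm=True`` writes plain-text P2 instead of binary P5 (PGM only).
    """
    path = Path(path)
    arr = (img.pixels * 255).astype(np.uint8)
    if ascii_pgm:
        if path.suffix.lower() not in (".pgm", ".pnm"):
            raise ValueError("ascii_pgm applies to .pgm output only")
        lines = [f"P2\n{arr.shape[1]} {arr.shape[0]}\n255\n"]
        lines += [" ".join(str(v) for v in row) + "\n" for row in arr]
        path.write_text("".join(lines))
    else:
        Image.fromarray(arr, mode="L").save(path)
    meta = {
        "n": img.n,
        "m": img.m,
        "polarity_tag": img.polarity_tag,
        "label": img.label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_image(
    path: Union[str, Path], n: Optional[int] = None, m: Optional[int] = None
) -> BinaryImage:
    """Read a PGM (P2/P5) or PNG stimulus; any nonzero pixel is white.

    Geometry comes from the sidecar when present, else from ``n``/``m``
    arguments, else the whole array is treated as margin-free (``m = 0``).
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: stimulus must be a square 2-D image, got {arr.shape}")
    pixels = (arr > 0).astype(np.uint8)
    N = pixels.shape[0]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    n = n if n is not None else meta.get("n")
    m = m if m is not None else meta.get("m")
    if n is None and m is None:
        n, m = N, 0
    elif n is None:
        n = N - 2 * int(m)
    elif m is None:
        m = (N - int(n)) // 2
    if int(n) + 2 * int(m) != N:
        raise ValueError(
            f"{path}: inconsistent geometry (N={N}, n={n}, m={m}; need N = n + 2m)"
        )
    return BinaryImage(
        pixels,
        int(n),
        int(m),
        polarity_tag=meta.get("polarity_tag", "framed-on-black"),
        label=meta.get("label", path.stem),
    )


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def raster_frame(rasters: dict) -> pd.DataFrame:
    """Flatten a run's rasters to a table: one row per spike.

    Columns: area, channel_F, subchannel_j, cell_i, row, col, time_ms.
    """
    rows = []
    for key, raster in sorted(rasters.items(), key=lambda kv: str(kv[0])):
        if isinstance(key, tuple) and key[0] in ("area1", "area2"):
            area, F, j = key[0], key[1], ""
        elif isinstance(key, tuple) and key[0] == "area3":
            area, F, j = key[0], key[1], key[2]
        else:
            area, F, j = key, "", ""
        steps, *grid = np.nonzero(raster.spikes)
        t = (steps + 1) * raster.dt
        if area == "area4":
            for k in range(len(steps)):
                rows.append((area, grid[0][k] + 1, grid[1][k] + 1, "", "", "", t[k]))
        elif area == "area5":
            for k in range(len(steps)):
                rows.append((area, "", "", grid[0][k] + 1, "", "", t[k]))
        else:
            for k in range(len(steps)):
                rows.append((area, F, j, "", grid[0][k], grid[1][k], t[k]))
    return pd.DataFrame(
        rows, columns=["area", "channel_F", "subchannel_j", "cell_i", "row", "col", "time_ms"]
    )


def write_rasters_csv(rasters: dict, path: Union[str, Path]) -> None:
    raster_frame(rasters).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: Optional[Union[str, Path]]) -> NetworkConfig:
    """Load a JSON config; missing fields take the shipped defaults.

    An empty file (or ``None``) yields the full default configuration.
    Unknown keys and invariant violations raise with the offending fields.
    """
    if path is None:
        return NetworkConfig()
    text = Path(path).read_text().strip()
    if not text:
        return NetworkConfig()
    return NetworkConfig.from_dict(json.loads(text))


def save_config(config: NetworkConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
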