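"""Image and table IO for the profiling pipeline.

TIFF is the image interchange format (multi-page = one page per channel);
PNG is accepted for binary masks. Feature tables are tidy CSV, one row per
cell and channel, with a comment header recording units and the
configuration hash so outputs are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.io import imread as _png_read

from .synthgen import CHANNELS, NucleusImage

__all__ = ["read_image", "read_mask", "write_heatmap", "write_feature_table",
           "read_feature_table", "config_hash"]


def read_image(path: str | Path, channel_names: tuple[str, ...] = CHANNELS,
               pixel_pitch_nm: float = 50.0) -> NucleusImage:
    """Read a multi-channel TIFF into a NucleusImage (mask initially full).

    Accepts a multi-page TIFF (page per channel) or a single-page 2D image
    (mapped to the first declared channel). 8/16-bit and float data are
    promoted to float64. A ``<name>.mask.tif`` sidecar, when present, is
    loaded as the nucleus mask; otherwise the mask is all-true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D or (C, H, W) TIFF, "
                         f"got shape {arr.shape}")
    if arr.shape[0] > len(channel_names):
        raise ValueError(f"{path}: {arr.shape[0]} pages but only "
                         f"{len(channel_names)} channel names declared")
    channels = {name: arr[i].astype(np.float64)
                for i, name in enumerate(channel_names[:arr.shape[0]])}
    mask_path = path.with_suffix(".mask.tif")
    if mask_path.exists():
        mask = read_mask(mask_path)
    else:
        mask = np.ones(arr.shape[1:], dtype=bool)
    return NucleusImage(channels=channels, mask=mask,
                        pixel_pitch_nm=pixel_pitch_nm,
                        meta={"source": str(path)})


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from TIFF or PNG; {0, 255} normalizes to {0, 1}."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(_png_read(path))
    else:
        arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def write_heatmap(scores: np.ndarray, path: str | Path) -> None:
    """Store a Score-CAM heatmap as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), scores.astype(np.float32))


def config_hash(config) -> str:
    """Short stable hash of a (nested dataclass / dict) configuration."""
    try:
        import dataclasses
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
    except TypeError:
        pass
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


UNITS_HEADER = ("# units: distances px, areas px^2, intensities image units, "
                "densities puncta per 250 px^2")


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        cfg_hash: str = "") -> None:
    """Write a tidy per-cell feature CSV with a units/config comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(UNITS_HEADER + "\n")
        fh.write(f"# config_hash: {cfg_hash}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
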