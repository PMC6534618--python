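"""File formats: multi-page TIFF + PNG masks + JSON sidecars, CSV tables.

Images are stored as float32 multi-page TIFF with one page per channel in
the order recorded in the sidecar; masks are PNGs (nonzero = inside); all
metadata lives in a structured-text sidecar ``<stem>.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import MultispectralImage
from .stats import FACTOR_COLUMNS, METRIC_COLUMNS

_REQUIRED_META = ("channels", "px_per_mm")


def write_multispectral(img: MultispectralImage, stem: str | Path,
                        extra_meta: dict | None = None) -> Path:
    """Write ``<stem>.tif`` (+ mask PNGs + JSON sidecar); returns the TIFF
    path."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tif = stem.with_suffix(".tif")
    tifffile.imwrite(tif, img.stack().astype(np.float32),
                     photometric="minisblack", planarconfig="separate")
    meta = {"channels": img.channel_names, "px_per_mm": img.px_per_mm,
            "masks": sorted(img.masks)}
    if extra_meta:
        meta.update(extra_meta)
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    for name, m in img.masks.items():
        iio.imwrite(stem.parent / f"{stem.name}.mask_{name}.png",
                    (np.asarray(m, dtype=bool) * np.uint8(255)))
    return tif


def read_multispectral(stem: str | Path) -> tuple[MultispectralImage, dict]:
    """Read a multispectral image written by :func:`write_multispectral`.

    Returns (image, sidecar metadata). Raises naming the missing file or
    metadata field.
    """
    stem = Path(stem)
    if stem.suffix == ".tif":
        stem = stem.with_suffix("")
    sidecar = stem.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required field {key!r}")
    data = tifffile.imread(stem.with_suffix(".tif"))
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(meta["channels"]):
        raise ValueError(
            f"{stem}.tif has {data.shape[0]} pages but sidecar lists "
            f"{len(meta['channels'])} channels")
    channels = {n: data[i].astype(float) for i, n in enumerate(meta["channels"])}
    masks = {}
    for name in meta.get("masks", []):
        p = stem.parent / f"{stem.name}.mask_{name}.png"
        if not p.exists():
            raise FileNotFoundError(f"missing mask file {p}")
        masks[name] = np.asarray(iio.imread(p)) > 0
    return (MultispectralImage(channels=channels, px_per_mm=meta["px_per_mm"],
                               masks=masks), meta)


def write_measurement_table(table: pd.DataFrame, path: str | Path) -> Path:
    """CSV with the canonical column order, header row, dot decimal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = FACTOR_COLUMNS + [c for c in METRIC_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)
    return path


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FACTOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table {path} lacks columns {missing}")
    return table


def write_pattern_spectrum(spectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"scale_px": spectrum.scales,
                  "energy": spectrum.energies}).to_csv(path, index=False)
    return path
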