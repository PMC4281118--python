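"""Rendered microscopy fields: disk-shaped neuron-like objects on noise.

Fixture generator for the segmentation stage.  Objects are hard-edged disks
of stated per-channel intensity placed on a Gaussian optical background; the
ground-truth object table (centres, radii, areas, intensities, overlap
flags) is returned alongside so downstream segmentation can be scored.
Fields are written as one 16-bit grayscale TIFF per channel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .._rng import spawn

__all__ = ["render_fields", "write_fields", "random_disk_layout"]


def random_disk_layout(
    n_objects: int,
    seed: int,
    field_shape: tuple[int, int] = (512, 512),
    um_per_px: float = 1.0,
    area_range_um2: tuple[float, float] = (120.0, 4000.0),
    min_gap_px: float = 4.0,
    intensity_range: tuple[float, float] = (500.0, 3000.0),
    max_tries: int = 20_000,
) -> pd.DataFrame:
    """Place non-overlapping disks with areas uniform in the given window."""
    rng = spawn(seed, "layout")
    rows, cols, radii, intens = [], [], [], []
    tries = 0
    while len(rows) < n_objects:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n_objects} disjoint disks in the field")
        area = rng.uniform(*area_range_um2)
        r_px = np.sqrt(area / np.pi) / um_per_px
        row = rng.uniform(r_px + 2, field_shape[0] - r_px - 2)
        col = rng.uniform(r_px + 2, field_shape[1] - r_px - 2)
        ok = True
        for rr, cc, pr in zip(rows, cols, radii):
            if np.hypot(row - rr, col - cc) < r_px + pr + min_gap_px:
                ok = False
                break
        if ok:
            rows.append(row)
            cols.append(col)
            radii.append(r_px)
            intens.append(rng.uniform(*intensity_range))
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "radius_um": np.array(radii) * um_per_px,
            "intensity": intens,
        }
    )


def render_fields(
    objects: pd.DataFrame,
    field_shape: tuple[int, int] = (512, 512),
    um_per_px: float = 1.0,
    background: tuple[float, float] = (100.0, 10.0),
    seed: int = 0,
    channels: Sequence[str] = ("ch1",),
) -> tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Render disks into per-channel 16-bit images; return images + ground truth.

    ``objects`` needs columns ``row``, ``col``, ``radius_um`` and either a
    single ``intensity`` column (applied to every channel) or one
    ``intensity_<channel>`` column per channel.  Overlapping disks are
    allowed but flagged in the returned truth table.
    """
    rng = spawn(seed, "render")
    shape = tuple(field_shape)
    truth = objects.reset_index(drop=True).copy()
    r_px = truth["radius_um"].to_numpy() / um_per_px
    if (r_px <= 0).any():
        raise ValueError("radius_um: radii must be positive")
    if (
        (truth["row"] - r_px < 1).any()
        or (truth["row"] + r_px > shape[0] - 1).any()
        or (truth["col"] - r_px < 1).any()
        or (truth["col"] + r_px > shape[1] - 1).any()
    ):
        raise ValueError("objects must fit inside the field with >= 1 px margin")

    coverage = np.zeros(shape, dtype=np.int16)
    masks = []
    for i in range(len(truth)):
        rr, cc, r = truth.loc[i, "row"], truth.loc[i, "col"], r_px[i]
        r0, r1 = int(np.floor(rr - r)) - 1, int(np.ceil(rr + r)) + 2
        c0, c1 = int(np.floor(cc - r)) - 1, int(np.ceil(cc + r)) + 2
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy - rr) ** 2 + (xx - cc) ** 2 <= r**2
        masks.append((slice(r0, r1), slice(c0, c1), disk))
        coverage[r0:r1, c0:c1] += disk

    overlapped = []
    for sl_r, sl_c, disk in masks:
        overlapped.append(bool((coverage[sl_r, sl_c][disk] > 1).any()))
    truth["overlaps"] = overlapped
    truth["area_um2"] = np.pi * truth["radius_um"] ** 2
    truth["circularity"] = 1.0

    images: Dict[str, np.ndarray] = {}
    for ch in channels:
        col = f"intensity_{ch}" if f"intensity_{ch}" in truth else "intensity"
        img = rng.normal(background[0], background[1], shape)
        for i, (sl_r, sl_c, disk) in enumerate(masks):
            img[sl_r, sl_c][disk] += float(truth.loc[i, col])
        images[ch] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return images, truth


def write_fields(images: Mapping[str, np.ndarray], out_dir, prefix: str = "field") -> list:
    """Write one 16-bit grayscale TIFF per channel; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, img in images.items():
        path = out_dir / f"{prefix}_{ch}.tif"
        tifffile.imwrite(path, img.astype(np.uint16))
        paths.append(path)
    return paths
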