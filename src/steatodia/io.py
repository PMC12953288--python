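"""File I/O: calibrated rasters with sidecars, cohort tables, droplet tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate.images import GroundTruthDroplet
from .morphometry import SizeClass
from .simulate.cohort import COHORT_COLUMNS

__all__ = [
    "write_image",
    "read_image",
    "write_ground_truth",
    "read_ground_truth",
    "write_cohort",
    "read_cohort",
]


def write_image(path, image: np.ndarray, pixel_size_um: float, seed: int | None = None) -> None:
    """Write an 8-bit raster (TIFF or PNG by extension) plus a JSON sidecar
    carrying the pixel calibration and generator seed."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.uint8))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")
    meta = {"pixel_size_um": pixel_size_um}
    if seed is not None:
        meta["seed"] = seed
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a raster and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        image = tifffile.imread(path)
    else:
        from PIL import Image

        image = np.asarray(Image.open(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return image, meta


def write_ground_truth(path, droplets: list[GroundTruthDroplet]) -> None:
    pd.DataFrame(
        [
            {
                "droplet_id": d.droplet_id,
                "x": d.center_xy[0],
                "y": d.center_xy[1],
                "area_um2": d.area_um2,
                "axis_ratio": d.axis_ratio,
                "size_class": d.size_class.value,
            }
            for d in droplets
        ],
        columns=["droplet_id", "x", "y", "area_um2", "axis_ratio", "size_class"],
    ).to_csv(path, index=False)


def read_ground_truth(path) -> list[GroundTruthDroplet]:
    df = pd.read_csv(path)
    return [
        GroundTruthDroplet(
            droplet_id=int(r.droplet_id),
            center_xy=(float(r.x), float(r.y)),
            area_um2=float(r.area_um2),
            axis_ratio=float(r.axis_ratio),
            size_class=SizeClass(r.size_class),
        )
        for r in df.itertuples()
    ]


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the core schema columns are present."""
    df = pd.read_csv(path)
    required = [c for c in COHORT_COLUMNS if c not in ("biopsy_length_mm", "portal_tracts")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing columns: {missing}")
    return df
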