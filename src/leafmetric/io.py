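"""Image and manifest readers/writers."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pixel_space import DEFAULT_CMAX, PixelCoord, RasterImage

logger = logging.getLogger(__name__)


def read_image(path: str | Path, unp: float, c_max: int = DEFAULT_CMAX) -> RasterImage:
    """Load a PNG/TIFF image as a :class:`RasterImage`.

    Alpha channels are dropped; grayscale is replicated across channels;
    higher bit depths are rescaled to ``[0, c_max - 1]`` and the rescaling
    is logged.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16 or (arr.size and arr.max() > c_max - 1):
        src_max = 65535 if arr.dtype == np.uint16 else int(arr.max())
        logger.info("rescaling %s from depth %d to [0, %d]", path, src_max, c_max - 1)
        arr = np.rint(arr.astype(np.float64) * (c_max - 1) / src_max).astype(np.int64)
    return RasterImage(arr, unp=unp, c_max=c_max)


@dataclass(frozen=True)
class ManifestSample:
    """One manifest row bound to its loaded image."""

    leaf_id: str
    image: RasterImage
    seed_point: PixelCoord
    l_o: float
    h_o: float


def read_manifest(
    path: str | Path, unp: float | None = None, c_max: int = DEFAULT_CMAX
) -> list[ManifestSample]:
    """Load a cohort manifest CSV and its images.

    Expected columns: ``leaf_id, image_path, seed_x, seed_y, l_o, h_o`` and
    optionally ``unp`` (else the ``unp`` argument applies to every image).
    Relative image paths resolve against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"leaf_id", "image_path", "seed_x", "seed_y", "l_o", "h_o"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        row_unp = getattr(row, "unp", None) if "unp" in df.columns else unp
        if row_unp is None:
            raise ValueError("manifest has no 'unp' column and no unp was supplied")
        img_path = Path(row.image_path)
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        samples.append(
            ManifestSample(
                leaf_id=str(row.leaf_id),
                image=read_image(img_path, unp=float(row_unp), c_max=c_max),
                seed_point=PixelCoord(int(row.seed_x), int(row.seed_y)),
                l_o=float(row.l_o),
                h_o=float(row.h_o),
            )
        )
    return samples


@dataclass(frozen=True)
class RunConfig:
    """Sweep configuration: color depth, tolerance range, grouping and sampling."""

    c_max: int = DEFAULT_CMAX
    x_min: int = 1
    x_max: int = 255
    x_step: int = 1
    q: float = 10.0
    upn: float | None = None
    sampler: str = "grid"
    seed: int | None = None

    def __post_init__(self):
        if not 1 <= self.x_min <= self.x_max <= self.c_max - 1:
            raise ValueError("require 1 <= x_min <= x_max <= c_max - 1")
        if self.x_step < 1:
            raise ValueError("x_step must be at least 1")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.sampler not in ("grid", "random"):
            raise ValueError(f"unknown sampler {self.sampler!r}")

    @property
    def x_values(self) -> list[int]:
        return list(range(self.x_min, self.x_max + 1, self.x_step))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
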