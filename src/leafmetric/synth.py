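"""Synthetic eelgrass-leaf images with known morphometry.

Renders ribbon-like blades — long, narrow, optionally tapered and gently
curved — on a contrasting background, with two controllable noise sources
that emulate what a flatbed or underwater scan of a wet *Zostera marina*
leaf actually shows:

* **intra-leaf color jitter**: small independent per-channel perturbations
  within the blade, standing for natural tonal variation;
* **humidity halo**: a ring of pixels hugging the blade contour whose
  colors are intermediate between leaf and background, standing for the
  moisture film that makes the blade's edge ambiguous.  Halo colors are
  drawn from a line segment in RGB space strictly between the leaf and
  background colors, which guarantees a tolerance threshold below which
  the halo is excluded from the grown region and above which it is
  annexed — the regime change the selection index must detect.

Every image carries its ground truth (length, width, proxy area, exact
pixel area), so each estimator in the pipeline can be checked against
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .pixel_space import PixelCoord, RasterImage, color_distance

#: Default blade and background tones: a mid green on a near-white scanner bed.
DEFAULT_LEAF_COLOR = (40, 110, 60)
DEFAULT_BACKGROUND_COLOR = (235, 235, 240)

#: Observed width range for the species (mm); renders outside it are refused
#: unless forced.
WIDTH_RANGE_MM = (1.5, 12.0)
MAX_LENGTH_MM = 460.0


@dataclass(frozen=True)
class LeafSpec:
    """Parameters of one synthetic leaf image.

    Lengths are in mm; ``unp`` is the image scale in pixels per mm.  The
    blade is an axis-aligned ribbon of nominal width ``true_width``,
    optionally tapering linearly to ``(1 - taper)`` of it at the tip and
    optionally bowed by a half-sine midline of amplitude ``curvature`` mm.
    ``halo_span`` places halo colors on the leaf-to-background RGB segment
    at fractional positions in that interval.
    """

    true_length: float
    true_width: float
    taper: float = 0.0
    curvature: float = 0.0
    leaf_color: tuple[int, int, int] = DEFAULT_LEAF_COLOR
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND_COLOR
    halo_width: int = 2
    halo_span: tuple[float, float] = (0.25, 0.55)
    jitter: int = 3
    unp: float = 5.0
    margin: int = 8
    rng_seed: int = 0

    def validate(self, force: bool = False) -> None:
        if self.true_length <= 0 or self.true_width <= 0:
            raise ValueError("leaf length and width must be positive")
        if not force:
            lo, hi = WIDTH_RANGE_MM
            if not lo <= self.true_width <= hi:
                raise ValueError(
                    f"width {self.true_width} mm outside the validated range "
                    f"[{lo}, {hi}] mm (use force=True to override)"
                )
            if self.true_length > MAX_LENGTH_MM:
                raise ValueError(
                    f"length {self.true_length} mm exceeds the validated maximum "
                    f"{MAX_LENGTH_MM} mm (use force=True to override)"
                )
        if not 0 <= self.taper < 1:
            raise ValueError("taper must lie in [0, 1)")
        if self.halo_width < 0 or self.jitter < 0:
            raise ValueError("halo_width and jitter must be nonnegative")
        if self.unp <= 0:
            raise ValueError("unp must be positive")
        lo, hi = self.halo_span
        if not 0 < lo <= hi < 1:
            raise ValueError("halo_span must lie strictly inside (0, 1)")

    @property
    def leaf_background_distance(self) -> float:
        return color_distance(self.leaf_color, self.background_color)

    @property
    def leaf_halo_distance(self) -> float:
        """Smallest RGB distance from the leaf color to any halo color."""
        return self.halo_span[0] * self.leaf_background_distance

    @property
    def halo_background_distance(self) -> float:
        """Smallest RGB distance from any halo color to the background."""
        return (1 - self.halo_span[1]) * self.leaf_background_distance


@dataclass(frozen=True)
class LeafSample:
    """A rendered leaf: image, seed point and ground truth."""

    leaf_id: str
    image: RasterImage
    seed_point: PixelCoord
    l_o: float          # ground-truth length, mm
    h_o: float          # ground-truth nominal width, mm
    pixel_area: float   # exact rasterized area, mm^2
    spec: LeafSpec

    @property
    def a_o(self) -> float:
        return self.l_o * self.h_o


def _leaf_mask(spec: LeafSpec) -> tuple[np.ndarray, PixelCoord]:
    """Rasterize the blade: boolean mask plus a seed pixel on the midline.

    The blade's straight edge is anchored on a pixel boundary, so for the
    default straight rectangle the rasterized width is the physical width
    rounded to the nearest pixel (error at most half a pixel) and the
    length likewise.
    """
    unp = spec.unp
    len_px = max(1, round(spec.true_length * unp))
    w_px = spec.true_width * unp
    amp_px = spec.curvature * unp
    top = spec.margin + spec.halo_width          # pixel boundary anchor
    x0 = spec.margin + spec.halo_width
    h_img = top + int(np.ceil(w_px + amp_px)) + spec.margin + spec.halo_width + 1
    w_img = len_px + 2 * (spec.margin + spec.halo_width)

    cols = np.arange(len_px)
    frac = cols / max(len_px - 1, 1)
    center = top + w_px / 2.0 + amp_px * np.sin(np.pi * frac)
    width_px = w_px * (1.0 - spec.taper * frac)

    mask = np.zeros((h_img, w_img), dtype=bool)
    rows = np.arange(h_img)[:, None] + 0.5  # pixel centers
    lo = center - width_px / 2.0
    hi = center + width_px / 2.0
    mask[:, x0:x0 + len_px] = (rows >= lo[None, :]) & (rows < hi[None, :])
    mid_col = x0 + len_px // 2
    mid_row = int(center[len_px // 2])
    return mask, PixelCoord(mid_col, mid_row)


def render_leaf(spec: LeafSpec, leaf_id: str = "leaf", force: bool = False) -> LeafSample:
    """Render one leaf image with its ground truth.

    Deterministic for a fixed ``spec.rng_seed``; halo colors and jitter are
    the only random elements.
    """
    spec.validate(force=force)
    rng = np.random.default_rng(spec.rng_seed)
    mask, seed_pt = _leaf_mask(spec)
    h_img, w_img = mask.shape

    img = np.empty((h_img, w_img, 3), dtype=np.int64)
    img[:] = spec.background_color

    leaf = np.asarray(spec.leaf_color, dtype=np.float64)
    back = np.asarray(spec.background_color, dtype=np.float64)

    if spec.halo_width > 0:
        dilated = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), bool), iterations=spec.halo_width
        )
        halo = dilated & ~mask
        t = rng.uniform(*spec.halo_span, size=int(halo.sum()))
        img[halo] = np.rint(leaf[None, :] + t[:, None] * (back - leaf)[None, :]).astype(np.int64)

    img[mask] = spec.leaf_color
    if spec.jitter > 0:
        noise = rng.integers(-spec.jitter, spec.jitter + 1, size=(int(mask.sum()), 3))
        img[mask] = np.clip(img[mask] + noise, 0, 255)

    image = RasterImage(img, unp=spec.unp)
    return LeafSample(
        leaf_id=leaf_id,
        image=image,
        seed_point=seed_pt,
        l_o=spec.true_length,
        h_o=spec.true_width,
        pixel_area=float(mask.sum()) / spec.unp**2,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Defaults emulate the field sampling the method targets: blade lengths
    spread over the species' observed range up to 460 mm and nominal widths
    within the reported 1.5–12 mm variation (sampled in the commonly
    measured 2.5–6 mm band), on a near-white background with a 2-pixel
    humidity halo.
    """

    n_leaves: int = 50
    length_range: tuple[float, float] = (10.0, 460.0)
    width_range: tuple[float, float] = (2.5, 6.0)
    template: LeafSpec = field(
        default_factory=lambda: LeafSpec(true_length=100.0, true_width=4.0)
    )


def generate_cohort(
    cohort: CohortSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    force: bool = False,
    **overrides,
) -> list[LeafSample]:
    """Generate a cohort of leaves; optionally write images and a manifest.

    Lengths and widths are drawn uniformly from the cohort's ranges; all
    randomness (shapes, halo colors, jitter) flows from ``seed``.  When
    ``out_dir`` is given, PNG images and a ``manifest.csv`` compatible with
    the sweep driver are written there.
    """
    cohort = cohort or CohortSpec()
    if overrides:
        cohort = CohortSpec(**{**asdict_cohort(cohort), **overrides})
    if cohort.n_leaves < 1:
        raise ValueError("n_leaves must be at least 1")
    l_lo, l_hi = cohort.length_range
    w_lo, w_hi = cohort.width_range
    if not (0 < l_lo < l_hi) or not (0 < w_lo <= w_hi):
        raise ValueError("degenerate length or width range")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(cohort.n_leaves):
        spec = replace_spec(
            cohort.template,
            true_length=float(rng.uniform(l_lo, l_hi)),
            true_width=float(rng.uniform(w_lo, w_hi)),
            rng_seed=int(rng.integers(2**31)),
        )
        samples.append(render_leaf(spec, leaf_id=f"leaf{i:04d}", force=force))
    if out_dir is not None:
        write_cohort(samples, out_dir)
    return samples


def asdict_cohort(cohort: CohortSpec) -> dict:
    d = asdict(cohort)
    d["template"] = cohort.template
    return d


def replace_spec(spec: LeafSpec, **kw) -> LeafSpec:
    return LeafSpec(**{**asdict(spec), **kw})


def write_cohort(samples: Sequence[LeafSample], out_dir: str | Path) -> Path:
    """Write cohort images as PNG plus a manifest CSV and a spec JSON."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        path = out / f"{s.leaf_id}.png"
        iio.imwrite(path, s.image.pixels.astype(np.uint8))
        rows.append({
            "leaf_id": s.leaf_id,
            "image_path": path.name,
            "seed_x": s.seed_point.x,
            "seed_y": s.seed_point.y,
            "l_o": s.l_o,
            "h_o": s.h_o,
            "unp": s.image.unp,
            "rng_seed": s.spec.rng_seed,
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    specs = {s.leaf_id: asdict(s.spec) for s in samples}
    (out / "specs.json").write_text(json.dumps(specs, indent=1))
    return manifest
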