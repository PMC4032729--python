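"""Seed-based region growing and peripheral contour extraction.

A leaf region is the connected component, under the tolerance-of-similarity
relation, of the pixel graph containing a seed placed inside the leaf.
Similarity is evaluated pairwise between adjacent pixels (pixel-to-neighbor,
not pixel-to-seed), so a region can drift in color along a chain of pairwise
similar pixels; that non-transitivity is deliberate — it is exactly the
mechanism by which a humidity halo of intermediate colors is annexed once
the tolerance exceeds the leaf-to-halo color distance, and the tolerance
selection stage exists to detect it.

The peripheral contour of a region is the set of member pixels having at
least one 8-neighbor (off-image positions included) outside the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order

from .pixel_space import (
    PixelCoord,
    RasterImage,
    ToleranceInterval,
    _as_coord,
    validate_tolerance,
)

logger = logging.getLogger(__name__)

# Directed offsets covering every undirected 8-neighbor pair exactly once.
_EDGE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class EdgeTable:
    """Color distances for every 8-adjacent pixel pair of one image.

    Computing the distances once lets a tolerance sweep re-threshold the
    same table for each ``x`` instead of re-measuring the image.
    """

    shape: tuple[int, int]  # (height, width)
    rows: np.ndarray        # flat index of the first endpoint
    cols: np.ndarray        # flat index of the second endpoint
    dist: np.ndarray        # RGB distance between the endpoints


def edge_table(image: RasterImage) -> EdgeTable:
    """Compute RGB distances along all 8-adjacent pixel pairs of ``image``."""
    px = image.pixels.astype(np.float64)
    h, w = px.shape[:2]
    idx = np.arange(h * w).reshape(h, w)
    rows, cols, dists = [], [], []
    for dy, dx in _EDGE_OFFSETS:
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        ys2 = slice(max(0, dy), h - max(0, -dy))
        xs2 = slice(max(0, dx), w - max(0, -dx))
        a = px[ys, xs]
        b = px[ys2, xs2]
        d = np.sqrt(((a - b) ** 2).sum(axis=-1))
        rows.append(idx[ys, xs].ravel())
        cols.append(idx[ys2, xs2].ravel())
        dists.append(d.ravel())
    return EdgeTable(
        (h, w),
        np.concatenate(rows) if rows else np.empty(0, np.int64),
        np.concatenate(cols) if cols else np.empty(0, np.int64),
        np.concatenate(dists) if dists else np.empty(0, np.float64),
    )


@dataclass
class LeafRegion:
    """A connected pixel region grown from a seed at tolerance ``ST(x)``.

    ``mask`` is a boolean array over the source image (rows x cols); the
    set-valued views exist for the small-image contracts and tests, the
    mask for bulk measurement.
    """

    mask: np.ndarray
    seed: PixelCoord
    tol: ToleranceInterval
    unp: float

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    @cached_property
    def members(self) -> frozenset[PixelCoord]:
        ys, xs = np.nonzero(self.mask)
        return frozenset(PixelCoord(int(x), int(y)) for x, y in zip(xs, ys))

    @cached_property
    def contour_mask(self) -> np.ndarray:
        return peripheral_contour_mask(self.mask)

    @cached_property
    def contour(self) -> frozenset[PixelCoord]:
        ys, xs = np.nonzero(self.contour_mask)
        return frozenset(PixelCoord(int(x), int(y)) for x, y in zip(xs, ys))

    @property
    def touches_border(self) -> bool:
        """True when the region reaches the image frame — the signature of a
        segmentation flood (tolerance admitted the background)."""
        m = self.mask
        return bool(m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())

    def pixel_area(self) -> float:
        """Exact region area in squared length units: ``|members| / unp**2``."""
        return self.size / self.unp**2


def grow_region(
    image: RasterImage,
    seed,
    tol,
    edges: EdgeTable | None = None,
) -> LeafRegion:
    """Grow the connected region containing ``seed`` at tolerance ``ST(x)``.

    The result is the connected component of the pixel graph whose edges
    join 8-adjacent pixels with color distance at most ``x``; it is a set,
    independent of traversal order, and monotone in ``x``.

    Parameters
    ----------
    edges : EdgeTable, optional
        Precomputed distances from :func:`edge_table`; supply it when
        growing the same image at several tolerances.
    """
    sx, sy = _as_coord(seed)
    if not image.in_bounds((sx, sy)):
        raise ValueError(f"seed ({sx}, {sy}) outside {image.width}x{image.height} image")
    x = validate_tolerance(tol, image.c_max)
    if edges is None:
        edges = edge_table(image)
    elif edges.shape != (image.height, image.width):
        raise ValueError("edge table does not match image shape")

    h, w = edges.shape
    n = h * w
    keep = edges.dist <= x
    r, c = edges.rows[keep], edges.cols[keep]
    graph = sparse.csr_matrix(
        (np.ones(2 * len(r), dtype=np.int8), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    )
    order = breadth_first_order(graph, sy * w + sx, directed=True, return_predecessors=False)
    mask = np.zeros(n, dtype=bool)
    mask[order] = True
    region = LeafRegion(mask.reshape(h, w), PixelCoord(sx, sy), ToleranceInterval(x), image.unp)
    logger.debug(
        "grow_region: seed=(%d,%d) x=%d members=%d contour=%d flooded=%s",
        sx, sy, x, region.size, int(region.contour_mask.sum()), region.touches_border,
    )
    return region


def peripheral_contour_mask(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a boolean region mask.

    A member belongs to the contour iff at least one of its 8 neighbors
    (off-image positions counting as outside) is not a member; equivalently
    the member set minus its 8-connected erosion.
    """
    if not mask.any():
        raise ValueError("empty region has no contour")
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    return mask & ~interior


def peripheral_contour(region: LeafRegion) -> frozenset[PixelCoord]:
    """The peripheral contour of a region as a set of coordinates."""
    return region.contour


def trace_boundary(region: LeafRegion) -> list[PixelCoord]:
    """Ordered boundary walk (Moore tracing) for visualization only.

    Measurements use the contour *set*; the ordering carries no meaning in
    any estimator.
    """
    mask = region.mask
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty region")
    # start at the topmost-then-leftmost member
    i = np.lexsort((xs, ys))[0]
    start = (int(xs[i]), int(ys[i]))
    if region.size == 1:
        return [PixelCoord(*start)]
    # clockwise Moore neighborhood starting from the west neighbor
    ring = ((-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1))

    def is_member(x, y):
        return 0 <= y < mask.shape[0] and 0 <= x < mask.shape[1] and mask[y, x]

    walk = [PixelCoord(*start)]
    prev_dir = 0
    cur = start
    while True:
        found = False
        for k in range(8):
            j = (prev_dir + k) % 8
            dx, dy = ring[j]
            nx, ny = cur[0] + dx, cur[1] + dy
            if is_member(nx, ny):
                cur = (nx, ny)
                # back up two steps in the ring for the next scan
                prev_dir = (j + 6) % 8
                found = True
                break
        if not found:  # isolated pixel chain end
            break
        if cur == start:
            break
        walk.append(PixelCoord(*cur))
        if len(walk) > 4 * region.size:  # safety bound
            break
    return walk


def export_mask_png(region: LeafRegion, path) -> None:
    """Write the region mask as a black/white PNG for quality control."""
    import imageio.v3 as iio

    iio.imwrite(path, (region.mask * 255).astype(np.uint8))


def export_contour_overlay_png(region: LeafRegion, image: RasterImage, path) -> None:
    """Write the source image with the contour painted red, for QC."""
    import imageio.v3 as iio

    rgb = np.clip(image.pixels * (255 // (image.c_max - 1) if image.c_max <= 256 else 1), 0, 255)
    rgb = rgb.astype(np.uint8).copy()
    rgb[region.contour_mask] = (255, 0, 0)
    iio.imwrite(path, rgb)
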