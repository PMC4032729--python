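"""Length, width and area estimators for a segmented leaf region.

Two estimators of blade area are provided:

* the length-times-width proxy ``a_d = l_d * h_d`` with ``l_d = np_l / unp``
  and ``h_d = np_h / unp``, where ``np_l`` and ``np_h`` are pixel counts
  along the blade's length and width;
* the Monte Carlo estimate ``a_mc = LPN / UPN**2``, where ``LPN`` counts
  sample points landing inside the region and ``UPN**2`` is the number of
  sample points per unit area.

For a ribbon-like blade the length axis is taken as the major principal
axis of the region's pixel coordinates (for an axis-aligned leaf this is
the bounding-box axis); the width ``np_h`` is counted on the unit-width
cross-section slab at the midpoint of the length extent, mirroring the
manual protocol of measuring width halfway along the blade.  A maximum
cross-section mode is available for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import LeafRegion


@dataclass(frozen=True)
class LeafMeasurement:
    """Image-derived measurements of one leaf at one tolerance ``ST(x)``."""

    x: int            # similarity tolerance bound
    np_l: int         # pixel count along the length axis
    np_h: int         # pixel count across the width at the midpoint
    l_d: float        # digital length, length units
    h_d: float        # digital width, length units
    a_d: float        # length-times-width area, squared length units
    lpn: int          # Monte Carlo sample points inside the region
    upn: float        # Monte Carlo sample points per unit length
    a_mc: float       # Monte Carlo area, squared length units
    flooded: bool     # region reached the image frame
    seed: int | None = None  # RNG seed when the random sampler was used


def principal_axis(region: LeafRegion) -> np.ndarray:
    """Unit vector of the region's major principal axis in (x, y) order.

    Largest-eigenvalue eigenvector of the coordinate covariance; degenerate
    (single-pixel or isotropic) regions default to the x axis.
    """
    ys, xs = np.nonzero(region.mask)
    if len(xs) == 0:
        raise ValueError("empty region")
    coords = np.stack([xs, ys]).astype(np.float64)
    if len(xs) == 1:
        return np.array([1.0, 0.0])
    cov = np.cov(coords)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    # orient toward +x (or +y when vertical) so projections are reproducible
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def pixel_extents(region: LeafRegion, mode: str = "midpoint") -> tuple[int, int]:
    """Pixel counts ``(np_l, np_h)`` along the blade's length and width.

    ``np_l`` is the pixel extent of the region projected on its major
    principal axis.  ``np_h`` counts the region pixels in the unit-width
    slab perpendicular to that axis at the midpoint of the length extent
    (``mode="midpoint"``, default) or in the fullest such slab
    (``mode="max"``).
    """
    if mode not in ("midpoint", "max"):
        raise ValueError(f"unknown width mode {mode!r}")
    ys, xs = np.nonzero(region.mask)
    if len(xs) == 0:
        raise ValueError("empty region")
    axis = principal_axis(region)
    proj = xs * axis[0] + ys * axis[1]
    s = proj - proj.min()
    # bin the projections into unit-width slabs along the axis
    slab = np.floor(s + 1e-9).astype(np.int64)
    np_l = int(slab.max()) + 1
    if mode == "midpoint":
        mid = (np_l - 1) // 2
        np_h = int(np.count_nonzero(slab == mid))
    else:
        np_h = int(np.bincount(slab).max())
    return np_l, np_h


def digital_length(np_l: int, unp: float) -> float:
    """Digital length ``l_d = np_l / unp`` in physical length units."""
    if unp <= 0:
        raise ValueError("unp must be positive")
    if np_l < 0:
        raise ValueError("pixel count must be nonnegative")
    return np_l / unp


def digital_width(np_h: int, unp: float) -> float:
    """Digital width ``h_d = np_h / unp`` in physical length units."""
    return digital_length(np_h, unp)


def digital_area(l_d: float, h_d: float) -> float:
    """Length-times-width proxy area ``a_d = l_d * h_d``."""
    if l_d < 0 or h_d < 0:
        raise ValueError("length and width must be nonnegative")
    return l_d * h_d


def monte_carlo_area(
    region: LeafRegion,
    unp: float,
    upn: float,
    sampler: str = "grid",
    rng: np.random.Generator | int | None = None,
) -> tuple[int, float]:
    """Monte Carlo area of a region: returns ``(LPN, a_mc)``.

    Sample points are laid over the full image frame; a point is inside the
    leaf iff the pixel containing it belongs to the region, and
    ``a_mc = LPN / UPN**2``.

    ``sampler="grid"`` (default) uses a deterministic uniform grid of pitch
    ``1/UPN``; ``sampler="random"`` draws the same number of points
    uniformly at random and requires ``rng``.
    """
    if upn <= 0:
        raise ValueError("UPN must be positive")
    if unp <= 0:
        raise ValueError("unp must be positive")
    mask = region.mask
    h, w = mask.shape
    frame_w = w / unp   # physical frame extent
    frame_h = h / unp
    if sampler == "grid":
        nx = int(np.ceil(frame_w * upn))
        ny = int(np.ceil(frame_h * upn))
        px = (np.arange(nx) + 0.5) / upn
        py = (np.arange(ny) + 0.5) / upn
        ix = np.floor(px * unp).astype(np.int64)
        iy = np.floor(py * unp).astype(np.int64)
        ix = ix[ix < w]
        iy = iy[iy < h]
        lpn = int(mask[np.ix_(iy, ix)].sum())
    elif sampler == "random":
        if rng is None:
            raise ValueError("random sampler requires an rng or seed")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        n_pts = int(round(upn**2 * frame_w * frame_h))
        px = gen.uniform(0, frame_w, n_pts)
        py = gen.uniform(0, frame_h, n_pts)
        ix = np.minimum(np.floor(px * unp).astype(np.int64), w - 1)
        iy = np.minimum(np.floor(py * unp).astype(np.int64), h - 1)
        lpn = int(mask[iy, ix].sum())
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    return lpn, lpn / upn**2


def measure_region(
    region: LeafRegion,
    upn: float,
    sampler: str = "grid",
    rng_seed: int | None = None,
    width_mode: str = "midpoint",
) -> LeafMeasurement:
    """All image-derived measurements of one region at its tolerance."""
    np_l, np_h = pixel_extents(region, mode=width_mode)
    unp = region.unp
    l_d = digital_length(np_l, unp)
    h_d = digital_width(np_h, unp)
    a_d = digital_area(l_d, h_d)
    lpn, a_mc = monte_carlo_area(
        region, unp, upn, sampler=sampler,
        rng=rng_seed if sampler == "random" else None,
    )
    return LeafMeasurement(
        x=region.tol.x, np_l=np_l, np_h=np_h, l_d=l_d, h_d=h_d, a_d=a_d,
        lpn=lpn, upn=upn, a_mc=a_mc, flooded=region.touches_border,
        seed=rng_seed if sampler == "random" else None,
    )
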