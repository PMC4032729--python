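"""Discrete RGB color geometry and pixel adjacency.

The segmentation machinery rests on four small notions:

* a color is a point of the discrete RGB cube ``[0, C_max - 1]^3``;
* the distance between two colors is the Euclidean distance in that cube;
* two pixels are *similar* at tolerance ``ST(x) = [0, x]`` when their color
  distance does not exceed ``x`` (``1 <= x <= C_max - 1``);
* two pixels are *connected* at tolerance ``ST(x)`` when they are
  8-neighbors and similar.

Everything else (region growing, contour extraction, the tolerance sweep)
is built from these predicates.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np

#: Default number of color levels per channel (standard 8-bit RGB).
DEFAULT_CMAX = 256


class RGBColor(NamedTuple):
    """A color as integer channel intensities in ``[0, C_max - 1]``."""

    r: int
    g: int
    b: int


class PixelCoord(NamedTuple):
    """An image coordinate: ``x`` is the column index, ``y`` the row index."""

    x: int
    y: int


class ToleranceInterval(NamedTuple):
    """The similarity tolerance ``ST(x) = [0, x]``, identified by its upper bound."""

    x: int


def _as_color(c) -> tuple[int, int, int]:
    r, g, b = c
    return int(r), int(g), int(b)


def _as_coord(p) -> PixelCoord:
    x, y = p
    return PixelCoord(int(x), int(y))


def _tol_value(tol) -> int:
    if isinstance(tol, ToleranceInterval):
        return tol.x
    return int(tol)


def validate_color(c, c_max: int = DEFAULT_CMAX) -> tuple[int, int, int]:
    """Check that every channel of ``c`` lies in ``[0, c_max - 1]``."""
    rgb = _as_color(c)
    for v in rgb:
        if not 0 <= v <= c_max - 1:
            raise ValueError(f"channel intensity {v} outside [0, {c_max - 1}]")
    return rgb


def validate_tolerance(tol, c_max: int = DEFAULT_CMAX) -> int:
    """Check that the tolerance bound lies in ``[1, c_max - 1]``."""
    x = _tol_value(tol)
    if not 1 <= x <= c_max - 1:
        raise ValueError(f"tolerance x={x} outside [1, {c_max - 1}]")
    return x


class RasterImage:
    """A raster color image with a physical scale.

    Parameters
    ----------
    pixels : ndarray of shape (height, width, 3)
        Integer channel intensities in ``[0, c_max - 1]``.
    unp : float
        Pixels per physical length unit (points per mm); the scale factor
        that converts pixel counts into lengths.
    c_max : int
        Number of color levels per channel.
    """

    def __init__(self, pixels: np.ndarray, unp: float, c_max: int = DEFAULT_CMAX):
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (height, width, 3)")
        if unp <= 0:
            raise ValueError("unp (pixels per unit length) must be positive")
        if pixels.size and (pixels.min() < 0 or pixels.max() > c_max - 1):
            raise ValueError(f"channel intensities outside [0, {c_max - 1}]")
        self.pixels = pixels.astype(np.int64, copy=False)
        self.unp = float(unp)
        self.c_max = int(c_max)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def in_bounds(self, p) -> bool:
        x, y = _as_coord(p)
        return 0 <= x < self.width and 0 <= y < self.height

    def color_at(self, p) -> RGBColor:
        x, y = _as_coord(p)
        if not self.in_bounds((x, y)):
            raise ValueError(f"coordinate ({x}, {y}) outside {self.width}x{self.height} image")
        return RGBColor(*(int(v) for v in self.pixels[y, x]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RasterImage({self.width}x{self.height}, unp={self.unp}, c_max={self.c_max})"


def color_distance(p, q, c_max: int = DEFAULT_CMAX) -> float:
    """Euclidean distance between two colors in the RGB cube.

    Satisfies the metric axioms; zero iff the colors coincide.
    """
    pr, pg, pb = validate_color(p, c_max)
    qr, qg, qb = validate_color(q, c_max)
    return math.sqrt((pr - qr) ** 2 + (pg - qg) ** 2 + (pb - qb) ** 2)


def similar(p, q, tol, c_max: int = DEFAULT_CMAX) -> bool:
    """Whether two colors are similar at tolerance ``ST(x)``.

    True iff their RGB distance is at most ``x``. Reflexive, symmetric, and
    monotone in ``x``. The distance is compared in floating point with no
    prior rounding.
    """
    x = validate_tolerance(tol, c_max)
    return color_distance(p, q, c_max) <= x


# The 8-neighborhood offsets: edge-sharing first, then corner-sharing.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
)


def vicinity(p, image: RasterImage) -> set[PixelCoord]:
    """The 8-neighborhood of ``p`` clipped to the image bounds.

    Off-image positions are dropped, so border pixels have 5 neighbors and
    corner pixels 3; the result never contains ``p`` itself.
    """
    px, py = _as_coord(p)
    if not image.in_bounds((px, py)):
        raise ValueError(f"coordinate ({px}, {py}) out of bounds")
    out = set()
    for dx, dy in NEIGHBOR_OFFSETS:
        q = PixelCoord(px + dx, py + dy)
        if image.in_bounds(q):
            out.add(q)
    return out


def adjacent(p, q) -> bool:
    """Whether two coordinates share a border or a corner (8-adjacency)."""
    px, py = _as_coord(p)
    qx, qy = _as_coord(q)
    return max(abs(px - qx), abs(py - qy)) == 1


def connected(p, q, tol, image: RasterImage) -> bool:
    """Whether pixels ``p`` and ``q`` are connected at tolerance ``ST(x)``.

    True iff ``q`` is in the vicinity of ``p`` and their colors are similar
    at ``ST(x)``. Symmetric in ``p`` and ``q``.
    """
    pc = _as_coord(p)
    qc = _as_coord(q)
    for c in (pc, qc):
        if not image.in_bounds(c):
            raise ValueError(f"coordinate {tuple(c)} out of bounds")
    if qc not in vicinity(pc, image):
        return False
    return similar(image.color_at(pc), image.color_at(qc), tol, image.c_max)


def colors_to_array(colors: Sequence) -> np.ndarray:
    """Stack a sequence of colors into a float array of shape (n, 3)."""
    return np.asarray([_as_color(c) for c in colors], dtype=np.float64)
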