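"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import settings

from leafmetric.pixel_space import RasterImage

settings.register_profile("ci", derandomize=True, max_examples=50, database=None)
settings.load_profile("ci")


def make_image(pixels, unp: float = 1.0) -> RasterImage:
    """Build a RasterImage from a (h, w, 3) or broadcastable nested list."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:  # grayscale shorthand
        arr = np.stack([arr] * 3, axis=-1)
    return RasterImage(arr, unp=unp)


def solid_image(width: int, height: int, color=(100, 100, 100), unp: float = 1.0) -> RasterImage:
    arr = np.empty((height, width, 3), dtype=np.int64)
    arr[:] = color
    return RasterImage(arr, unp=unp)


def random_small_image(rng: np.random.Generator, max_side: int = 8, n_colors: int = 4) -> RasterImage:
    """A random image up to max_side x max_side drawn from a small palette."""
    w = int(rng.integers(1, max_side + 1))
    h = int(rng.integers(1, max_side + 1))
    k = int(rng.integers(1, n_colors + 1))
    palette = rng.integers(0, 256, size=(k, 3))
    idx = rng.integers(0, k, size=(h, w))
    return RasterImage(palette[idx], unp=1.0)


def brute_force_component(image: RasterImage, seed, x: int) -> set[tuple[int, int]]:
    """Independent oracle: breadth-first search over explicitly enumerated
    similarity edges (8-adjacency + color distance <= x), pure Python."""
    w, h = image.width, image.height
    px = image.pixels

    def dist(p, q):
        return math.sqrt(sum((int(px[p[1], p[0]][c]) - int(px[q[1], q[0]][c])) ** 2 for c in range(3)))

    def neighbors(p):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                q = (p[0] + dx, p[1] + dy)
                if 0 <= q[0] < w and 0 <= q[1] < h:
                    yield q

    start = (int(seed[0]), int(seed[1]))
    seen = {start}
    queue = deque([start])
    while queue:
        p = queue.popleft()
        for q in neighbors(p):
            if q not in seen and dist(p, q) <= x:
                seen.add(q)
                queue.append(q)
    return seen


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
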