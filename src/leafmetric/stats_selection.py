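"""Grouped error statistics and the tolerance-selection index.

Digital measurements of a leaf depend on the similarity tolerance ``ST(x)``
used to segment it: too small a tolerance fragments the blade, too large a
tolerance annexes humidity-halo pixels and overestimates width and area.
The selection procedure quantifies, for each candidate ``x``, how well the
image-derived measurements agree with direct (ruler) measurements across a
cohort of leaves, and picks the ``x`` minimizing area overestimation.

The cohort is partitioned into length groups ``G_k`` over intervals
``I_k = [q(k-1), qk)`` of width ``q = l_max / n``; groups with fewer than
two leaves carry no dispersion information and are excluded.  Per-leaf
errors are observed minus image-derived values (positive = the image
underestimates).  Group mean errors ``delta_l^k, delta_h^k, delta_a^k``
and cohort-level means and pooled standard deviations define acceptance
bands ``[delta_bar - sigma, delta_bar + sigma]``; the proportions

* ``lambda_l, lambda_h`` — leaves whose group's mean length/width error
  falls inside its band (``theta = 1 - lambda`` the complements),
* ``lambda_a`` — leaves whose group passes both bands *and* whose area
  error is nonnegative (area not overestimated); ``beta_a`` its complement,

yield the selection index ``IS_x = beta_a / lambda_a``, and identically
``IS_x^mc = beta_amc / lambda_amc`` with the Monte Carlo area in place of
the length-times-width proxy.  The optimal tolerance is the admissible
``x`` with the smallest ``IS_x`` (ties broken toward the smaller, hence
less noise-permissive, ``x``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contour import edge_table, grow_region
from .morphometry import LeafMeasurement, measure_region
from .pixel_space import PixelCoord, RasterImage

logger = logging.getLogger(__name__)


def truncate(value: float, decimals: int = 4) -> float:
    """Truncate (not round) a nonnegative value to ``decimals`` places.

    Used for display parity with reported index tables, which truncate the
    quotient; a tiny epsilon absorbs binary representation error of exact
    decimal quotients.
    """
    scale = 10**decimals
    return math.floor(value * scale + 1e-9) / scale


# ---------------------------------------------------------------------------
# cohort containers


@dataclass
class LeafRecord:
    """One leaf's direct measurements and its per-tolerance image measurements.

    ``a_o`` is the length-times-width proxy of the directly observed blade
    length and width.
    """

    leaf_id: str
    l_o: float  # observed length, mm
    h_o: float  # observed width, mm
    measurements: dict[int, LeafMeasurement] = field(default_factory=dict)

    def __post_init__(self):
        if self.l_o <= 0 or self.h_o <= 0:
            raise ValueError("observed length and width must be positive")

    @property
    def a_o(self) -> float:
        return self.l_o * self.h_o


@dataclass(frozen=True)
class LengthPartition:
    """The partition of ``[0, l_max]`` into ``n`` intervals of width ``q``."""

    l_max: float
    n: int

    @property
    def q(self) -> float:
        return self.l_max / self.n

    def interval(self, k: int) -> tuple[float, float]:
        """Bounds of ``I_k = [q(k-1), qk)`` for ``1 <= k <= n``."""
        if not 1 <= k <= self.n:
            raise ValueError(f"interval index {k} outside [1, {self.n}]")
        return (self.q * (k - 1), self.q * k)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return [self.interval(k) for k in range(1, self.n + 1)]

    def index_of(self, length: float) -> int:
        """The ``k`` with ``length`` in ``I_k``; the last interval is closed
        above so the longest leaf is not orphaned."""
        if length < 0 or length > self.l_max:
            raise ValueError(f"length {length} outside [0, {self.l_max}]")
        if length == self.l_max:
            return self.n
        return int(length // self.q) + 1


def build_partition(l_max: float, n: int) -> LengthPartition:
    """Partition ``[0, l_max]`` into ``n`` half-open intervals of width
    ``q = l_max / n``."""
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    return LengthPartition(float(l_max), int(n))


@dataclass
class LeafGroup:
    """The group ``G_k`` of leaves whose observed length lies in ``I_k``.

    Groups with fewer than two leaves are excluded from the cohort
    statistics (no within-group dispersion)."""

    k: int
    interval: tuple[float, float]
    members: list[LeafRecord] = field(default_factory=list)

    @property
    def n_k(self) -> int:
        return len(self.members)

    @property
    def included(self) -> bool:
        return self.n_k >= 2


def assign_groups(
    leaves: Iterable[LeafRecord], partition: LengthPartition
) -> tuple[list[LeafGroup], list[LeafRecord]]:
    """Bin leaves into length groups.

    Returns ``(groups, out_of_range)``: one :class:`LeafGroup` per partition
    interval (possibly empty), and the leaves whose observed length falls
    outside ``[0, l_max]`` — these are reported back and logged, never
    silently dropped.
    """
    groups = {k: LeafGroup(k, partition.interval(k)) for k in range(1, partition.n + 1)}
    out_of_range: list[LeafRecord] = []
    for leaf in leaves:
        try:
            k = partition.index_of(leaf.l_o)
        except ValueError:
            out_of_range.append(leaf)
            continue
        groups[k].members.append(leaf)
    if out_of_range:
        logger.warning(
            "%d leaves outside [0, %.6g] were not grouped: %s",
            len(out_of_range), partition.l_max, [l.leaf_id for l in out_of_range],
        )
    return list(groups.values()), out_of_range


def included_groups(groups: Sequence[LeafGroup]) -> list[LeafGroup]:
    """The collection ``C_G`` of groups that enter the statistics."""
    return [g for g in groups if g.included]


# ---------------------------------------------------------------------------
# per-leaf and per-group error statistics


def leaf_errors(record: LeafRecord, x: int) -> tuple[float, float, float, float]:
    """Errors ``(e_l, e_h, e_a, e_mc)`` of one leaf at tolerance ``x``.

    Observed minus image-derived; positive values mean the image
    underestimates the observed quantity.
    """
    if x not in record.measurements:
        raise KeyError(f"leaf {record.leaf_id} has no measurement at x={x}")
    m = record.measurements[x]
    return (
        record.l_o - m.l_d,
        record.h_o - m.h_d,
        record.a_o - m.a_d,
        record.a_o - m.a_mc,
    )


@dataclass(frozen=True)
class GroupStats:
    """Per-group error arrays and their means at one tolerance."""

    k: int
    n_k: int
    e_l: np.ndarray
    e_h: np.ndarray
    e_a: np.ndarray
    e_mc: np.ndarray
    delta_l: float
    delta_h: float
    delta_a: float


def group_deviations(group: LeafGroup, x: int) -> GroupStats:
    """Mean errors ``delta_l^k, delta_h^k, delta_a^k`` of an included group."""
    if not group.included:
        raise ValueError(f"group {group.k} has n_k={group.n_k} < 2 and is excluded")
    errs = np.array([leaf_errors(leaf, x) for leaf in group.members], dtype=np.float64)
    e_l, e_h, e_a, e_mc = errs.T
    return GroupStats(
        k=group.k, n_k=group.n_k, e_l=e_l, e_h=e_h, e_a=e_a, e_mc=e_mc,
        delta_l=float(e_l.mean()), delta_h=float(e_h.mean()), delta_a=float(e_a.mean()),
    )


def cohort_deviations(
    stats: Sequence[GroupStats],
) -> tuple[float, float, float, float]:
    """Cohort means and pooled SDs ``(delta_bar_l, delta_bar_h, sigma_dl, sigma_dh)``.

    ``delta_bar`` averages the group mean errors over the included groups;
    ``sigma`` pools the within-group sums of squares about each group's own
    mean with denominator ``sum(n_k - 1)``, so every leaf contributes and a
    single group reduces to its ordinary sample SD.
    """
    if not stats:
        raise ValueError("no included groups: cohort statistics undefined")
    delta_bar_l = float(np.mean([g.delta_l for g in stats]))
    delta_bar_h = float(np.mean([g.delta_h for g in stats]))
    ss_l = sum(float(((g.e_l - g.delta_l) ** 2).sum()) for g in stats)
    ss_h = sum(float(((g.e_h - g.delta_h) ** 2).sum()) for g in stats)
    dof = sum(g.n_k - 1 for g in stats)
    sigma_dl = math.sqrt(ss_l / dof) if dof > 0 else 0.0
    sigma_dh = math.sqrt(ss_h / dof) if dof > 0 else 0.0
    return delta_bar_l, delta_bar_h, sigma_dl, sigma_dh


def proportions(
    stats: Sequence[GroupStats],
    delta_bar_l: float,
    delta_bar_h: float,
    sigma_dl: float,
    sigma_dh: float,
) -> dict[str, float]:
    """Leaf-weighted band-acceptance and overestimation proportions.

    A group passes the length band iff
    ``delta_bar_l - sigma_dl <= delta_l^k <= delta_bar_l + sigma_dl``
    (width analogously).  All proportions are over leaves: a group's
    ``n_k`` leaves pass or fail with it.  ``lambda_a`` additionally
    requires the leaf's own ``e_a >= 0`` (area not overestimated);
    ``beta_a`` is the full complement.  The ``*_mc`` pair repeats the
    area condition with the Monte Carlo estimate.  The complements are
    counted directly (not via ``1 - lambda``) so the identities
    ``lambda + theta = 1`` and ``lambda + beta = 1`` are genuine checks.
    """
    n_total = sum(g.n_k for g in stats)
    if n_total == 0:
        raise ValueError("no leaves in the included groups")
    lo_l, hi_l = delta_bar_l - sigma_dl, delta_bar_l + sigma_dl
    lo_h, hi_h = delta_bar_h - sigma_dh, delta_bar_h + sigma_dh

    n_pass_l = n_fail_l = n_pass_h = n_fail_h = 0
    n_cons_a = n_over_a = n_cons_mc = n_over_mc = 0
    for g in stats:
        pass_l = lo_l <= g.delta_l <= hi_l
        pass_h = lo_h <= g.delta_h <= hi_h
        n_pass_l += g.n_k if pass_l else 0
        n_fail_l += 0 if pass_l else g.n_k
        n_pass_h += g.n_k if pass_h else 0
        n_fail_h += 0 if pass_h else g.n_k
        if pass_l and pass_h:
            ca = int(np.count_nonzero(g.e_a >= 0))
            cm = int(np.count_nonzero(g.e_mc >= 0))
            n_cons_a += ca
            n_over_a += g.n_k - ca
            n_cons_mc += cm
            n_over_mc += g.n_k - cm
        else:
            n_over_a += g.n_k
            n_over_mc += g.n_k
    return {
        "lambda_l": n_pass_l / n_total,
        "theta_l": n_fail_l / n_total,
        "lambda_h": n_pass_h / n_total,
        "theta_h": n_fail_h / n_total,
        "lambda_a": n_cons_a / n_total,
        "beta_a": n_over_a / n_total,
        "lambda_amc": n_cons_mc / n_total,
        "beta_amc": n_over_mc / n_total,
    }


def selection_index(lambda_a: float, beta_a: float) -> float:
    """The selection index ``IS_x = beta_a / lambda_a``.

    Smaller values indicate less area overestimation.  Undefined when no
    leaf is consistently estimated (``lambda_a = 0``): such a tolerance is
    inadmissible.
    """
    if lambda_a <= 0:
        raise ValueError("lambda_a = 0: selection index undefined (inadmissible tolerance)")
    if beta_a < 0:
        raise ValueError("beta_a must be nonnegative")
    return beta_a / lambda_a


def selection_index_mc(lambda_amc: float, beta_amc: float) -> float:
    """Monte Carlo variant ``IS_x^mc = beta_amc / lambda_amc``."""
    return selection_index(lambda_amc, beta_amc)


def rmsd(observed: Sequence[float], estimated: Sequence[float]) -> float:
    """Root-mean-square deviation between paired observed and estimated values."""
    obs = np.asarray(observed, dtype=np.float64)
    est = np.asarray(estimated, dtype=np.float64)
    if obs.shape != est.shape or obs.ndim != 1:
        raise ValueError("observed and estimated must be 1-d sequences of equal length")
    if obs.size == 0:
        raise ValueError("empty sequences")
    return float(np.sqrt(np.mean((obs - est) ** 2)))


# ---------------------------------------------------------------------------
# cohort statistics per tolerance


@dataclass(frozen=True)
class CohortStats:
    """All cohort-level statistics for one tolerance ``ST(x)``."""

    x: int
    n_leaves: int            # leaves in the included groups
    n_groups: int            # included groups
    n_flooded: int           # leaves whose region reached the frame
    delta_bar_l: float
    delta_bar_h: float
    sigma_dl: float
    sigma_dh: float
    lambda_l: float
    theta_l: float
    lambda_h: float
    theta_h: float
    lambda_a: float
    beta_a: float
    lambda_amc: float
    beta_amc: float
    is_x: float              # inf when inadmissible (lambda_a = 0)
    is_x_mc: float

    @property
    def admissible(self) -> bool:
        return math.isfinite(self.is_x)


def cohort_stats(groups: Sequence[LeafGroup], x: int) -> CohortStats:
    """Compute all statistics of one sweep row from grouped leaves."""
    cg = included_groups(groups)
    if not cg:
        raise ValueError("no group has two or more leaves: statistics impossible")
    gstats = [group_deviations(g, x) for g in cg]
    dbl, dbh, sdl, sdh = cohort_deviations(gstats)
    props = proportions(gstats, dbl, dbh, sdl, sdh)
    try:
        is_x = selection_index(props["lambda_a"], props["beta_a"])
    except ValueError:
        is_x = math.inf
    try:
        is_x_mc = selection_index_mc(props["lambda_amc"], props["beta_amc"])
    except ValueError:
        is_x_mc = math.inf
    n_leaves = sum(g.n_k for g in cg)
    n_flooded = sum(
        1 for g in cg for leaf in g.members if leaf.measurements[x].flooded
    )
    return CohortStats(
        x=x, n_leaves=n_leaves, n_groups=len(cg), n_flooded=n_flooded,
        delta_bar_l=dbl, delta_bar_h=dbh, sigma_dl=sdl, sigma_dh=sdh,
        is_x=is_x, is_x_mc=is_x_mc, **props,
    )


def measure_cohort(
    samples: Sequence,
    x_values: Sequence[int],
    upn: float | None = None,
    sampler: str = "grid",
    seed: int | None = None,
    width_mode: str = "midpoint",
) -> list[LeafRecord]:
    """Segment and measure every leaf at every tolerance.

    ``samples`` is a sequence of objects with attributes ``leaf_id``,
    ``image`` (:class:`~leafmetric.pixel_space.RasterImage`), ``seed_point``
    (pixel coordinate inside the leaf), ``l_o`` and ``h_o``.  The per-image
    edge distances are computed once and re-thresholded for each ``x``.
    ``upn`` defaults to twice the image scale ``unp``.  With the random
    sampler, each (leaf, x) pair draws from a stream derived from ``seed``.
    """
    records: list[LeafRecord] = []
    rng_root = np.random.default_rng(seed) if sampler == "random" else None
    for sample in samples:
        image: RasterImage = sample.image
        edges = edge_table(image)
        record = LeafRecord(leaf_id=str(sample.leaf_id), l_o=sample.l_o, h_o=sample.h_o)
        upn_i = 2 * image.unp if upn is None else upn
        for x in x_values:
            region = grow_region(image, sample.seed_point, x, edges=edges)
            sub_seed = int(rng_root.integers(2**31)) if rng_root is not None else None
            m = measure_region(
                region, upn_i, sampler=sampler, rng_seed=sub_seed, width_mode=width_mode
            )
            record.measurements[x] = m
            if m.flooded:
                logger.info("leaf %s flooded to the frame at x=%d", record.leaf_id, x)
        records.append(record)
    return records


def sweep_table(
    records: Sequence[LeafRecord],
    x_values: Sequence[int],
    partition: LengthPartition,
) -> pd.DataFrame:
    """One :class:`CohortStats` row per tolerance, as a DataFrame indexed by x."""
    groups, out = assign_groups(records, partition)
    rows = [cohort_stats(groups, x) for x in x_values]
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("x")
    df.attrs["out_of_range"] = [l.leaf_id for l in out]
    df.attrs["sigma_method"] = "pooled within-group SD, denominator sum(n_k - 1)"
    return df


def rmsd_table(records: Sequence[LeafRecord], x_values: Sequence[int]) -> pd.DataFrame:
    """Per-tolerance RMSD of observed vs image-derived width, length and areas."""
    rows = []
    for x in x_values:
        l_o = [r.l_o for r in records]
        h_o = [r.h_o for r in records]
        a_o = [r.a_o for r in records]
        l_d = [r.measurements[x].l_d for r in records]
        h_d = [r.measurements[x].h_d for r in records]
        a_d = [r.measurements[x].a_d for r in records]
        a_mc = [r.measurements[x].a_mc for r in records]
        rows.append({
            "x": x,
            "rmsd_h": rmsd(h_o, h_d),
            "rmsd_l": rmsd(l_o, l_d),
            "rmsd_a": rmsd(a_o, a_d),
            "rmsd_amc": rmsd(a_o, a_mc),
        })
    return pd.DataFrame(rows).set_index("x")


def select_optimal_st(table: pd.DataFrame) -> int:
    """The tolerance minimizing ``IS_x`` among admissible rows.

    Ties are broken toward the smallest ``x`` (the less noise-permissive
    tolerance).  Raises when every row is inadmissible.
    """
    if table.empty:
        raise ValueError("empty sweep table")
    admissible = table[np.isfinite(table["is_x"])]
    if admissible.empty:
        raise ValueError("every tolerance is inadmissible (lambda_a = 0 throughout)")
    best = admissible["is_x"].min()
    return int(admissible.index[admissible["is_x"] == best].min())
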