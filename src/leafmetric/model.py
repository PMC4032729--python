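"""Model/Results interface for the tolerance sweep and selection.

:class:`ToleranceSweepModel` bundles a cohort of leaf images with their
direct measurements and a set of candidate similarity tolerances; its
:meth:`~ToleranceSweepModel.fit` segments and measures every leaf at every
tolerance and returns a :class:`ToleranceSweepResults` carrying the per-
tolerance cohort statistics, the RMSD validation table, the selected
optimal tolerance, and a ``summary()`` in the familiar fitted-model style.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats_selection as ss
from .stats_selection import LengthPartition, build_partition, truncate


class ToleranceSweepModel:
    """Tolerance-of-similarity sweep over a cohort of leaf images.

    Parameters
    ----------
    samples : sequence
        Objects with ``leaf_id``, ``image``, ``seed_point``, ``l_o``, ``h_o``
        (e.g. :class:`~leafmetric.synth.LeafSample` or manifest rows).
    x_values : sequence of int
        Candidate tolerance bounds to sweep.
    q : float
        Length-group width in mm (default 10); the partition spans
        ``[0, l_max]`` with ``l_max`` the observed maximum rounded up to a
        multiple of ``q``, unless an explicit ``partition`` is given.
    upn : float, optional
        Monte Carlo sample points per unit length; default twice the image
        scale, which makes the grid estimator exact at pixel resolution.
    sampler : {"grid", "random"}
        Monte Carlo point placement; ``random`` requires ``seed``.
    """

    def __init__(
        self,
        samples: Sequence,
        x_values: Sequence[int],
        *,
        q: float = 10.0,
        partition: LengthPartition | None = None,
        upn: float | None = None,
        sampler: str = "grid",
        seed: int | None = None,
        width_mode: str = "midpoint",
    ):
        if not samples:
            raise ValueError("empty cohort")
        x_values = sorted(int(x) for x in x_values)
        if not x_values:
            raise ValueError("no tolerance values to sweep")
        if sampler == "random" and seed is None:
            raise ValueError("random sampler requires a seed")
        self.samples = list(samples)
        self.x_values = x_values
        if partition is None:
            l_max = max(s.l_o for s in self.samples)
            n = max(1, int(np.ceil(l_max / q)))
            partition = build_partition(n * q, n)
        self.partition = partition
        self.upn = upn
        self.sampler = sampler
        self.seed = seed
        self.width_mode = width_mode

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, x_values: Sequence[int], **kw):
        """Build the model from a manifest CSV of images and observations."""
        from .io import read_manifest

        return cls(read_manifest(manifest_path), x_values, **kw)

    def fit(self) -> "ToleranceSweepResults":
        """Segment, measure and score the cohort at every tolerance."""
        records = ss.measure_cohort(
            self.samples, self.x_values, upn=self.upn,
            sampler=self.sampler, seed=self.seed, width_mode=self.width_mode,
        )
        table = ss.sweep_table(records, self.x_values, self.partition)
        rmsd = ss.rmsd_table(records, self.x_values)
        x_opt = ss.select_optimal_st(table)
        return ToleranceSweepResults(self, records, table, rmsd, x_opt)


@dataclass
class ToleranceSweepResults:
    """Fitted sweep: per-tolerance statistics and the selected tolerance."""

    model: ToleranceSweepModel
    records: list
    table: pd.DataFrame
    rmsd: pd.DataFrame
    x_opt: int

    @property
    def is_opt(self) -> float:
        return float(self.table.loc[self.x_opt, "is_x"])

    @property
    def is_opt_mc(self) -> float:
        return float(self.table.loc[self.x_opt, "is_x_mc"])

    def report(self) -> dict:
        """Machine-readable selection report."""
        row = self.table.loc[self.x_opt]
        return {
            "x_opt": int(self.x_opt),
            "is_x": float(row["is_x"]),
            "is_x_mc": float(row["is_x_mc"]),
            "lambda_a": float(row["lambda_a"]),
            "beta_a": float(row["beta_a"]),
            "n_leaves": int(row["n_leaves"]),
            "n_groups": int(row["n_groups"]),
            "x_values": list(self.model.x_values),
            "partition": {
                "l_max": self.model.partition.l_max,
                "n": self.model.partition.n,
                "q": self.model.partition.q,
            },
            "sigma_method": "pooled within-group SD, denominator sum(n_k - 1)",
            "sampler": self.model.sampler,
            "seed": self.model.seed,
        }

    def summary(self, truncate_display: bool = True) -> str:
        """Human-readable sweep summary table."""
        df = self.table[[
            "delta_bar_h", "sigma_dh", "delta_bar_l", "sigma_dl",
            "theta_l", "theta_h", "lambda_l", "lambda_h",
            "lambda_a", "beta_a", "is_x", "lambda_amc", "beta_amc", "is_x_mc",
        ]].copy()
        if truncate_display:
            for col in ("is_x", "is_x_mc"):
                df[col] = [
                    truncate(v) if np.isfinite(v) else np.inf for v in df[col]
                ]
        lines = [
            "Tolerance-of-similarity sweep",
            "=" * 72,
            f"leaves: {len(self.records)}   groups (n_k >= 2): "
            f"{int(self.table['n_groups'].iloc[0])}   "
            f"partition: q={self.model.partition.q:g} mm, n={self.model.partition.n}",
            df.round(4).to_string(),
            "-" * 72,
            f"selected ST(x): x* = {self.x_opt}   "
            f"IS = {self.is_opt:.4f}   IS_mc = {self.is_opt_mc:.4f}",
        ]
        return "\n".join(lines)

    def write_outputs(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the statistics CSV, RMSD CSV and selection report JSON."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "stats": out / "sweep_stats.csv",
            "rmsd": out / "rmsd.csv",
            "report": out / "selection_report.json",
        }
        self.table.to_csv(paths["stats"])
        self.rmsd.to_csv(paths["rmsd"])
        paths["report"].write_text(json.dumps(self.report(), indent=1))
        return paths
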