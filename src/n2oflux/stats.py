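"""Sweep execution and attached-versus-free-living uptake statistics.

Reproduces the study-level summaries: per-gap uptake profiles normalized to
the attached (d = 0) configuration of the same producer/consumer size
combination, fractional reductions for gap pairs 0 -> 0.1 um and 0 -> 2 um,
and the fold change in attached volume-normalized uptake between consumer-
to-producer radius ratios of about 0.1 and about 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analytic, fdsolver
from .scenarios import Scenario, SweepGrid

TABLE_COLUMNS = [
    "scenario_id",
    "producer_radius_um",
    "consumer_radius_um",
    "gap_um",
    "domain_side_um",
    "diffusivity",
    "absolute_uptake",
    "volume_normalized_uptake",
    "engine",
    "converged",
    "iterations",
]

#: Relative tolerance for mapping the "~0.1" and "~1" ratio endpoints onto grid ratios.
RATIO_ENDPOINT_RTOL = 0.3


class AggregationError(RuntimeError):
    """Raised when a summary is requested over flagged (non-converged) rows."""


def run_sweep(
    grid: SweepGrid,
    engine: str = "analytic",
    tolerance: float | None = None,
    fd_spacings: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Run every scenario of a sweep through one engine.

    Returns one row per scenario in sweep order.  Failures are recorded as
    flagged rows (converged = False, NaN uptake), never dropped silently.
    ``engine`` is ``analytic``, or ``fd`` with one or more grid spacings
    (two or more spacings trigger Richardson extrapolation).
    """
    if len(grid) == 0:
        raise ValueError("sweep is empty")
    if engine not in ("analytic", "fd"):
        raise ValueError(f"unknown engine {engine!r}; expected 'analytic' or 'fd'")
    if engine == "fd" and not fd_spacings:
        raise ValueError("engine 'fd' requires fd_spacings")
    rows = []
    for scenario in grid.scenarios:
        try:
            if engine == "analytic":
                kwargs = {} if tolerance is None else {"tolerance": tolerance}
                res = analytic.solve_scenario(scenario, **kwargs)
            elif len(fd_spacings) == 1:
                res = fdsolver.solve_scenario_fd(scenario, fd_spacings[0])
            else:
                res = fdsolver.refine_and_extrapolate(scenario, fd_spacings)
            rows.append(
                (
                    scenario.scenario_id,
                    scenario.producer_radius,
                    scenario.consumer_radius,
                    scenario.gap,
                    scenario.domain_side,
                    scenario.diffusivity,
                    res.absolute_uptake,
                    res.volume_normalized_uptake,
                    res.engine,
                    True,
                    res.iterations,
                )
            )
        except (analytic.ConvergenceError, fdsolver.SolverError, fdsolver.ResolutionError):
            rows.append(
                (
                    scenario.scenario_id,
                    scenario.producer_radius,
                    scenario.consumer_radius,
                    scenario.gap,
                    scenario.domain_side,
                    scenario.diffusivity,
                    math.nan,
                    math.nan,
                    engine,
                    False,
                    0,
                )
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if table["scenario_id"].duplicated().any():
        raise ValueError("duplicate scenario_ids in sweep")
    return table


def fold_reduction(reference_uptake: float, uptake: float) -> float:
    """Fractional reduction 1 - uptake/reference (negative if uptake exceeds it)."""
    if not reference_uptake > 0:
        raise ValueError(f"reference uptake must be > 0, got {reference_uptake}")
    if uptake < 0:
        raise ValueError(f"uptake must be >= 0, got {uptake}")
    return 1.0 - uptake / reference_uptake


def _check_converged(table: pd.DataFrame) -> None:
    if not table["converged"].all():
        bad = table.loc[~table["converged"], "scenario_id"].tolist()
        raise AggregationError(f"refusing to aggregate flagged rows: {bad}")


def distance_profile(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uptake(gap)/uptake(0) per size combination, plus per-gap mean and s.d.

    Returns ``(curves, per_gap)``: ``curves`` holds one normalized value per
    (producer, consumer, gap); ``per_gap`` aggregates across size
    combinations with columns mean, sd (and the +-2 s.d. whisker bounds,
    matching a box of +-1 s.d. with whiskers at +-2 s.d.).
    """
    _check_converged(table)
    curves = []
    for (R, r), sub in table.groupby(["producer_radius_um", "consumer_radius_um"]):
        attached = sub.loc[sub["gap_um"] == 0.0, "absolute_uptake"]
        if attached.empty:
            raise ValueError(f"no attached (gap 0) row for combination R={R}, r={r}")
        ref = float(attached.iloc[0])
        for _, row in sub.iterrows():
            curves.append(
                (R, r, row["gap_um"], row["absolute_uptake"] / ref)
            )
    curves_df = pd.DataFrame(
        curves,
        columns=["producer_radius_um", "consumer_radius_um", "gap_um", "normalized_uptake"],
    ).sort_values(["producer_radius_um", "consumer_radius_um", "gap_um"], ignore_index=True)
    grouped = curves_df.groupby("gap_um")["normalized_uptake"]
    per_gap = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sd": grouped.std(ddof=1),
            "n": grouped.size(),
        }
    )
    per_gap["whisker_low"] = per_gap["mean"] - 2 * per_gap["sd"]
    per_gap["whisker_high"] = per_gap["mean"] + 2 * per_gap["sd"]
    return curves_df, per_gap


def attached_ratio_curve(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[float, float]]:
    """Attached volume-normalized uptake versus radius ratio r/R.

    Returns the (ratio, volume-normalized uptake) points sorted by ratio and,
    per producer radius, the least-squares power-law exponent of
    volume-normalized uptake versus consumer radius (theory: -2, since
    absolute uptake scales like r while volume scales like r^3).
    """
    _check_converged(table)
    attached = table[table["gap_um"] == 0.0].copy()
    if attached.empty:
        raise ValueError("no attached (gap 0) rows in table")
    attached["ratio"] = attached["consumer_radius_um"] / attached["producer_radius_um"]
    points = attached[
        ["ratio", "volume_normalized_uptake", "producer_radius_um", "consumer_radius_um"]
    ].sort_values("ratio", ignore_index=True)
    exponents: dict[float, float] = {}
    for R, sub in attached.groupby("producer_radius_um"):
        if len(sub) >= 2:
            slope = np.polyfit(
                np.log(sub["consumer_radius_um"]), np.log(sub["volume_normalized_uptake"]), 1
            )[0]
            exponents[float(R)] = float(slope)
    return points, exponents


@dataclass(frozen=True)
class SummaryReport:
    """Study-level summary of a default-structure sweep."""

    mean_reduction_0_to_0p1: float
    mean_reduction_0_to_2: float
    max_reduction_0_to_2: float
    min_reduction_0_to_0p1: float
    max_reduction_0_to_0p1: float
    min_reduction_0_to_2: float
    attached_fold_ratio_0p1_to_1: float
    ratio_pairs_used: tuple[dict, ...]
    per_gap_normalized_mean: dict[float, float]
    per_gap_normalized_sd: dict[float, float]
    engine: str
    n_combinations: int

    def to_dict(self) -> dict:
        d = {
            "mean_reduction_0_to_0p1": self.mean_reduction_0_to_0p1,
            "mean_reduction_0_to_2": self.mean_reduction_0_to_2,
            "max_reduction_0_to_2": self.max_reduction_0_to_2,
            "min_reduction_0_to_0p1": self.min_reduction_0_to_0p1,
            "max_reduction_0_to_0p1": self.max_reduction_0_to_0p1,
            "min_reduction_0_to_2": self.min_reduction_0_to_2,
            "attached_fold_ratio_0p1_to_1": self.attached_fold_ratio_0p1_to_1,
            "ratio_pairs_used": list(self.ratio_pairs_used),
            "per_gap_normalized_mean": {str(k): v for k, v in self.per_gap_normalized_mean.items()},
            "per_gap_normalized_sd": {str(k): v for k, v in self.per_gap_normalized_sd.items()},
            "engine": self.engine,
            "n_combinations": self.n_combinations,
        }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _reduction_stats(table: pd.DataFrame, gap: float) -> np.ndarray:
    reductions = []
    for (R, r), sub in table.groupby(["producer_radius_um", "consumer_radius_um"]):
        ref = sub.loc[sub["gap_um"] == 0.0, "absolute_uptake"]
        val = sub.loc[sub["gap_um"] == gap, "absolute_uptake"]
        if ref.empty or val.empty:
            raise ValueError(
                f"combination R={R}, r={r} lacks gap 0 or gap {gap} rows"
            )
        reductions.append(fold_reduction(float(ref.iloc[0]), float(val.iloc[0])))
    return np.asarray(reductions)


def summarize(table: pd.DataFrame, ratio_endpoints: tuple[float, float] = (0.1, 1.0)) -> SummaryReport:
    """Compute the headline attached-vs-free-living statistics of a sweep.

    Requires a default-structure sweep: every size combination present at
    every gap including 0, 0.1 and 2 um.  The ratio fold change maps the
    endpoint ratios (default ~0.1 and ~1) to the nearest grid ratios within
    30% relative tolerance and averages over producers admitting both.
    """
    _check_converged(table)
    red01 = _reduction_stats(table, 0.1)
    red2 = _reduction_stats(table, 2.0)

    attached = table[table["gap_um"] == 0.0].copy()
    attached["ratio"] = attached["consumer_radius_um"] / attached["producer_radius_um"]
    lo_target, hi_target = ratio_endpoints
    folds = []
    pairs = []
    for R, sub in attached.groupby("producer_radius_um"):
        ratios = sub["ratio"].to_numpy()
        lo_idx = int(np.argmin(np.abs(ratios - lo_target)))
        hi_idx = int(np.argmin(np.abs(ratios - hi_target)))
        lo_ok = abs(ratios[lo_idx] - lo_target) <= RATIO_ENDPOINT_RTOL * lo_target
        hi_ok = abs(ratios[hi_idx] - hi_target) <= RATIO_ENDPOINT_RTOL * hi_target
        if lo_ok and hi_ok and lo_idx != hi_idx:
            v = sub["volume_normalized_uptake"].to_numpy()
            folds.append(v[lo_idx] / v[hi_idx])
            pairs.append(
                {
                    "producer_radius_um": float(R),
                    "ratio_low": float(ratios[lo_idx]),
                    "ratio_high": float(ratios[hi_idx]),
                    "fold": float(v[lo_idx] / v[hi_idx]),
                }
            )
    if not folds:
        raise ValueError(
            f"no producer admits both ratio endpoints ~{lo_target} and ~{hi_target}"
        )
    _, per_gap = distance_profile(table)
    engines = table["engine"].unique()
    return SummaryReport(
        mean_reduction_0_to_0p1=float(red01.mean()),
        mean_reduction_0_to_2=float(red2.mean()),
        max_reduction_0_to_2=float(red2.max()),
        min_reduction_0_to_0p1=float(red01.min()),
        max_reduction_0_to_0p1=float(red01.max()),
        min_reduction_0_to_2=float(red2.min()),
        attached_fold_ratio_0p1_to_1=float(np.mean(folds)),
        ratio_pairs_used=tuple(pairs),
        per_gap_normalized_mean={float(g): float(v) for g, v in per_gap["mean"].items()},
        per_gap_normalized_sd={float(g): float(v) for g, v in per_gap["sd"].items()},
        engine=str(engines[0]) if len(engines) == 1 else "mixed",
        n_combinations=int(table.groupby(["producer_radius_um", "consumer_radius_um"]).ngroups),
    )
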