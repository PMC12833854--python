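"""Localized tumor-growth-rate (TGR) matrices over all time-point pairs.

For two measurement days x < y the localized rate is
r_{x→y} = ln(N_y/N_x)/(t_y − t_x), the exponential rate that would carry the
burden from N_x to N_y. Computed for every ordered pair of usable days these
rates form an upper-triangular matrix — n(n−1)/2 intervals for n days —
mapping when a treatment acts rather than just whether it acts overall.

Matrices are keyed by day values (not indices), so animals measured on a
subset of the study grid align correctly. Rates telescope exactly on a single
animal's data: r_{x→z}·(t_z−t_x) = r_{x→y}·(t_y−t_x) + r_{y→z}·(t_z−t_y).

Rates are binned for display into five classes (day⁻¹): high r > 0.25,
medium 0.15–0.25, low 0.10–0.15, very low 0.05–0.10, minimal r < 0.05.
Lower bounds are inclusive; "high" is strictly above 0.25.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from tgrkit.model import AnimalSeries


@dataclass
class TGRMatrix:
    """Upper-triangular map (x_day, y_day) → rate, for one animal or a group."""

    days: tuple[float, ...]
    rates: dict[tuple[float, float], float] = field(default_factory=dict)
    owner: str = ""
    aggregated: bool = False

    def get(self, x_day: float, y_day: float) -> Optional[float]:
        return self.rates.get((x_day, y_day))

    def diagonal_pairs(self) -> list[tuple[float, float]]:
        """Consecutive-day intervals: the only mutually data-disjoint ones."""
        return list(zip(self.days, self.days[1:]))


#: display bins (label, lower bound inclusive, upper bound) per the five-color scheme
RATE_CLASS_BOUNDS: Sequence[tuple[str, float, float]] = (
    ("minimal", -math.inf, 0.05),
    ("very_low", 0.05, 0.10),
    ("low", 0.10, 0.15),
    ("medium", 0.15, 0.25),
    ("high", 0.25, math.inf),
)


def classify_rate(r: float) -> str:
    """Five-class display bin for a rate (day⁻¹).

    Boundary convention: lower bound inclusive, upper exclusive, except that
    "high" means strictly r > 0.25 — so 0.25 itself is medium.
    """
    if not math.isfinite(r):
        raise ValueError("rate must be finite")
    if r > 0.25:
        return "high"
    if r >= 0.15:
        return "medium"
    if r >= 0.10:
        return "low"
    if r >= 0.05:
        return "very_low"
    return "minimal"


def tgr_rate(N_x: float, N_y: float, t_x: float, t_y: float) -> float:
    """Localized growth rate ln(N_y/N_x)/(t_y − t_x) in day⁻¹."""
    if N_x <= 0 or N_y <= 0:
        raise ValueError("burdens must be positive for a log-ratio rate")
    if t_y <= t_x:
        raise ValueError("t_y must exceed t_x")
    return math.log(N_y / N_x) / (t_y - t_x)


def interval_count(n_timepoints: int) -> int:
    """Number of ordered day pairs: n(n−1)/2."""
    if n_timepoints < 0:
        raise ValueError("n_timepoints must be non-negative")
    return n_timepoints * (n_timepoints - 1) // 2


def build_animal_matrix(series: AnimalSeries, days: Optional[Sequence[float]] = None) -> TGRMatrix:
    """TGR matrix for one animal over every pair of usable days.

    Pairs touching missing, excluded or non-positive values are absent.
    ``days`` fixes the matrix grid (defaults to the animal's own days) so
    per-animal matrices can share a study-wide grid.
    """
    usable = series.usable_measurements()
    grid = tuple(days) if days is not None else tuple(m.day for m in series.measurements)
    matrix = TGRMatrix(days=grid, owner=series.animal_id)
    if len(usable) < 2:
        warnings.warn(
            f"animal {series.animal_id!r}: fewer than 2 usable points; "
            "empty TGR matrix", stacklevel=2)
        return matrix
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            matrix.rates[(a.day, b.day)] = tgr_rate(a.value, b.value, a.day, b.day)
    return matrix


def aggregate_group_matrix(
    matrices: Sequence[TGRMatrix], method: str = "mean", owner: str = ""
) -> TGRMatrix:
    """Entrywise mean or median across animals possessing each interval.

    Display-only: group statistics always run on the per-animal rates, never
    on this aggregate.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    grids = {m.days for m in matrices}
    if len(grids) > 1:
        raise ValueError("matrices do not share a day grid")
    agg = TGRMatrix(days=matrices[0].days, owner=owner, aggregated=True)
    keys = set()
    for m in matrices:
        keys.update(m.rates)
    reduce = np.mean if method == "mean" else np.median
    for key in keys:
        vals = [m.rates[key] for m in matrices if key in m.rates]
        agg.rates[key] = float(reduce(vals))
    return agg
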