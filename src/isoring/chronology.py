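"""Dating of tree-ring subsections and multi-tree averaging.

Xylogenesis growth curves map calendar dates to relative ring position:
the formation curve gives the date a position begins forming (cell
enlargement onset) and the maturation curve the date its wall thickening
completes.  A subsection's time window runs from the date formation
reaches its relative start to the date maturation reaches its relative
end, the latter capped at relative position 0.97 because full-ring
maturation dates extend far into the winter.

The multi-tree mean series is built by densifying each tree's subsection
series onto a 0.001 relative-position grid (subsection values inside
subsections, linear interpolation between them, edge fill outside) and
averaging the trees within equal-width bins whose count equals the
rounded mean subsection count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurves",
    "Subsection",
    "TimeWindow",
    "MeanRingSeries",
    "MATURATION_CAP",
    "window_for_subsection",
    "shift_window",
    "interpolate_tree_series",
    "mean_ring_series",
    "REL_GRID",
]

#: Relative ring position beyond which maturation dates are not trusted.
MATURATION_CAP = 0.97

#: Centers of the 0.001-resolution relative-position grid.
REL_GRID = (np.arange(1000) + 0.5) / 1000.0


@dataclass(frozen=True)
class GrowthCurves:
    """Daily formation and maturation curves for one year.

    Both curves map day-of-year to relative ring position in [0, 1],
    monotone non-decreasing, with maturation <= formation pointwise (a
    position can only mature after it has formed).
    """

    year: int
    doy: np.ndarray
    formation: np.ndarray
    maturation: np.ndarray

    def __post_init__(self) -> None:
        f, m = np.asarray(self.formation), np.asarray(self.maturation)
        if np.any(np.diff(self.doy) <= 0):
            raise ValueError("doy must be strictly increasing")
        if np.any(np.diff(f) < -1e-12) or np.any(np.diff(m) < -1e-12):
            raise ValueError("growth curves must be monotone non-decreasing")
        if np.any(m > f + 1e-12):
            raise ValueError("maturation must not exceed formation")
        if f.min() < -1e-12 or f.max() > 1 + 1e-12:
            raise ValueError("curve range must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "doy": self.doy,
                "formation_rel": self.formation,
                "maturation_rel": self.maturation,
            }
        )


@dataclass(frozen=True)
class Subsection:
    """One measured tree-ring subsection."""

    tree_id: str
    year: int
    rel_start: float
    rel_end: float
    value_permil: float
    isotope: str = "O"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_start < self.rel_end <= 1.0 + 1e-12:
            raise ValueError("need 0 <= rel_start < rel_end <= 1")


@dataclass(frozen=True)
class TimeWindow:
    """Formation-to-maturation window of a subsection, in whole days.

    ``start_doy``/``end_doy`` are inclusive day-of-year bounds (start
    floored, end ceiled from the interpolated curve crossings).
    """

    year: int
    start_doy: int
    end_doy: int
    capped: bool = False

    def __post_init__(self) -> None:
        # end is inclusive, so start == end is a valid one-day window
        if self.start_doy > self.end_doy:
            raise ValueError(
                f"degenerate window: start {self.start_doy} > end {self.end_doy}"
            )

    @property
    def center_doy(self) -> float:
        return 0.5 * (self.start_doy + self.end_doy)

    @property
    def length_days(self) -> int:
        return self.end_doy - self.start_doy + 1


@dataclass(frozen=True)
class MeanRingSeries:
    """Binned multi-tree mean isotope series for one year."""

    year: int
    edges: np.ndarray          # bin boundaries in relative position, length n+1
    values: np.ndarray         # mean ‰ per bin
    n_trees: np.ndarray        # contributing trees per bin
    isotope: str = "O"


def _first_crossing(doy: np.ndarray, curve: np.ndarray, threshold: float) -> float:
    """Date (fractional doy) at which a monotone curve first reaches threshold.

    Linear interpolation between daily points; on flat segments the first
    date reaching the threshold is returned.  Thresholds at 0 use the
    first strictly positive curve value (the date growth starts).
    """
    if threshold <= 0.0:
        idx = np.flatnonzero(curve > 0.0)
        if idx.size == 0:
            raise ValueError("curve never starts (all zero)")
        i = idx[0]
        return float(doy[i - 1]) if i > 0 else float(doy[0])
    idx = np.flatnonzero(curve >= threshold)
    if idx.size == 0:
        raise ValueError(f"curve never reaches relative position {threshold}")
    i = idx[0]
    if i == 0:
        return float(doy[0])
    v0, v1 = curve[i - 1], curve[i]
    d0, d1 = doy[i - 1], doy[i]
    return float(d0 + (threshold - v0) / (v1 - v0) * (d1 - d0))


def window_for_subsection(
    curves: GrowthCurves, rel_start: float, rel_end: float
) -> TimeWindow:
    """Date a subsection: formation start to (capped) maturation end.

    Start is the first date the formation curve reaches ``rel_start``
    (floored to a day); end is the first date the maturation curve
    reaches ``min(rel_end, 0.97)`` (ceiled to a day).
    """
    if not rel_start < rel_end:
        raise ValueError("rel_start must be < rel_end")
    target_end = min(rel_end, MATURATION_CAP)
    start = _first_crossing(curves.doy, curves.formation, rel_start)
    end = _first_crossing(curves.doy, curves.maturation, target_end)
    return TimeWindow(
        year=curves.year,
        start_doy=int(math.floor(start)),
        end_doy=int(math.ceil(end)),
        capped=rel_end > MATURATION_CAP,
    )


def shift_window(
    window: TimeWindow,
    d_formation: float,
    d_maturation: float,
    max_shift: float = 20.0,
) -> TimeWindow:
    """Shift formation (start) and maturation (end) dates by whole days.

    Raises on shifts beyond ``max_shift`` or if the shifted window
    inverts (start >= end).
    """
    if abs(d_formation) > max_shift or abs(d_maturation) > max_shift:
        raise ValueError(f"shift exceeds configured bound of {max_shift} days")
    start = window.start_doy + int(round(d_formation))
    end = window.end_doy + int(round(d_maturation))
    if start > end:
        raise ValueError(
            f"degenerate window after shift: start {start} > end {end}"
        )
    return TimeWindow(window.year, start, end, window.capped)


def interpolate_tree_series(subsections: list[Subsection]) -> np.ndarray:
    """Densify one tree's subsection series onto the 0.001 grid.

    Grid points inside a subsection take its measured value; gaps between
    subsections are linearly interpolated between the neighboring
    subsection values (anchored at the facing subsection edges); leading
    and trailing gaps take the first/last subsection value.
    """
    if not subsections:
        raise ValueError("need at least one subsection")
    subs = sorted(subsections, key=lambda s: s.rel_start)
    for a, b in zip(subs, subs[1:]):
        if b.rel_start < a.rel_end - 1e-12:
            raise ValueError(
                f"overlapping subsections: [{a.rel_start}, {a.rel_end}] and "
                f"[{b.rel_start}, {b.rel_end}]"
            )
    out = np.full_like(REL_GRID, np.nan)
    # values inside subsections
    for s in subs:
        mask = (REL_GRID >= s.rel_start) & (REL_GRID < s.rel_end)
        out[mask] = s.value_permil
    # interior gaps: linear between facing subsection edges
    for a, b in zip(subs, subs[1:]):
        gap = (REL_GRID >= a.rel_end) & (REL_GRID < b.rel_start)
        if gap.any():
            frac = (REL_GRID[gap] - a.rel_end) / (b.rel_start - a.rel_end)
            out[gap] = a.value_permil + frac * (b.value_permil - a.value_permil)
    # leading / trailing fill
    out[REL_GRID < subs[0].rel_start] = subs[0].value_permil
    out[REL_GRID >= subs[-1].rel_end] = subs[-1].value_permil
    return out


def mean_ring_series(
    trees: dict[str, list[Subsection]],
    year: int,
    isotope: str = "O",
    n_bins: int | None = None,
) -> MeanRingSeries:
    """Average several trees' dense series into the year's mean ring series.

    The resolution (bin count) defaults to the rounded mean subsection
    count over trees; equal-width bins tile [0, 1] and each bin's value
    is the mean of all trees' grid values falling inside it.
    """
    if not trees:
        raise ValueError("need at least one tree")
    dense = np.vstack([interpolate_tree_series(subs) for subs in trees.values()])
    if n_bins is None:
        n_bins = int(round(float(np.mean([len(s) for s in trees.values()]))))
    n_bins = max(n_bins, 1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.minimum((REL_GRID * n_bins).astype(int), n_bins - 1)
    values = np.array(
        [dense[:, bin_idx == b].mean() for b in range(n_bins)]
    )
    counts = np.array(
        [
            sum(
                any(s.rel_start < edges[b + 1] and s.rel_end > edges[b] for s in subs)
                for subs in trees.values()
            )
            for b in range(n_bins)
        ]
    )
    return MeanRingSeries(year=year, edges=edges, values=values, n_trees=counts, isotope=isotope)


def mean_series_subsections(series: MeanRingSeries, tree_id: str = "mean") -> list[Subsection]:
    """View a mean ring series as subsections (for dating and analysis)."""
    return [
        Subsection(
            tree_id=tree_id,
            year=series.year,
            rel_start=float(series.edges[i]),
            rel_end=float(series.edges[i + 1]),
            value_permil=float(series.values[i]),
            isotope=series.isotope,
        )
        for i in range(len(series.values))
    ]
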