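"""Stacked species richness maps and their paired comparisons.

Richness is the cell-wise count of species whose binarized ranges include
a cell (species complexes count as single modeled units).  Two richness
surfaces are compared at randomly selected points with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid
from .projection import BinaryRange


@dataclass
class RichnessMap:
    """Integer species-count grid with provenance."""

    grid: Grid
    counts: np.ndarray
    scenario: str = ""
    threshold: str = ""
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")


def stack_richness(ranges: list[BinaryRange], scenario: str = "",
                   threshold: str = "") -> RichnessMap:
    """Cell-wise sum of 0/1 ranges.  Conservation holds exactly:
    total richness over cells equals the sum of the species' areas."""
    if not ranges:
        raise ValueError("need at least one range to stack")
    grid = ranges[0].grid
    counts = np.zeros(grid.shape, dtype=int)
    for r in ranges:
        grid.require_same(r.grid)
        counts += r.mask
    return RichnessMap(grid=grid, counts=counts, scenario=scenario,
                       threshold=threshold,
                       species=tuple(r.species for r in ranges))


@dataclass
class RichnessComparison:
    """Paired t-test of two richness surfaces at sampled points.

    When every per-point difference is identical the t statistic is
    undefined; ``degenerate`` is then True and ``t``/``p`` are None.
    """

    t: float | None
    p: float | None
    mean_diff: float
    n_points: int
    degenerate: bool
    points: pd.DataFrame


def compare_richness_at_points(
    map_a: RichnessMap,
    map_b: RichnessMap,
    n_points: int = 250,
    seed: int = 0,
    frame_mask: np.ndarray | None = None,
) -> RichnessComparison:
    """Sample ``n_points`` cells without replacement (uniformly over the
    analysis frame, default the whole grid) and run a two-sided paired
    t-test on the per-point richness differences (A minus B)."""
    map_a.grid.require_same(map_b.grid)
    if n_points < 2:
        raise ValueError("need at least 2 comparison points")
    if frame_mask is None:
        frame = np.ones(map_a.grid.shape, dtype=bool)
    else:
        frame = np.asarray(frame_mask, dtype=bool)
        if frame.shape != map_a.grid.shape:
            raise ValueError("frame mask shape does not match grid")
    cells = np.flatnonzero(frame)
    if n_points > len(cells):
        raise ValueError("more comparison points than frame cells")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(cells, size=n_points, replace=False))
    rows, cols = np.divmod(chosen, map_a.grid.n_cols)
    a = map_a.counts[rows, cols].astype(float)
    b = map_b.counts[rows, cols].astype(float)
    diff = a - b
    lon, lat = map_a.grid.cell_center(rows, cols)
    points = pd.DataFrame({
        "point_id": np.arange(n_points), "lon": lon, "lat": lat,
        "richness_a": a, "richness_b": b, "diff": diff,
    })
    mean_diff = float(diff.mean())
    sd = diff.std(ddof=1)
    if sd == 0:
        return RichnessComparison(t=None, p=None, mean_diff=mean_diff,
                                  n_points=n_points, degenerate=True,
                                  points=points)
    t = mean_diff / (sd / np.sqrt(n_points))
    p = 2 * stats.t.sf(abs(t), df=n_points - 1)
    return RichnessComparison(t=float(t), p=float(p), mean_diff=mean_diff,
                              n_points=n_points, degenerate=False,
                              points=points)
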