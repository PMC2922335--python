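"""Binary ranges: thresholding, dispersal-buffer clipping and change metrics.

Continuous suitability surfaces become presence/absence maps under two
rules — a strict fixed cumulative cutoff of 10 and a liberal minimum
training presence — and projected maps are clipped by the documented range
dilated by a fixed dispersal buffer (10 km by default) before habitat
change is quantified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from .grid import EARTH_RADIUS_KM, Grid

if TYPE_CHECKING:  # pragma: no cover
    from .maxent import SuitabilitySurface


@dataclass
class BinaryRange:
    """A 0/1 presence grid with provenance."""

    grid: Grid
    mask: np.ndarray
    species: str = ""
    scenario: str = ""
    threshold_rule: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def area(self) -> int:
        """Suitable-cell count (unweighted; the grid has fixed cell size)."""
        return int(self.mask.sum())

    def area_weighted(self) -> float:
        """Cosine-latitude-weighted area (sensitivity-check variant), in
        units of equatorial cells."""
        _, lat = self.grid.cell_centers()
        return float((self.mask * np.cos(np.radians(lat))).sum())


@dataclass(frozen=True)
class ThresholdRule:
    """Binarization rule.

    kind='strict'  -> suitable iff cumulative >= ``cumulative_cutoff`` (10).
    kind='liberal' -> suitable iff score >= minimum training presence score
                      (scale-free: any monotone output scale gives the same
                      map; raw is used internally).
    """

    kind: str
    cumulative_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "liberal"):
            raise ValueError("kind must be 'strict' or 'liberal'")


STRICT = ThresholdRule("strict")
LIBERAL = ThresholdRule("liberal")


@dataclass(frozen=True)
class ChangeRecord:
    """Habitat change for one species under one scenario.

    percent_change = 100 * (current - future) / current: positive is loss,
    negative is gain; never exceeds 100.
    """

    species: str
    gcm: str
    co2: str
    year: int
    threshold: str
    current_area: int
    future_area: int
    percent_change: float


def binarize(
    surface: "SuitabilitySurface",
    rule: ThresholdRule,
    training_presence_scores: np.ndarray | None = None,
    species: str = "",
    scenario: str = "",
) -> BinaryRange:
    """Threshold a suitability surface into a presence/absence map.

    The liberal rule needs the raw scores at the training presences; by
    construction every training presence cell is then suitable on the
    training surface.
    """
    if rule.kind == "strict":
        mask = surface.cumulative >= rule.cumulative_cutoff
    else:
        if training_presence_scores is None or len(training_presence_scores) == 0:
            raise ValueError("liberal rule requires training presence scores")
        mask = surface.raw >= np.min(training_presence_scores)
    mask = mask & surface.valid
    return BinaryRange(grid=surface.grid, mask=mask, species=species,
                       scenario=scenario, threshold_rule=rule.kind)


def buffer_mask(known: BinaryRange, distance_km: float) -> BinaryRange:
    """Dilate a range so every cell center within ``distance_km``
    (great-circle) of a range cell center is included.

    Distances are evaluated on the sphere via chordal nearest-neighbour
    search (monotone in arc length, so the cutoff is exact).
    """
    if distance_km < 0:
        raise ValueError("buffer distance must be nonnegative")
    if distance_km == 0 or known.area == 0 or known.mask.all():
        return BinaryRange(grid=known.grid, mask=known.mask.copy(),
                           species=known.species, scenario=known.scenario,
                           threshold_rule=f"{known.threshold_rule}+buffer{distance_km:g}km")
    lon, lat = known.grid.cell_centers()
    xyz = _to_unit_xyz(lon.ravel(), lat.ravel())
    src = xyz[known.mask.ravel()]
    chord = 2 * np.sin(min(distance_km / EARTH_RADIUS_KM, np.pi) / 2)
    tree = cKDTree(src)
    dist, _ = tree.query(xyz, k=1)
    mask = (dist <= chord * EARTH_RADIUS_KM).reshape(known.grid.shape)
    return BinaryRange(grid=known.grid, mask=mask | known.mask,
                       species=known.species, scenario=known.scenario,
                       threshold_rule=f"{known.threshold_rule}+buffer{distance_km:g}km")


def _to_unit_xyz(lon, lat) -> np.ndarray:
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return EARTH_RADIUS_KM * np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def clip(range_: BinaryRange, mask: BinaryRange) -> BinaryRange:
    """Cell-wise AND of a range with a (buffered known-range) mask."""
    range_.grid.require_same(mask.grid)
    return BinaryRange(grid=range_.grid, mask=range_.mask & mask.mask,
                       species=range_.species, scenario=range_.scenario,
                       threshold_rule=range_.threshold_rule + "+clipped")


def percent_overlap(modeled: BinaryRange, known: BinaryRange,
                    denominator: str = "known") -> float:
    """Percent of the documented range captured by the model:
    100 * |modeled AND known| / |known| (or / |modeled| with
    denominator='modeled', exposed for sensitivity checks)."""
    modeled.grid.require_same(known.grid)
    inter = int((modeled.mask & known.mask).sum())
    denom = known.area if denominator == "known" else modeled.area
    if denom == 0:
        raise ValueError("empty denominator range: overlap undefined")
    return 100.0 * inter / denom


def percent_change(
    current: BinaryRange,
    future: BinaryRange,
    gcm: str = "",
    co2: str = "",
    year: int = 0,
    threshold: str = "",
) -> ChangeRecord:
    """Percent of current suitable area lost in a future map (negative =
    gain).  Both maps must already be clipped by the same buffered mask."""
    current.grid.require_same(future.grid)
    cur = current.area
    if cur == 0:
        raise ValueError("current area is zero: percent loss undefined")
    fut = future.area
    return ChangeRecord(
        species=current.species, gcm=gcm, co2=co2, year=year,
        threshold=threshold or current.threshold_rule,
        current_area=cur, future_area=fut,
        percent_change=100.0 * (cur - fut) / cur,
    )


def range_centroid_latitude(range_: BinaryRange) -> float:
    """Unweighted mean latitude of suitable cell centers, decimal degrees."""
    if range_.area == 0:
        raise ValueError("empty range has no centroid")
    _, lat = range_.grid.cell_centers()
    return float(lat[range_.mask].mean())
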