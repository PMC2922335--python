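"""Synthetic landscapes, virtual species and scenario deltas.

Everything downstream of data acquisition is exercised on landscapes built
here: spatially autocorrelated, cross-correlated covariate stacks standing
in for bioclim layers, virtual species whose true suitability is a known
closed form, spatially (optionally biased) occurrence samples, coarse
"documented range" masks emulating county-level maps, and additive future
climate deltas for a GCM x emissions x horizon scenario grid.

Because the truth is known, model recovery, thresholding behaviour and
projected habitat loss can all be checked against analytic values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grid import ClimateStack, Grid, PointSet
from .projection import BinaryRange

TEMPERATURE = "temperature"
PRECIPITATION = "precipitation"


def default_layer_roles(n_layers: int = 11) -> list[str]:
    """Role per layer; the default 11 split 6 temperature / 5 precipitation,
    mirroring the balance of the classic winnowed bioclim set."""
    n_temp = (n_layers + 1) // 2
    return [TEMPERATURE] * n_temp + [PRECIPITATION] * (n_layers - n_temp)


def default_target_correlation(layer_roles: list[str]) -> np.ndarray:
    """Moderately collinear covariates: 0.7 within the temperature block,
    0.5 within precipitation, 0.2 across blocks."""
    n = len(layer_roles)
    corr = np.full((n, n), 0.2)
    for i in range(n):
        for j in range(n):
            if layer_roles[i] == layer_roles[j]:
                corr[i, j] = 0.7 if layer_roles[i] == TEMPERATURE else 0.5
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for one synthetic climate stack.

    ``autocorrelation_range`` is the Gaussian smoothing sigma in cells
    (0 means white noise); ``gradient_amplitude`` is the peak-to-peak size,
    in layer standard deviations, of the monotone north-to-south warming
    trend added to temperature-like layers.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 0.0083
    origin: tuple[float, float] = (-85.0, 40.0)
    n_layers: int = 11
    layer_roles: tuple[str, ...] = None  # type: ignore[assignment]
    autocorrelation_range: float = 10.0
    target_correlation: np.ndarray = None  # type: ignore[assignment]
    gradient_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("landscape needs at least 2 rows and 2 columns")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        roles = self.layer_roles
        if roles is None:
            roles = tuple(default_layer_roles(self.n_layers))
        object.__setattr__(self, "layer_roles", tuple(roles))
        if len(self.layer_roles) != self.n_layers:
            raise ValueError("one role per layer required")
        corr = self.target_correlation
        if corr is None:
            corr = default_target_correlation(list(self.layer_roles))
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (self.n_layers, self.n_layers):
            raise ValueError("target_correlation must be n_layers x n_layers")
        if not np.allclose(corr, corr.T):
            raise ValueError("target_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("target_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError("target_correlation is not positive semidefinite")
        object.__setattr__(self, "target_correlation", corr)

    @property
    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, self.cell_size, self.origin)


@dataclass(frozen=True)
class VirtualSpecies:
    """A species whose true suitability is logistic in the covariates.

    suitability(x) = expit(intercept + sum_i linear_i x_i + quadratic_i x_i^2),
    bounded in (0, 1) by construction.  ``suitability_threshold`` defines the
    species' true range (suitability >= threshold).
    """

    name: str
    linear: np.ndarray
    quadratic: np.ndarray
    intercept: float = 0.0
    suitability_threshold: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float))
        object.__setattr__(self, "quadratic", np.asarray(self.quadratic, dtype=float))
        if self.linear.shape != self.quadratic.shape or self.linear.ndim != 1:
            raise ValueError("linear/quadratic must be matching 1-D arrays")


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive per-layer climate offsets for one future scenario."""

    gcm: str
    co2: str
    year: int
    offsets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))

    @property
    def label(self) -> str:
        return f"{self.gcm}_{self.co2}_{self.year}"


CURRENT_SCENARIO = "current"


def generate_climate_stack(spec: LandscapeSpec) -> ClimateStack:
    """Build a seeded, spatially autocorrelated, cross-correlated stack.

    Independent white-noise fields are Gaussian-smoothed to the requested
    autocorrelation range, standardized, mixed through a matrix square root
    of the target correlation, and temperature-like layers then receive a
    monotone north-to-south warming gradient.  Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_layers, spec.n_rows, spec.n_cols)
    fields = rng.standard_normal(shape)
    if spec.autocorrelation_range > 0:
        for k in range(spec.n_layers):
            fields[k] = ndimage.gaussian_filter(
                fields[k], sigma=spec.autocorrelation_range, mode="reflect"
            )
    flat = fields.reshape(spec.n_layers, -1)
    flat -= flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    flat /= sd

    # PSD-safe square root (handles rank-deficient target correlations)
    eigvals, eigvecs = np.linalg.eigh(spec.target_correlation)
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0, None))) @ eigvecs.T
    mixed = (root @ flat).reshape(shape)

    if spec.gradient_amplitude != 0 and spec.n_rows > 1:
        # row 0 is north; temperature increases southward
        gradient = spec.gradient_amplitude * (
            np.arange(spec.n_rows) / (spec.n_rows - 1) - 0.5
        )
        for k, role in enumerate(spec.layer_roles):
            if role == TEMPERATURE:
                mixed[k] += gradient[:, None]

    names = [f"bio{k + 1:02d}_{role[:4]}" for k, role in enumerate(spec.layer_roles)]
    return ClimateStack(grid=spec.grid, values=mixed, layer_names=names)


def true_suitability(species: VirtualSpecies, stack: ClimateStack) -> np.ndarray:
    """Per-cell true suitability in [0, 1]; NaN outside the valid mask."""
    if len(species.linear) != stack.n_layers:
        raise ValueError(
            f"species {species.name!r} has {len(species.linear)} coefficients "
            f"but the stack has {stack.n_layers} layers"
        )
    lin = np.tensordot(species.linear, stack.values, axes=1)
    quad = np.tensordot(species.quadratic, stack.values**2, axes=1)
    suit = expit(species.intercept + lin + quad)
    return np.where(stack.valid, suit, np.nan)


def true_range(species: VirtualSpecies, stack: ClimateStack) -> BinaryRange:
    """The species' true range: suitability at or above its threshold."""
    suit = true_suitability(species, stack)
    mask = (suit >= species.suitability_threshold) & stack.valid
    return BinaryRange(grid=stack.grid, mask=mask, species=species.name,
                       scenario="truth", threshold_rule="true-threshold")


def sample_occurrences(
    species: VirtualSpecies,
    stack: ClimateStack,
    n: int,
    bias_surface: np.ndarray | None = None,
    seed: int = 0,
    for_modelling: bool = False,
) -> PointSet:
    """Draw ``n`` presence points, cell probability ~ suitability x bias.

    Points are snapped to cell centers; cells may repeat.  With
    ``for_modelling=True`` the returned set enforces the more-than-30-points
    rule required of sets used to fit models.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    suit = true_suitability(species, stack)
    weights = np.where(stack.valid, suit, 0.0)
    if bias_surface is not None:
        bias = np.asarray(bias_surface, dtype=float)
        if bias.shape != stack.grid.shape:
            raise ValueError("bias surface shape does not match grid")
        if bias.min() < 0:
            raise ValueError("bias surface must be nonnegative")
        weights = weights * bias
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all-zero sampling weights: no cell can be sampled")
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(stack.grid.n_cells, size=n, replace=True,
                          p=(weights / total).ravel())
    rows, cols = np.divmod(flat_idx, stack.grid.n_cols)
    return PointSet(grid=stack.grid, rows=rows, cols=cols,
                    species=species.name, for_modelling=for_modelling)


def collection_bias_surface(grid: Grid, n_foci: int = 3, sigma_cells: float = 8.0,
                            floor: float = 0.1, seed: int = 0) -> np.ndarray:
    """Museum-record style bias: effort peaks near a few foci, with a uniform
    floor so no cell is strictly unsamplable."""
    rng = np.random.default_rng(seed)
    surface = np.zeros(grid.shape)
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    for _ in range(n_foci):
        r0 = rng.uniform(0, grid.n_rows)
        c0 = rng.uniform(0, grid.n_cols)
        surface += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_cells**2))
    surface /= max(surface.max(), 1e-12)
    return floor + (1 - floor) * surface


def build_target_group_background(
    occurrence_sets: list[PointSet],
    target_size: int | None = None,
    seed: int = 0,
) -> PointSet:
    """Pool every species' points into one target-group background.

    The union is deduplicated by cell, so the background carries the pooled
    collection footprint once per locality.  If ``target_size`` is given and
    the deduplicated pool is larger, it is subsampled without replacement to
    that size (the study default mirrors a pool of 4215 localities).
    This pooled set is the single background shared by all model fits.
    """
    sets = [s for s in occurrence_sets if len(s) > 0]
    if not sets:
        raise ValueError("cannot build a background from no occurrence points")
    grid = sets[0].grid
    for s in sets[1:]:
        grid.require_same(s.grid)
    rows = np.concatenate([s.rows for s in sets])
    cols = np.concatenate([s.cols for s in sets])
    pooled = PointSet(grid=grid, rows=rows, cols=cols,
                      species="target-group-background").dedupe()
    if target_size is not None and len(pooled) > target_size:
        keep = np.sort(np.random.default_rng(seed).choice(
            len(pooled), size=target_size, replace=False))
        pooled = PointSet(grid=grid, rows=pooled.rows[keep],
                          cols=pooled.cols[keep],
                          species="target-group-background")
    return pooled


def apply_scenario(stack: ClimateStack, delta: ScenarioDelta) -> ClimateStack:
    """Return a new stack with per-layer additive offsets; input untouched."""
    if len(delta.offsets) != stack.n_layers:
        raise ValueError(
            f"scenario {delta.label} has {len(delta.offsets)} offsets "
            f"but the stack has {stack.n_layers} layers"
        )
    out = stack.copy()
    out.values += delta.offsets[:, None, None]
    return out


def generate_known_range(
    species: VirtualSpecies, stack: ClimateStack, coarsening: int = 1
) -> BinaryRange:
    """Coarse documented-range stand-in: the true range dilated onto
    ``coarsening`` x ``coarsening`` blocks (county-resolution over-coverage).
    Always a superset of the true range."""
    if coarsening < 1:
        raise ValueError("coarsening must be >= 1")
    truth = true_range(species, stack).mask
    if coarsening == 1:
        mask = truth
    else:
        n_rows, n_cols = truth.shape
        pr = (-n_rows) % coarsening
        pc = (-n_cols) % coarsening
        padded = np.pad(truth, ((0, pr), (0, pc)))
        blocks = padded.reshape(
            padded.shape[0] // coarsening, coarsening,
            padded.shape[1] // coarsening, coarsening,
        )
        block_any = blocks.any(axis=(1, 3))
        mask = np.repeat(np.repeat(block_any, coarsening, axis=0),
                         coarsening, axis=1)[:n_rows, :n_cols]
    return BinaryRange(grid=stack.grid, mask=mask, species=species.name,
                       scenario="known", threshold_rule=f"county-coarsen-{coarsening}")


# -- default scenario grid -------------------------------------------------

GCMS = ("CGCM3", "HADCM3")
CO2_LEVELS = ("A2a", "B2a")  # medium-high and low-medium emissions
YEARS = (2020, 2050, 2080)

_YEAR_WARMING = {2020: 0.5, 2050: 1.0, 2080: 1.5}  # layer-sd units
_CO2_FACTOR = {"A2a": 1.3, "B2a": 0.8}
_GCM_FACTOR = {"CGCM3": 1.15, "HADCM3": 0.9}
_PRECIP_RATIO = -0.5  # drying, as a fraction of the warming offset


def default_scenario_deltas(
    layer_roles: list[str] | tuple[str, ...],
    gcms: tuple[str, ...] = GCMS,
    co2_levels: tuple[str, ...] = CO2_LEVELS,
    years: tuple[int, ...] = YEARS,
) -> list[ScenarioDelta]:
    """The 2 GCM x 2 emissions x 3 horizon scenario grid of additive deltas.

    Warming grows with horizon and emissions and differs mildly between
    circulation models; precipitation-like layers dry in proportion.
    """
    deltas = []
    for gcm in gcms:
        for co2 in co2_levels:
            for year in years:
                warm = (_YEAR_WARMING.get(year, 0.5 + (year - 2020) / 60.0)
                        * _CO2_FACTOR.get(co2, 1.0) * _GCM_FACTOR.get(gcm, 1.0))
                offsets = np.array([
                    warm if role == TEMPERATURE else warm * _PRECIP_RATIO
                    for role in layer_roles
                ])
                deltas.append(ScenarioDelta(gcm=gcm, co2=co2, year=year,
                                            offsets=offsets))
    return deltas


def make_virtual_species(
    n_species: int,
    spec: LandscapeSpec,
    seed: int = 0,
    suitability_threshold: float = 0.5,
) -> list[VirtualSpecies]:
    """A community of virtual species with quadratic climate responses.

    Each species responds to the first temperature-like layer through a
    concave quadratic whose optimum is spread across the landscape's thermal
    gradient (so range centroids span the latitude range), plus a weaker
    response to one randomly chosen other layer.  Niche widths are narrow
    relative to the landscape's climatic span, giving the restricted ranges
    (modest prevalence) characteristic of montane ectotherms.
    """
    rng = np.random.default_rng(seed)
    roles = list(spec.layer_roles)
    temp_idx = roles.index(TEMPERATURE) if TEMPERATURE in roles else 0
    species = []
    for i in range(n_species):
        linear = np.zeros(spec.n_layers)
        quad = np.zeros(spec.n_layers)
        # thermal optimum spread across the gradient
        optimum = rng.uniform(-0.8, 0.8) * spec.gradient_amplitude
        width = rng.uniform(0.2, 0.4)
        a = -1.0 / (2 * width**2)
        quad[temp_idx] = a
        linear[temp_idx] = -2 * a * optimum
        # mild secondary response
        other = int(rng.integers(0, spec.n_layers))
        if other != temp_idx:
            linear[other] += rng.uniform(-0.3, 0.3)
        peak = rng.uniform(1.0, 2.0)  # log-odds at the thermal optimum
        intercept = peak + a * optimum**2
        species.append(VirtualSpecies(
            name=f"species_{i:02d}", linear=linear, quadratic=quad,
            intercept=intercept, suitability_threshold=suitability_threshold,
        ))
    return species
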