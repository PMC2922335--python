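"""Model evaluation: presence-background AUC and the null-model test.

A model's training AUC is judged against the 95th percentile of AUCs from
models fitted to random draws of the pooled target-group background: a
model is significant only if its AUC strictly exceeds that percentile.
Null sets are drawn without replacement at one of the configured sizes
(50, 205, 405 or 695 by default), matched to the species' presence count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import ClimateStack, PointSet
from .maxent import FitConfig, MaxentModel, SuitabilitySurface, fit_species

NULL_SAMPLE_SIZES = (50, 205, 405, 695)


def auc_from_scores(presence_scores: np.ndarray,
                    background_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (presence, background) pairs where the
    presence outscores the background point; ties count 0.5.  Invariant
    under any strictly monotone rescaling of the scores."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if len(pres) == 0 or len(bg) == 0:
        raise ValueError("AUC needs non-empty presence and background scores")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_pres = ranks[: len(pres)].sum()
    u = r_pres - len(pres) * (len(pres) + 1) / 2
    return float(u / (len(pres) * len(bg)))


def compute_auc(surface: SuitabilitySurface, presences: PointSet,
                background: PointSet) -> float:
    """Training AUC of a suitability surface: presences versus the training
    background (the negative class), on the raw scale (any monotone scale
    gives the same value)."""
    pres = surface.raw[presences.rows, presences.cols]
    bg = surface.raw[background.rows, background.cols]
    return auc_from_scores(pres, bg)


def training_auc(model: MaxentModel) -> float:
    """AUC straight from a fitted model's stored raw values: training
    presences versus the training background."""
    return auc_from_scores(model.training_presence_raw, model.background_raw)


@dataclass(frozen=True)
class NullDistribution:
    """AUCs of models fitted to random background draws of one size."""

    sample_size: int
    auc_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "auc_values",
                           np.asarray(self.auc_values, dtype=float))
        if len(self.auc_values) < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_replicates(self) -> int:
        return len(self.auc_values)

    @property
    def percentile_95(self) -> float:
        return float(np.percentile(self.auc_values, 95))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.n_replicates),
            "sample_size": self.sample_size,
            "auc": self.auc_values,
        })


def build_null_distribution(
    background_pool: PointSet,
    sample_size: int,
    n_replicates: int,
    stack: ClimateStack,
    config: FitConfig = FitConfig(),
    seed: int = 0,
) -> NullDistribution:
    """Fit the full pipeline to ``n_replicates`` random draws (without
    replacement) from the background pool, treated as presences, and collect
    their training AUCs.  Deterministic given the seed; each replicate
    traverses the identical feature/regularization configuration used for
    real species fits."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if sample_size > len(background_pool):
        raise ValueError(
            f"sample_size {sample_size} exceeds pool size {len(background_pool)}")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_replicates)
    for r in range(n_replicates):
        idx = rng.choice(len(background_pool), size=sample_size, replace=False)
        draw = PointSet(grid=background_pool.grid,
                        rows=background_pool.rows[idx],
                        cols=background_pool.cols[idx],
                        species=f"null_{sample_size}_{r}")
        model = fit_species(draw, background_pool, stack, config)
        aucs[r] = auc_from_scores(model.training_presence_raw,
                                  model.background_raw)
    return NullDistribution(sample_size=sample_size, auc_values=aucs)


def match_null_size(n_presences: int,
                    sizes: tuple[int, ...] = NULL_SAMPLE_SIZES) -> int:
    """Nearest configured null size to the species' presence count; ties go
    to the larger size."""
    sizes = tuple(sorted(sizes))
    best = min(sizes, key=lambda s: (abs(s - n_presences), -s))
    return best


def type_i_error_experiment(
    background_pool: PointSet,
    sample_size: int,
    n_trials: int,
    n_replicates: int,
    stack: ClimateStack,
    config: FitConfig = FitConfig(),
    seed: int = 0,
) -> float:
    """Calibration check of the null-model test.

    Each trial draws a pseudo-species from the background pool itself (so
    the null hypothesis is true by construction), builds a fresh null
    distribution of ``n_replicates`` AUCs, and tests the pseudo-species
    against it.  Returns the rejection rate, which should sit near the
    nominal 5% level.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for t in range(n_trials):
        null = build_null_distribution(
            background_pool, sample_size, n_replicates, stack, config,
            seed=int(rng.integers(0, 2**31 - 1)))
        idx = rng.choice(len(background_pool), size=sample_size, replace=False)
        pseudo = PointSet(grid=background_pool.grid,
                          rows=background_pool.rows[idx],
                          cols=background_pool.cols[idx],
                          species=f"trial_{t}")
        model = fit_species(pseudo, background_pool, stack, config)
        auc = auc_from_scores(model.training_presence_raw,
                              model.background_raw)
        if test_significance(auc, null).significant:
            rejections += 1
    return rejections / n_trials


@dataclass(frozen=True)
class SignificanceResult:
    auc: float
    matched_size: int
    percentile_95: float
    significant: bool


def test_significance(observed_auc: float,
                      null: NullDistribution) -> SignificanceResult:
    """Significant iff the observed AUC strictly exceeds the null's
    empirical 95th percentile."""
    p95 = null.percentile_95
    return SignificanceResult(
        auc=float(observed_auc), matched_size=null.sample_size,
        percentile_95=p95, significant=bool(observed_auc > p95),
    )
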