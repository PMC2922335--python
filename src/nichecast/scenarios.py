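"""Scenario grids and the factorial general linear model on habitat loss.

Per species the scenario grid crosses 2 GCMs x 2 emissions levels x 2
threshold rules (8 scenarios); projection years are analysed separately,
so richness maps additionally cross the years.  Percent habitat loss
(square-root transformed) is modelled per year as a function of GCM, CO2
level and threshold (categorical) and current range size and range-centroid
latitude (continuous), with all two- and three-way interactions, judged by
partial (Type III) F tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

LOSS_COLUMNS = ["species", "gcm", "co2", "threshold", "year",
                "current_area", "future_area", "percent_change",
                "range_size", "centroid_latitude"]

_FACTORS = ("gcm", "co2", "threshold")
_COVARIATES = ("centroid_latitude", "range_size")


@dataclass(frozen=True)
class ScenarioGrid:
    """Enumerated scenario combinations.

    ``per_species`` crosses GCM x CO2 x threshold (year is analysed
    separately); ``richness`` additionally crosses the years.
    """

    per_species: tuple[tuple[str, str, str], ...]
    richness: tuple[tuple[str, str, str, int], ...]


def enumerate_scenarios(gcms, co2_levels, thresholds, years) -> ScenarioGrid:
    """Full cross-products of the scenario factors."""
    gcms, co2_levels, thresholds, years = (tuple(v) for v in
                                           (gcms, co2_levels, thresholds, years))
    for name, levels in (("gcms", gcms), ("co2_levels", co2_levels),
                         ("thresholds", thresholds), ("years", years)):
        if not levels:
            raise ValueError(f"{name} must be non-empty")
    return ScenarioGrid(
        per_species=tuple(product(gcms, co2_levels, thresholds)),
        richness=tuple((g, c, t, y) for g, c, t in
                       product(gcms, co2_levels, thresholds) for y in years),
    )


def transform_loss(percent_change: np.ndarray, kind: str = "sqrt_clamped"):
    """Response transform for the GLM.

    'sqrt_clamped' (default): sqrt(max(x, 0)) — gains are clamped to zero
    and the clamped count logged.  'signed_sqrt': sign(x) sqrt(|x|),
    exposed as an alternative that preserves gains.
    """
    x = np.asarray(percent_change, dtype=float)
    if kind == "sqrt_clamped":
        n_clamped = int((x < 0).sum())
        if n_clamped:
            log.info("loss transform clamped %d negative (gain) rows to 0",
                     n_clamped)
        return np.sqrt(np.clip(x, 0, None)), n_clamped
    if kind == "signed_sqrt":
        return np.sign(x) * np.sqrt(np.abs(x)), 0
    raise ValueError(f"unknown transform {kind!r}")


def _term_label(name: str) -> str:
    parts = []
    for piece in name.split(":"):
        piece = piece.strip()
        if piece.startswith("C("):
            piece = piece[2:].split(",")[0].strip()
        else:
            piece = piece.split("[")[0]
        parts.append(piece)
    return "*".join(parts)


def factorial_ols(table: pd.DataFrame, year: int,
                  transform: str = "sqrt_clamped"):
    """The fitted OLS results object behind :func:`fit_factorial_glm`
    (coefficients, standard errors, residual df), for effect inspection."""
    df = table[table["year"] == year].copy()
    if df.empty:
        raise ValueError(f"no rows for year {year}")
    # patsy silently drops single-level factors instead of flagging the
    # aliasing, so catch them up front
    single = [f for f in _FACTORS if df[f].nunique() < 2]
    if single:
        raise ValueError(
            "design matrix is rank deficient; aliased terms: "
            + ", ".join(f"{f} (single level)" for f in single))
    df["loss_t"], _ = transform_loss(df["percent_change"].to_numpy(), transform)
    terms = " + ".join(
        ["C(gcm, Sum)", "C(co2, Sum)", "C(threshold, Sum)",
         "centroid_latitude", "range_size"])
    model = smf.ols(f"loss_t ~ ({terms}) ** 3", data=df)
    _check_full_rank(model)
    return model.fit()


def fit_factorial_glm(
    table: pd.DataFrame,
    year: int,
    transform: str = "sqrt_clamped",
    ss_type: int = 3,
) -> pd.DataFrame:
    """Fit the year's factorial GLM and return its ANOVA table.

    Terms: intercept, the 5 main effects, all 10 two-way and all 10
    three-way interactions among {gcm, co2, threshold, centroid latitude,
    range size}.  Factors are sum-coded so the partial (Type III) sums of
    squares are the conventional ones; sequential (Type I) SS available via
    ``ss_type=1``.  Returns one row per term (source, df, ss, ms, F, p)
    plus an 'Error' row.
    """
    fit = factorial_ols(table, year, transform)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova on saturated designs warns
        anova = sm.stats.anova_lm(fit, typ=ss_type)
    rows = []
    for name, row in anova.iterrows():
        if name == "Intercept":
            continue
        label = "Error" if name == "Residual" else _term_label(name)
        d = int(row["df"])
        ss = float(row["sum_sq"])
        ms = ss / d if d else np.nan
        f_val = row.get("F", np.nan)
        p_val = row.get("PR(>F)", np.nan)
        rows.append({"source": label, "df": d, "ss": ss, "ms": ms,
                     "F": float(f_val) if np.isfinite(f_val) else np.nan,
                     "p": float(p_val) if np.isfinite(p_val) else np.nan})
    out = pd.DataFrame(rows)
    # Error row last, terms in formula order otherwise
    err = out["source"] == "Error"
    out = pd.concat([out[~err], out[err]], ignore_index=True)
    out.attrs["year"] = year
    out.attrs["n_rows"] = int(fit.nobs)
    return out


def _check_full_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = piv[diag < diag.max() * 1e-10] if diag.max() > 0 else piv
        names = [model.exog_names[i] for i in np.atleast_1d(bad)]
        raise ValueError(
            "design matrix is rank deficient; aliased terms: "
            + ", ".join(sorted({_term_label(n) for n in names}))
        )


def error_df(table: pd.DataFrame, year: int) -> int:
    """Residual degrees of freedom of the year's factorial GLM."""
    return int(fit_factorial_glm(table, year).set_index("source").loc["Error", "df"])


def summarize_by_latitude_band(
    table: pd.DataFrame,
    bands: list[tuple[float, float]],
) -> pd.DataFrame:
    """Mean and min-max of percent habitat change per latitude band x year
    x threshold (the quantities a loss-by-latitude figure displays).
    Bands are half-open [lo, hi) and must not overlap; bands holding no
    species yield missing (NaN) summaries."""
    for (lo1, hi1) in bands:
        if hi1 <= lo1:
            raise ValueError("each band must satisfy lo < hi")
    for i, (lo1, hi1) in enumerate(bands):
        for lo2, hi2 in bands[i + 1 :]:
            if max(lo1, lo2) < min(hi1, hi2):
                raise ValueError("latitude bands must be disjoint")
    rows = []
    for (lo, hi) in bands:
        in_band = table[(table["centroid_latitude"] >= lo)
                        & (table["centroid_latitude"] < hi)]
        for year in sorted(table["year"].unique()):
            for thr in sorted(table["threshold"].unique()):
                sub = in_band[(in_band["year"] == year)
                              & (in_band["threshold"] == thr)]
                vals = sub["percent_change"]
                rows.append({
                    "band_lo": lo, "band_hi": hi, "year": year,
                    "threshold": thr, "n": len(sub),
                    "mean_loss": vals.mean() if len(sub) else np.nan,
                    "min_loss": vals.min() if len(sub) else np.nan,
                    "max_loss": vals.max() if len(sub) else np.nan,
                })
    return pd.DataFrame(rows)
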