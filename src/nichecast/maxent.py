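"""Maximum-entropy presence-background niche model.

The model is a Gibbs distribution over the background cells,

    raw(x) = exp(sum_j lambda_j f_j(x)) / Z,

whose weights maximize the L1-penalized log-likelihood of the presence
sample: mean_i lambda . f(x_i) - log Z - sum_j beta_j |lambda_j|.  This is
the minimum-relative-entropy distribution whose feature expectations match
the presence means to within per-feature beta boxes.  Fitting is cyclic
coordinate descent with a prox-Newton step and soft-thresholding, the
sequential flavour of the reference implementations.

Outputs come on three monotone scales: raw (normalized probability over
the training background), cumulative (percent of raw mass at or below a
cell's raw value, max exactly 100) and logistic
(raw * e^H / (1 + raw * e^H) with H the entropy of the raw distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .features import FeatureSet
from .grid import ClimateStack, Grid, PointSet

# Per-class default regularization, interpolated on presence count as in
# the reference implementation's defaults; a single global multiplier
# scales all of them.
DEFAULT_BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "linear": ((10, 30, 100), (1.0, 1.0, 1.05)),
    "quadratic": ((10, 30, 100), (1.3, 0.8, 0.5)),
    "product": ((10, 30, 100), (1.3, 0.8, 0.5)),
    "hinge": ((0, 1), (0.5, 0.5)),
    "threshold": ((0, 100), (2.0, 1.0)),
}


class ConvergenceWarning(UserWarning):
    pass


class ConvergenceError(RuntimeError):
    """Raised on non-convergence; carries the best iterate as ``.model``."""

    def __init__(self, message: str, model: "MaxentModel"):
        super().__init__(message)
        self.model = model


def default_betas(feature_set: FeatureSet, sample_size: int,
                  multiplier: float = 1.0) -> np.ndarray:
    """Per-feature regularization beta_j = multiplier * beta_class(m) / sqrt(m),
    scaled by each feature's presence-sample spread when fitting."""
    m = max(sample_size, 1)
    out = np.empty(feature_set.n_features)
    for j, f in enumerate(feature_set.features):
        xs, ys = DEFAULT_BETA_TABLES[f.kind]
        out[j] = np.interp(m, xs, ys)
    return multiplier * out / np.sqrt(m)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    ``log_z`` is the log partition value over the training background;
    ``entropy`` the Shannon entropy of the fitted raw distribution (used by
    the logistic transform); ``background_raw`` the fitted raw probabilities
    at the training background cells (the reference distribution for the
    cumulative transform); ``training_presence_raw`` the raw values at the
    (deduplicated) training presences, retained for the minimum-training-
    presence threshold.
    """

    feature_set: FeatureSet
    weights: np.ndarray
    regularization: np.ndarray
    log_z: float
    entropy: float
    background_raw: np.ndarray
    training_presence_raw: np.ndarray
    clamp: bool = True
    converged: bool = True
    n_sweeps: int = 0
    species: str = ""

    def linear_score(self, covariates: np.ndarray) -> np.ndarray:
        feats = self.feature_set.evaluate(covariates, clamp=self.clamp)
        return feats @ self.weights


def fit_maxent(
    presences: PointSet,
    background: PointSet,
    features: FeatureSet,
    regularization: float | np.ndarray | None = 1.0,
    stack: ClimateStack | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 500,
    on_nonconvergence: str = "warn",
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``regularization`` is a global multiplier on the per-class default
    betas (scalar, default 1.0; 0 disables the penalty) or an explicit
    per-feature beta vector.  Duplicate presences per cell are collapsed
    before fitting.  Convergence is declared when a full coordinate sweep
    improves the penalized log-likelihood by less than ``tol``;
    non-convergence warns (``on_nonconvergence='warn'``) or raises a
    :class:`ConvergenceError` carrying the best iterate (``'raise'``).
    """
    if stack is None:
        raise ValueError("a climate stack is required to evaluate covariates")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 cells")
    pres = presences.dedupe()
    if len(pres) < 1:
        raise ValueError("at least one presence is required")
    m = len(pres)

    xb = stack.extract(background.rows, background.cols)
    xp = stack.extract(pres.rows, pres.cols)
    if not (np.isfinite(xb).all() and np.isfinite(xp).all()):
        raise ValueError("non-finite covariates at presence or background cells")

    fb = features.evaluate(xb, clamp=False)
    fp = features.evaluate(xp, clamp=False)
    pbar = fp.mean(axis=0)

    if regularization is None:
        regularization = 1.0
    if np.isscalar(regularization):
        if regularization == 0:
            beta = np.zeros(features.n_features)
        else:
            spread = fp.std(axis=0, ddof=0)
            fallback = fb.std(axis=0, ddof=0)
            spread = np.where(spread > 0, spread, fallback)
            # beta_j = mult * beta_class(m) * s_j / sqrt(m)
            beta = float(regularization) * default_betas(features, m) * spread
    else:
        beta = np.asarray(regularization, dtype=float)
        if beta.shape != (features.n_features,):
            raise ValueError("regularization vector length must match features")

    lam, log_z, n_sweeps, converged = _coordinate_descent(
        fb, pbar, beta, tol=tol, max_sweeps=max_sweeps)

    s = fb @ lam
    log_p = s - logsumexp(s)
    p = np.exp(log_p)
    entropy = float(-(p * log_p).sum())
    pres_raw = np.exp(fp @ lam - log_z)

    model = MaxentModel(
        feature_set=features, weights=lam, regularization=beta,
        log_z=float(log_z), entropy=entropy, background_raw=p,
        training_presence_raw=pres_raw, species=pres.species,
        converged=converged, n_sweeps=n_sweeps,
    )
    if not converged:
        msg = (f"maxent fit for {pres.species!r} did not converge in "
               f"{max_sweeps} sweeps")
        if on_nonconvergence == "raise":
            raise ConvergenceError(msg, model)
        warnings.warn(msg, ConvergenceWarning, stacklevel=2)
    return model


def _penalized_ll(lam, s, pbar, beta):
    return float(lam @ pbar - logsumexp(s) - beta @ np.abs(lam))


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def _coordinate_descent(fb, pbar, beta, tol, max_sweeps):
    nb, k = fb.shape
    lam = np.zeros(k)
    s = np.zeros(nb)
    obj = _penalized_ll(lam, s, pbar, beta)
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        log_z = logsumexp(s)
        p = np.exp(s - log_z)
        for j in range(k):
            col = fb[:, j]
            ef = p @ col
            grad = pbar[j] - ef
            hess = p @ (col * col) - ef * ef
            if hess < 1e-12:
                continue
            new = _soft(lam[j] + grad / hess, beta[j] / hess)
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # prox-Newton step with halving safeguard on the true objective
            base = _penalized_ll(lam, s, pbar, beta)
            for _ in range(25):
                cand_s = s + delta * col
                cand = lam.copy()
                cand[j] += delta
                if _penalized_ll(cand, cand_s, pbar, beta) >= base - 1e-15:
                    lam = cand
                    s = cand_s
                    log_z = logsumexp(s)
                    p = np.exp(s - log_z)
                    break
                delta *= 0.5
        new_obj = _penalized_ll(lam, s, pbar, beta)
        if new_obj - obj < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return lam, logsumexp(s), sweep, converged


@dataclass(frozen=True)
class FitConfig:
    """One pipeline-wide fitting configuration.

    ``feature_classes=None`` selects classes by the presence-count rule;
    ``regularization`` is the global multiplier on the default betas.  Null
    replicates reuse the exact same configuration as real fits.
    """

    feature_classes: tuple[str, ...] | None = None
    n_hinge_knots: int = 8
    n_threshold_knots: int = 8
    regularization: float = 1.0
    tol: float = 1e-6
    max_sweeps: int = 500
    clamp: bool = True


def fit_species(presences: PointSet, background: PointSet,
                stack: ClimateStack, config: FitConfig = FitConfig()) -> MaxentModel:
    """Build features for this presence count and fit under ``config``."""
    from .features import build_features

    m = len(presences.dedupe())
    features = build_features(
        stack, background, sample_size=m,
        classes=config.feature_classes,
        n_hinge_knots=config.n_hinge_knots,
        n_threshold_knots=config.n_threshold_knots,
    )
    model = fit_maxent(presences, background, features,
                       regularization=config.regularization, stack=stack,
                       tol=config.tol, max_sweeps=config.max_sweeps)
    model.clamp = config.clamp
    return model


# -- output scales ---------------------------------------------------------


@dataclass
class SuitabilitySurface:
    """Per-cell model output on the three monotone scales."""

    grid: Grid
    raw: np.ndarray
    cumulative: np.ndarray
    logistic: np.ndarray
    valid: np.ndarray
    species: str = ""
    scenario: str = ""


def predict_raw(model: MaxentModel, stack: ClimateStack,
                scenario: str = "current") -> SuitabilitySurface:
    """Project the fitted model onto a stack.

    The normalizer is the training one, so raw values remain comparable
    across projection stacks and sum to 1 over the training background on
    the training stack.  Features are clamped to their training ranges when
    ``model.clamp`` (the default).
    """
    if stack.n_layers != len(model.feature_set.layer_names):
        raise ValueError("stack layer count does not match the fitted features")
    rows, cols = np.nonzero(stack.valid)
    x = stack.extract(rows, cols)
    raw_vals = np.exp(model.linear_score(x) - model.log_z)
    raw = np.full(stack.grid.shape, np.nan)
    raw[rows, cols] = raw_vals
    cum = np.full(stack.grid.shape, np.nan)
    cum[rows, cols] = cumulative_from_raw(raw_vals, model.background_raw)
    logi = np.full(stack.grid.shape, np.nan)
    logi[rows, cols] = logistic_from_raw(raw_vals, model.entropy)
    return SuitabilitySurface(grid=stack.grid, raw=raw, cumulative=cum,
                              logistic=logi, valid=stack.valid.copy(),
                              species=model.species, scenario=scenario)


def cumulative_from_raw(query_raw: np.ndarray,
                        background_raw: np.ndarray) -> np.ndarray:
    """Cumulative scale: 100 x (background raw mass at or below each query
    value) / (total background mass).  Inclusive ties: equal raw values get
    identical cumulative values; the maximum over the background is exactly
    100."""
    q = np.asarray(query_raw, dtype=float)
    bg = np.sort(np.asarray(background_raw, dtype=float))
    csum = np.concatenate([[0.0], np.cumsum(bg)])
    total = csum[-1]
    idx = np.searchsorted(bg, q, side="right")
    return 100.0 * csum[idx] / total


def logistic_from_raw(query_raw: np.ndarray, entropy: float) -> np.ndarray:
    """Logistic scale: r e^H / (1 + r e^H); strictly increasing in raw."""
    q = np.asarray(query_raw, dtype=float)
    z = q * np.exp(entropy)
    return z / (1.0 + z)


# -- serialization ---------------------------------------------------------


def write_lambdas(model: MaxentModel, path) -> None:
    """Plain-text "lambdas"-style model file: one line per feature
    (description, weight, scaling min/max), a footer with the normalizer and
    entropy, clamp ranges, training presence raw values and the background
    raw distribution (needed to reproduce the cumulative transform)."""
    fs = model.feature_set
    with open(path, "w") as fh:
        fh.write(f"# nichecast maxent model: {model.species}\n")
        fh.write(f"layers\t{','.join(fs.layer_names)}\n")
        fh.write(f"classes\t{','.join(fs.classes)}\n")
        for f, w, lo, hi, b in zip(fs.features, model.weights, fs.scale_min,
                                   fs.scale_max, model.regularization):
            fh.write(f"feature\t{f.kind}\t{','.join(map(str, f.layers))}\t"
                     f"{float(f.knot)!r}\t{f.direction}\t{float(w)!r}\t"
                     f"{float(lo)!r}\t{float(hi)!r}\t{float(b)!r}\n")
        fh.write("clamp_min\t" + ",".join(repr(float(v)) for v in fs.clamp_min) + "\n")
        fh.write("clamp_max\t" + ",".join(repr(float(v)) for v in fs.clamp_max) + "\n")
        fh.write(f"log_z\t{float(model.log_z)!r}\n")
        fh.write(f"entropy\t{float(model.entropy)!r}\n")
        fh.write(f"clamp\t{int(model.clamp)}\n")
        fh.write(f"converged\t{int(model.converged)}\n")
        fh.write("presence_raw\t" +
                 ",".join(repr(float(v)) for v in model.training_presence_raw) + "\n")
        fh.write("background_raw\t" +
                 ",".join(repr(float(v)) for v in model.background_raw) + "\n")


def read_lambdas(path) -> MaxentModel:
    from .features import Feature  # local to avoid clutter at import time

    layer_names: list[str] = []
    classes: tuple[str, ...] = ()
    feats, weights, smin, smax, betas = [], [], [], [], []
    extra: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("\t")
            if key == "layers":
                layer_names = rest.split(",")
            elif key == "classes":
                classes = tuple(rest.split(","))
            elif key == "feature":
                kind, layers, knot, direction, w, lo, hi, b = rest.split("\t")
                feats.append(Feature(kind, tuple(int(i) for i in layers.split(",")),
                                     float(knot), direction))
                weights.append(float(w))
                smin.append(float(lo))
                smax.append(float(hi))
                betas.append(float(b))
            else:
                extra[key] = rest
    fs = FeatureSet(
        features=feats, layer_names=layer_names,
        scale_min=np.array(smin), scale_max=np.array(smax),
        clamp_min=np.array([float(v) for v in extra["clamp_min"].split(",")]),
        clamp_max=np.array([float(v) for v in extra["clamp_max"].split(",")]),
        classes=classes,
    )
    return MaxentModel(
        feature_set=fs, weights=np.array(weights),
        regularization=np.array(betas),
        log_z=float(extra["log_z"]), entropy=float(extra["entropy"]),
        background_raw=np.array([float(v) for v in
                                 extra["background_raw"].split(",")]),
        training_presence_raw=np.array([float(v) for v in
                                        extra["presence_raw"].split(",")]),
        clamp=bool(int(extra["clamp"])), converged=bool(int(extra["converged"])),
    )
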