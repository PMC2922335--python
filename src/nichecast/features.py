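"""Feature construction for the maximum-entropy niche model.

Covariate layers are expanded into the classic Maxent feature classes —
linear, quadratic, product, hinge (forward and reverse) and threshold —
min-max scaled so every feature lies in [0, 1] on the background sample.
Which classes are active follows the presence-count "auto features" rule;
scaling constants and knots come from the background only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import ClimateStack, PointSet

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")


def auto_feature_classes(sample_size: int) -> tuple[str, ...]:
    """Feature classes by presence count, mirroring the reference
    auto-features rule: <10 linear; >=10 add quadratic; >=15 add hinge;
    >=80 add product and threshold."""
    classes = ["linear"]
    if sample_size >= 10:
        classes.append("quadratic")
    if sample_size >= 15:
        classes.append("hinge")
    if sample_size >= 80:
        classes.extend(["product", "threshold"])
    return tuple(classes)


@dataclass(frozen=True)
class Feature:
    """One basis function.

    kind: feature class; layers: source layer index (or index pair for
    product); knot: hinge/threshold location in covariate units (hinge is
    'forward' max(0, x-knot) or 'reverse' max(0, knot-x))."""

    kind: str
    layers: tuple[int, ...]
    knot: float = float("nan")
    direction: str = ""

    def describe(self, names: list[str]) -> str:
        lab = "*".join(names[i] for i in self.layers)
        if self.kind == "hinge":
            return f"hinge_{self.direction}({lab}@{self.knot:.6g})"
        if self.kind == "threshold":
            return f"threshold({lab}@{self.knot:.6g})"
        return f"{self.kind}({lab})"


@dataclass
class FeatureSet:
    """Feature definitions plus background-derived scaling and clamp ranges.

    ``scale_min``/``scale_max`` are per-feature min/max of the raw feature
    value over the background; ``clamp_min``/``clamp_max`` are per-layer
    covariate ranges used to clamp when projecting beyond training
    conditions.
    """

    features: list[Feature]
    layer_names: list[str]
    scale_min: np.ndarray
    scale_max: np.ndarray
    clamp_min: np.ndarray
    clamp_max: np.ndarray
    classes: tuple[str, ...] = ("linear",)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def evaluate(self, covariates: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Scaled feature matrix (n_points, n_features) from covariates
        (n_points, n_layers).  Clamping restricts covariates to their
        background (training) ranges first."""
        x = np.asarray(covariates, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.layer_names):
            raise ValueError("covariates must be (n_points, n_layers)")
        if clamp:
            x = np.clip(x, self.clamp_min, self.clamp_max)
        raw = np.empty((x.shape[0], self.n_features))
        for j, f in enumerate(self.features):
            raw[:, j] = _raw_feature(f, x)
        span = self.scale_max - self.scale_min
        return (raw - self.scale_min) / span

    def describe_all(self) -> list[str]:
        return [f.describe(self.layer_names) for f in self.features]


def _raw_feature(f: Feature, x: np.ndarray) -> np.ndarray:
    v = x[:, f.layers[0]]
    if f.kind == "linear":
        return v
    if f.kind == "quadratic":
        return v**2
    if f.kind == "product":
        return v * x[:, f.layers[1]]
    if f.kind == "hinge":
        return np.maximum(0.0, v - f.knot) if f.direction == "forward" \
            else np.maximum(0.0, f.knot - v)
    if f.kind == "threshold":
        return (v > f.knot).astype(float)
    raise ValueError(f"unknown feature kind {f.kind!r}")


def build_features(
    stack: ClimateStack,
    background: PointSet,
    sample_size: int,
    classes: tuple[str, ...] | None = None,
    n_hinge_knots: int = 8,
    n_threshold_knots: int = 8,
) -> FeatureSet:
    """Construct the feature set for a fit with ``sample_size`` presences.

    Classes default to the presence-count rule.  Hinge/threshold knots are
    evenly spaced interior points of each layer's background range.
    Features constant on the background (e.g. from a constant layer) are
    dropped with a warning.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if classes is None:
        classes = auto_feature_classes(sample_size)
    unknown = set(classes) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    bg = stack.extract(background.rows, background.cols)
    if not np.isfinite(bg).all():
        raise ValueError("background covariates contain non-finite values")
    clamp_min = bg.min(axis=0)
    clamp_max = bg.max(axis=0)
    n_layers = stack.n_layers

    candidates: list[Feature] = []
    for li in range(n_layers):
        if "linear" in classes:
            candidates.append(Feature("linear", (li,)))
        if "quadratic" in classes:
            candidates.append(Feature("quadratic", (li,)))
        lo, hi = clamp_min[li], clamp_max[li]
        if hi > lo:
            if "hinge" in classes:
                knots = np.linspace(lo, hi, n_hinge_knots + 2)[1:-1]
                for k in knots:
                    candidates.append(Feature("hinge", (li,), float(k), "forward"))
                    candidates.append(Feature("hinge", (li,), float(k), "reverse"))
            if "threshold" in classes:
                knots = np.linspace(lo, hi, n_threshold_knots + 2)[1:-1]
                for k in knots:
                    candidates.append(Feature("threshold", (li,), float(k)))
    if "product" in classes:
        for li in range(n_layers):
            for lj in range(li + 1, n_layers):
                candidates.append(Feature("product", (li, lj)))

    kept, smin, smax, dropped = [], [], [], []
    for f in candidates:
        vals = _raw_feature(f, bg)
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo <= 0:
            dropped.append(f)
            continue
        kept.append(f)
        smin.append(lo)
        smax.append(hi)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} feature(s) constant on the background "
            f"(e.g. {dropped[0].describe(stack.layer_names)})",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no usable (non-constant) features on this background")
    return FeatureSet(
        features=kept,
        layer_names=list(stack.layer_names),
        scale_min=np.array(smin),
        scale_max=np.array(smax),
        clamp_min=clamp_min,
        clamp_max=clamp_max,
        classes=tuple(classes),
    )
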