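"""Feature construction for the presence-background maximum-entropy model.

Raw predictor values are affinely scaled to [0, 1] using the background
min/max, then expanded into the classic feature classes:

- L  linear: the scaled value itself
- Q  quadratic: the scaled value squared
- P  product: pairwise products of scaled values
- H  hinge: forward ramps max(0, (x-k)/(max-k)) and reverse ramps
     max(0, (k-x)/(k-min)) at evenly spaced interior knots k
- T  threshold: step indicators 1[x > k] at evenly spaced interior knots

The background-derived scaling is stored so presence and projection data are
transformed identically.  Feature ordering is deterministic: class order
L, Q, P, H, T; within a class, variable order; within a variable, knot order
(hinges: all forward knots then all reverse knots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("L", "Q", "P", "H", "T")

#: the nine feature combinations of the standard tuning grid
FC_GRID_DEFAULT = ("L", "H", "LQ", "LQH", "LQHP", "LQHPT", "QHP", "QHPT", "HPT")
#: the eight regularization multipliers of the standard tuning grid
RM_GRID_DEFAULT = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to build, and knot counts for H/T."""

    classes: str = "LQH"
    hinge_knots: int = 30
    threshold_knots: int = 30

    def __post_init__(self) -> None:
        cl = self.classes.upper()
        if not cl or any(c not in FEATURE_CLASSES for c in cl):
            raise ValueError(f"classes must be a non-empty subset of "
                             f"{FEATURE_CLASSES}, got {self.classes!r}")
        if "H" in cl and self.hinge_knots < 1:
            raise ValueError("hinge_knots must be >= 1 when H is enabled")
        if "T" in cl and self.threshold_knots < 1:
            raise ValueError("threshold_knots must be >= 1 when T is enabled")
        object.__setattr__(self, "classes", cl)

    def has(self, c: str) -> bool:
        return c in self.classes


@dataclass
class FeatureMatrix:
    """samples x features design matrix plus the metadata needed to rebuild it.

    ``scaling`` maps variable name -> (min, max) over the background; it is
    reused verbatim when transforming presence or projection samples so all
    data live on the background's [0, 1] scale.
    """

    values: np.ndarray
    names: list[str]
    variable_names: list[str]
    scaling: dict[str, tuple[float, float]]
    spec: FeatureSpec
    #: feature class per column, and the variable(s) each column draws on
    classes: list[str] = field(default_factory=list)
    parents: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _interior_knots(k: int) -> np.ndarray:
    """k evenly spaced knots strictly inside (0, 1)."""
    return np.arange(1, k + 1) / (k + 1)


def compute_scaling(background: np.ndarray, variable_names: list[str],
                    ) -> dict[str, tuple[float, float]]:
    bg = np.asarray(background, dtype=float)
    return {name: (float(bg[:, j].min()), float(bg[:, j].max()))
            for j, name in enumerate(variable_names)}


def build_features(values: np.ndarray, spec: FeatureSpec,
                   variable_names: list[str],
                   scaling: dict[str, tuple[float, float]] | None = None,
                   ) -> FeatureMatrix:
    """Expand raw variable values into the requested feature classes.

    When ``scaling`` is omitted the min/max of ``values`` define it (i.e.
    ``values`` is the background); otherwise the supplied background scaling
    is reused.  Constant variables keep their (all-zero) linear feature but
    contribute no Q/P/H/T features.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(variable_names):
        raise ValueError("values width does not match variable_names")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in feature input")
    if scaling is None:
        scaling = compute_scaling(values, variable_names)

    scaled = np.empty_like(values)
    informative: list[bool] = []
    for j, name in enumerate(variable_names):
        lo, hi = scaling[name]
        if hi > lo:
            scaled[:, j] = (values[:, j] - lo) / (hi - lo)
            informative.append(True)
        else:
            scaled[:, j] = 0.0
            informative.append(False)
            log.warning("variable %s constant over background: only its "
                        "linear feature is kept", name)

    cols: list[np.ndarray] = []
    names: list[str] = []
    classes: list[str] = []
    parents: list[tuple[str, ...]] = []

    def emit(col: np.ndarray, name: str, cls: str, par: tuple[str, ...]) -> None:
        cols.append(col)
        names.append(name)
        classes.append(cls)
        parents.append(par)

    if spec.has("L"):
        for j, v in enumerate(variable_names):
            emit(scaled[:, j], f"L({v})", "L", (v,))
    if spec.has("Q"):
        for j, v in enumerate(variable_names):
            if informative[j]:
                emit(scaled[:, j] ** 2, f"Q({v})", "Q", (v,))
    if spec.has("P"):
        for (i, vi), (j, vj) in combinations(enumerate(variable_names), 2):
            if informative[i] and informative[j]:
                emit(scaled[:, i] * scaled[:, j], f"P({vi}*{vj})", "P", (vi, vj))
    if spec.has("H"):
        knots = _interior_knots(spec.hinge_knots)
        for j, v in enumerate(variable_names):
            if not informative[j]:
                continue
            s = scaled[:, j]
            for k in knots:
                emit(np.maximum(0.0, (s - k) / (1.0 - k)),
                     f"H+({v}@{k:.4f})", "H", (v,))
            for k in knots:
                emit(np.maximum(0.0, (k - s) / k),
                     f"H-({v}@{k:.4f})", "H", (v,))
    if spec.has("T"):
        knots = _interior_knots(spec.threshold_knots)
        for j, v in enumerate(variable_names):
            if not informative[j]:
                continue
            s = scaled[:, j]
            for k in knots:
                emit((s > k).astype(float), f"T({v}@{k:.4f})", "T", (v,))

    mat = np.column_stack(cols) if cols else np.empty((values.shape[0], 0))
    return FeatureMatrix(values=mat, names=names,
                         variable_names=list(variable_names),
                         scaling=dict(scaling), spec=spec,
                         classes=classes, parents=parents)
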