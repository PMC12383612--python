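"""Suitability classification, spherical class areas, and change analysis.

Averaged suitability probabilities are binned into four classes with fixed
thresholds (non < 0.1 <= low < 0.3 <= medium < 0.5 <= high), binarised at
P >= 0.1 into suitable/unsuitable, and compared across periods as a per-cell
transition matrix: 1->1 retention, 1->0 loss, 0->1 gain.  Change rates use
the union of current and future suitable area as the denominator, so the
three rates always sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridDef

CLASS_LABELS = ("non", "low", "medium", "high")
DEFAULT_BREAKS = (0.1, 0.3, 0.5)


@dataclass(frozen=True)
class ClassScheme:
    breaks: tuple[float, float, float] = DEFAULT_BREAKS
    labels: tuple[str, str, str, str] = CLASS_LABELS

    def __post_init__(self) -> None:
        b = self.breaks
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("breaks must be strictly increasing within (0,1)")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need one more label than breaks")


@dataclass
class ChangeSummary:
    """Retained/lost/gained suitable area between two periods."""

    retained_area: float      # km^2, suitable in both periods (1->1)
    lost_area: float          # km^2, suitable only currently (1->0)
    gained_area: float        # km^2, suitable only in future (0->1)

    @property
    def union_area(self) -> float:
        return self.retained_area + self.lost_area + self.gained_area

    @property
    def retention_rate(self) -> float:
        return 100.0 * self.retained_area / self.union_area

    @property
    def loss_rate(self) -> float:
        return 100.0 * self.lost_area / self.union_area

    @property
    def gain_rate(self) -> float:
        return 100.0 * self.gained_area / self.union_area

    def as_row(self, scale: float = 1e4) -> dict:
        """Row in the conventional reporting units (areas in 10^4 km^2)."""
        return {
            "Stability_area": self.retained_area / scale,
            "Contraction_area": self.lost_area / scale,
            "Expansion_area": self.gained_area / scale,
            "Stability_rate": self.retention_rate,
            "Contraction_rate": self.loss_rate,
            "Expansion_rate": self.gain_rate,
        }


def _check_probabilities(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("probability layer has values outside [0, 1]")
    return p


def classify(p_layer: np.ndarray,
             scheme: ClassScheme = ClassScheme()) -> np.ndarray:
    """Bin probabilities into class indices 0..3 (non/low/medium/high).

    Bins are half-open, [0, b1), [b1, b2), [b2, b3), [b3, 1]; NaN (masked)
    cells propagate as -1.
    """
    p = _check_probabilities(p_layer)
    out = np.full(p.shape, -1, dtype=int)
    valid = np.isfinite(p)
    out[valid] = np.searchsorted(np.asarray(scheme.breaks), p[valid],
                                 side="right")
    return out


def binarize(p_layer: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """1 where P >= threshold (inclusive), 0 below; NaN cells -> -1."""
    p = _check_probabilities(p_layer)
    out = np.full(p.shape, -1, dtype=int)
    valid = np.isfinite(p)
    out[valid] = (p[valid] >= threshold).astype(int)
    return out


def class_areas(class_layer: np.ndarray, grid: GridDef,
                scheme: ClassScheme = ClassScheme()) -> pd.DataFrame:
    """Spherical area and share of valid area per suitability class."""
    cls = np.asarray(class_layer)
    if cls.shape != grid.shape:
        raise ValueError("class layer shape does not match grid")
    areas = grid.area_grid_km2()
    valid = cls >= 0
    total = float(areas[valid].sum())
    rows = []
    for i, label in enumerate(scheme.labels):
        a = float(areas[cls == i].sum())
        rows.append({"class": label, "area_km2": a,
                     "percent_of_valid": 100.0 * a / total if total else 0.0})
    df = pd.DataFrame(rows).set_index("class")
    return with_suitable_total(df)


def with_suitable_total(df: pd.DataFrame) -> pd.DataFrame:
    """Append the suitable-total row: the sum over the low, medium and high
    classes (everything at or above the lowest suitability threshold)."""
    out = df.copy()
    out.loc["suitable_total"] = df.loc[["low", "medium", "high"]].sum()
    return out


def change(current: np.ndarray, future: np.ndarray, grid: GridDef,
           ) -> tuple[np.ndarray, ChangeSummary]:
    """Per-cell binary transition map and its area summary.

    Transition codes: 0 never suitable, 1 gained (0->1), 2 lost (1->0),
    3 retained (1->1); masked cells -1.
    """
    cur = np.asarray(current)
    fut = np.asarray(future)
    if cur.shape != grid.shape or fut.shape != grid.shape:
        raise ValueError("layer shapes do not match grid")
    if np.any((cur >= 0) != (fut >= 0)):
        raise ValueError("current/future masks differ")
    valid = cur >= 0
    code = np.full(cur.shape, -1, dtype=int)
    code[valid] = 2 * cur[valid] + fut[valid]

    areas = grid.area_grid_km2()
    summary = ChangeSummary(
        retained_area=float(areas[code == 3].sum()),
        lost_area=float(areas[code == 2].sum()),
        gained_area=float(areas[code == 1].sum()),
    )
    return code, summary


def jenks_breaks(values: np.ndarray, n_classes: int = 4,
                 max_points: int = 2000, seed: int = 0) -> list[float]:
    """Jenks natural-breaks class bounds (optional utility).

    Exact O(n^2 k) dynamic programme (Fisher's algorithm) on the sorted
    values; inputs larger than ``max_points`` are subsampled for
    tractability.  Returns the n_classes - 1 interior break values.  The
    pipeline's operative classifier uses the fixed thresholds instead.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < n_classes:
        raise ValueError("need at least n_classes values")
    if vals.size > max_points:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_points, replace=False)
    x = np.sort(vals)
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # sum of squared deviations of x[i:j]
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        cnt = j - i
        return s2 - s * s / cnt

    INF = np.inf
    cost = np.full((n_classes + 1, n + 1), INF)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cost[k, j] = best
            back[k, j] = arg
    cuts = []
    j = n
    for k in range(n_classes, 0, -1):
        i = back[k, j]
        if k > 1:
            cuts.append(float(x[i]))
        j = i
    return sorted(cuts)
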