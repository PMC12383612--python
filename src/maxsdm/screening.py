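"""Terrain derivation and collinearity screening of predictors.

Slope and aspect are derived from elevation with Horn's 3x3 method on the
lon/lat grid (per-row metric cell sizes).  Collinearity among candidate
predictors is measured with Spearman rank correlation; pairs exceeding the
threshold are resolved by discarding the member with the lower model
contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EnvStack, GridDef, M_PER_DEGREE
from .occurrences import OccurrenceSet, assign_cells

log = logging.getLogger(__name__)

FLAT_ASPECT = -1.0


@dataclass
class ScreeningResult:
    correlation: pd.DataFrame                  # symmetric Spearman matrix
    contributions: dict[str, float]            # percent contributions
    retained: list[str]
    dropped: list[tuple[str, str, float, str]] = field(default_factory=list)
    threshold: float = 0.75

    def report(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "retained", "partner": "",
                 "abs_r": np.nan, "reason": ""} for v in self.retained]
        rows += [{"variable": name, "status": "dropped", "partner": partner,
                  "abs_r": r, "reason": reason}
                 for name, partner, r, reason in self.dropped]
        return pd.DataFrame(rows)


def derive_terrain(elevation: np.ndarray, grid: GridDef,
                   mask: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees clockwise from north) via Horn's
    3x3 finite differences.

    The lon/lat grid is given per-row metric cell sizes
    dx = cell_size * 111195 m * cos(lat), dy = cell_size * 111195 m.
    Flat cells carry the aspect sentinel -1; edges use replicated padding.
    """
    z = np.asarray(elevation, dtype=float)
    if z.shape != grid.shape:
        raise ValueError("elevation shape does not match grid")
    zp = np.pad(z, 1, mode="edge")

    # 3x3 window: a b c / d e f / g h i, row 0 = north
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]

    dy_m = grid.cell_size * M_PER_DEGREE
    dx_m = (grid.cell_size * M_PER_DEGREE
            * np.cos(np.radians(grid.row_lats()))[:, None])

    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_m)
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * dy_m)  # + northward

    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    flat = (dz_dx == 0) & (dz_dy == 0)
    # downhill direction (-dz_dx east, -dz_dy north), azimuth from north
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    aspect[flat] = FLAT_ASPECT
    if mask is not None:
        slope = np.where(mask, slope, 0.0)
        aspect = np.where(mask, aspect, FLAT_ASPECT)
    return slope, aspect


def add_terrain_layers(stack: EnvStack, elevation_layer: str = "elevation",
                       ) -> EnvStack:
    """Append slope/aspect layers derived from the stack's elevation."""
    slope, aspect = derive_terrain(stack.layers[elevation_layer], stack.grid,
                                   stack.mask)
    stack.add_layer("slope", slope)
    stack.add_layer("aspect", aspect)
    return stack


def spearman_matrix(stack: EnvStack, at: OccurrenceSet | None = None,
                    names: list[str] | None = None) -> pd.DataFrame:
    """Spearman rank-correlation matrix between layers.

    By default the layers are sampled at the occurrence cells; with
    ``at=None`` the correlation is computed over all valid cells.  Pairs
    involving a constant layer are undefined and reported as NaN.
    """
    names = names if names is not None else stack.layer_names
    if at is not None:
        assignments, _ = assign_cells(at, stack.grid)
        cells = list(assignments.values())
        if len(cells) < 3:
            raise ValueError("need at least 3 sample points")
        rows = np.array([rc[0] for rc in cells])
        cols = np.array([rc[1] for rc in cells])
        data = stack.values_at_cells(rows, cols, names)
    else:
        data = stack.valid_values(names)
        if data.shape[0] < 3:
            raise ValueError("need at least 3 valid cells")

    k = len(names)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(data[:, i]) == 0 or np.ptp(data[:, j]) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(data[:, i], data[:, j]).statistic
            corr[i, j] = corr[j, i] = r
    return pd.DataFrame(corr, index=names, columns=names)


def prune_collinear(corr: pd.DataFrame, contributions: dict[str, float],
                    threshold: float = 0.75) -> ScreeningResult:
    """Greedily drop the lower-contribution member of each collinear pair.

    While any retained pair has \\|r\\| strictly above the threshold, the
    pair with the largest \\|r\\| is resolved (ties: lexicographic pair
    order) by discarding the variable with the lower contribution (ties:
    the lexicographically later name).  Undefined correlations count as 0.
    """
    names = list(corr.index)
    missing = [n for n in names if n not in contributions]
    if missing:
        raise ValueError(f"contributions missing for: {missing}")
    absr = corr.abs().to_numpy(copy=True)
    absr = np.nan_to_num(absr, nan=0.0)
    np.fill_diagonal(absr, 0.0)

    retained = set(names)
    dropped: list[tuple[str, str, float, str]] = []
    while True:
        best: tuple[float, str, str] | None = None
        for i, ni in enumerate(names):
            if ni not in retained:
                continue
            for j in range(i + 1, len(names)):
                nj = names[j]
                if nj not in retained or absr[i, j] <= threshold:
                    continue
                cand = (absr[i, j], ni, nj)
                if best is None or (cand[0], ) > (best[0], ) or \
                        (cand[0] == best[0] and (ni, nj) < (best[1], best[2])):
                    best = cand
        if best is None:
            break
        r, ni, nj = best
        ci, cj = contributions[ni], contributions[nj]
        if ci < cj:
            loser, keeper = ni, nj
        elif cj < ci:
            loser, keeper = nj, ni
        else:  # equal contribution: drop the lexicographically later name
            keeper, loser = sorted((ni, nj))
        retained.discard(loser)
        dropped.append((loser, keeper, float(r),
                        f"|r|={r:.3f}>{threshold} vs {keeper}; "
                        f"lower contribution"))
        log.info("screening: dropped %s (|r|=%.3f with %s)", loser, r, keeper)

    return ScreeningResult(
        correlation=corr,
        contributions=dict(contributions),
        retained=[n for n in names if n in retained],
        dropped=dropped,
        threshold=threshold,
    )
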