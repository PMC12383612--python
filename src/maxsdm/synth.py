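"""Synthetic landscapes with known suitability ground truth.

Generates (i) stacks of spatially autocorrelated environmental layers on a
lon/lat grid, (ii) a known Gibbs-form suitability surface over those layers,
and (iii) clustered presence points sampled proportionally to that surface.
Because the ground-truth coefficients are known, every downstream stage —
thinning, screening, model fitting, tuning, classification, change
detection, centroid tracking — can be validated without any external
climate or occurrence data.

Random fields are kernel-smoothed white noise: Gaussian white noise
convolved with a Gaussian kernel of configurable correlation length, then
affinely rescaled to a target range.  This gives controllable qualitative
spatial structure (what the downstream stages need) without attempting to
emulate real climatologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import EnvStack, GridDef
from .occurrences import OccurrenceRecord, OccurrenceSet


class EmptyDomainError(ValueError):
    """Raised when no valid cells remain to define a distribution over."""


@dataclass
class TruthModel:
    """Known Gibbs-form suitability surface used as simulation ground truth.

    suitability(cell) is proportional to exp(sum_j lambda_j f_j(cell)) over
    valid cells and normalised to sum to 1, i.e. exactly the functional form
    the maximum-entropy model estimates.
    """

    grid: GridDef
    coefficients: dict[str, float]
    feature_form: str
    suitability: np.ndarray          # 2-D, sums to 1 over valid cells
    mask: np.ndarray
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)


def generate_env_stack(grid: GridDef, layer_names: list[str],
                       corr_length: float = 5.0, seed: int = 0,
                       ranges: dict[str, tuple[float, float]] | None = None,
                       mask: np.ndarray | None = None) -> EnvStack:
    """Generate a stack of smoothed-random-field layers.

    Each layer is white noise convolved with a Gaussian kernel of scale
    ``corr_length`` (in cells; 0 means no smoothing), then rescaled to the
    layer's target range (default [0, 1]).  Deterministic given ``seed``.
    """
    if corr_length < 0:
        raise ValueError("corr_length must be >= 0")
    if len(set(layer_names)) != len(layer_names):
        raise ValueError("layer names must be unique")
    rng = np.random.default_rng(seed)
    stack = EnvStack(grid, {}, mask)
    for name in layer_names:
        field_ = rng.standard_normal(grid.shape)
        if corr_length > 0:
            field_ = ndimage.gaussian_filter(field_, sigma=corr_length,
                                             mode="reflect")
        lo, hi = (ranges or {}).get(name, (0.0, 1.0))
        fmin, fmax = field_.min(), field_.max()
        if fmax > fmin:
            field_ = lo + (field_ - fmin) / (fmax - fmin) * (hi - lo)
        else:
            field_ = np.full(grid.shape, (lo + hi) / 2.0)
        stack.add_layer(name, field_)
    return stack


def _truth_features(stack: EnvStack, names: list[str],
                    ) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, float]]]:
    """Min-max scaled layer values (and squares) keyed by feature name."""
    feats: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    for key in names:
        base = key[:-2] if key.endswith("^2") else key
        if base not in stack.layers:
            raise KeyError(f"coefficient {key!r} refers to unknown layer {base!r}")
        vals = stack.layers[base]
        vmin = float(vals[stack.mask].min())
        vmax = float(vals[stack.mask].max())
        scaling[base] = (vmin, vmax)
        scaled = (vals - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(vals)
        feats[key] = scaled ** 2 if key.endswith("^2") else scaled
    return feats, scaling


def make_truth(stack: EnvStack, coefficients: dict[str, float],
               feature_form: str = "linear") -> TruthModel:
    """Build the normalised Gibbs suitability surface for known coefficients.

    ``feature_form`` is "linear" (coefficients on scaled layer values) or
    "quadratic" (additionally allows keys like ``"elev^2"`` for squared
    scaled values).
    """
    if feature_form not in {"linear", "quadratic"}:
        raise ValueError(f"unknown feature_form {feature_form!r}")
    if feature_form == "linear" and any(k.endswith("^2") for k in coefficients):
        raise ValueError("squared terms require feature_form='quadratic'")
    if not np.any(stack.mask):
        raise EmptyDomainError("all cells masked: no domain to normalise over")

    feats, scaling = _truth_features(stack, list(coefficients))
    eta = np.zeros(stack.grid.shape)
    for key, lam in coefficients.items():
        eta += lam * feats[key]
    eta_valid = eta[stack.mask]
    # softmax over valid cells, stabilised
    w = np.exp(eta_valid - eta_valid.max())
    w /= w.sum()
    suit = np.zeros(stack.grid.shape)
    suit[stack.mask] = w
    return TruthModel(grid=stack.grid, coefficients=dict(coefficients),
                      feature_form=feature_form, suitability=suit,
                      mask=stack.mask.copy(), scaling=scaling)


def sample_occurrences(truth: TruthModel, n: int, cluster_sd: float = 0.005,
                       per_cluster: int = 1, seed: int = 0,
                       species: str = "synthetic") -> OccurrenceSet:
    """Sample clustered presence points proportionally to truth suitability.

    ``n`` cluster seeds are drawn cell-by-cell with probability equal to the
    suitability mass; each seed spawns ``per_cluster`` points jittered
    around the cell center with isotropic normal scale ``cluster_sd``
    degrees, clipped to the grid extent.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mass = truth.suitability[truth.mask]
    if mass.sum() <= 0:
        raise EmptyDomainError("truth surface carries no probability mass")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(truth.mask)
    draws = rng.choice(len(mass), size=n, p=mass / mass.sum())

    grid = truth.grid
    eps = 1e-9  # keep jittered points strictly inside the extent
    records: list[OccurrenceRecord] = []
    k = 0
    for d in draws:
        lon_c, lat_c = grid.cell_center(int(rows[d]), int(cols[d]))
        for _ in range(per_cluster):
            if cluster_sd > 0:
                lon = lon_c + rng.normal(0.0, cluster_sd)
                lat = lat_c + rng.normal(0.0, cluster_sd)
            else:
                lon, lat = lon_c, lat_c
            lon = float(np.clip(lon, grid.west + eps, grid.east - eps))
            lat = float(np.clip(lat, grid.south + eps, grid.north - eps))
            k += 1
            records.append(OccurrenceRecord(id=f"occ{k:05d}", lon=lon,
                                            lat=lat, species=species,
                                            source="synthetic"))
    return OccurrenceSet(records=records)


def default_fixture(seed: int = 0, n_layers: int = 8,
                    grid: GridDef | None = None,
                    ) -> tuple[EnvStack, TruthModel, OccurrenceSet]:
    """The standard synthetic study system used throughout the tests.

    A 60x90 grid of 2.5-arcminute cells (~2.5 deg x 3.75 deg window),
    ``n_layers`` autocorrelated layers, a truth surface driven by the first
    three layers, and ~150 raw clustered points that thin to roughly 48 —
    sized like a single-species national study.
    """
    if grid is None:
        grid = GridDef(n_rows=60, n_cols=90, west=100.0, north=40.0)
    names = [f"env{i + 1}" for i in range(n_layers)]
    ranges = {names[0]: (1.0, 4178.0)}  # one elevation-like layer
    stack = generate_env_stack(grid, names, corr_length=6.0, seed=seed,
                               ranges=ranges)
    coeffs = {names[0]: -2.0, names[1]: 3.0, names[2]: 1.5}
    truth = make_truth(stack, coeffs)
    occ = sample_occurrences(truth, n=50, cluster_sd=0.005, per_cluster=3,
                             seed=seed + 1)
    return stack, truth, occ
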