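"""Presence-background maximum-entropy model: fitting and prediction.

The model is the Gibbs distribution over background cells

    q(x) = exp(sum_j lambda_j f_j(x)) / Z

whose coefficients maximise the L1-penalised presence log-likelihood

    (1/m) sum_presence lambda . f(x_i)  -  log Z
        -  sum_j RM * beta_j * |lambda_j|.

This convex penalised-likelihood form has the same optimum as the classic
constrained maximum-entropy formulation and is solved here by cyclic
coordinate descent with soft-thresholded Newton steps and a backtracking
line search (the objective never decreases, so the solver is monotone and
deterministic).

Per-feature penalty weights beta_j follow class- and sample-size-dependent
schedules (linear interpolation in the presence count m), scaled by the
feature's background standard deviation and 1/sqrt(m); the global
regularization multiplier RM inflates all of them uniformly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import FeatureMatrix, FeatureSpec, build_features
from .grids import EnvStack

log = logging.getLogger(__name__)

#: per-class penalty schedules: (presence count, base beta) pairs,
#: linearly interpolated and clamped at the ends
BETA_SCHEDULES: dict[str, tuple[tuple[float, float], ...]] = {
    "L": ((10, 1.0), (30, 0.2), (100, 0.05)),
    "Q": ((10, 1.0), (30, 0.2), (100, 0.05)),
    "P": ((10, 2.6), (30, 1.0), (100, 0.25)),
    "H": ((0, 0.5), (100, 0.5)),
    "T": ((10, 2.0), (100, 1.0)),
}


def beta_for_class(cls: str, m: int) -> float:
    """Base penalty for a feature class at presence sample size m."""
    pts = BETA_SCHEDULES[cls]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(m, xs, ys))


def _soft(z: float, c: float) -> float:
    if z > c:
        return z - c
    if z < -c:
        return z + c
    return 0.0


@dataclass
class MaxEntModel:
    """A fitted maximum-entropy presence-background model."""

    spec: FeatureSpec
    feature_names: list[str]
    variable_names: list[str]
    lambdas: np.ndarray
    reg_multiplier: float
    betas: np.ndarray                       # per-feature, before RM scaling
    scaling: dict[str, tuple[float, float]]
    clamp_ranges: dict[str, tuple[float, float]]
    log_partition: float                    # log Z over training background
    entropy: float                          # H of fitted background distribution
    n_presence: int
    n_background: int
    bg_variable_means: dict[str, float]
    feature_parents: list[tuple[str, ...]] = field(default_factory=list)
    credits: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0

    # -- scoring -----------------------------------------------------------

    @property
    def n_params(self) -> int:
        """Number of non-zero coefficients."""
        return int(np.count_nonzero(self.lambdas))

    def _features_from_values(self, values: np.ndarray,
                              clamp: bool = False) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if clamp:
            values = values.copy()
            for j, v in enumerate(self.variable_names):
                lo, hi = self.clamp_ranges[v]
                values[:, j] = np.clip(values[:, j], lo, hi)
        fm = build_features(values, self.spec, self.variable_names,
                            scaling=self.scaling)
        return fm.values

    def eta(self, values: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Linear predictor lambda . f(x) for raw variable rows."""
        return self._features_from_values(values, clamp) @ self.lambdas

    def eta_from_features(self, fm: FeatureMatrix) -> np.ndarray:
        return fm.values @ self.lambdas

    def log_q(self, values: np.ndarray, clamp: bool = False) -> np.ndarray:
        """log q(x) relative to the training background normalisation."""
        return self.eta(values, clamp) - self.log_partition

    def logistic(self, values: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Logistic suitability index in [0, 1] (prevalence 0.5)."""
        z = self.log_q(values, clamp) + self.entropy
        return 1.0 / (1.0 + np.exp(-z))

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "classes": self.spec.classes,
            "hinge_knots": self.spec.hinge_knots,
            "threshold_knots": self.spec.threshold_knots,
            "reg_multiplier": self.reg_multiplier,
            "variable_names": self.variable_names,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "clamp_ranges": {k: list(v) for k, v in self.clamp_ranges.items()},
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "bg_variable_means": self.bg_variable_means,
            "features": [
                {"name": n, "lambda": float(l), "beta": float(b)}
                for n, l, b in zip(self.feature_names, self.lambdas, self.betas)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaxEntModel":
        with open(path) as fh:
            d = json.load(fh)
        spec = FeatureSpec(d["classes"], d["hinge_knots"], d["threshold_knots"])
        return cls(
            spec=spec,
            feature_names=[f["name"] for f in d["features"]],
            variable_names=d["variable_names"],
            lambdas=np.array([f["lambda"] for f in d["features"]]),
            reg_multiplier=d["reg_multiplier"],
            betas=np.array([f["beta"] for f in d["features"]]),
            scaling={k: tuple(v) for k, v in d["scaling"].items()},
            clamp_ranges={k: tuple(v) for k, v in d["clamp_ranges"].items()},
            log_partition=d["log_partition"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
            n_background=d["n_background"],
            bg_variable_means=d["bg_variable_means"],
        )


def fit(presence: FeatureMatrix, background: FeatureMatrix, rm: float = 1.0,
        seed: int | None = None, tol: float = 1e-6,
        max_iter: int = 5000) -> MaxEntModel:
    """Fit the penalised maximum-entropy model by coordinate descent.

    ``presence`` and ``background`` must share feature names and scaling
    (build both with the background's scaling).  ``seed`` is accepted for
    interface symmetry; the solver itself is deterministic.  ``max_iter``
    caps full coordinate sweeps; convergence is declared when the largest
    KKT violation falls below ``tol``.
    """
    if presence.names != background.names:
        raise ValueError("presence/background feature names differ")
    if presence.scaling != background.scaling:
        raise ValueError("presence/background scaling differ")
    if presence.n_samples == 0:
        raise ValueError("no presence samples")
    if rm < 0:
        raise ValueError("regularization multiplier must be >= 0")
    F_pr = presence.values
    F_bg = background.values
    if not (np.all(np.isfinite(F_pr)) and np.all(np.isfinite(F_bg))):
        raise ValueError("non-finite feature values")

    m, p = F_pr.shape
    N = F_bg.shape[0]
    pbar = F_pr.mean(axis=0)

    sd_bg = F_bg.std(axis=0)
    base_beta = np.array([beta_for_class(c, m) for c in background.classes]) \
        if p else np.empty(0)
    betas = base_beta * np.maximum(sd_bg, 1e-6) / np.sqrt(m)
    cvec = rm * betas

    lam = np.zeros(p)
    eta = np.zeros(N)
    logZ = float(np.log(N))
    credits: dict[str, float] = {v: 0.0 for v in background.variable_names}

    converged = False
    sweeps = 0
    for sweep in range(max_iter):
        sweeps = sweep + 1
        max_viol = 0.0
        improved = 0.0
        for j in range(p):
            fj = F_bg[:, j]
            w = np.exp(eta - logZ)
            Ef = float(w @ fj)
            g = pbar[j] - Ef
            c = cvec[j]
            if lam[j] != 0.0:
                viol = abs(g - c * np.sign(lam[j]))
            else:
                viol = max(0.0, abs(g) - c)
            if viol > max_viol:
                max_viol = viol
            if viol <= tol:
                continue
            h = float(w @ (fj * fj)) - Ef * Ef
            h = max(h, 1e-12)
            new = _soft(h * lam[j] + g, c) / h
            d = new - lam[j]
            if d == 0.0:
                continue
            # backtracking: the 1-D objective is concave in lambda_j, so a
            # halved Newton step eventually improves it
            accepted = False
            for _ in range(40):
                trial = lam[j] + d
                eta_t = eta + d * fj
                logZ_t = float(logsumexp(eta_t))
                delta = (pbar[j] * d - (logZ_t - logZ)
                         - c * (abs(trial) - abs(lam[j])))
                if delta > 0.0 or (delta > -1e-13 and abs(d) < 1e-9):
                    accepted = delta > 0.0
                    break
                d *= 0.5
            if not accepted:
                continue
            lam[j] = trial
            eta = eta_t
            logZ = logZ_t
            improved += delta
            share = 1.0 / len(background.parents[j])
            for v in background.parents[j]:
                credits[v] += delta * share
        if max_viol < tol:
            converged = True
            break
        if improved < 1e-13 and sweep > 0:
            # stalled: no coordinate can improve the objective further
            converged = max_viol < 1e-4
            break

    if not converged:
        log.warning("coordinate descent stopped after %d sweeps "
                    "(max KKT violation above tolerance)", sweeps)

    w = np.exp(eta - logZ)
    w = w / w.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.sum(np.where(w > 0, w * np.log(w), 0.0)))

    bg_means = {v: float(np.mean(
        _unscale_column(background, v)))
        for v in background.variable_names}

    return MaxEntModel(
        spec=background.spec,
        feature_names=list(background.names),
        variable_names=list(background.variable_names),
        lambdas=lam,
        reg_multiplier=rm,
        betas=betas,
        scaling=dict(background.scaling),
        clamp_ranges=dict(background.scaling),
        log_partition=logZ,
        entropy=ent,
        n_presence=m,
        n_background=N,
        bg_variable_means=bg_means,
        feature_parents=list(background.parents),
        credits=credits,
        converged=converged,
        n_iter=sweeps,
    )


def _unscale_column(fm: FeatureMatrix, variable: str) -> np.ndarray:
    """Recover raw values of a variable from its linear feature column."""
    lo, hi = fm.scaling[variable]
    try:
        j = fm.names.index(f"L({variable})")
        scaled = fm.values[:, j]
    except ValueError:
        # no linear feature built; mid-range is the only safe stand-in
        return np.array([0.5 * (lo + hi)])
    return lo + scaled * (hi - lo) if hi > lo else np.full(fm.n_samples, lo)


# -- prediction over rasters ------------------------------------------------

def predict(model: MaxEntModel, stack: EnvStack,
            output: str = "logistic", clamp: bool = False) -> np.ndarray:
    """Predict a suitability layer over an environment stack.

    ``output``:
      - ``raw``: q(x) renormalised over the prediction domain's valid cells
        (sums to 1);
      - ``logistic``: q * e^H / (1 + q * e^H) with the un-renormalised
        training q and the training-background entropy H (prevalence 0.5);
      - ``cumulative``: percentage of raw probability mass carried by cells
        with raw value <= the cell's own, scaled 0-100.

    ``clamp`` truncates each variable to its training range before feature
    construction (recommended when projecting to novel climates).
    """
    missing = [v for v in model.variable_names if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing model variable(s): {missing}")
    if output not in {"raw", "logistic", "cumulative"}:
        raise ValueError(f"unknown output type {output!r}")

    vals = stack.valid_values(model.variable_names)
    eta = model.eta(vals, clamp=clamp)

    out = np.full(stack.grid.shape, np.nan)
    if output == "raw":
        w = np.exp(eta - logsumexp(eta))
        out[stack.mask] = w
    elif output == "logistic":
        z = eta - model.log_partition + model.entropy
        out[stack.mask] = 1.0 / (1.0 + np.exp(-z))
    else:  # cumulative
        w = np.exp(eta - logsumexp(eta))
        order = np.argsort(w, kind="stable")
        csum = np.cumsum(w[order])
        cum = np.empty_like(w)
        # equal raw values share the mass at or below their common value
        uniq, inv = np.unique(w, return_inverse=True)
        mass_at_or_below = np.empty_like(uniq)
        sorted_w = w[order]
        for i, u in enumerate(uniq):
            mass_at_or_below[i] = csum[np.searchsorted(sorted_w, u, "right") - 1]
        cum = mass_at_or_below[inv] * 100.0
        out[stack.mask] = cum
    return out


def training_gain(model: MaxEntModel, presence: FeatureMatrix) -> float:
    """Regularised training gain: penalised mean presence log-probability
    improvement over the uniform background model (0 for the uniform model,
    >= 0 for any fitted model)."""
    eta = presence.values @ model.lambdas
    penalty = float(model.reg_multiplier * model.betas @ np.abs(model.lambdas))
    return float(eta.mean() - model.log_partition
                 + np.log(model.n_background) - penalty)


def percent_contribution(model: MaxEntModel) -> pd.Series:
    """Percent contribution per variable from the fit's objective credits.

    Each accepted coordinate update's objective improvement is credited to
    the feature's underlying variable (product features split equally);
    credits are normalised to sum to 100.
    """
    credits = pd.Series(model.credits, dtype=float).clip(lower=0.0)
    total = credits.sum()
    if total <= 0:
        log.warning("zero total training gain: contributions undefined, "
                    "reporting 0 for all variables")
        return credits * 0.0
    return 100.0 * credits / total


def jackknife(presence_values: np.ndarray, background_values: np.ndarray,
              variable_names: list[str], spec: FeatureSpec,
              rm: float = 1.0, **fit_kwargs) -> pd.DataFrame:
    """Jackknife variable importance via refits.

    For each variable: refit using only that variable and using all other
    variables; report regularised training gains alongside the full model's.
    """
    if len(variable_names) < 2:
        raise ValueError("jackknife requires at least 2 variables")
    presence_values = np.atleast_2d(np.asarray(presence_values, dtype=float))
    background_values = np.atleast_2d(np.asarray(background_values, dtype=float))

    def gain_for(names: list[str], cols: list[int]) -> float:
        bg = build_features(background_values[:, cols], spec, names)
        pr = build_features(presence_values[:, cols], spec, names,
                            scaling=bg.scaling)
        mod = fit(pr, bg, rm=rm, **fit_kwargs)
        return training_gain(mod, pr)

    all_cols = list(range(len(variable_names)))
    full_gain = gain_for(list(variable_names), all_cols)
    rows = []
    for i, v in enumerate(variable_names):
        others = [j for j in all_cols if j != i]
        rows.append({
            "variable": v,
            "gain_only": gain_for([v], [i]),
            "gain_without": gain_for([variable_names[j] for j in others],
                                     others),
            "gain_full": full_gain,
        })
    return pd.DataFrame(rows).set_index("variable")


def response_curve(model: MaxEntModel, variable: str,
                   n_points: int = 100) -> pd.DataFrame:
    """Marginal response curve: logistic output as the target variable
    sweeps its training range with all other variables held at their
    background means."""
    if variable not in model.variable_names:
        raise KeyError(f"{variable!r} not a model variable")
    lo, hi = model.clamp_ranges[variable]
    grid = np.linspace(lo, hi, n_points)
    base = np.array([model.bg_variable_means[v] for v in model.variable_names])
    vals = np.tile(base, (n_points, 1))
    vals[:, model.variable_names.index(variable)] = grid
    suit = model.logistic(vals)
    return pd.DataFrame({"value": grid, "suitability": suit})


def optimal_range(curve: pd.DataFrame,
                  threshold: float = 0.5) -> tuple[float, float] | None:
    """Smallest and largest curve values with suitability >= threshold,
    linearly interpolated at the crossings; None if never reached."""
    x = curve["value"].to_numpy(dtype=float)
    y = curve["suitability"].to_numpy(dtype=float)
    above = y >= threshold
    if not above.any():
        return None
    first = int(np.argmax(above))
    last = len(y) - 1 - int(np.argmax(above[::-1]))
    lo = x[first]
    if first > 0:
        x0, x1, y0, y1 = x[first - 1], x[first], y[first - 1], y[first]
        lo = x0 + (threshold - y0) / (y1 - y0) * (x1 - x0)
    hi = x[last]
    if last < len(y) - 1:
        x0, x1, y0, y1 = x[last], x[last + 1], y[last], y[last + 1]
        hi = x0 + (threshold - y0) / (y1 - y0) * (x1 - x0)
    return float(lo), float(hi)


def sample_background(stack: EnvStack, n_max: int = 10_000,
                      seed: int | None = None,
                      variable_names: list[str] | None = None,
                      ) -> np.ndarray:
    """Uniform random sample of valid cells' variable values, without
    replacement, capped at ``n_max`` (presence cells are not excluded)."""
    vals = stack.valid_values(variable_names)
    n_valid = vals.shape[0]
    if n_valid <= n_max:
        return vals
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_valid, size=n_max, replace=False)
    return vals[np.sort(idx)]
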