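"""Tuning over the RM x FC grid and model evaluation.

Candidate models over a grid of regularization multipliers and feature-class
combinations are compared with small-sample-corrected AIC (AICc, on the
full-data fit), the 10th-percentile training omission rate (OR10), and the
train-minus-test AUC difference (both cross-validated).  The selected model
minimises Delta.AICc, with ties broken by lower OR10, lower AUC.diff, then
fewer parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (FC_GRID_DEFAULT, RM_GRID_DEFAULT, FeatureSpec,
                       build_features)
from .grids import EnvStack
from .model import MaxEntModel, fit, predict

log = logging.getLogger(__name__)


@dataclass
class Partition:
    """Fold assignment of presence samples for cross-validation."""

    scheme: str                 # "random_kfold" or "subsample_75_25"
    k: int
    assignments: np.ndarray     # per-presence fold label (kfold) or per-rep
                                # boolean train masks (subsample), see make()
    seed: int = 0
    train_masks: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def make(cls, n: int, scheme: str = "random_kfold", k: int = 5,
             seed: int = 0, train_frac: float = 0.75) -> "Partition":
        rng = np.random.default_rng(seed)
        if scheme == "random_kfold":
            if k > n:
                raise ValueError("k exceeds number of presences")
            labels = np.arange(n) % k
            rng.shuffle(labels)
            masks = [labels != fold for fold in range(k)]
            return cls(scheme, k, labels, seed, masks)
        if scheme == "subsample_75_25":
            masks = []
            n_train = max(1, int(round(train_frac * n)))
            if n_train >= n:
                n_train = n - 1
            for _ in range(k):
                idx = rng.permutation(n)
                mask = np.zeros(n, dtype=bool)
                mask[idx[:n_train]] = True
                masks.append(mask)
            return cls(scheme, k, np.zeros(n, dtype=int), seed, masks)
        raise ValueError(f"unknown partition scheme {scheme!r}")


@dataclass
class CandidateResult:
    fc: str
    rm: float
    aicc: float | None
    delta_aicc: float | None
    or10: float
    auc_diff: float
    auc_train: float
    n_params: int

    def as_row(self) -> dict:
        return {"fc": self.fc, "rm": self.rm, "aicc": self.aicc,
                "delta_aicc": self.delta_aicc, "or10": self.or10,
                "auc_diff": self.auc_diff, "auc_train": self.auc_train,
                "n_params": self.n_params}


def aicc(model: MaxEntModel, presence_eta: np.ndarray) -> float | None:
    """Small-sample-corrected AIC from presence log-likelihoods.

    L = sum over presences of log(raw q normalised over background);
    k = number of non-zero coefficients.  Undefined (None) when
    m - k - 1 <= 0.
    """
    m = len(presence_eta)
    k = model.n_params
    if m - k - 1 <= 0:
        return None
    ll = float(np.sum(presence_eta - model.log_partition))
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (m - k - 1)


def or10(train_scores: np.ndarray, test_scores: np.ndarray) -> float | None:
    """10th-percentile training omission rate.

    The threshold is the ceil(0.1 * n_train)-th smallest training score; the
    rate is the fraction of test scores strictly below it.
    """
    train_scores = np.asarray(train_scores, dtype=float)
    test_scores = np.asarray(test_scores, dtype=float)
    if train_scores.size == 0:
        raise ValueError("empty training scores")
    if test_scores.size == 0:
        return None
    rank = math.ceil(0.1 * train_scores.size)
    thr = np.sort(train_scores)[rank - 1]
    return float(np.mean(test_scores < thr))


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    combined = np.concatenate([pos, neg])
    ranks = pd.Series(combined).rank(method="average").to_numpy()
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_curve(pos_scores: np.ndarray, neg_scores: np.ndarray,
              ) -> pd.DataFrame:
    """ROC points (false positive rate, true positive rate) over all
    distinct score thresholds, from (0,0) to (1,1)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def auc_accuracy_band(auc_value: float) -> str:
    """Conventional five-level qualitative label for a model's AUC."""
    if auc_value < 0.6:
        return "ineffective"
    if auc_value < 0.7:
        return "low reliability"
    if auc_value < 0.8:
        return "effective"
    if auc_value < 0.9:
        return "high prediction accuracy"
    return "excellent"


def _fit_scores(presence_values: np.ndarray, background_values: np.ndarray,
                variable_names: list[str], spec: FeatureSpec, rm: float,
                train_mask: np.ndarray | None = None, **fit_kwargs,
                ) -> tuple[MaxEntModel, np.ndarray, np.ndarray, np.ndarray]:
    """Fit on (a subset of) presences; return model and eta scores for
    train presences, test presences, and background."""
    bg = build_features(background_values, spec, variable_names)
    if train_mask is None:
        train_vals = presence_values
        test_vals = presence_values[:0]
    else:
        train_vals = presence_values[train_mask]
        test_vals = presence_values[~train_mask]
    pr = build_features(train_vals, spec, variable_names, scaling=bg.scaling)
    mod = fit(pr, bg, rm=rm, **fit_kwargs)
    s_train = pr.values @ mod.lambdas
    s_test = mod.eta(test_vals) if len(test_vals) else np.empty(0)
    s_bg = bg.values @ mod.lambdas
    return mod, s_train, s_test, s_bg


def tune(presence_values: np.ndarray, background_values: np.ndarray,
         variable_names: list[str],
         fc_grid: tuple[str, ...] = FC_GRID_DEFAULT,
         rm_grid: tuple[float, ...] = RM_GRID_DEFAULT,
         partition: Partition | None = None,
         hinge_knots: int = 30, threshold_knots: int = 30,
         **fit_kwargs) -> tuple[list[CandidateResult], CandidateResult]:
    """Evaluate every (FC, RM) candidate; return all results and the best.

    The full-data fit supplies AICc and the parameter count; the
    cross-validated fits supply mean OR10 and AUC.diff.  Candidates whose
    AICc is undefined are kept in the table but excluded from the
    Delta.AICc minimum and from selection.
    """
    if not fc_grid or not rm_grid:
        raise ValueError("fc_grid and rm_grid must be non-empty")
    presence_values = np.atleast_2d(np.asarray(presence_values, dtype=float))
    m = presence_values.shape[0]
    if partition is None:
        partition = Partition.make(m, "random_kfold", k=min(5, m), seed=0)

    results: list[CandidateResult] = []
    for fc in fc_grid:
        spec = FeatureSpec(fc, hinge_knots, threshold_knots)
        for rm in rm_grid:
            mod, s_tr, _, _ = _fit_scores(presence_values, background_values,
                                          variable_names, spec, rm,
                                          **fit_kwargs)
            a = aicc(mod, s_tr)
            ors, diffs, aucs_tr = [], [], []
            for mask in partition.train_masks:
                _, f_tr, f_te, f_bg = _fit_scores(
                    presence_values, background_values, variable_names,
                    spec, rm, train_mask=mask, **fit_kwargs)
                o = or10(f_tr, f_te)
                if o is not None:
                    ors.append(o)
                a_tr = auc(f_tr, f_bg)
                a_te = auc(f_te, f_bg) if len(f_te) else np.nan
                aucs_tr.append(a_tr)
                if np.isfinite(a_te):
                    diffs.append(a_tr - a_te)
            results.append(CandidateResult(
                fc=fc, rm=float(rm), aicc=a, delta_aicc=None,
                or10=float(np.mean(ors)) if ors else np.nan,
                auc_diff=float(np.mean(diffs)) if diffs else np.nan,
                auc_train=float(np.mean(aucs_tr)),
                n_params=mod.n_params))

    valid = [r.aicc for r in results if r.aicc is not None]
    if not valid:
        raise ValueError("AICc undefined for every candidate")
    a_min = min(valid)
    for r in results:
        r.delta_aicc = None if r.aicc is None else r.aicc - a_min

    def sort_key(r: CandidateResult):
        o = r.or10 if np.isfinite(r.or10) else np.inf
        d = r.auc_diff if np.isfinite(r.auc_diff) else np.inf
        return (r.delta_aicc, o, d, r.n_params)

    best = min((r for r in results if r.delta_aicc is not None), key=sort_key)
    log.info("tuning: selected FC=%s RM=%.1f (Delta.AICc=0, OR10=%.3f, "
             "AUC.diff=%.3f)", best.fc, best.rm, best.or10, best.auc_diff)
    return results, best


def tuning_table(results: list[CandidateResult]) -> pd.DataFrame:
    """Candidate table with the standard tuning columns."""
    df = pd.DataFrame([r.as_row() for r in results])
    return df.rename(columns={
        "fc": "Feature Combination", "rm": "Regularization Multiplier",
        "delta_aicc": "Delta.AICc", "or10": "OR10", "auc_diff": "AUC.diff",
    })


@dataclass
class ReplicateSummary:
    mean_layer: np.ndarray
    auc_train: list[float]
    auc_test: list[float]
    models: list[MaxEntModel]

    @property
    def auc_train_mean(self) -> float:
        return float(np.mean(self.auc_train))

    @property
    def auc_train_sd(self) -> float:
        return float(np.std(self.auc_train, ddof=1)) \
            if len(self.auc_train) > 1 else 0.0

    @property
    def accuracy_band(self) -> str:
        return auc_accuracy_band(self.auc_train_mean)


def replicate_runs(presence_values: np.ndarray, background_values: np.ndarray,
                   variable_names: list[str], stack: EnvStack,
                   fc: str = "LQH", rm: float = 4.0, n_rep: int = 10,
                   split: float = 0.75, seed: int = 0,
                   hinge_knots: int = 30, threshold_knots: int = 30,
                   clamp: bool = False, **fit_kwargs) -> ReplicateSummary:
    """Final-model replication: n_rep random train/test splits, each fitted
    and evaluated; the suitability layer is the cell-wise mean of the
    replicates' logistic predictions."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    presence_values = np.atleast_2d(np.asarray(presence_values, dtype=float))
    m = presence_values.shape[0]
    spec = FeatureSpec(fc, hinge_knots, threshold_knots)
    part = Partition.make(m, "subsample_75_25", k=n_rep, seed=seed,
                          train_frac=split)
    layers, aucs_tr, aucs_te, models = [], [], [], []
    for mask in part.train_masks:
        mod, s_tr, s_te, s_bg = _fit_scores(
            presence_values, background_values, variable_names, spec, rm,
            train_mask=mask, **fit_kwargs)
        aucs_tr.append(auc(s_tr, s_bg))
        if len(s_te):
            aucs_te.append(auc(s_te, s_bg))
        layers.append(predict(mod, stack, output="logistic", clamp=clamp))
        models.append(mod)
    mean_layer = np.nanmean(np.stack(layers), axis=0) if layers else None
    mean_layer = np.where(stack.mask, mean_layer, np.nan)
    return ReplicateSummary(mean_layer=mean_layer, auc_train=aucs_tr,
                            auc_test=aucs_te, models=models)
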