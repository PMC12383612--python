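"""End-to-end orchestration: simulate -> thin -> screen -> tune -> fit ->
project -> classify -> change -> centroid.

The pipeline runs on synthetic landscapes with known ground truth (see
:mod:`maxsdm.synth`): a current-period environment stack is generated,
future-scenario stacks are derived from it by imposing a poleward
environmental drift whose strength grows with scenario forcing and period,
and every downstream stage then operates exactly as it would on real
rasters.  All stages draw their seeds deterministically from one master
seed, so a config re-run reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import habitat, rangeshift, screening, selection, synth
from .features import FC_GRID_DEFAULT, RM_GRID_DEFAULT, FeatureSpec, build_features
from .grids import CELL_2P5_ARCMIN, EnvStack, GridDef, write_ascii_grid
from .model import fit, percent_contribution, sample_background
from .model import predict as model_predict
from .occurrences import OccurrenceSet, thin

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "maxsdm_run"
    seed: int = 0

    # synthetic landscape
    n_rows: int = 60
    n_cols: int = 90
    west: float = 100.0
    north: float = 40.0
    cell_size: float = CELL_2P5_ARCMIN
    n_layers: int = 8
    corr_length: float = 6.0
    n_clusters: int = 50
    per_cluster: int = 3
    cluster_sd: float = 0.005
    scenarios: tuple[str, ...] = ("ssp126", "ssp370", "ssp585")
    periods: tuple[str, ...] = ("2050s", "2070s", "2090s")
    #: scenario forcing factors controlling the synthetic poleward drift
    scenario_strength: dict = field(default_factory=lambda: {
        "ssp126": 0.5, "ssp370": 1.0, "ssp585": 1.5})
    drift_frac: float = 0.06   # per period step, fraction of layer range

    # screening
    screening_threshold: float = 0.75
    prelim_fc: str = "LQH"
    prelim_rm: float = 1.0

    # tuning and final model
    fc_grid: tuple[str, ...] = FC_GRID_DEFAULT
    rm_grid: tuple[float, ...] = RM_GRID_DEFAULT
    cv_folds: int = 5
    hinge_knots: int = 30
    threshold_knots: int = 30
    n_background: int = 10_000
    n_rep: int = 10
    split: float = 0.75

    # classification / change / centroid
    class_breaks: tuple[float, float, float] = (0.1, 0.3, 0.5)
    binary_threshold: float = 0.1
    years_between: float = 20.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for name in ("binary_threshold",):
            if not (0 < getattr(cfg, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh)


def make_future_stack(current: EnvStack, strength: float, period_idx: int,
                      drift_frac: float) -> EnvStack:
    """Derive a future-scenario stack by poleward environmental drift.

    Each layer gains ``drift_frac * strength * (period_idx + 1)`` of its own
    range, weighted by a north-south gradient, so environmental conditions
    migrate poleward with forcing — the qualitative signature of warming
    scenarios the change and centroid stages need to detect.
    """
    grid = current.grid
    northness = ((grid.row_lats() - grid.south)
                 / (grid.north - grid.south))[:, None]
    layers = {}
    for name, vals in current.layers.items():
        amp = drift_frac * strength * (period_idx + 1) * np.ptp(vals)
        layers[name] = vals + amp * northness
    return EnvStack(grid, layers, current.mask.copy())


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle and writes all
    tables/layers under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog: list[dict] = []

    def record(stage: str, **info) -> None:
        entry = {"stage": stage, **info}
        runlog.append(entry)
        log.info("stage %s: %s", stage, info)

    # -- simulate ------------------------------------------------------
    grid = GridDef(config.n_rows, config.n_cols, config.west, config.north,
                   config.cell_size)
    names = [f"env{i + 1}" for i in range(config.n_layers)]
    sseed = stage_seed(config.seed, "simulate")
    current = synth.generate_env_stack(
        grid, names, corr_length=config.corr_length, seed=sseed,
        ranges={names[0]: (1.0, 4178.0)})
    coeffs = {names[0]: -2.0, names[1]: 3.0, names[2]: 1.5}
    truth = synth.make_truth(current, coeffs)
    raw_occ = synth.sample_occurrences(
        truth, n=config.n_clusters, cluster_sd=config.cluster_sd,
        per_cluster=config.per_cluster, seed=stage_seed(config.seed, "occ"))
    raw_occ.to_csv(out / "occurrences_raw.csv")
    stacks: dict[tuple[str, str], EnvStack] = {("current", ""): current}
    for scen in config.scenarios:
        for i, period in enumerate(config.periods):
            stacks[(period, scen)] = make_future_stack(
                current, config.scenario_strength[scen], i, config.drift_frac)
    record("simulate", seed=sseed, n_raw_points=len(raw_occ),
           n_stacks=len(stacks))

    # -- thin ----------------------------------------------------------
    occ = thin(raw_occ, grid, stack=current)
    occ.to_csv(out / "occurrences_thinned.csv")
    record("thin", n_before=len(raw_occ), n_after=len(occ))

    # -- screen --------------------------------------------------------
    rows, cols = grid.locate(occ.lons, occ.lats)
    presence_all = current.values_at_cells(rows, cols, names)
    bg_seed = stage_seed(config.seed, "background")
    background_all = sample_background(current, config.n_background,
                                       seed=bg_seed, variable_names=names)
    prelim_spec = FeatureSpec(config.prelim_fc, config.hinge_knots,
                              config.threshold_knots)
    bg_fm = build_features(background_all, prelim_spec, names)
    pr_fm = build_features(presence_all, prelim_spec, names,
                           scaling=bg_fm.scaling)
    prelim = fit(pr_fm, bg_fm, rm=config.prelim_rm)
    contributions = percent_contribution(prelim).to_dict()
    corr = screening.spearman_matrix(current, at=occ, names=names)
    corr.to_csv(out / "spearman_matrix.csv")
    screen = screening.prune_collinear(corr, contributions,
                                       config.screening_threshold)
    screen.report().to_csv(out / "screening_report.csv", index=False)
    retained = screen.retained
    record("screen", retained=retained,
           dropped=[d[0] for d in screen.dropped])

    keep_idx = [names.index(v) for v in retained]
    presence = presence_all[:, keep_idx]
    background = background_all[:, keep_idx]

    # -- tune ----------------------------------------------------------
    part = selection.Partition.make(
        len(occ), "random_kfold", k=min(config.cv_folds, len(occ)),
        seed=stage_seed(config.seed, "tune"))
    results, best = selection.tune(
        presence, background, retained, fc_grid=config.fc_grid,
        rm_grid=config.rm_grid, partition=part,
        hinge_knots=config.hinge_knots,
        threshold_knots=config.threshold_knots)
    selection.tuning_table(results).to_csv(out / "tuning_table.csv",
                                           index=False)
    record("tune", best_fc=best.fc, best_rm=best.rm,
           n_candidates=len(results))

    # -- fit + project ---------------------------------------------------
    # the replicate models are fitted once (training domain = current
    # stack); each future stack only needs re-projection with clamping
    rep = selection.replicate_runs(
        presence, background, retained, current.subset(retained),
        fc=best.fc, rm=best.rm, n_rep=config.n_rep, split=config.split,
        seed=stage_seed(config.seed, "replicates"),
        hinge_knots=config.hinge_knots,
        threshold_knots=config.threshold_knots, clamp=False)
    auc_summary = {"auc_train_mean": rep.auc_train_mean,
                   "auc_train_sd": rep.auc_train_sd,
                   "accuracy_band": rep.accuracy_band}
    suit_layers: dict[tuple[str, str], np.ndarray] = {}
    for (period, scen), stack in stacks.items():
        is_current = period == "current"
        if is_current:
            mean_layer = rep.mean_layer
        else:
            preds = [model_predict(mod, stack.subset(retained),
                                   output="logistic", clamp=True)
                     for mod in rep.models]
            mean_layer = np.where(stack.mask,
                                  np.nanmean(np.stack(preds), axis=0), np.nan)
        key = period if is_current else f"{period}_{scen}"
        suit_layers[(period, scen)] = mean_layer
        write_ascii_grid(out / f"suitability_{key}.asc", mean_layer,
                         grid, mask=stack.mask)
    record("fit_project", **auc_summary)

    # -- classify + change ----------------------------------------------
    scheme = habitat.ClassScheme(breaks=tuple(config.class_breaks))
    area_rows = []
    for (period, scen), layer in suit_layers.items():
        cls = habitat.classify(layer, scheme)
        areas = habitat.class_areas(cls, grid, scheme)
        for label, row in areas.iterrows():
            area_rows.append({"period": period, "scenario": scen,
                              "class": label,
                              "area_1e4_km2": row["area_km2"] / 1e4,
                              "percent": row["percent_of_valid"]})
    pd.DataFrame(area_rows).to_csv(out / "class_areas.csv", index=False)

    cur_bin = habitat.binarize(suit_layers[("current", "")],
                               config.binary_threshold)
    change_rows = []
    for scen in config.scenarios:
        for period in config.periods:
            fut_bin = habitat.binarize(suit_layers[(period, scen)],
                                       config.binary_threshold)
            _, summary = habitat.change(cur_bin, fut_bin, grid)
            change_rows.append({"Period": f"{period}-{scen}",
                                **summary.as_row()})
    change_df = pd.DataFrame(change_rows)
    change_df.to_csv(out / "change_summary.csv", index=False)
    record("change", n_rows=len(change_rows))

    # -- centroids -------------------------------------------------------
    seg_frames = []
    track_files = []
    for scen in config.scenarios:
        cents = [rangeshift.weighted_centroid(
            suit_layers[("current", "")], grid, config.binary_threshold,
            period="current", scenario=scen)]
        cents += [rangeshift.weighted_centroid(
            suit_layers[(p, scen)], grid, config.binary_threshold,
            period=p, scenario=scen) for p in config.periods]
        segments, cumulative = rangeshift.build_track(
            cents, years_between=config.years_between)
        seg_frames.append(rangeshift.track_table(segments))
        gj = rangeshift.track_geojson(cents, segments)
        path = out / f"centroid_track_{scen}.geojson"
        rangeshift.write_geojson(path, gj)
        track_files.append(str(path))
    segments_df = pd.concat(seg_frames, ignore_index=True)
    segments_df.to_csv(out / "centroid_segments.csv", index=False)
    record("centroid", n_segments=len(segments_df))

    with open(out / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "stages": runlog}, fh, indent=1,
                  default=str)

    return {
        "grid": grid,
        "truth": truth,
        "occurrences": occ,
        "screening": screen,
        "tuning": results,
        "best": best,
        "suitability": suit_layers,
        "auc": auc_summary,
        "change": change_df,
        "segments": segments_df,
        "track_files": track_files,
        "run_log": runlog,
    }
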