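"""End-to-end orchestration: images (or analytic series) to evaluated model.

Two entry paths share the downstream stages:

* :func:`process_image_series` runs the image path for one plant —
  registration, Excess-Green segmentation, center detection, lagged dense
  flow, radial projection and per-frame aggregation — yielding a
  :class:`~leafflow.features.PlantTimeSeries`.
* :func:`run_pipeline` takes a cohort (typically the synthetic generator's
  analytic mode), extracts the 115 features with the PCA blocks fitted on
  the training split only, tunes and evaluates the requested models, and
  returns a stamped report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import (
    FEATURE_NAMES,
    PCABlockExtractor,
    PlantTimeSeries,
    feature_matrix,
    ld_labels,
)
from .flow import dense_flow, pair_frames
from .normals import aggregate_frame, radial_projection
from .preprocessing import (
    CenterDetectionError,
    detect_center,
    exg_mask,
    plant_roi,
    register_series,
    resize_image,
)
from .prediction import EvaluationReport, ModelSpec, default_gbr_grid, default_svr_grid, evaluate, grouped_importance, split_dataset, tune_model
from .synthetic import AnalyticSeries, Cohort, RosetteSeries


@dataclass
class PipelineResult:
    features: pd.DataFrame  # one row per plant, canonical 115 columns
    weights: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    reports: dict[str, EvaluationReport]
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_plants": len(self.weights),
            "n_features": self.features.shape[1],
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
        }


def process_image_series(
    frames: list[np.ndarray],
    cfg: PipelineConfig,
    *,
    fallback_center: tuple[float, float] | None = None,
) -> PlantTimeSeries:
    """Image path for a single plant: frames in, movement series out.

    Frames are registered to the first frame, segmented with Excess Green,
    and the seedling center is Hough-detected on the first frame (falling
    back to ``fallback_center`` if detection fails). Dense flow is computed
    between frames ``lag`` apart on the flow-resolution raster and each
    field is radially projected and aggregated.
    """
    if len(frames) <= cfg.lag_frames:
        raise ValueError("not enough frames for the configured lag")
    interval_h = cfg.capture_interval_min / 60.0
    registered = register_series(
        [np.asarray(f) for f in frames],
        [i * interval_h for i in range(len(frames))],
    )
    small = [resize_image(r.image, cfg.resize_flow) for r in registered]
    try:
        center = detect_center(small[0], cfg.roi_radius_px)
    except CenterDetectionError:
        if fallback_center is None:
            raise
        center = fallback_center
    pairs = pair_frames(len(frames), cfg.capture_interval_min, cfg.lag_hours)
    aggregates = []
    for k_prev, k in pairs:
        field = dense_flow(
            small[k_prev - 1], small[k - 1], backend=cfg.flow_backend,
            frame_index=k, lag_frames=cfg.lag_frames,
        )
        veg = exg_mask(small[k - 1], cfg.exg_threshold)
        roi = plant_roi(center, cfg.roi_radius_px, veg)
        aggregates.append(aggregate_frame(radial_projection(field, roi), frame_index=k))
    ks = np.array([a.frame_index for a in aggregates])
    t = (ks - ks[0]) * interval_h
    return PlantTimeSeries(
        t=t,
        magnitude=np.array([a.magnitude for a in aggregates]),
        angle=np.array([a.theta for a in aggregates]),
        pa=np.array([a.s for a in aggregates], dtype=float),
        ld_label=ld_labels(t, cfg.ld_schedule),
        k=ks,
    )


def _to_timeseries(series, cfg: PipelineConfig) -> PlantTimeSeries:
    if isinstance(series, PlantTimeSeries):
        return series
    if isinstance(series, AnalyticSeries):
        return PlantTimeSeries(
            t=series.t, magnitude=series.magnitude, angle=series.angle,
            pa=series.pa, ld_label=ld_labels(series.t, cfg.ld_schedule),
        )
    if isinstance(series, RosetteSeries):
        return process_image_series(
            series.images, cfg, fallback_center=series.truth.center
        )
    raise TypeError(f"unsupported series type {type(series)!r}")


def run_pipeline(
    cfg: PipelineConfig,
    cohort: Cohort,
    *,
    models: tuple[str, ...] = ("gbr",),
) -> PipelineResult:
    """Features + tuned models + held-out evaluation for a cohort.

    The PCA feature blocks and all model fitting see the training split
    only; the held-out split is used once, for the reported correlation.
    """
    series = [_to_timeseries(s, cfg) for s in cohort.series]
    weights = np.asarray(cohort.weights, dtype=float)
    train_idx, test_idx = split_dataset(
        len(series), cfg.test_fraction, cfg.child_seed("split")
    )
    pca = PCABlockExtractor(cfg.pca_components, seed=cfg.child_seed("pca"))
    pca.fit([series[i] for i in train_idx])
    feats = feature_matrix(
        series, cohort.ppfd, cohort.track, pca,
        schedule=cfg.ld_schedule, shifts_hours=cfg.shifts_hours,
    )
    X = feats.to_numpy()
    reports: dict[str, EvaluationReport] = {}
    for kind in models:
        grid = (
            default_gbr_grid(cfg.reduced_grids)
            if kind == "gbr"
            else default_svr_grid(cfg.reduced_grids)
        )
        spec = ModelSpec(kind=kind, grid=grid, cv_folds=cfg.cv_folds,
                         seed=cfg.child_seed(f"model-{kind}"))
        model, best, folds = tune_model(spec, X[train_idx], weights[train_idx])
        corr = evaluate(model, X[test_idx], weights[test_idx])
        grouped = grouped_importance(model) if kind == "gbr" else None
        reports[kind] = EvaluationReport(
            kind=kind, test_correlation=corr, best_params=best,
            cv_r2=folds, grouped_importances=grouped,
        )
    return PipelineResult(
        features=feats, weights=weights, train_idx=train_idx, test_idx=test_idx,
        reports=reports, config_hash=cfg.config_hash(), seed=cfg.seed,
    )
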