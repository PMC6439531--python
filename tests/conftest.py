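import numpy as np
import pytest

import leafflow as lf


@pytest.fixture(scope="session")
def expanding_rosette():
    """Rendered series with strong radial expansion over a 12-h baseline."""
    truth = lf.PlantTruth(
        center=(80, 60), initial_area=250, growth_rate=0.015,
        nutation_amplitude=4, nutation_phase=-np.pi / 2,
    )
    cfg = lf.SimConfig(
        n_frames=13, capture_interval_min=60.0, image_size=(160, 120),
        seed=3, noise_sd=1.0, panel_drift_amplitude=0.0,
    )
    return lf.simulate_rosette_series(truth, cfg)


@pytest.fixture(scope="session")
def drifting_rosette():
    """Rendered series with panel drift, for registration tests."""
    truth = lf.PlantTruth(center=(80, 60), initial_area=250, growth_rate=0.0,
                          nutation_amplitude=0.0)
    cfg = lf.SimConfig(
        n_frames=6, capture_interval_min=240.0, image_size=(160, 120),
        seed=11, noise_sd=1.0, panel_drift_amplitude=2.5, panel_drift_period=48.0,
    )
    return lf.simulate_rosette_series(truth, cfg)


@pytest.fixture(scope="session")
def analytic_cohort():
    """Seeded 60-plant analytic cohort, the model-layer workhorse."""
    cfg = lf.PipelineConfig(seed=1)
    return cfg, lf.simulate_cohort(60, lf.SimConfig(seed=cfg.child_seed("cohort")))


@pytest.fixture(scope="session")
def pipeline_result(analytic_cohort):
    cfg, cohort = analytic_cohort
    return lf.run_pipeline(cfg, cohort, models=("gbr",))


def naive_radial_projection(u, v, mask, center):
    """Independent double-loop oracle for the radial projection + aggregation."""
    h, w = u.shape
    cx, cy = center
    nx = np.zeros_like(u)
    ny = np.zeros_like(v)
    sign = np.zeros((h, w), dtype=int)
    total = np.zeros(2)
    m = 0
    for j in range(h):
        for i in range(w):
            if not mask[j, i]:
                continue
            dx, dy = i - cx, j - cy
            dist = (dx * dx + dy * dy) ** 0.5
            if dist == 0:
                m += 1
                continue
            rx, ry = dx / dist, dy / dist
            dot = u[j, i] * rx + v[j, i] * ry
            nx[j, i] = dot * rx
            ny[j, i] = dot * ry
            sign[j, i] = 0 if dot == 0 else (1 if dot > 0 else -1)
            total += (nx[j, i], ny[j, i])
            m += 1
    return nx, ny, sign, total, m
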