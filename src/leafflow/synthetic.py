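"""Synthetic rosette imagery and analytic time series with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for top-view seedling imagery in a plant factory:

* a multi-leaf rosette whose projected area grows exponentially,
* a 24-h-periodic oscillation of apparent leaf extent (nutation) locked to
  the light/dark schedule,
* a dark circular depression in the floating panel around each seedling,
* slow sinusoidal drift of the whole panel (a few pixels), and
* harvest fresh weights generated from the growth parameters with additive
  Gaussian noise.

Every frame comes with exact truth: the drifting center, the plant-pixel
count, and the dense displacement field between any two frames (a uniform
radial scaling about the center plus the panel translation), so downstream
stages can be tested against known answers without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

__all__ = [
    "PlantTruth",
    "SimConfig",
    "CohortParams",
    "RosetteSeries",
    "AnalyticSeries",
    "Cohort",
    "simulate_rosette_series",
    "simulate_weight",
    "simulate_cohort",
]


@dataclass
class PlantTruth:
    """Generative parameters of a single simulated plant.

    ``nutation_amplitude`` is the peak-to-peak radial excursion of a leaf tip
    in pixels, i.e. the distance the tip travels over half a nutation period
    (12 h at the default 24-h period).
    """

    center: tuple[float, float] = (160.0, 120.0)  # (x, y) px
    initial_area: float = 300.0  # projected area at t=0, px^2
    growth_rate: float = 0.006  # exponential rate r, per hour
    nutation_amplitude: float = 3.0  # px per half period
    nutation_period: float = 24.0  # hours
    nutation_phase: float = 0.0  # radians
    leaf_angles: tuple[float, ...] = ()  # phyllotactic directions, radians
    harvest_weight: float = 80.0  # grams

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.nutation_period <= 0:
            raise ValueError("nutation_period must be positive")
        if self.harvest_weight <= 0:
            raise ValueError("harvest_weight must be positive")
        if not self.leaf_angles:
            self.leaf_angles = tuple(
                _wrap_angle(0.4 + m * GOLDEN_ANGLE) for m in range(3)
            )
        if any(a <= -math.pi or a > math.pi for a in self.leaf_angles):
            raise ValueError("leaf_angles must lie in (-pi, pi]")

    # --- geometry shared by renderer and truth-flow --------------------------

    def area_at(self, t_hours: float) -> float:
        return self.initial_area * math.exp(self.growth_rate * t_hours)

    def lobe_scale(self, t_hours: float) -> float:
        """Semi-major axis of each leaf lobe at time t (px).

        The rosette is drawn as ``len(leaf_angles)`` half-overlapping ellipse
        lobes (axis ratio 1:2) anchored at the center; nutation modulates the
        tip radius ``2a`` by +/- amplitude/2 around its growth trend.
        """
        n = len(self.leaf_angles)
        a_base = math.sqrt(2.0 * self.area_at(t_hours) / (n * math.pi))
        tip = 2.0 * a_base + 0.5 * self.nutation_amplitude * math.sin(
            2.0 * math.pi * t_hours / self.nutation_period + self.nutation_phase
        )
        return max(tip / 2.0, 0.5)


@dataclass
class SimConfig:
    """Rendering/protocol configuration for the simulator."""

    n_frames: int = 640
    capture_interval_min: float = 20.0
    ld_schedule: tuple[float, float] = (15.0, 9.0)
    image_size: tuple[int, int] = (320, 240)  # (width, height)
    depression_radius: float = 28.0  # px, dark ring around the seedling
    panel_drift_amplitude: float = 2.0  # px, <= 3 by design
    panel_drift_period: float = 96.0  # hours
    noise_sd: float = 2.0  # additive intensity noise, 0-255 units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.capture_interval_min <= 0:
            raise ValueError("capture_interval_min must be positive")

    def time_of(self, k: int) -> float:
        """Hours since the first frame for 1-based frame index k."""
        return (k - 1) * self.capture_interval_min / 60.0


PANEL_RGB = np.array([178.0, 170.0, 152.0])
LEAF_RGB = np.array([58.0, 148.0, 62.0])


def _wrap_angle(a: float) -> float:
    wrapped = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if wrapped == -math.pi else wrapped


class RosetteSeries:
    """A rendered image sequence plus exact per-frame ground truth."""

    def __init__(self, truth: PlantTruth, cfg: SimConfig):
        self.truth = truth
        self.cfg = cfg
        w, h = cfg.image_size
        final_t = cfg.time_of(cfg.n_frames)
        reach = 2.0 * truth.lobe_scale(final_t) + cfg.panel_drift_amplitude + 2.0
        cx, cy = truth.center
        if cx - reach < 0 or cy - reach < 0 or cx + reach >= w or cy + reach >= h:
            raise ValueError(
                f"image {w}x{h} too small to contain the rosette "
                f"(needs radius {reach:.1f} px around {truth.center})"
            )
        rng = np.random.default_rng(cfg.seed)
        self._noise = [
            rng.normal(0.0, cfg.noise_sd, size=(h, w, 3)) if cfg.noise_sd > 0 else 0.0
            for _ in range(cfg.n_frames)
        ]
        self.images = [self.render_frame(k) for k in range(1, cfg.n_frames + 1)]

    # --- truth accessors ------------------------------------------------------

    def drift(self, k: int) -> tuple[float, float]:
        cfg = self.cfg
        t = cfg.time_of(k)
        w = 2.0 * math.pi * t / cfg.panel_drift_period
        a = cfg.panel_drift_amplitude
        return (a * math.sin(w), a * math.sin(w + 1.0))

    def center_at(self, k: int) -> tuple[float, float]:
        dx, dy = self.drift(k)
        return (self.truth.center[0] + dx, self.truth.center[1] + dy)

    def plant_mask(self, k: int) -> np.ndarray:
        """Boolean raster of pixels whose center lies inside any leaf lobe."""
        alpha = self._leaf_alpha(k)
        return alpha > 0.5

    def plant_pixel_count(self, k: int) -> int:
        return int(self.plant_mask(k).sum())

    def true_flow(self, k1: int, k2: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact displacement (u, v) of frame-k1 plant pixels toward frame k2.

        The rosette at any instant is the image of a fixed template under a
        uniform scaling about the (drifting) center, so the true flow of a
        plant pixel is radial scaling plus the panel translation. Returns
        (u, v, mask) with u, v zero outside the frame-k1 plant mask.
        """
        t1, t2 = self.cfg.time_of(k1), self.cfg.time_of(k2)
        s = self.truth.lobe_scale(t2) / self.truth.lobe_scale(t1)
        c1 = np.array(self.center_at(k1))
        c2 = np.array(self.center_at(k2))
        mask = self.plant_mask(k1)
        w, h = self.cfg.image_size
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        u = (s - 1.0) * (xs - c1[0]) + (c2[0] - c1[0])
        v = (s - 1.0) * (ys - c1[1]) + (c2[1] - c1[1])
        u[~mask] = 0.0
        v[~mask] = 0.0
        return u, v, mask

    # --- rendering ------------------------------------------------------------

    def _leaf_alpha(self, k: int) -> np.ndarray:
        cfg, truth = self.cfg, self.truth
        t = cfg.time_of(k)
        w, h = cfg.image_size
        cx, cy = self.center_at(k)
        a = truth.lobe_scale(t)
        b = 0.5 * a
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        dx, dy = xs - cx, ys - cy
        alpha = np.zeros((h, w))
        for phi in truth.leaf_angles:
            c, s = math.cos(phi), math.sin(phi)
            # lobe-local coordinates: ellipse centered one semi-axis out
            xl = dx * c + dy * s - a
            yl = -dx * s + dy * c
            q = (xl / a) ** 2 + (yl / b) ** 2
            np.maximum(alpha, np.clip((1.0 - q) * a, 0.0, 1.0), out=alpha)
        return alpha

    def render_frame(self, k: int) -> np.ndarray:
        """Render 1-based frame k as an RGB uint8 array of shape (h, w, 3)."""
        cfg = self.cfg
        w, h = cfg.image_size
        cx, cy = self.center_at(k)
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        # panel texture rides along with the drift (the whole panel floats)
        tex = 1.0 + 0.04 * np.sin((xs - cx) / 13.0) + 0.04 * np.cos((ys - cy) / 17.0)
        img = PANEL_RGB[None, None, :] * tex[:, :, None]
        dist = np.hypot(xs - cx, ys - cy)
        ring = np.exp(-0.5 * ((dist - cfg.depression_radius) / 1.5) ** 2)
        img *= (1.0 - 0.55 * ring)[:, :, None]
        alpha = self._leaf_alpha(k)[:, :, None]
        img = img * (1.0 - alpha) + LEAF_RGB[None, None, :] * alpha
        img = img + (self._noise[k - 1] if cfg.noise_sd > 0 else 0.0)
        return np.clip(img, 0, 255).astype(np.uint8)


def simulate_rosette_series(truth: PlantTruth, cfg: SimConfig) -> RosetteSeries:
    """Render a full image sequence with ground truth; deterministic per seed."""
    return RosetteSeries(truth, cfg)


def simulate_weight(
    growth_rate: float,
    *,
    w0: float = 10.0,
    exponent_hours: float = 350.0,
    noise_sd: float = 8.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Harvest fresh weight (g) from a growth rate (per hour).

    ``weight = w0 * exp(exponent_hours * growth_rate) + N(0, noise_sd)``;
    strictly monotone in the rate at zero noise. A non-positive draw is
    resampled (fresh weight is physically positive); at zero noise the
    deterministic value is returned directly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = w0 * math.exp(exponent_hours * growth_rate)
    if noise_sd == 0:
        return base
    if rng is None:
        rng = np.random.default_rng(seed)
    weight = base + rng.normal(0.0, noise_sd)
    while weight <= 0:
        weight = base + rng.normal(0.0, noise_sd)
    return float(weight)


@dataclass
class CohortParams:
    """Population distributions for a simulated cohort.

    Defaults emulate lettuce seedlings imaged over ~9 days in a plant
    factory: relative area growth around 0.006 per hour and harvest fresh
    weights spanning roughly 40-120 g with a Gaussian spread.
    """

    growth_rate_mean: float = 0.006
    growth_rate_sd: float = 0.0015
    initial_area_mean: float = 300.0
    initial_area_sd: float = 40.0
    nutation_amplitude_mean: float = 3.0
    nutation_amplitude_sd: float = 1.0
    nutation_period: float = 24.0
    n_leaves: int = 3
    weight_w0: float = 10.0
    weight_exponent_hours: float = 350.0
    weight_noise_sd: float = 8.0
    ppfd_mean: float = 220.0
    ppfd_sd: float = 15.0
    n_tracks: int = 5
    magnitude_noise_sd: float = 0.05
    angle_noise_sd: float = 0.3
    pa_noise_frac: float = 0.01
    signal: str = "all"  # "all" or "pa": which channels reflect growth rate


@dataclass
class AnalyticSeries:
    """Closed-form per-plant series, bypassing rendering and flow estimation.

    One point per analyzable frame, time axis anchored at the first point.
    """

    t: np.ndarray  # hours
    magnitude: np.ndarray  # |mean normal vector|, px
    angle: np.ndarray  # radians in (-pi, pi], NaN where undefined
    pa: np.ndarray  # projected area, px


@dataclass
class Cohort:
    plants: list[PlantTruth]
    ppfd: np.ndarray
    track: np.ndarray  # integer categories 1..n_tracks
    weights: np.ndarray  # grams
    series: list  # AnalyticSeries or RosetteSeries per plant

    def metadata(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "plant_id": np.arange(len(self.plants)),
                "ppfd": self.ppfd,
                "track": self.track,
                "weight": self.weights,
            }
        )


def _analytic_series(
    truth: PlantTruth,
    params: CohortParams,
    cfg: SimConfig,
    lag_frames: int,
    rng: np.random.Generator,
) -> AnalyticSeries:
    n_pts = cfg.n_frames - lag_frames
    dt = cfg.capture_interval_min / 60.0
    t = np.arange(n_pts) * dt
    pa = truth.initial_area * np.exp(truth.growth_rate * t)
    pa = pa * (1.0 + params.pa_noise_frac * rng.standard_normal(n_pts))
    osc = np.sin(
        2.0 * np.pi * t / truth.nutation_period + truth.nutation_phase
    )
    # magnitude of the mean radial vector: growth trend + nutation rhythm
    growth_term = truth.growth_rate * np.sqrt(pa.clip(min=0.0)) * 12.0
    mag = (
        growth_term
        + 0.5 * truth.nutation_amplitude * (1.0 + osc)
        + params.magnitude_noise_sd * rng.standard_normal(n_pts)
    )
    mag = np.abs(mag)
    base_angle = truth.leaf_angles[0]
    ang = (
        base_angle
        + 0.4 * osc
        + params.angle_noise_sd * rng.standard_normal(n_pts)
    )
    ang = np.mod(ang + np.pi, 2.0 * np.pi) - np.pi
    return AnalyticSeries(t=t, magnitude=mag, angle=ang, pa=pa)


def simulate_cohort(
    n_plants: int,
    cfg: SimConfig | None = None,
    params: CohortParams | None = None,
    *,
    analytic: bool = True,
    lag_frames: int = 36,
    seed: int | None = None,
) -> Cohort:
    """Draw a cohort of independent plants with growth truth and weights.

    In analytic mode (default) rendering and flow estimation are skipped and
    each plant's magnitude/angle/projected-area series is produced in closed
    form — suitable for fast model-layer tests. With ``analytic=False`` each
    plant gets a rendered :class:`RosetteSeries`.

    With ``params.signal == "pa"`` the nutation parameters are drawn
    independently of the growth rate and the magnitude series carries no
    growth trend, so only the projected-area channel is informative about
    harvest weight.
    """
    if n_plants < 2:
        raise ValueError("n_plants must be >= 2")
    cfg = cfg or SimConfig()
    params = params or CohortParams()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    rng = np.random.default_rng(cfg.seed)

    plants: list[PlantTruth] = []
    ppfd = rng.normal(params.ppfd_mean, params.ppfd_sd, size=n_plants)
    track = rng.integers(1, params.n_tracks + 1, size=n_plants)
    weights = np.empty(n_plants)
    series: list = []
    for idx in range(n_plants):
        rate = -1.0
        while rate <= 0:
            rate = rng.normal(params.growth_rate_mean, params.growth_rate_sd)
        amp = abs(rng.normal(params.nutation_amplitude_mean, params.nutation_amplitude_sd))
        area0 = max(rng.normal(params.initial_area_mean, params.initial_area_sd), 50.0)
        base = rng.uniform(-math.pi, math.pi)
        angles = tuple(
            _wrap_angle(base + m * GOLDEN_ANGLE + rng.normal(0.0, 0.1))
            for m in range(params.n_leaves)
        )
        weight = simulate_weight(
            rate,
            w0=params.weight_w0,
            exponent_hours=params.weight_exponent_hours,
            noise_sd=params.weight_noise_sd,
            rng=rng,
        )
        truth = PlantTruth(
            center=(cfg.image_size[0] / 2.0, cfg.image_size[1] / 2.0),
            initial_area=area0,
            growth_rate=rate,
            nutation_amplitude=amp,
            nutation_period=params.nutation_period,
            nutation_phase=rng.uniform(0.0, 2.0 * math.pi),
            leaf_angles=angles,
            harvest_weight=weight,
        )
        plants.append(truth)
        weights[idx] = weight
        if analytic:
            use = params
            if params.signal == "pa":
                # decouple movement channels from the growth signal
                truth_mov = PlantTruth(
                    center=truth.center,
                    initial_area=truth.initial_area,
                    growth_rate=params.growth_rate_mean,
                    nutation_amplitude=amp,
                    nutation_period=truth.nutation_period,
                    nutation_phase=truth.nutation_phase,
                    leaf_angles=angles,
                    harvest_weight=weight,
                )
                mov = _analytic_series(truth_mov, use, cfg, lag_frames, rng)
                grow = _analytic_series(truth, use, cfg, lag_frames, rng)
                series.append(
                    AnalyticSeries(
                        t=grow.t, magnitude=mov.magnitude, angle=mov.angle, pa=grow.pa
                    )
                )
            else:
                series.append(_analytic_series(truth, use, cfg, lag_frames, rng))
        else:
            sub = SimConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31 - 1))})
            series.append(RosetteSeries(truth, sub))
    return Cohort(plants=plants, ppfd=ppfd, track=track, weights=weights, series=series)
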