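"""Reduction of per-plant movement series to the 115-dimensional feature vector.

Each plant contributes three series sampled once per analyzable frame —
the magnitude |Nbar_k|, the angle theta_k, and the projected area S_k —
604 points each under the full protocol (1,812 raw dimensions). These are
reduced to 115 features in nine groups:

=================  ====  =====================================================
group              size  content
=================  ====  =====================================================
ppfd                  1  photosynthetic photon flux density at the plant
track                 4  dummy encoding of the panel track category (1..5)
pca                  20  4 PCA blocks (angle / magnitude / PA / all) x 5 scores
angle-shift           6  self-correlation of the angle at 24..144 h lags
magnitude-shift       6  self-correlation of the magnitude at 24..144 h lags
pa-ave                9  mean PA in 24-h windows (last window 192-201 h)
angle-diff           23  |differences| of light/dark phase means of the angle
magnitude-diff       23  same for the magnitude
pa-diff              23  same for the projected area
=================  ====  =====================================================

The light/dark phase means under the 15/9 schedule over 0-201 h comprise 9
light periods (the last truncated to 192-201 h) and 8 dark periods; their
8 consecutive-light, 7 consecutive-dark and 8 within-cycle light-dark
absolute differences give the 23 "diff" features per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .normals import FrameAggregate

__all__ = [
    "PlantTimeSeries",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "FEATURE_SUBGROUPS",
    "DEFAULT_SHIFTS_HOURS",
    "build_timeseries",
    "shift_correlation",
    "pa_window_average",
    "phase_averages",
    "ld_diff_features",
    "PCABlockExtractor",
    "environment_features",
    "assemble_features",
    "moving_average_diff",
]

DEFAULT_SHIFTS_HOURS = (24.0, 48.0, 72.0, 96.0, 120.0, 144.0)
PA_WINDOWS_HOURS = (
    (0, 24), (24, 48), (48, 72), (72, 96), (96, 120),
    (120, 144), (144, 168), (168, 192), (192, 201),
)


@dataclass
class PlantTimeSeries:
    """Per-plant movement series on a common time axis.

    ``t`` is in hours, anchored at 0 = the first analyzable frame, which is
    also lights-on of the LD schedule. ``ld_label`` is "L" or "D" per point.
    Angle values may be NaN where the mean normal vector vanished.
    """

    t: np.ndarray
    magnitude: np.ndarray
    angle: np.ndarray
    pa: np.ndarray
    ld_label: np.ndarray
    k: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("magnitude", "angle", "pa", "ld_label"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match t")

    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def raw_dimension(self) -> int:
        """Size of the unreduced representation (three stacked series)."""
        return 3 * self.n_points


def ld_labels(t: np.ndarray, schedule: tuple[float, float] = (15.0, 9.0)) -> np.ndarray:
    """"L"/"D" label per time point; schedule anchored at t=0 = lights-on."""
    light, dark = schedule
    period = light + dark
    return np.where(np.mod(t, period) < light, "L", "D")


def build_timeseries(
    aggregates: list[FrameAggregate],
    schedule: tuple[float, float] = (15.0, 9.0),
    *,
    capture_interval_min: float = 20.0,
) -> PlantTimeSeries:
    """Assemble the per-plant series from sorted frame aggregates."""
    if not aggregates:
        raise ValueError("no aggregates given")
    ks = np.array([a.frame_index for a in aggregates])
    if len(np.unique(ks)) != len(ks):
        raise ValueError("duplicate frame indices in aggregates")
    order = np.argsort(ks)
    ks = ks[order]
    t = (ks - ks[0]) * capture_interval_min / 60.0
    mag = np.array([aggregates[i].magnitude for i in order], dtype=float)
    ang = np.array([aggregates[i].theta for i in order], dtype=float)
    pa = np.array([aggregates[i].s for i in order], dtype=float)
    return PlantTimeSeries(
        t=t, magnitude=mag, angle=ang, pa=pa, ld_label=ld_labels(t, schedule), k=ks
    )


def shift_correlation(
    series: np.ndarray,
    t: np.ndarray,
    shifts_hours: tuple[float, ...] = DEFAULT_SHIFTS_HOURS,
) -> np.ndarray:
    """Pearson correlation of the series with its lag-shifted copy.

    One value per shift, computed over the overlapping segment with NaN
    pairs dropped; NaN when the overlap has fewer than 3 points or either
    side is constant.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(series) != len(t):
        raise ValueError("series and t must have the same length")
    dt = float(np.median(np.diff(t)))
    out = np.full(len(shifts_hours), np.nan)
    for idx, sh in enumerate(shifts_hours):
        lag = sh / dt
        if abs(lag - round(lag)) > 1e-6:
            raise ValueError(f"shift {sh} h is not a multiple of the sampling step")
        lag = int(round(lag))
        if lag < 0 or lag >= len(series):
            continue
        a, b = series[: len(series) - lag], series[lag:]
        if lag == 0:
            a, b = series, series
        good = np.isfinite(a) & np.isfinite(b)
        if good.sum() < 3 or np.ptp(a[good]) == 0 or np.ptp(b[good]) == 0:
            continue
        out[idx] = stats.pearsonr(a[good], b[good]).statistic
    return out


def pa_window_average(
    pa: np.ndarray,
    t: np.ndarray,
    windows: tuple[tuple[float, float], ...] = PA_WINDOWS_HOURS,
) -> np.ndarray:
    """Mean projected area in each time window (final window right-closed)."""
    pa = np.asarray(pa, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.full(len(windows), np.nan)
    for idx, (lo, hi) in enumerate(windows):
        sel = (t >= lo) & ((t <= hi) if idx == len(windows) - 1 else (t < hi))
        vals = pa[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[idx] = vals.mean()
    return out


def phase_averages(
    series: np.ndarray,
    t: np.ndarray,
    schedule: tuple[float, float] = (15.0, 9.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of the series within each light and each dark period.

    Periods are enumerated from t=0 (lights-on); a final partial period is
    kept if it contains any samples. Over 0-201 h under 15/9 this yields 9
    light means and 8 dark means.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    light, dark = schedule
    period = light + dark
    t_max = t.max()
    l_means, d_means = [], []
    cycle = 0
    while cycle * period <= t_max:
        start = cycle * period
        sel = (t >= start) & (t < start + light)
        vals = series[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            l_means.append(vals.mean())
        sel = (t >= start + light) & (t < start + period)
        vals = series[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            d_means.append(vals.mean())
        cycle += 1
    return np.array(l_means), np.array(d_means)


def ld_diff_features(l_means: np.ndarray, d_means: np.ndarray) -> np.ndarray:
    """Absolute differences between consecutive and paired phase means.

    Order: consecutive light-light diffs, consecutive dark-dark diffs, then
    within-cycle light-dark diffs (each dark period paired with the light
    period preceding it). With 9 light and 8 dark means this is
    8 + 7 + 8 = 23 values.
    """
    l_means = np.asarray(l_means, dtype=float)
    d_means = np.asarray(d_means, dtype=float)
    if len(l_means) != len(d_means) + 1:
        raise ValueError(
            f"expected one more light period than dark periods, got "
            f"{len(l_means)} light / {len(d_means)} dark"
        )
    ll = np.abs(np.diff(l_means))
    dd = np.abs(np.diff(d_means))
    ld = np.abs(l_means[: len(d_means)] - d_means)
    return np.concatenate([ll, dd, ld])


class PCABlockExtractor:
    """Four PCA blocks over the cohort's series: angle, magnitude, PA, all.

    Fitted on training plants only (each plant is one observation; the
    series points are the variables); NaNs are imputed with the training
    column mean before centering. ``transform`` returns the concatenated
    component scores — 20 values per plant at the default 5 components.
    """

    BLOCKS = ("ang", "mag", "pa", "all")

    def __init__(self, n_components: int = 5, seed: int = 0):
        self.n_components = n_components
        self.seed = seed
        self._models: dict[str, PCA] = {}
        self._means: dict[str, np.ndarray] = {}

    @staticmethod
    def _block_matrix(series_list: list[PlantTimeSeries], block: str) -> np.ndarray:
        if block == "ang":
            rows = [s.angle for s in series_list]
        elif block == "mag":
            rows = [s.magnitude for s in series_list]
        elif block == "pa":
            rows = [s.pa for s in series_list]
        else:
            rows = [np.concatenate([s.angle, s.magnitude, s.pa]) for s in series_list]
        return np.vstack([np.asarray(r, dtype=float) for r in rows])

    def fit(self, train_series: list[PlantTimeSeries]) -> "PCABlockExtractor":
        if len(train_series) <= self.n_components:
            raise ValueError(
                f"need more than {self.n_components} training plants to fit PCA"
            )
        for block in self.BLOCKS:
            mat = self._block_matrix(train_series, block)
            col_mean = np.nanmean(mat, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            mat = np.where(np.isfinite(mat), mat, col_mean)
            model = PCA(n_components=self.n_components, random_state=self.seed)
            model.fit(mat)
            self._models[block] = model
            self._means[block] = col_mean
        return self

    def transform(self, series_list: list[PlantTimeSeries]) -> np.ndarray:
        if not self._models:
            raise RuntimeError("PCABlockExtractor must be fitted first")
        scores = []
        for block in self.BLOCKS:
            mat = self._block_matrix(series_list, block)
            mat = np.where(np.isfinite(mat), mat, self._means[block])
            scores.append(self._models[block].transform(mat))
        return np.hstack(scores)


def environment_features(ppfd: float, track_id: int, *, n_tracks: int = 5) -> np.ndarray:
    """[ppfd] plus dummy indicators for tracks 2..n (track 1 = baseline)."""
    track_id = int(track_id)
    if not (1 <= track_id <= n_tracks):
        raise ValueError(f"track_id must be in 1..{n_tracks}, got {track_id}")
    dummies = np.zeros(n_tracks - 1)
    if track_id > 1:
        dummies[track_id - 2] = 1.0
    return np.concatenate([[float(ppfd)], dummies])


def _names() -> tuple[list[str], dict[str, slice], dict[str, slice]]:
    names: list[str] = ["ppfd"]
    groups: dict[str, slice] = {"ppfd": slice(0, 1)}
    sub: dict[str, slice] = {}

    def add(group: str, items: list[str], subname: str | None = None):
        start = len(names)
        names.extend(items)
        stop = len(names)
        if group not in groups:
            groups[group] = slice(start, stop)
        else:
            groups[group] = slice(groups[group].start, stop)
        if subname:
            sub[subname] = slice(start, stop)

    add("track", [f"track_{i}" for i in range(2, 6)])
    for blk in PCABlockExtractor.BLOCKS:
        add("pca", [f"pca-{blk}_{c + 1}" for c in range(5)], f"pca-{blk}")
    add("angle-shift", [f"ang-shift_{h:.0f}h" for h in DEFAULT_SHIFTS_HOURS])
    add("magnitude-shift", [f"mag-shift_{h:.0f}h" for h in DEFAULT_SHIFTS_HOURS])
    add("pa-ave", [f"pa-ave_{lo:.0f}-{hi:.0f}h" for lo, hi in PA_WINDOWS_HOURS])
    for chan, gname in (("ang", "angle-diff"), ("mag", "magnitude-diff"), ("pa", "pa-diff")):
        add(gname, [f"{chan}-ll-diff_{i + 1}" for i in range(8)], f"{chan}-ll-diff")
        add(gname, [f"{chan}-dd-diff_{i + 1}" for i in range(7)], f"{chan}-dd-diff")
        add(gname, [f"{chan}-ld-diff_{i + 1}" for i in range(8)], f"{chan}-ld-diff")
    return names, groups, sub


FEATURE_NAMES, FEATURE_GROUPS, FEATURE_SUBGROUPS = _names()
GROUP_SIZES = {
    "ppfd": 1, "track": 4, "pca": 20, "angle-shift": 6, "magnitude-shift": 6,
    "pa-ave": 9, "angle-diff": 23, "magnitude-diff": 23, "pa-diff": 23,
}


@dataclass
class FeatureVector:
    """The 115 named features of one plant, in canonical group order."""

    values: np.ndarray
    names: tuple[str, ...] = field(default_factory=lambda: tuple(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def assemble_features(
    env: np.ndarray,
    pca_scores: np.ndarray,
    angle_shift: np.ndarray,
    magnitude_shift: np.ndarray,
    pa_ave: np.ndarray,
    angle_diff: np.ndarray,
    magnitude_diff: np.ndarray,
    pa_diff: np.ndarray,
) -> FeatureVector:
    """Concatenate the feature blocks in canonical order (length 115)."""
    blocks = {
        "environment (ppfd + track)": (env, 5),
        "pca": (pca_scores, 20),
        "angle-shift": (angle_shift, 6),
        "magnitude-shift": (magnitude_shift, 6),
        "pa-ave": (pa_ave, 9),
        "angle-diff": (angle_diff, 23),
        "magnitude-diff": (magnitude_diff, 23),
        "pa-diff": (pa_diff, 23),
    }
    parts = []
    for name, (arr, expected) in blocks.items():
        arr = np.asarray(arr, dtype=float).ravel()
        if len(arr) != expected:
            raise ValueError(f"{name} block has {len(arr)} values, expected {expected}")
        parts.append(arr)
    return FeatureVector(np.concatenate(parts))


def extract_features(
    series: PlantTimeSeries,
    ppfd: float,
    track_id: int,
    pca: PCABlockExtractor,
    *,
    schedule: tuple[float, float] = (15.0, 9.0),
    shifts_hours: tuple[float, ...] = DEFAULT_SHIFTS_HOURS,
) -> FeatureVector:
    """Full reduction of one plant's series to its 115 features."""
    env = environment_features(ppfd, track_id)
    pca_scores = pca.transform([series])[0]
    ang_shift = shift_correlation(series.angle, series.t, shifts_hours)
    mag_shift = shift_correlation(series.magnitude, series.t, shifts_hours)
    pa_ave = pa_window_average(series.pa, series.t)
    diffs = []
    for chan in (series.angle, series.magnitude, series.pa):
        l_means, d_means = phase_averages(chan, series.t, schedule)
        diffs.append(ld_diff_features(l_means, d_means))
    return assemble_features(env, pca_scores, ang_shift, mag_shift, pa_ave, *diffs)


def feature_matrix(
    series_list: list[PlantTimeSeries],
    ppfd: np.ndarray,
    track: np.ndarray,
    pca: PCABlockExtractor,
    **kwargs,
) -> pd.DataFrame:
    """Feature rows for many plants as a DataFrame with canonical columns."""
    rows = [
        extract_features(s, p, tr, pca, **kwargs).values
        for s, p, tr in zip(series_list, ppfd, track)
    ]
    return pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)


def moving_average_diff(
    pa: np.ndarray,
    t: np.ndarray,
    window_hours: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average of the first difference of the PA series.

    Smoothing the per-step growth increment over a 12-h window exposes the
    circadian modulation of the growth rate. Returns ``(t_mid, smoothed)``
    aligned to the midpoints of the differenced series.
    """
    pa = np.asarray(pa, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(pa) < 2:
        raise ValueError("need at least two points")
    dt = float(np.median(np.diff(t)))
    if window_hours > t[-1] - t[0]:
        raise ValueError("window exceeds the series span")
    diff = np.diff(pa)
    t_mid = 0.5 * (t[:-1] + t[1:])
    win = max(int(round(window_hours / dt)), 1)
    if win % 2 == 0:
        win += 1
    kernel = np.ones(win) / win
    padded = np.pad(diff, win // 2, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return t_mid, smoothed
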