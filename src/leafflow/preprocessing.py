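"""Registration, vegetation segmentation and plant-ROI construction.

Coordinate convention throughout the package: x rightward (array column),
y downward (array row), origin at the top-left pixel center, angles from
``atan2(y, x)`` in (-pi, pi]. A shift ``(dx, dy)`` is the displacement of
the moving image's content relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature as skfeature
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation

__all__ = [
    "RegisteredFrame",
    "PlantROI",
    "resize_image",
    "poc_shift",
    "register_series",
    "exg_index",
    "exg_mask",
    "detect_center",
    "detect_centers",
    "plant_roi",
    "load_manifest",
]


@dataclass
class RegisteredFrame:
    image: np.ndarray  # RGB raster, uint8 or float
    shift_applied: tuple[float, float]  # (dx, dy) px moving the frame onto the reference
    timestamp: float  # hours since t=0
    frame_index: int  # 1-based k


@dataclass
class PlantROI:
    """Circular region of interest around a seedling center.

    ``mask`` is true exactly where a pixel center lies within ``radius`` of
    ``center`` (Euclidean) *and* the Excess-Green segmentation marked it as
    plant. Pixels outside the circle are never included.
    """

    center: tuple[float, float]
    radius: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def resize_image(image: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``(width, height)``; dtype preserved."""
    w, h = target_size
    if w < 1 or h < 1:
        raise ValueError("target dimensions must be >= 1")
    if image.shape[0] == h and image.shape[1] == w:
        return image.copy()
    out_shape = (h, w) + image.shape[2:]
    out = sktransform.resize(
        image.astype(float), out_shape, order=1, anti_aliasing=False,
        preserve_range=True, mode="edge",
    )
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(image.dtype).min, np.iinfo(image.dtype).max)
    return out.astype(image.dtype)


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        img = image.astype(float)
        return 0.2125 * img[..., 0] + 0.7154 * img[..., 1] + 0.0721 * img[..., 2]
    return image.astype(float)


def poc_shift(
    reference: np.ndarray, moving: np.ndarray, *, upsample_factor: int = 20
) -> tuple[float, float]:
    """Sub-pixel translation of ``moving`` relative to ``reference`` by
    phase-only correlation (Fourier phase correlation with local upsampled
    peak refinement).

    Returns ``(dx, dy)`` such that translating ``moving`` by ``(-dx, -dy)``
    aligns it with ``reference``.
    """
    ref, mov = _to_gray(reference), _to_gray(moving)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("phase correlation is undefined for a constant image")
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample_factor)
    # phase_cross_correlation returns the (row, col) shift to apply to the
    # moving image; the content displacement is its negation
    return (float(-shift[1]), float(-shift[0]))


def register_series(
    frames: list[np.ndarray],
    timestamps: list[float] | None = None,
    *,
    upsample_factor: int = 20,
) -> list[RegisteredFrame]:
    """Align every frame to the first frame of the series by its POC shift."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if timestamps is None:
        timestamps = list(range(len(frames)))
    out = [RegisteredFrame(frames[0].copy(), (0.0, 0.0), float(timestamps[0]), 1)]
    for idx in range(1, len(frames)):
        dx, dy = poc_shift(frames[0], frames[idx], upsample_factor=upsample_factor)
        img = frames[idx].astype(float)
        if img.ndim == 3:
            aligned = np.stack(
                [ndimage.shift(img[..., c], (-dy, -dx), order=1, mode="nearest")
                 for c in range(img.shape[2])],
                axis=-1,
            )
        else:
            aligned = ndimage.shift(img, (-dy, -dx), order=1, mode="nearest")
        if np.issubdtype(frames[idx].dtype, np.integer):
            aligned = np.clip(np.rint(aligned), 0, 255)
        out.append(
            RegisteredFrame(
                aligned.astype(frames[idx].dtype),
                (dx, dy),
                float(timestamps[idx]),
                idx + 1,
            )
        )
    return out


def exg_index(rgb_image: np.ndarray) -> np.ndarray:
    """Excess-Green index ``2g - r - b`` on chromatic coordinates.

    ``r = R/(R+G+B)`` etc.; a pixel with ``R+G+B = 0`` gets index 0. The
    index is invariant to uniform intensity scaling by construction.
    """
    img = rgb_image.astype(float)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image")
    total = img[..., 0] + img[..., 1] + img[..., 2]
    safe = np.where(total > 0, total, 1.0)
    r, g, b = (img[..., c] / safe for c in range(3))
    exg = 2.0 * g - r - b
    exg[total == 0] = 0.0
    return exg


def exg_mask(rgb_image: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Vegetation mask: Excess-Green index strictly above ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return exg_index(rgb_image) > threshold


class CenterDetectionError(RuntimeError):
    """No circular depression found; caller may fall back to a configured center."""


def detect_centers(
    image: np.ndarray,
    expected_radius: float,
    n: int = 1,
    *,
    radius_tolerance: float = 0.2,
    canny_sigma: float = 2.0,
    min_accumulator: float = 0.3,
) -> list[tuple[float, float]]:
    """Centers of the ``n`` best-scoring circles near ``expected_radius``.

    Circle-Hough voting on Canny edges, searching radii within
    ``+/- radius_tolerance`` of the expected value; results ordered by
    accumulator score. Raises :class:`CenterDetectionError` when no peak
    reaches ``min_accumulator``.
    """
    gray = _to_gray(image)
    span = gray.max() - gray.min()
    edges = skfeature.canny(
        (gray - gray.min()) / span if span > 0 else gray, sigma=canny_sigma
    )
    lo = max(int(expected_radius * (1.0 - radius_tolerance)), 3)
    hi = int(np.ceil(expected_radius * (1.0 + radius_tolerance))) + 1
    radii = np.arange(lo, hi)
    accum = sktransform.hough_circle(edges, radii)
    scores, cx, cy, _ = sktransform.hough_circle_peaks(
        accum, radii, total_num_peaks=max(n, 1), min_xdistance=int(expected_radius),
        min_ydistance=int(expected_radius),
    )
    keep = [i for i in range(len(scores)) if scores[i] >= min_accumulator]
    if len(keep) < n:
        raise CenterDetectionError(
            f"found {len(keep)} circle(s) near radius {expected_radius}, needed {n}"
        )
    return [(float(cx[i]), float(cy[i])) for i in keep[:n]]


def detect_center(image: np.ndarray, expected_radius: float) -> tuple[float, float]:
    """Center (x, y) of the best circular depression near ``expected_radius``."""
    return detect_centers(image, expected_radius, n=1)[0]


def plant_roi(
    center: tuple[float, float],
    radius: float,
    exg: np.ndarray,
) -> PlantROI:
    """Combine the circular ROI with the vegetation mask.

    Membership rule: Euclidean distance from ``center`` to the pixel center
    is ``<= radius``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    h, w = exg.shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center {center} lies outside the {w}x{h} image")
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inside = np.hypot(xs - cx, ys - cy) <= radius
    return PlantROI(center=(float(cx), float(cy)), radius=float(radius),
                    mask=inside & exg.astype(bool))


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Frame manifest CSV with columns frame_index, path, timestamp_hours."""
    df = pd.read_csv(path)
    required = {"frame_index", "path", "timestamp_hours"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df.sort_values("frame_index").reset_index(drop=True)
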