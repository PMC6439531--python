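"""Radial (normal-vector) analysis of dense flow about the seedling center.

Each flow vector p at a plant pixel is projected onto the radial axis
through the seedling center: with r-hat the unit vector from center to
pixel, the normal vector is n = (p . r-hat) r-hat and its sign separates
outward motion (leaf standing, +1) from inward motion (leaf extension or
drooping, -1). Per frame k the masked normal vectors are aggregated into

    N_k      = sum over masked pixels of n,
    Nbar_k   = N_k / m_k,
    S_k      = m_k  (the projected area: number of plant pixels),

with the magnitude |Nbar_k| and angle theta_k = atan2(Nbar_k) summarizing
overall movement. theta_k is undefined (NaN) when the mean vector is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import FlowField
from .preprocessing import PlantROI

__all__ = ["NormalField", "FrameAggregate", "radial_projection", "aggregate_frame",
           "sign_map", "aggregates_to_frame"]


@dataclass
class NormalField:
    """Radial components of a flow field within a plant ROI.

    ``nx``/``ny`` hold the projected vector per pixel (zero outside the
    mask and at the exact center); ``sign`` is +1 outward, -1 inward, 0 for
    a vanishing radial component.
    """

    nx: np.ndarray
    ny: np.ndarray
    sign: np.ndarray
    mask: np.ndarray
    center: tuple[float, float]


@dataclass
class FrameAggregate:
    """Per-frame summary of the normal field."""

    frame_index: int
    n_sum: tuple[float, float]  # N_k
    n_mean: tuple[float, float]  # Nbar_k (0,0 when the mask is empty)
    magnitude: float  # |Nbar_k|
    theta: float  # atan2(Nbar_k), NaN when undefined
    s: int  # S_k = m_k, the projected area / masked-pixel count

    @property
    def m(self) -> int:
        return self.s


def radial_projection(flow: FlowField, roi: PlantROI) -> NormalField:
    """Project flow onto radial directions about the ROI center.

    For each masked pixel, ``n = (p . r_hat) r_hat`` with ``r_hat`` the unit
    vector from the center to the pixel; a pixel exactly at the center has
    no defined radial direction and gets n = 0, sign 0.
    """
    h, w = flow.shape
    cx, cy = roi.center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("ROI center must lie inside the flow grid")
    if roi.mask.shape != (h, w):
        raise ValueError("ROI mask shape must match the flow grid")
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    dx, dy = xs - cx, ys - cy
    dist = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(dist > 0, dx / dist, 0.0)
        ry = np.where(dist > 0, dy / dist, 0.0)
        # (p . r) / |r| rather than p . r-hat: exact cancellation for
        # tangential flow with integer components
        dot = np.where(dist > 0, (flow.u * dx + flow.v * dy) / dist, 0.0)
    mask = roi.mask.astype(bool)
    dot = np.where(mask, dot, 0.0)
    return NormalField(
        nx=dot * rx,
        ny=dot * ry,
        sign=np.sign(dot).astype(np.int8) * mask,
        mask=mask,
        center=(float(cx), float(cy)),
    )


def aggregate_frame(nfield: NormalField, frame_index: int = 0) -> FrameAggregate:
    """Sum and average the normal field over the masked pixels."""
    m = int(nfield.mask.sum())
    nx_sum = float(nfield.nx[nfield.mask].sum())
    ny_sum = float(nfield.ny[nfield.mask].sum())
    if m == 0:
        return FrameAggregate(frame_index, (0.0, 0.0), (0.0, 0.0), 0.0, math.nan, 0)
    mean = (nx_sum / m, ny_sum / m)
    magnitude = math.hypot(*mean)
    theta = math.atan2(mean[1], mean[0]) if magnitude > 0 else math.nan
    return FrameAggregate(frame_index, (nx_sum, ny_sum), mean, magnitude, theta, m)


def sign_map(nfield: NormalField) -> tuple[np.ndarray, float]:
    """Inward/outward sign raster plus the outward fraction statistic.

    Returns ``(signs, fraction_outward)`` where the fraction is the share of
    masked pixels with a strictly outward radial component (NaN when the
    mask is empty).
    """
    m = int(nfield.mask.sum())
    frac = float((nfield.sign == 1).sum()) / m if m > 0 else math.nan
    return nfield.sign.copy(), frac


def aggregates_to_frame(
    aggregates: list[FrameAggregate],
    *,
    plant_id: int = 0,
    capture_interval_min: float = 20.0,
) -> pd.DataFrame:
    """Tidy per-frame table: plant_id, k, t_hours, Nx, Ny, magnitude, theta, S.

    ``t_hours`` is anchored at the first aggregate's frame index.
    """
    if not aggregates:
        raise ValueError("no aggregates given")
    k0 = min(a.frame_index for a in aggregates)
    rows = [
        {
            "plant_id": plant_id,
            "k": a.frame_index,
            "t_hours": (a.frame_index - k0) * capture_interval_min / 60.0,
            "Nx": a.n_sum[0],
            "Ny": a.n_sum[1],
            "magnitude": a.magnitude,
            "theta": a.theta,
            "S": a.s,
        }
        for a in aggregates
    ]
    return pd.DataFrame(rows)
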