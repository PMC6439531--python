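"""Pipeline configuration: one structured object carrying every stage parameter.

Defaults reproduce the standard protocol this pipeline targets: images every
20 min for 640 frames, a 15 h light / 9 h dark cycle, dense flow between
frames 12 h apart on a 320x240 grid, Excess-Green segmentation at 0.2, and a
28-px circular region of interest around each detected seedling center.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    """All stage parameters with protocol defaults.

    Attributes
    ----------
    capture_interval_min : minutes between consecutive frames.
    n_frames : frames per plant in the full protocol.
    lag_hours : temporal baseline of the dense-flow pairs.
    light_hours, dark_hours : the LD schedule, anchored at t=0 = lights-on.
    resize_full : (width, height) of the registration/segmentation raster.
    resize_flow : (width, height) of the optical-flow raster.
    exg_threshold : Excess-Green threshold for vegetation segmentation.
    roi_radius_px : radius of the circular plant ROI on the flow raster.
    shifts_hours : lags for the periodicity (shift-correlation) features.
    pca_components : components per PCA block (four blocks).
    test_fraction : held-out fraction for model evaluation.
    cv_folds : folds for hyperparameter-tuning cross-validation.
    reduced_grids : use desk-scale hyperparameter grids (full grids on demand).
    seed : master seed; per-stage seeds are derived by stable hashing.
    """

    capture_interval_min: float = 20.0
    n_frames: int = 640
    lag_hours: float = 12.0
    light_hours: float = 15.0
    dark_hours: float = 9.0
    resize_full: tuple[int, int] = (640, 480)
    resize_flow: tuple[int, int] = (320, 240)
    exg_threshold: float = 0.2
    roi_radius_px: float = 28.0
    px_per_cm: float = 11.2  # 28 px corresponds to 2.5 cm on the flow raster
    flow_backend: str = "ilk"
    shifts_hours: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0, 120.0, 144.0)
    pca_components: int = 5
    test_fraction: float = 0.3
    cv_folds: int = 5
    reduced_grids: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capture_interval_min <= 0:
            raise ValueError("capture_interval_min must be positive")
        if self.light_hours <= 0 or self.dark_hours <= 0:
            raise ValueError("LD schedule periods must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def ld_schedule(self) -> tuple[float, float]:
        return (self.light_hours, self.dark_hours)

    @property
    def lag_frames(self) -> int:
        lag = self.lag_hours * 60.0 / self.capture_interval_min
        if abs(lag - round(lag)) > 1e-9:
            raise ValueError("lag_hours must be a multiple of the capture interval")
        return int(round(lag))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resize_full"] = list(self.resize_full)
        d["resize_flow"] = list(self.resize_flow)
        d["shifts_hours"] = list(self.shifts_hours)
        return d

    def config_hash(self) -> str:
        """Stable short hash stamped onto every pipeline artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def child_seed(self, stage: str) -> int:
        """Derive a per-stage seed (< 2**31) from the master seed by hashing."""
        return child_seed(self.seed, stage)

    def save(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` text file."""
        lines = ["[pipeline]"]
        for key, val in self.to_dict().items():
            if isinstance(val, list):
                val = ",".join(str(v) for v in val)
            lines.append(f"{key} = {val}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Parse a ``key = value`` config file; unknown keys are rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = _coerce(known[key].type, val)
        return cls(**kwargs)


def _coerce(annotation: object, text: str):
    ann = str(annotation)
    if "tuple[int, int]" in ann:
        parts = [int(float(p)) for p in text.split(",")]
        return (parts[0], parts[1])
    if "tuple[float" in ann:
        return tuple(float(p) for p in text.split(","))
    if "bool" in ann:
        return text.strip().lower() in {"1", "true", "yes", "on"}
    if "int" in ann:
        return int(float(text))
    if "float" in ann:
        return float(text)
    return text


def child_seed(seed: int, stage: str) -> int:
    """Stable stage seed: hash of ``"{seed}:{stage}"``, reduced below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
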