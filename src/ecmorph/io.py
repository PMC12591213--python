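"""Readers, writers and run configuration.

CSV outputs are comma-separated UTF-8 with a mandatory header row and '.'
decimals; models, ground truths and decoupling reports serialize to JSON
(floats round-trip exactly via the shortest-repr encoding).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deconvolution import DEFAULT_BASIS, StainBasis
from .expansion import DecouplingReport, FollicleCounts, InjectionSchedule
from .morphometry import FEATURE_NAMES, MorphometryConfig
from .synthetic import GroundTruth
from .turnover import Scaler, TurnoverModel

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "write_features",
    "read_features",
    "write_scores",
    "write_model",
    "read_model",
    "write_ground_truth",
    "read_ground_truth",
    "read_stain_basis",
    "read_schedule",
    "read_follicle_counts",
    "write_decoupling_report",
]


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; written alongside outputs."""

    pixel_size_um: float = 0.5
    stain_basis: list = field(
        default_factory=lambda: DEFAULT_BASIS.rows.tolist()
    )
    denoise_window: int = 3
    binarize_method: str = "fraction"
    binarize_threshold: float = 0.5
    linear_se_length: int = 5
    diamond_se_radius: int = 1
    lasso_folds: int = 10
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.denoise_window < 3 or self.denoise_window % 2 == 0:
            raise ValueError("denoise_window must be an odd integer >= 3")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if np.asarray(self.stain_basis, dtype=float).shape != (3, 3):
            raise ValueError("stain_basis must be a 3x3 matrix")

    @property
    def basis(self) -> StainBasis:
        return StainBasis(rows=np.asarray(self.stain_basis, dtype=float))

    @property
    def morphometry(self) -> MorphometryConfig:
        return MorphometryConfig(
            denoise_window=self.denoise_window,
            binarize_threshold=self.binarize_threshold,
            binarize_method=self.binarize_method,
            linear_se_length=self.linear_se_length,
            diamond_se_radius=self.diamond_se_radius,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_image(path) -> tuple[np.ndarray, dict]:
    """Load an 8/16-bit RGB TIFF or PNG as a float raster in [0, 1]."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in (".tif", ".tiff", ".png"):
        raise ValueError(f"unsupported image format {path.suffix!r}; use TIFF or PNG")
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("RGB required: image has no 3-channel colour axis")
    arr = arr[..., :3]
    if arr.dtype == np.uint8:
        scale, depth = 255.0, 8
    elif arr.dtype == np.uint16:
        scale, depth = 65535.0, 16
    else:
        raise ValueError(f"unsupported bit depth/dtype {arr.dtype}; use 8- or 16-bit")
    return arr.astype(float) / scale, {"bit_depth": depth, "path": str(path)}


def write_image(rgb: np.ndarray, path) -> None:
    """Save a float RGB raster in [0, 1] as 16-bit TIFF or PNG."""
    import imageio.v3 as iio

    data = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (data * 65535).round().astype(np.uint16))


def write_features(frame: pd.DataFrame, path) -> None:
    """Features CSV: id column then the 26 canonical feature columns."""
    frame = frame.reindex(columns=list(FEATURE_NAMES))
    frame.to_csv(path, index=True, index_label="image_id", float_format="%.12g")


def read_features(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="image_id")
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"features file is missing column(s): {missing}")
    return frame[list(FEATURE_NAMES)]


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("turnover_score").to_csv(
        path, index=True, index_label="image_id", float_format="%.12g"
    )


def write_model(model: TurnoverModel, path) -> None:
    payload = {
        "scaler": {
            "mean": model.scaler.mean.to_dict(),
            "std": model.scaler.std.to_dict(),
            "dropped": model.scaler.dropped,
        },
        "selected": model.selected,
        "coefficients": model.coefficients.to_dict(),
        "intercept": model.intercept,
        "fitted": {str(k): v for k, v in model.fitted.items()},
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_model(path) -> TurnoverModel:
    with open(path) as fh:
        payload = json.load(fh)
    scaler = Scaler(
        mean=pd.Series(payload["scaler"]["mean"], dtype=float),
        std=pd.Series(payload["scaler"]["std"], dtype=float),
        dropped=list(payload["scaler"]["dropped"]),
    )
    return TurnoverModel(
        scaler=scaler,
        selected=list(payload["selected"]),
        coefficients=pd.Series(payload["coefficients"], dtype=float),
        intercept=float(payload["intercept"]),
        fitted=pd.Series(payload["fitted"], dtype=float),
        metadata=dict(payload.get("metadata", {})),
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "fibers": [
            {
                "anchor_um": list(f.anchor_um),
                "orientation": f.orientation,
                "length_um": f.length_um,
                "width_um": f.width_um,
                "waviness": f.waviness,
                "stain": f.stain,
                "fragments": f.fragments,
            }
            for f in truth.fibers
        ],
        "summaries": {
            "fiber_count": truth.fiber_count,
            "mean_length_um": truth.mean_length_um,
            "mean_width_um": truth.mean_width_um,
            "orientation_circular_variance": truth.orientation_circular_variance,
            "porosity_pct": truth.porosity_pct,
            "mature_area_fraction": truth.mature_area_fraction,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_ground_truth(path) -> GroundTruth:
    from .synthetic import FiberSpec

    with open(path) as fh:
        payload = json.load(fh)
    fibers = [
        FiberSpec(
            anchor_um=tuple(f["anchor_um"]),
            orientation=f["orientation"],
            length_um=f["length_um"],
            width_um=f["width_um"],
            waviness=f["waviness"],
            stain=f["stain"],
            fragments=f["fragments"],
        )
        for f in payload["fibers"]
    ]
    return GroundTruth(fibers=fibers, **payload["summaries"])


def read_stain_basis(path) -> StainBasis:
    """Load a 3x3 stain-absorbance matrix from YAML (key ``rows`` or bare)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rows = data["rows"] if isinstance(data, dict) else data
    return StainBasis(rows=np.asarray(rows, dtype=float))


def read_schedule(path) -> InjectionSchedule:
    """Injection schedule from YAML: initial_volume_ml, additions, cap_ml."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return InjectionSchedule(
        initial_volume_ml=float(data["initial_volume_ml"]),
        additions=tuple(
            (float(d), float(v)) for d, v in data.get("additions", [])
        ),
        cap_ml=None if data.get("cap_ml") is None else float(data["cap_ml"]),
    )


def read_follicle_counts(path) -> FollicleCounts:
    """Follicle densities from CSV with columns day, density_per_mm2."""
    frame = pd.read_csv(path)
    for col in ("day", "density_per_mm2"):
        if col not in frame.columns:
            raise ValueError(f"follicle-density CSV is missing column {col!r}")
    return FollicleCounts(
        observations=tuple(
            (float(r.day), float(r.density_per_mm2)) for r in frame.itertuples()
        )
    )


def write_decoupling_report(report: DecouplingReport, path) -> None:
    payload = {
        "decoupling_day": report.decoupling_day,
        "tolerance": report.tolerance,
        "shortfall": {str(k): v for k, v in report.shortfall.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
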