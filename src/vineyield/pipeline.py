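"""End-to-end orchestration: image -> Lab b* -> two-stage Otsu ->
particle analysis -> per-vine records -> yield model.

`PipelineConfig` carries every tunable of the detection chain with the
standard defaults (Gaussian radius 2 px, area floor 200 px, circularity
0.25-1.00, 8-connectivity, double-cluster split factor 1.5, dark/low-b*
cluster polarity).  `run_detect` processes a batch of images and
optionally writes the particle table, mask rasters and a JSON run
manifest; `run_yield` fits the area->weight regression on one season's
table and applies it to another.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .color_ops import extract_b_channel, gaussian_smooth, read_rgb_image, srgb_to_lab
from .metrics import accuracy_pct
from .particles import (
    ParticleSet,
    ScaleCalibration,
    adjust_double_clusters,
    filter_particles,
    label_components,
    measure_particles,
)
from .segmentation import BACKGROUND, CLUSTER, EXCLUDED_VEGETATION, two_stage_segmentation
from .yield_model import AreaYieldModel, AreaYieldResults

__all__ = ["PipelineConfig", "detect_image", "run_detect", "run_yield", "run_cost"]


@dataclass
class PipelineConfig:
    gaussian_radius: float = 2.0
    min_area_px: int = 200
    circularity_range: tuple = (0.25, 1.00)
    connectivity: int = 8
    split_factor: float = 1.5
    cluster_polarity: str = "low"
    pixels_per_cm: Optional[float] = None
    scale_line_px: Optional[float] = None
    scale_known_cm: Optional[float] = None
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        self.circularity_range = tuple(self.circularity_range)
        if self.gaussian_radius <= 0:
            raise ValueError("gaussian_radius must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def calibration(self) -> Optional[ScaleCalibration]:
        if self.pixels_per_cm is not None:
            return ScaleCalibration(pixels_per_cm=self.pixels_per_cm)
        if self.scale_line_px is not None and self.scale_known_cm is not None:
            return ScaleCalibration.from_line(self.scale_line_px, self.scale_known_cm)
        return None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["circularity_range"] = list(self.circularity_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(d)


def detect_image(
    image: np.ndarray, config: PipelineConfig = None, image_id: str = ""
) -> dict:
    """Run the full detection chain on one RGB array.

    Returns a dict with the cluster mask, the measured/filtered/adjusted
    particle set and the per-stage status flag.
    """
    config = config or PipelineConfig()
    lab = srgb_to_lab(image)
    channel = gaussian_smooth(extract_b_channel(lab), radius=config.gaussian_radius)
    mask = two_stage_segmentation(channel, cluster_polarity=config.cluster_polarity)

    labeled, _ = label_components(mask, connectivity=config.connectivity)
    measured = measure_particles(labeled, calibration=config.calibration(), image_id=image_id)
    kept = filter_particles(
        measured,
        min_area_px=config.min_area_px,
        circularity_range=config.circularity_range,
    )
    adjusted = adjust_double_clusters(kept, split_factor=config.split_factor)
    return {
        "image_id": image_id,
        "mask": mask,
        "particles_raw": measured,
        "particles": adjusted,
        "status": mask.status,
    }


def _mask_to_png(mask_state: np.ndarray, path) -> None:
    from PIL import Image

    # 0 background / 128 excluded vegetation / 255 cluster
    out = np.zeros(mask_state.shape, dtype=np.uint8)
    out[mask_state == EXCLUDED_VEGETATION] = 128
    out[mask_state == CLUSTER] = 255
    Image.fromarray(out).save(path)


def run_detect(images, config: PipelineConfig = None) -> dict:
    """Batch detection over image paths or (image_id, array) pairs.

    Unreadable files are recorded as per-file errors and the batch
    continues.  When ``config.output_dir`` is set, writes
    ``particles.csv``, one mask PNG per image and ``report.json``.
    """
    config = config or PipelineConfig()
    results, errors = [], {}
    for item in images:
        if isinstance(item, tuple):
            image_id, arr = item
        else:
            image_id = Path(item).stem
            try:
                arr = read_rgb_image(item)
            except Exception as exc:  # unreadable file: record, continue
                errors[str(item)] = str(exc)
                continue
        results.append(detect_image(arr, config, image_id=image_id))

    rows = [row for r in results for row in r["particles"].to_records()]
    particle_table = pd.DataFrame(
        rows,
        columns=[
            "image_id", "particle_id", "area_px", "area_cm2", "perimeter_px",
            "circularity", "centroid_row", "centroid_col", "bbox_min_row",
            "bbox_min_col", "bbox_max_row", "bbox_max_col", "counts_as",
        ],
    )
    report = {
        "software": f"vineyield {__version__}",
        "config": config.to_dict(),
        "n_images": len(results),
        "errors": errors,
        "images": [
            {
                "image_id": r["image_id"],
                "status": r["status"],
                "raw_count": r["particles"].raw_count,
                "adjusted_count": r["particles"].adjusted_count,
                "total_area_px": int(sum(p.area_px for p in r["particles"].particles)),
            }
            for r in results
        ],
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        particle_table.to_csv(out / "particles.csv", index=False)
        for r in results:
            _mask_to_png(r["mask"].state, out / f"mask_{r['image_id']}.png")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return {"results": results, "particle_table": particle_table, "report": report}


_REQUIRED_YIELD_COLS = {"vine_id", "vigor_zone", "total_cluster_area_cm2"}


def run_yield(
    train_table: pd.DataFrame,
    apply_table: pd.DataFrame,
    through_origin: bool = False,
    output_dir: Optional[str] = None,
) -> dict:
    """Fit the area->weight regression on one season, apply to another.

    Emits per-vine estimates, per-vine accuracy where measured yield is
    available, and zone-mean accuracy (accuracy of the zone mean
    estimate against the zone mean measurement).
    """
    for name, tbl in (("train", train_table), ("apply", apply_table)):
        missing = _REQUIRED_YIELD_COLS - set(tbl.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if "measured_yield_g" not in train_table.columns:
        raise ValueError("train table missing columns: ['measured_yield_g']")

    results = AreaYieldModel(train_table, through_origin=through_origin).fit()

    out = apply_table.copy()
    if len(out):
        out["estimated_yield_g"] = results.predict(
            out["total_cluster_area_cm2"].to_numpy(dtype=float)
        )
        if "measured_yield_g" in out.columns:
            ok = out["measured_yield_g"] > 0
            out.loc[ok, "accuracy_pct"] = accuracy_pct(
                out.loc[ok, "measured_yield_g"].to_numpy(),
                out.loc[ok, "estimated_yield_g"].to_numpy(),
            )
    else:
        out["estimated_yield_g"] = pd.Series(dtype=float)

    zone_rows = []
    if len(out) and "measured_yield_g" in out.columns:
        for zone, grp in out.groupby("vigor_zone"):
            grp = grp.dropna(subset=["measured_yield_g"])
            if not len(grp) or grp["measured_yield_g"].mean() <= 0:
                continue
            zone_rows.append(
                {
                    "vigor_zone": zone,
                    "n_vines": int(len(grp)),
                    "mean_measured_g": float(grp["measured_yield_g"].mean()),
                    "mean_estimated_g": float(grp["estimated_yield_g"].mean()),
                    "accuracy_pct": accuracy_pct(
                        grp["measured_yield_g"].mean(), grp["estimated_yield_g"].mean()
                    ),
                }
            )
    zone_table = pd.DataFrame(
        zone_rows,
        columns=["vigor_zone", "n_vines", "mean_measured_g", "mean_estimated_g", "accuracy_pct"],
    )

    if output_dir:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "vines_estimated.csv", index=False)
        zone_table.to_csv(outdir / "zone_accuracy.csv", index=False)
        results.to_json(outdir / "area_yield_model.json")
    return {"model": results, "vine_table": out, "zone_table": zone_table}


def run_cost(area_ha: float, **overrides) -> dict:
    """Ground vs UAV cost comparison for one vineyard size."""
    from .cost_model import compare_modes

    if area_ha <= 0:
        raise ValueError("area must be positive")
    return compare_modes(area_ha, **overrides)
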