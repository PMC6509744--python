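"""Connected-component morphometry of the cluster mask.

Mirrors a classic "analyze particles" step: label the cluster pixels
(8-connected by default), measure area / perimeter / circularity per
component, apply the area and circularity retention filters, and apply
the double-cluster adjustment that counts an oversized blob as two
touching bunches.

Perimeter is the chain-code boundary length of ``skimage.measure
.regionprops`` (straight steps 1, diagonal steps sqrt(2)); a 10 x 10
square therefore has perimeter 36 and circularity 4*pi*100/36^2 = 0.970.
Circularity is capped at 1.0 since discretization can push the raw ratio
slightly above the disc limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
from skimage import measure

from .segmentation import CLUSTER, ClusterMask

__all__ = [
    "ScaleCalibration",
    "Particle",
    "ParticleSet",
    "label_components",
    "measure_particles",
    "filter_particles",
    "adjust_double_clusters",
]


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-centimetre scale from a known-length target in the image."""

    pixels_per_cm: float
    line_length_px: Optional[float] = None
    known_length_cm: Optional[float] = None

    def __post_init__(self):
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")

    @classmethod
    def from_line(cls, line_length_px: float, known_length_cm: float) -> "ScaleCalibration":
        if line_length_px <= 0 or known_length_cm <= 0:
            raise ValueError("line length and known length must be positive")
        return cls(
            pixels_per_cm=line_length_px / known_length_cm,
            line_length_px=line_length_px,
            known_length_cm=known_length_cm,
        )

    def px_area_to_cm2(self, area_px: float) -> float:
        return area_px / self.pixels_per_cm**2


@dataclass(frozen=True)
class Particle:
    id: int
    area_px: int
    perimeter_px: float
    circularity: float
    centroid: tuple  # (row, col)
    bbox: tuple  # (min_row, min_col, max_row, max_col)
    area_cm2: Optional[float] = None
    counts_as: int = 1  # 2 after the double-cluster adjustment


@dataclass
class ParticleSet:
    particles: List[Particle]
    image_id: str = ""
    calibration: Optional[ScaleCalibration] = None
    adjusted_count: Optional[int] = None

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def raw_count(self) -> int:
        return len(self.particles)

    def total_area_cm2(self) -> float:
        if self.calibration is None:
            raise ValueError("particle set is uncalibrated; no cm^2 areas available")
        return float(sum(p.area_cm2 for p in self.particles))

    def to_records(self) -> List[dict]:
        rows = []
        for p in self.particles:
            rows.append(
                {
                    "image_id": self.image_id,
                    "particle_id": p.id,
                    "area_px": p.area_px,
                    "area_cm2": p.area_cm2,
                    "perimeter_px": p.perimeter_px,
                    "circularity": p.circularity,
                    "centroid_row": p.centroid[0],
                    "centroid_col": p.centroid[1],
                    "bbox_min_row": p.bbox[0],
                    "bbox_min_col": p.bbox[1],
                    "bbox_max_row": p.bbox[2],
                    "bbox_max_col": p.bbox[3],
                    "counts_as": p.counts_as,
                }
            )
        return rows


def label_components(mask: ClusterMask | np.ndarray, connectivity: int = 8):
    """Label connected cluster components in raster-scan order.

    Returns (labeled raster, count).  ``connectivity`` is 8 (default,
    diagonal neighbours connect) or 4.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = mask.state == CLUSTER if isinstance(mask, ClusterMask) else np.asarray(mask, bool)
    skconn = 2 if connectivity == 8 else 1
    labeled, n = measure.label(binary, connectivity=skconn, return_num=True)
    return labeled, int(n)


def measure_particles(
    labeled: np.ndarray,
    calibration: Optional[ScaleCalibration] = None,
    image_id: str = "",
) -> ParticleSet:
    """Measure every labeled component.

    Areas are pixel counts; ``area_cm2`` is filled only when a
    calibration is supplied (yield operations refuse uncalibrated sets).
    """
    particles: List[Particle] = []
    for rp in measure.regionprops(labeled):
        area = int(rp.area)
        perim = float(rp.perimeter)
        if perim > 0:
            circ = min(1.0, 4.0 * math.pi * area / perim**2)
        else:
            circ = 1.0  # single pixel / degenerate boundary: treat as round
        particles.append(
            Particle(
                id=int(rp.label),
                area_px=area,
                perimeter_px=perim,
                circularity=circ,
                centroid=tuple(float(c) for c in rp.centroid),
                bbox=tuple(int(v) for v in rp.bbox),
                area_cm2=calibration.px_area_to_cm2(area) if calibration else None,
            )
        )
    return ParticleSet(particles=particles, image_id=image_id, calibration=calibration)


def filter_particles(
    pset: ParticleSet,
    min_area_px: int = 200,
    circularity_range: tuple = (0.25, 1.00),
) -> ParticleSet:
    """Retain particles with area >= min_area_px (inclusive) and
    circularity inside the closed range.  Defaults match the standard
    analyze-particles settings for grape bunches at ~2 mm ground
    resolution: 200 px to infinity, circularity 0.25-1.00.
    """
    lo, hi = circularity_range
    if lo > hi:
        raise ValueError(f"inverted circularity range: {circularity_range}")
    kept = [
        p
        for p in pset.particles
        if p.area_px >= min_area_px and lo <= p.circularity <= hi
    ]
    return ParticleSet(
        particles=kept, image_id=pset.image_id, calibration=pset.calibration
    )


def adjust_double_clusters(pset: ParticleSet, split_factor: float = 1.5) -> ParticleSet:
    """Count oversized particles as two touching clusters.

    A particle whose area exceeds ``split_factor`` times the median area
    of the set counts as 2 (two bunches segmented as one blob); the
    adjusted count is raw count + number of oversized particles.  Works
    on calibrated areas when available, raw pixel areas otherwise.
    """
    if split_factor <= 1:
        raise ValueError("split_factor must exceed 1")
    if not pset.particles:
        return ParticleSet(
            particles=[],
            image_id=pset.image_id,
            calibration=pset.calibration,
            adjusted_count=0,
        )
    areas = np.array(
        [p.area_cm2 if p.area_cm2 is not None else p.area_px for p in pset.particles],
        dtype=np.float64,
    )
    cutoff = split_factor * float(np.median(areas))
    adjusted = [
        replace(p, counts_as=2 if a > cutoff else 1)
        for p, a in zip(pset.particles, areas)
    ]
    return ParticleSet(
        particles=adjusted,
        image_id=pset.image_id,
        calibration=pset.calibration,
        adjusted_count=int(sum(p.counts_as for p in adjusted)),
    )
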