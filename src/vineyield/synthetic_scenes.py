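"""Seeded synthetic vineyard fruiting-zone scenes with ground truth.

Each scene emulates a nadir-ish close view of a vertically trained
fruiting zone: a green foliage band on top, brown soil below, and dark
blue-purple grape clusters hanging in a fruiting band, rendered as
unions of jittered ellipses to mimic compound bunch outlines.  Two
acquisition regimes are provided as presets:

* best condition (B): clusters largely free of leaves and directly lit
  (low occlusion, low shadow);
* worst condition (W): clusters heavily overdrawn by foliage and
  shadowed (high occlusion, strong multiplicative darkening).

Per-pixel class labels and per-cluster areas are recorded *before*
sensor noise is added, so every downstream stage (segmentation,
particle filtering, counting, yield regression) can be scored against
exact truth.  All randomness flows from one ``numpy.random.default_rng``
(PCG64) seed; identical specs give bit-identical scenes.

A companion generator produces per-vine area/yield tables with a known
linear area->weight law for regression parameter-recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "best_condition_preset",
    "worst_condition_preset",
    "generate_vine_table",
]

LABEL_SOIL = 0
LABEL_FOLIAGE = 1
LABEL_CLUSTER = 2


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic fruiting-zone image."""

    width: int = 480
    height: int = 360
    n_clusters: int = 8
    cluster_radius_mean: float = 16.0
    cluster_radius_sd: float = 1.2
    cluster_color: Tuple[int, int, int] = (60, 40, 80)
    foliage_color: Tuple[int, int, int] = (70, 120, 50)
    soil_color: Tuple[int, int, int] = (110, 95, 85)
    color_jitter: float = 3.0
    occlusion_fraction: float = 0.0
    shadow_strength: float = 0.0
    noise_sd: float = 3.0
    foliage_band_fraction: float = 0.6
    min_gap_px: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("cluster_color", "foliage_color", "soil_color"):
            c = getattr(self, name)
            object.__setattr__(self, name, tuple(int(v) for v in c))
            if any(v < 0 or v > 255 for v in getattr(self, name)):
                raise ValueError(f"{name} must be valid 8-bit sRGB")
        for name in ("occlusion_fraction", "shadow_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("cluster_color", "foliage_color", "soil_color"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-pixel and per-cluster truth for one rendered scene."""

    cluster_count: int
    per_cluster_area_px: List[int]  # rendered (pre-occlusion) areas
    per_cluster_visible_px: List[int]  # after foliage occlusion
    pixel_labels: np.ndarray  # H x W uint8: soil/foliage/cluster
    cluster_ids: np.ndarray  # H x W int32, 0 = no cluster
    shadow_mask: np.ndarray  # H x W bool


def best_condition_preset(seed: int = 0, **overrides) -> SceneSpec:
    """Partially defoliated, directly lit fruiting zone."""
    return SceneSpec(
        occlusion_fraction=0.05, shadow_strength=0.05, seed=seed, **overrides
    )


def worst_condition_preset(seed: int = 0, **overrides) -> SceneSpec:
    """Leaf-covered, shaded fruiting zone."""
    return SceneSpec(
        occlusion_fraction=0.5, shadow_strength=0.4, seed=seed, **overrides
    )


def _place_centers(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample cluster centers in the fruiting band with a
    guaranteed inter-cluster gap (so truth clusters stay disconnected)."""
    fh = int(spec.height * spec.foliage_band_fraction)
    rmax = spec.cluster_radius_mean + 3.0 * spec.cluster_radius_sd
    extent = 1.4 * rmax  # max blob half-extent incl. ellipse offsets
    margin = int(np.ceil(extent)) + 2
    row_lo = fh + margin
    row_hi = min(spec.height - margin, fh + margin + int(3.2 * extent))
    col_lo, col_hi = margin, spec.width - margin
    min_dist = 2.0 * extent + spec.min_gap_px

    centers = []
    attempts = 0
    while len(centers) < spec.n_clusters and attempts < 600:
        attempts += 1
        r = rng.uniform(row_lo, max(row_lo + 1, row_hi))
        c = rng.uniform(col_lo, col_hi)
        if all(np.hypot(r - r0, c - c0) >= min_dist for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < spec.n_clusters:
        warnings.warn(
            f"placed only {len(centers)} of {spec.n_clusters} clusters "
            "without overlap; ground truth reflects the actual count"
        )
    return centers, fh


def _render_cluster_mask(
    spec: SceneSpec, rng: np.random.Generator, center, rr, cc
) -> np.ndarray:
    """Union of 4 jittered ellipses around ``center`` -> boolean mask.

    The union is rescaled so the blob area tracks the drawn radius
    (target 1.8 r^2): outlines stay lumpy like compound bunches, but
    within-scene size spread reflects the radius distribution only.
    """
    r0, c0 = center
    base_r = rng.normal(spec.cluster_radius_mean, spec.cluster_radius_sd)
    base_r = max(6.0, base_r)
    params = [
        (
            rng.uniform(-0.2, 0.2) * base_r,
            rng.uniform(-0.2, 0.2) * base_r,
            rng.uniform(0.68, 0.80) * base_r,  # semi-axes
            rng.uniform(0.68, 0.80) * base_r,
            rng.uniform(0, np.pi),
        )
        for _ in range(4)
    ]

    def union(scale: float) -> np.ndarray:
        m = np.zeros(rr.shape, dtype=bool)
        for dr, dc, sa, sb, theta in params:
            y = rr - (r0 + dr * scale)
            x = cc - (c0 + dc * scale)
            u = np.cos(theta) * x + np.sin(theta) * y
            v = -np.sin(theta) * x + np.cos(theta) * y
            m |= (u / (sa * scale)) ** 2 + (v / (sb * scale)) ** 2 <= 1.0
        return m

    target = 1.8 * base_r**2
    area0 = max(1, int(union(1.0).sum()))
    return union(float(np.sqrt(target / area0)))


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Render one scene.  Returns (uint8 H x W x 3 image, GroundTruth)."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    img = np.empty((H, W, 3), dtype=np.float64)
    labels = np.full((H, W), LABEL_SOIL, dtype=np.uint8)

    centers, fh = _place_centers(spec, rng)
    labels[:fh, :] = LABEL_FOLIAGE
    img[:] = spec.soil_color
    img[:fh, :] = spec.foliage_color
    # gentle low-frequency mottling so regions are not flat fields
    for band, color in ((slice(0, fh), spec.foliage_color), (slice(fh, H), spec.soil_color)):
        rows = img[band]
        mottle = rng.normal(0.0, spec.color_jitter, size=(rows.shape[0] // 8 + 1, W // 8 + 1, 3))
        mottle = np.kron(mottle, np.ones((8, 8, 1)))[: rows.shape[0], :W]
        img[band] = np.asarray(color, dtype=np.float64) + mottle

    rr, cc = np.mgrid[0:H, 0:W]
    cluster_ids = np.zeros((H, W), dtype=np.int32)
    rendered_areas: List[int] = []
    visible_areas: List[int] = []

    for k, center in enumerate(centers, start=1):
        mask = _render_cluster_mask(spec, rng, center, rr, cc)
        mask &= cluster_ids == 0
        color = np.asarray(spec.cluster_color, dtype=np.float64) + rng.normal(
            0.0, spec.color_jitter, size=3
        )
        img[mask] = np.clip(color, 0, 255)
        cluster_ids[mask] = k
        labels[mask] = LABEL_CLUSTER
        rendered_areas.append(int(mask.sum()))

        # foliage occlusion: leaves overhang the bunch, fragmenting the
        # visible fruit until the requested cover fraction is reached
        if spec.occlusion_fraction > 0 and mask.any():
            area0 = int(mask.sum())
            r0, c0 = center
            leaf_r = 0.6 * spec.cluster_radius_mean
            budget = spec.occlusion_fraction * area0
            for _ in range(24):
                covered = area0 - int(np.count_nonzero(cluster_ids == k))
                if covered >= budget:
                    break
                # leaf size capped by the remaining cover budget so light
                # occlusion means small leaf bits, not one giant leaf
                r_cap = 1.2 * np.sqrt(max(budget - covered, 1.0) / np.pi)
                leaf_r_eff = min(leaf_r, r_cap)
                lr = r0 + rng.uniform(-1.2, 1.2) * spec.cluster_radius_mean
                lc = c0 + rng.uniform(-1.2, 1.2) * spec.cluster_radius_mean
                sa = rng.uniform(0.7, 1.3) * leaf_r_eff
                sb = rng.uniform(0.7, 1.3) * leaf_r_eff
                leaf = ((rr - lr) / sa) ** 2 + ((cc - lc) / sb) ** 2 <= 1.0
                occluded = leaf & (cluster_ids == k)
                if not occluded.any():
                    continue
                leaf_color = np.asarray(
                    spec.foliage_color, dtype=np.float64
                ) + rng.normal(0.0, spec.color_jitter, size=3)
                img[occluded] = np.clip(leaf_color, 0, 255)
                labels[occluded] = LABEL_FOLIAGE
                cluster_ids[occluded] = 0
        visible_areas.append(int(np.count_nonzero(cluster_ids == k)))

    # dappled canopy shade: a smooth low-frequency multiplicative field,
    # never a hard edge (hard shadow boundaries are a mosaicking/optics
    # artifact this generator does not model)
    shadow_mask = np.zeros((H, W), dtype=bool)
    if spec.shadow_strength > 0:
        field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(H, W)), 32.0)
        lo, hi = field.min(), field.max()
        field = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)
        s_px = (spec.shadow_strength * field)[..., None]
        img = (1.0 - s_px) * img
        shadow_mask = s_px[..., 0] > spec.shadow_strength * 0.5

    truth = GroundTruth(
        cluster_count=len(centers),
        per_cluster_area_px=rendered_areas,
        per_cluster_visible_px=visible_areas,
        pixel_labels=labels,
        cluster_ids=cluster_ids,
        shadow_mask=shadow_mask,
    )

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return image, truth


# -- per-vine yield tables ----------------------------------------------

_ZONE_AREA_PARAMS = {
    # total visible cluster surface per vine, cm^2: mean, sd by vigor zone
    "HV": (168.6, 84.0),
    "LV": (69.2, 35.6),
}


def generate_vine_table(
    n_per_zone: int = 10,
    true_slope: float = 4.0,
    true_intercept: float = 0.0,
    noise_fraction: float = 0.15,
    condition: str = "B",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-vine cluster areas and yields under a known linear law.

    Areas are drawn per vigor zone from the typical high/low-vigor
    distributions (truncated at 10 cm^2); measured yield is
    ``true_slope * area + true_intercept`` plus Gaussian noise with
    sd = ``noise_fraction`` of the mean yield.  Ideal for checking that
    the fitted regression recovers ``true_slope``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for zone, (mu, sd) in _ZONE_AREA_PARAMS.items():
        areas = np.maximum(10.0, rng.normal(mu, sd, size=n_per_zone))
        clean = true_slope * areas + true_intercept
        noise_sd = noise_fraction * float(np.mean(clean))
        yields = np.maximum(0.0, clean + rng.normal(0.0, noise_sd, size=n_per_zone))
        for i, (a, y) in enumerate(zip(areas, yields), start=1):
            rows.append(
                {
                    "vine_id": f"{zone}-{i:02d}",
                    "vigor_zone": zone,
                    "condition": condition,
                    "total_cluster_area_cm2": float(a),
                    "measured_yield_g": float(y),
                }
            )
    return pd.DataFrame(rows)
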