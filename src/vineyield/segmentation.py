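"""Two-stage Otsu segmentation of the smoothed b* channel.

Stage 1 thresholds the full-image histogram and removes the
above-threshold (high-b*, yellow-green) class as vegetation.  Stage 2
rebuilds the histogram over the remaining pixels only and takes the
below-threshold (low-b*, blue) class as grape clusters; everything else
(typically soil and trellis background) stays background.

Histograms use 256 linear bins spanning the min-max of the included
pixels, so both stages behave like 8-bit thresholding regardless of the
channel's physical scale.  Degenerate stages (no contrast left) fail
soft: the mask comes back with no cluster pixels and a status flag, so
batch runs continue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .color_ops import ScalarChannel

__all__ = [
    "Histogram",
    "ThresholdResult",
    "ClusterMask",
    "DegenerateHistogramError",
    "build_histogram",
    "otsu_threshold",
    "two_stage_segmentation",
    "class_separation",
    "BACKGROUND",
    "CLUSTER",
    "EXCLUDED_VEGETATION",
]

N_BINS = 256

# mask state codes
BACKGROUND = 0
CLUSTER = 1
EXCLUDED_VEGETATION = 2


class DegenerateHistogramError(ValueError):
    """Raised when a histogram cannot support a two-class split."""


@dataclass(frozen=True)
class Histogram:
    counts: np.ndarray  # (256,) int64
    vmin: float
    vmax: float
    n_pixels: int

    @property
    def degenerate(self) -> bool:
        return int(np.count_nonzero(self.counts)) < 2

    @property
    def bin_width(self) -> float:
        return (self.vmax - self.vmin) / N_BINS

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        """Bin index of each value under this histogram's linear mapping."""
        if self.vmax == self.vmin:
            return np.zeros(np.shape(values), dtype=np.int64)
        idx = np.floor(
            (np.asarray(values, dtype=np.float64) - self.vmin)
            / (self.vmax - self.vmin)
            * N_BINS
        ).astype(np.int64)
        return np.clip(idx, 0, N_BINS - 1)


@dataclass(frozen=True)
class ThresholdResult:
    threshold_bin: int
    threshold_value: float  # upper edge of the threshold bin, channel units
    interclass_variance: float
    class_fractions: tuple  # (low class, high class), sums to 1


@dataclass
class ClusterMask:
    """Per-pixel segmentation state plus the two thresholds that made it."""

    state: np.ndarray  # H x W uint8 in {BACKGROUND, CLUSTER, EXCLUDED_VEGETATION}
    veg_threshold: Optional[ThresholdResult] = None
    cluster_threshold: Optional[ThresholdResult] = None
    status: str = "ok"  # "ok" | "degenerate-stage1" | "degenerate-stage2"

    def counts(self) -> dict:
        return {
            "cluster": int(np.count_nonzero(self.state == CLUSTER)),
            "background": int(np.count_nonzero(self.state == BACKGROUND)),
            "excluded_vegetation": int(
                np.count_nonzero(self.state == EXCLUDED_VEGETATION)
            ),
        }


def build_histogram(
    channel: ScalarChannel | np.ndarray,
    exclusion: Optional[np.ndarray] = None,
) -> Histogram:
    """256-bin histogram over the min-max range of the included pixels.

    ``exclusion`` is a boolean mask of pixels to drop (True = excluded).
    """
    values = channel.values if isinstance(channel, ScalarChannel) else np.asarray(channel)
    values = values.astype(np.float64)
    if exclusion is not None:
        values = values[~np.asarray(exclusion, dtype=bool)]
    else:
        values = values.ravel()
    if values.size == 0:
        raise ValueError("no pixels left to histogram after exclusion")
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax == vmin:
        counts = np.zeros(N_BINS, dtype=np.int64)
        counts[0] = values.size
        return Histogram(counts=counts, vmin=vmin, vmax=vmax, n_pixels=values.size)
    counts, _ = np.histogram(values, bins=N_BINS, range=(vmin, vmax))
    return Histogram(
        counts=counts.astype(np.int64), vmin=vmin, vmax=vmax, n_pixels=int(values.size)
    )


def otsu_threshold(hist: Histogram) -> ThresholdResult:
    """Otsu's threshold on a 256-bin histogram.

    Maximizes the between-class variance over every split t (low class =
    bins <= t, high class = bins > t), which is equivalent to minimizing
    the weighted within-class variance.  Ties break to the lowest bin.
    """
    if hist.degenerate:
        raise DegenerateHistogramError(
            "histogram has fewer than two populated bins; threshold undefined"
        )
    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    p = counts / total
    bins = np.arange(N_BINS, dtype=np.float64)

    w0 = np.cumsum(p)  # weight of low class for t = 0..255
    mu = np.cumsum(p * bins)
    mu_total = mu[-1]

    w1 = 1.0 - w0
    # between-class variance; undefined where either class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0, posinf=-1.0, neginf=-1.0)
    sigma_b[-1] = -1.0  # t = 255 leaves the high class empty

    t = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    value = hist.vmin + (t + 1) * hist.bin_width
    return ThresholdResult(
        threshold_bin=t,
        threshold_value=float(value),
        interclass_variance=float(sigma_b[t] * hist.bin_width**2),
        class_fractions=(float(w0[t]), float(w1[t])),
    )


def class_separation(hist: Histogram, thr: ThresholdResult) -> float:
    """Ashman-style separation of the two classes induced by a threshold:

        D = sqrt(2) |mu1 - mu0| / sqrt(s0^2 + s1^2).

    Splitting a unimodal Gaussian at its Otsu threshold gives D ~ 2.6
    regardless of scale; well-separated fruit/background classes give
    D >> 4.  Used to reject splits of an effectively one-class stage.
    """
    counts = hist.counts.astype(np.float64)
    bins = np.arange(N_BINS, dtype=np.float64)
    t = thr.threshold_bin
    lo_c, hi_c = counts[: t + 1], counts[t + 1 :]
    lo_b, hi_b = bins[: t + 1], bins[t + 1 :]
    if lo_c.sum() == 0 or hi_c.sum() == 0:
        return 0.0
    mu0 = (lo_c * lo_b).sum() / lo_c.sum()
    mu1 = (hi_c * hi_b).sum() / hi_c.sum()
    v0 = (lo_c * (lo_b - mu0) ** 2).sum() / lo_c.sum()
    v1 = (hi_c * (hi_b - mu1) ** 2).sum() / hi_c.sum()
    denom = np.sqrt(v0 + v1)
    if denom == 0:
        return np.inf
    return float(np.sqrt(2.0) * (mu1 - mu0) / denom)


def two_stage_segmentation(
    b_smoothed: ScalarChannel,
    cluster_polarity: str = "low",
    min_separation: float = 4.0,
) -> ClusterMask:
    """Sequential vegetation removal then cluster isolation.

    Parameters
    ----------
    b_smoothed : smoothed b* channel
    cluster_polarity : "low" (default) labels the below-threshold class of
        stage 2 as clusters — dark blue-purple berries have low/negative
        b* while foliage and soil are positive.  "high" flips both stages
        for targets brighter than their background.
    min_separation : minimum Ashman D between the two classes of each
        stage; weaker splits (an effectively unimodal histogram, e.g. an
        image with no vegetation or no cluster contrast) fail soft as
        degenerate.
    """
    if cluster_polarity not in ("low", "high"):
        raise ValueError(f"cluster_polarity must be 'low' or 'high', got {cluster_polarity!r}")
    values = b_smoothed.values
    state = np.zeros(values.shape, dtype=np.uint8)

    hist1 = build_histogram(b_smoothed)
    try:
        thr1 = otsu_threshold(hist1)
    except DegenerateHistogramError:
        return ClusterMask(state=state, status="degenerate-stage1")
    # no separation guard here: the below-threshold class of stage 1 is
    # legitimately multimodal (clusters + soil), which deflates D

    bins1 = hist1.bin_of(values)
    if cluster_polarity == "low":
        vegetation = bins1 > thr1.threshold_bin
    else:
        vegetation = bins1 <= thr1.threshold_bin
    state[vegetation] = EXCLUDED_VEGETATION

    hist2 = build_histogram(b_smoothed, exclusion=vegetation)
    try:
        thr2 = otsu_threshold(hist2)
    except DegenerateHistogramError:
        return ClusterMask(
            state=state, veg_threshold=thr1, status="degenerate-stage2"
        )
    if class_separation(hist2, thr2) < min_separation:
        return ClusterMask(
            state=state, veg_threshold=thr1, status="degenerate-stage2"
        )

    bins2 = hist2.bin_of(values)
    if cluster_polarity == "low":
        cluster = (~vegetation) & (bins2 <= thr2.threshold_bin)
    else:
        cluster = (~vegetation) & (bins2 > thr2.threshold_bin)
    state[cluster] = CLUSTER

    return ClusterMask(
        state=state, veg_threshold=thr1, cluster_threshold=thr2, status="ok"
    )
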