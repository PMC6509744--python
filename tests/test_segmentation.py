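"""Histogramming, Otsu thresholding and the two-stage segmentation."""

import numpy as np
import pytest

from vineyield.color_ops import ScalarChannel
from vineyield.segmentation import (
    BACKGROUND,
    CLUSTER,
    EXCLUDED_VEGETATION,
    DegenerateHistogramError,
    Histogram,
    build_histogram,
    otsu_threshold,
    two_stage_segmentation,
)


def brute_force_otsu(counts: np.ndarray) -> int:
    """Exhaustive minimization of the weighted within-class variance."""
    counts = counts.astype(np.float64)
    n = counts.sum()
    bins = np.arange(counts.size, dtype=np.float64)
    best_t, best_within = None, np.inf
    for t in range(counts.size - 1):
        w0 = counts[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * bins[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * bins[t + 1 :]).sum() / w1
        var0 = (counts[: t + 1] * (bins[: t + 1] - mu0) ** 2).sum() / w0
        var1 = (counts[t + 1 :] * (bins[t + 1 :] - mu1) ** 2).sum() / w1
        within = (w0 * var0 + w1 * var1) / n
        if within < best_within - 1e-12:
            best_within, best_t = within, t
    return best_t


def _hist_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return Histogram(counts=counts, vmin=0.0, vmax=256.0, n_pixels=int(counts.sum()))


class TestBuildHistogram:
    def test_two_point_distribution(self):
        vals = np.array([0.0] * 50 + [255.0] * 50).reshape(10, 10)
        h = build_histogram(ScalarChannel(values=vals))
        assert h.counts[0] == 50
        assert h.counts[255] == 50
        assert h.counts.sum() == 100

    def test_exclusion_can_force_degenerate(self):
        vals = np.array([0.0] * 50 + [255.0] * 50).reshape(10, 10)
        h = build_histogram(ScalarChannel(values=vals), exclusion=vals == 255.0)
        assert h.degenerate

    def test_counts_conserve_pixels(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(size=(100, 100))
        h = build_histogram(ScalarChannel(values=vals))
        assert h.counts.sum() == 10_000

    def test_all_excluded_raises(self):
        vals = np.ones((5, 5))
        with pytest.raises(ValueError):
            build_histogram(ScalarChannel(values=vals), exclusion=np.ones((5, 5), bool))


class TestOtsu:
    def test_perfectly_separable_bimodal(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[10] = 400
        counts[200] = 600
        res = otsu_threshold(_hist_from_counts(counts))
        assert 10 <= res.threshold_bin < 200
        assert res.class_fractions == pytest.approx((0.4, 0.6), abs=1e-12)
        assert res.class_fractions[0] + res.class_fractions[1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_search(self, trial):
        rng = np.random.default_rng(1000 + trial)
        counts = rng.integers(0, 16, size=256)
        counts[rng.integers(0, 256, size=8)] += rng.integers(50, 200, size=8)
        res = otsu_threshold(_hist_from_counts(counts))
        assert res.threshold_bin == brute_force_otsu(counts)

    def test_two_population_misclassification_below_1pct(self):
        rng = np.random.default_rng(42)
        lo = rng.normal(60.0, 10.0, size=5000)
        hi = rng.normal(180.0, 10.0, size=5000)
        vals = np.concatenate([lo, hi]).reshape(100, 100)
        labels = np.array([0] * 5000 + [1] * 5000).reshape(100, 100)
        h = build_histogram(ScalarChannel(values=vals))
        res = otsu_threshold(h)
        pred = (h.bin_of(vals) > res.threshold_bin).astype(int)
        assert (pred != labels).mean() < 0.01

    def test_degenerate_histogram_raises(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[7] = 100
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(_hist_from_counts(counts))


def _trimodal_channel(seed=0, n_cluster=1500):
    """Vegetation b*~+30, soil b*~+10, clusters b*~-15."""
    rng = np.random.default_rng(seed)
    n_veg, n_soil = 5000, 3500
    vals = np.concatenate(
        [
            rng.normal(30.0, 1.5, n_veg),
            rng.normal(10.0, 1.5, n_soil),
            rng.normal(-15.0, 1.5, n_cluster),
        ]
    )
    labels = np.concatenate(
        [np.full(n_veg, "veg"), np.full(n_soil, "soil"), np.full(n_cluster, "cluster")]
    )
    side = int(np.sqrt(vals.size))
    order = rng.permutation(vals.size)[: side * side]
    return (
        ScalarChannel(values=vals[order].reshape(side, side)),
        labels[order].reshape(side, side),
    )


class TestTwoStage:
    def test_cluster_population_recovered(self):
        ch, labels = _trimodal_channel(seed=5)
        mask = two_stage_segmentation(ch)
        assert mask.status == "ok"
        cluster_px = labels == "cluster"
        recall = (mask.state[cluster_px] == CLUSTER).mean()
        assert recall >= 0.99

    def test_no_cluster_population_gives_few_false_positives(self):
        ch, labels = _trimodal_channel(seed=6, n_cluster=0)
        mask = two_stage_segmentation(ch)
        assert (mask.state == CLUSTER).mean() < 0.01

    def test_state_partitions_raster(self):
        ch, _ = _trimodal_channel(seed=7)
        mask = two_stage_segmentation(ch)
        counts = mask.counts()
        assert sum(counts.values()) == ch.values.size
        # sequential property: clusters never came from the removed class
        assert not np.any(
            (mask.state == CLUSTER) & (mask.state == EXCLUDED_VEGETATION)
        )

    def test_stage2_histogram_excludes_vegetation(self):
        ch, _ = _trimodal_channel(seed=8)
        mask = two_stage_segmentation(ch)
        n_veg = int((mask.state == EXCLUDED_VEGETATION).sum())
        h2 = build_histogram(ch, exclusion=mask.state == EXCLUDED_VEGETATION)
        assert h2.n_pixels == ch.values.size - n_veg

    def test_deterministic(self):
        ch, _ = _trimodal_channel(seed=9)
        m1 = two_stage_segmentation(ch)
        m2 = two_stage_segmentation(ch)
        assert np.array_equal(m1.state, m2.state)
        assert m1.veg_threshold == m2.veg_threshold

    def test_shift_invariance_of_threshold_value(self):
        ch, _ = _trimodal_channel(seed=10)
        h = build_histogram(ch)
        res = otsu_threshold(h)
        shifted = ScalarChannel(values=ch.values + 100.0)
        h2 = build_histogram(shifted)
        res2 = otsu_threshold(h2)
        assert res2.threshold_value - res.threshold_value == pytest.approx(
            100.0, abs=h.bin_width
        )

    def test_flat_channel_fails_soft(self):
        mask = two_stage_segmentation(ScalarChannel(values=np.full((20, 20), 3.0)))
        assert mask.status == "degenerate-stage1"
        assert (mask.state == CLUSTER).sum() == 0
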