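"""Component labeling, morphometry, retention filters, double-cluster rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vineyield.particles import (
    ParticleSet,
    ScaleCalibration,
    adjust_double_clusters,
    filter_particles,
    label_components,
    measure_particles,
)


def flood_fill_count(binary: np.ndarray, connectivity: int = 8) -> int:
    """Brute-force component count by explicit flood fill."""
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    H, W = binary.shape
    for i in range(H):
        for j in range(W):
            if binary[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and binary[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


class TestLabeling:
    def test_diagonal_touch_is_one_component_under_8conn(self):
        m = np.zeros((8, 8), bool)
        m[0:3, 0:3] = True
        m[3:6, 3:6] = True  # touches only at the (2,2)/(3,3) corner
        _, n8 = label_components(m, connectivity=8)
        _, n4 = label_components(m, connectivity=4)
        assert n8 == 1
        assert n4 == 2

    def test_separated_squares_are_two_components(self):
        m = np.zeros((10, 10), bool)
        m[1:4, 1:4] = True
        m[6:9, 6:9] = True
        _, n = label_components(m)
        assert n == 2

    def test_checkerboard_against_flood_fill_oracle(self):
        m = np.indices((4, 4)).sum(axis=0) % 2 == 0
        _, n = label_components(m, connectivity=8)
        assert n == flood_fill_count(m, 8) == 1

    @given(st.integers(0, 2**31 - 1))
    def test_random_masks_match_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((12, 12)) < 0.4
        for conn in (4, 8):
            _, n = label_components(m, connectivity=conn)
            assert n == flood_fill_count(m, conn)

    def test_empty_mask_zero_components(self):
        _, n = label_components(np.zeros((5, 5), bool))
        assert n == 0

    def test_component_areas_conserve_cluster_pixels(self):
        rng = np.random.default_rng(2)
        m = rng.random((40, 40)) < 0.3
        labeled, _ = label_components(m)
        ps = measure_particles(labeled)
        assert sum(p.area_px for p in ps.particles) == int(m.sum())


class TestMorphometry:
    def test_square_circularity_from_chain_code_perimeter(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        labeled, _ = label_components(m)
        p = measure_particles(labeled).particles[0]
        assert p.perimeter_px == pytest.approx(36.0)
        assert p.circularity == pytest.approx(4 * math.pi * 100 / 36**2, abs=1e-9)

    def test_disc_circularity_near_one(self):
        rr, cc = np.mgrid[0:80, 0:80]
        m = (rr - 40) ** 2 + (cc - 40) ** 2 <= 30**2
        labeled, _ = label_components(m)
        p = measure_particles(labeled).particles[0]
        assert 0.9 <= p.circularity <= 1.0

    def test_calibrated_area_conversion(self, calib):
        m = np.zeros((50, 50), bool)
        m[10:35, 10:50] = True  # 25*40 = 1000 px
        labeled, _ = label_components(m)
        p = measure_particles(labeled, calibration=calib).particles[0]
        assert p.area_px == 1000
        assert p.area_cm2 == pytest.approx(40.0)

    def test_doubling_scale_quarters_area(self):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        labeled, _ = label_components(m)
        a1 = measure_particles(labeled, ScaleCalibration(5.0)).particles[0].area_cm2
        a2 = measure_particles(labeled, ScaleCalibration(10.0)).particles[0].area_cm2
        assert a1 == 4 * a2

    def test_uncalibrated_has_no_cm2_and_refuses_totals(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:8] = True
        labeled, _ = label_components(m)
        ps = measure_particles(labeled)
        assert ps.particles[0].area_cm2 is None
        with pytest.raises(ValueError):
            ps.total_area_cm2()

    def test_scale_from_known_length_line(self):
        cal = ScaleCalibration.from_line(line_length_px=250.0, known_length_cm=50.0)
        assert cal.pixels_per_cm == pytest.approx(5.0)


def _synthetic_set(areas_circ, calib=None):
    """Build a ParticleSet with prescribed (area_px, circularity) pairs."""
    from vineyield.particles import Particle

    particles = [
        Particle(
            id=i + 1,
            area_px=a,
            perimeter_px=math.sqrt(4 * math.pi * a / c),
            circularity=c,
            centroid=(0.0, 0.0),
            bbox=(0, 0, 1, 1),
            area_cm2=(a / calib.pixels_per_cm**2) if calib else None,
        )
        for i, (a, c) in enumerate(areas_circ)
    ]
    return ParticleSet(particles=particles, calibration=calib)


class TestFilter:
    def test_area_floor_is_inclusive(self):
        ps = _synthetic_set([(199, 0.5), (200, 0.5), (201, 0.5)])
        kept = filter_particles(ps)
        assert [p.area_px for p in kept.particles] == [200, 201]

    def test_low_circularity_lines_removed(self):
        ps = _synthetic_set([(500, 0.05), (500, 0.25), (500, 1.0)])
        kept = filter_particles(ps)
        assert [p.circularity for p in kept.particles] == [0.25, 1.0]

    def test_empty_in_empty_out(self):
        assert len(filter_particles(_synthetic_set([]))) == 0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            filter_particles(_synthetic_set([(300, 0.5)]), circularity_range=(0.9, 0.2))

    @given(
        floor1=st.integers(0, 600),
        floor2=st.integers(0, 600),
        seed=st.integers(0, 10_000),
    )
    def test_raising_floor_never_increases_count(self, floor1, floor2, seed):
        rng = np.random.default_rng(seed)
        ps = _synthetic_set(
            [(int(a), float(c)) for a, c in zip(rng.integers(1, 800, 30), rng.uniform(0.01, 1.0, 30))]
        )
        lo, hi = sorted((floor1, floor2))
        assert len(filter_particles(ps, min_area_px=hi)) <= len(
            filter_particles(ps, min_area_px=lo)
        )


class TestDoubleClusterAdjustment:
    def test_hand_computed_example(self, calib):
        # areas 10,12,11,25 cm^2: median 11.5, 1.5x -> 17.25, only 25 exceeds
        areas_px = [int(a * calib.pixels_per_cm**2) for a in (10, 12, 11, 25)]
        ps = _synthetic_set([(a, 0.8) for a in areas_px], calib=calib)
        adj = adjust_double_clusters(ps, split_factor=1.5)
        assert adj.adjusted_count == 5
        assert sorted(p.counts_as for p in adj.particles) == [1, 1, 1, 2]

    def test_equal_areas_never_adjusted(self, calib):
        ps = _synthetic_set([(500, 0.8)] * 6, calib=calib)
        assert adjust_double_clusters(ps, split_factor=1.01).adjusted_count == 6

    def test_single_particle_counts_once(self, calib):
        ps = _synthetic_set([(900, 0.8)], calib=calib)
        assert adjust_double_clusters(ps).adjusted_count == 1

    def test_empty_set_adjusts_to_zero(self):
        assert adjust_double_clusters(_synthetic_set([])).adjusted_count == 0

    def test_adjustment_equals_raw_plus_oversized(self, calib):
        rng = np.random.default_rng(8)
        areas = rng.integers(200, 2000, 25)
        ps = _synthetic_set([(int(a), 0.7) for a in areas], calib=calib)
        adj = adjust_double_clusters(ps, split_factor=1.5)
        cutoff = 1.5 * np.median([p.area_cm2 for p in ps.particles])
        oversized = sum(p.area_cm2 > cutoff for p in ps.particles)
        assert adj.adjusted_count - ps.raw_count == oversized
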