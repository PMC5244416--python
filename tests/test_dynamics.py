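import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgedyn.dynamics import (
    MembraneEvent,
    VelocityHeatmap,
    build_velocity_heatmap,
    extract_events,
    summarize_events,
)
from edgedyn.segmentation import SectorDisplacement


def make_disp(d, normals, valid=None):
    n = d.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return SectorDisplacement(d_um=d, normals=normals, valid=valid)


def heatmap_of(matrix, interval=5.0):
    """Wrap a pre-normalized matrix as a VelocityHeatmap for event tests."""
    m = np.asarray(matrix, dtype=float)
    return VelocityHeatmap(
        raw=m, normalized=m, missing=np.zeros_like(m, dtype=bool),
        frame_interval_s=interval, norm_constant=1.0,
    )


def region_angle_oracle(rows, cols):
    """Independent moment computation for planted regions (no wraparound)."""
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    return abs(math.degrees(0.5 * math.atan2(2 * mu11, mu20 - mu02)))


class TestBuildVelocityHeatmap:
    def test_static_boundary_all_zero(self):
        normals = np.tile([1.0, 0.0], (8, 1))
        disps = [make_disp(np.zeros((8, 2)), normals) for _ in range(5)]
        hm = build_velocity_heatmap(disps, 5.0)
        assert np.all(hm.raw == 0)
        assert np.all(hm.normalized == 0)

    def test_uniform_maximal_step_normalizes_to_one(self):
        normals = np.tile([0.0, 1.0], (6, 1))
        d = normals * 0.7
        disps = [make_disp(d.copy(), normals) for _ in range(4)]
        hm = build_velocity_heatmap(disps, 5.0)
        assert np.allclose(hm.raw, 0.7)
        assert np.allclose(hm.normalized, 1.0)

    def test_normalization_is_odd(self):
        rng = np.random.default_rng(0)
        normals = np.tile([1.0, 0.0], (5, 1))
        disps_pos = [make_disp(normals * rng.normal(0, 1, (5, 1)), normals)
                     for _ in range(3)]
        disps_neg = [make_disp(-d.d_um, d.normals) for d in disps_pos]
        hp = build_velocity_heatmap(disps_pos, 5.0)
        hn = build_velocity_heatmap(disps_neg, 5.0)
        assert np.allclose(hp.normalized, -hn.normalized)

    def test_missing_sectors_masked(self):
        normals = np.tile([1.0, 0.0], (4, 1))
        valid = np.array([True, False, True, True])
        disps = [make_disp(normals * 0.5, normals, valid.copy()) for _ in range(3)]
        hm = build_velocity_heatmap(disps, 5.0)
        assert hm.missing[1].all()
        assert np.isnan(hm.raw[1]).all()

    def test_all_missing_column_errors(self):
        normals = np.tile([1.0, 0.0], (4, 1))
        disps = [make_disp(np.zeros((4, 2)), normals, np.zeros(4, dtype=bool))]
        with pytest.raises(ValueError, match="missing"):
            build_velocity_heatmap(disps, 5.0)

    def test_norm_constant_override(self):
        normals = np.tile([1.0, 0.0], (4, 1))
        disps = [make_disp(normals * 0.5, normals)]
        hm = build_velocity_heatmap(disps, 5.0, norm_constant=1.0)
        assert np.allclose(hm.normalized, 0.5)


class TestExtractEvents:
    def test_rectangular_block(self):
        m = np.zeros((12, 20))
        m[3:7, 10:14] = 1.0
        events = extract_events(heatmap_of(m), 0.3, 6)
        assert len(events) == 1
        e = events[0]
        assert e.polarity == "protrusion"
        assert e.duration_s == 20.0
        assert e.angle_deg == 0.0
        assert e.area == 16

    def test_diagonal_streak_is_45_degrees(self):
        m = np.zeros((16, 16))
        rows = np.arange(3, 11)
        cols = np.arange(3, 11)
        m[rows, cols] = 1.0
        events = extract_events(heatmap_of(m), 0.3, 6)
        assert len(events) == 1
        oracle = region_angle_oracle(rows.astype(float), cols.astype(float))
        assert events[0].angle_deg == pytest.approx(oracle, abs=1e-9)
        assert events[0].angle_deg == pytest.approx(45.0, abs=1e-9)
        assert events[0].is_traveling_wave

    def test_wraparound_merges_across_seam(self):
        m = np.zeros((10, 15))
        m[0, 4:10] = 1.0
        m[9, 4:10] = 1.0
        events = extract_events(heatmap_of(m), 0.3, 6)
        assert len(events) == 1
        assert events[0].area == 12

    def test_wraparound_angle_unwrapped(self):
        # 4 rows x 3 cols across the seam: major axis along the sector axis
        m = np.zeros((10, 15))
        m[0:2, 4:7] = 1.0
        m[8:10, 4:7] = 1.0
        (e,) = extract_events(heatmap_of(m), 0.3, 6)
        assert e.angle_deg == pytest.approx(90.0, abs=1e-9)

    def test_retraction_polarity(self):
        m = np.zeros((10, 12))
        m[2:5, 3:8] = -1.0
        (e,) = extract_events(heatmap_of(m), 0.3, 6)
        assert e.polarity == "retraction"

    def test_min_area_filter(self):
        m = np.zeros((10, 12))
        m[4, 5:8] = 1.0  # area 3 < 6
        assert extract_events(heatmap_of(m), 0.3, 6) == []

    def test_angle_exactly_ten_is_not_wave(self):
        e = MembraneEvent("protrusion", np.zeros((1, 2), int), 6, 30.0, 10.0,
                         (0, 5), (0, 0), 1.0)
        assert not e.is_traveling_wave
        e2 = MembraneEvent("protrusion", np.zeros((1, 2), int), 6, 30.0, 10.01,
                          (0, 5), (0, 0), 1.0)
        assert e2.is_traveling_wave

    def test_sign_symmetry(self):
        rng = np.random.default_rng(5)
        m = np.zeros((14, 25))
        m[2:6, 3:10] = 1.0
        m[8:12, 14:22] = -1.0
        ev_pos = extract_events(heatmap_of(m), 0.3, 6)
        ev_neg = extract_events(heatmap_of(-m), 0.3, 6)
        assert sorted(e.polarity for e in ev_pos) == ["protrusion", "retraction"]
        key = lambda e: e.frame_range
        for a, b in zip(sorted(ev_pos, key=key), sorted(ev_neg, key=key)):
            assert a.polarity != b.polarity
            assert a.duration_s == b.duration_s
            assert a.angle_deg == b.angle_deg

    def test_nonfinite_outside_mask_errors(self):
        m = np.zeros((8, 10))
        m[3, 4] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            extract_events(heatmap_of(m), 0.3, 6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, seed):
        # premise: isolated unimodal events (a raw noise field can split one
        # component into two as the threshold rises, which is not an event
        # field); blobs confined to disjoint tiles have nested level sets
        rng = np.random.default_rng(seed)
        m = np.zeros((12, 24))
        for ti in range(2):
            for tj in range(3):
                amp = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
                r0, c0 = 6 * ti, 8 * tj
                rr, cc = np.mgrid[0:6, 0:8]
                blob = amp * np.exp(
                    -((rr - rng.uniform(2, 4)) ** 2 + (cc - rng.uniform(3, 5)) ** 2)
                    / rng.uniform(1.5, 4.0)
                )
                blob[0, :] = blob[-1, :] = blob[:, 0] = blob[:, -1] = 0.0
                m[r0:r0 + 6, c0:c0 + 8] = blob
        counts = [len(extract_events(heatmap_of(m), thr, 2))
                  for thr in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPixelPathRecovery:
    """Planted-event recovery through the full rasterized pixel pipeline."""

    def test_single_pulse_movie(self, pulse_movie):
        from edgedyn.config import PipelineConfig
        from edgedyn.pipeline import analyze_movie

        cfg, movie, gt = pulse_movie
        res = analyze_movie(movie, PipelineConfig(pixel_size_um=cfg.pixel_size_um))
        events = res.membrane_events
        assert len(events) == 1
        (e,) = events
        pulse = cfg.boundary_kinematics[0]
        planted_duration = (pulse.end_frame - pulse.start_frame) * cfg.frame_interval_s
        assert e.polarity == "protrusion"
        assert abs(e.duration_s - planted_duration) <= cfg.frame_interval_s
        assert abs(e.angle_deg - pulse.planted_angle_deg) <= 5.0
        assert not e.is_traveling_wave

    def test_drifting_pulse_movie(self):
        from edgedyn.config import KinematicPulse, PipelineConfig, SimConfig
        from edgedyn.pipeline import analyze_movie
        from edgedyn.synthetic import generate_cell_movie

        cfg = SimConfig(
            n_frames=12,
            image_shape=(400, 400),
            seed=13,
            cell_radius_um=20.0,
            boundary_kinematics=[
                KinematicPulse("protrusion", 1, 8, 40.0, 24.0, 0.2,
                               drift_sectors_per_frame=1.0)
            ],
        )
        movie, _ = generate_cell_movie(cfg)
        res = analyze_movie(movie, PipelineConfig(pixel_size_um=cfg.pixel_size_um))
        assert len(res.membrane_events) == 1
        (e,) = res.membrane_events
        assert e.polarity == "protrusion"
        assert abs(e.angle_deg - 45.0) <= 5.0
        assert e.is_traveling_wave


class TestSummarizeEvents:
    def _event(self, duration_s=10.0, angle=0.0):
        return MembraneEvent("protrusion", np.zeros((1, 2), int), 6, duration_s,
                            angle, (0, 1), (0, 0), 1.0)

    def test_events_per_minute(self):
        events = [self._event() for _ in range(3)]
        s = summarize_events(events, 300.0)
        assert s.events_per_minute == pytest.approx(0.6)

    def test_percent_traveling_waves(self):
        events = [self._event(angle=a) for a in (5.0, 15.0, 25.0)]
        s = summarize_events(events, 300.0)
        assert s.percent_traveling_waves == pytest.approx(100 * 2 / 3)

    def test_empty_flagged_not_zeroed(self):
        s = summarize_events([], 300.0)
        assert s.count == 0
        assert not s.defined
        assert math.isnan(s.mean_duration_s)
        assert math.isnan(s.mean_angle_deg)
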