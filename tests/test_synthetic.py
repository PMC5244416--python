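import math

import numpy as np
import pytest

from edgedyn.config import AdhesionSpec, KinematicPulse, SimConfig
from edgedyn.dynamics import build_velocity_heatmap
from edgedyn.motility import Track, meandering_index
from edgedyn.segmentation import boundary_from_polyline, discretize_sectors, track_sectors
from edgedyn.synthetic import (
    SimulationError,
    generate_adhesion_frame,
    generate_cell_movie,
    generate_tracks,
    generate_wound_series,
    ground_truth_velocity_heatmap,
    random_event_config,
)


def band_pixel_pairs(movie, gt, frame):
    """Pixel pairs of the planted 2 um edge band, from ground-truth geometry."""
    h, w = movie.data.shape[2:]
    px = movie.pixel_size_um
    cx, cy = gt.centroid_um
    y, x = np.mgrid[0:h, 0:w]
    rho = np.hypot(x * px - cx, y * px - cy)
    theta = np.arctan2(y * px - cy, x * px - cx) % (2 * math.pi)
    r = np.interp(theta, gt.thetas, gt.radii_um[frame], period=2 * math.pi)
    band = (rho <= r) & (rho >= r - 2.0)
    return movie.data[frame, 0][band], movie.data[frame, 1][band]


class TestCellMovie:
    def test_static_cell_all_frames_identical(self):
        cfg = SimConfig(n_frames=5, image_shape=(128, 128), noise_sd=0.0, seed=3,
                        cell_radius_um=10.0)
        movie, gt = generate_cell_movie(cfg)
        for f in range(1, 5):
            assert np.array_equal(movie.data[f], movie.data[0])
        assert np.all(gt.sector_velocity_um_per_frame == 0)

    def test_single_pulse_ground_truth_event(self):
        cfg = SimConfig(
            n_frames=10,
            image_shape=(256, 256),
            boundary_kinematics=[KinematicPulse("protrusion", 2, 8, 30.0, 15.0, 0.1)],
        )
        _, gt = generate_cell_movie(cfg)
        row = gt.events.iloc[0]
        assert row["angle_deg"] == 0.0
        assert row["duration_s"] == (8 - 2) * cfg.frame_interval_s
        assert row["kind"] == "protrusion"

    def test_band_correlation_matches_target(self):
        # oracle: direct Pearson correlation of the generated band pixel pairs
        cfg = SimConfig(n_frames=3, image_shape=(300, 300), coloc_rho=0.8, seed=1)
        movie, gt = generate_cell_movie(cfg)
        g, r = band_pixel_pairs(movie, gt, 0)
        assert g.size >= 500
        assert abs(np.corrcoef(g, r)[0, 1] - 0.8) < 0.05

    def test_negative_correlation(self):
        cfg = SimConfig(n_frames=2, image_shape=(256, 256), coloc_rho=-0.7, seed=9)
        movie, gt = generate_cell_movie(cfg)
        g, r = band_pixel_pairs(movie, gt, 0)
        assert abs(np.corrcoef(g, r)[0, 1] - (-0.7)) < 0.05

    def test_determinism(self):
        cfg = SimConfig(n_frames=4, image_shape=(128, 128), coloc_rho=0.5,
                        noise_sd=4.0, seed=11, cell_radius_um=10.0)
        m1, g1 = generate_cell_movie(cfg)
        m2, g2 = generate_cell_movie(cfg)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(g1.radii_um, g2.radii_um)
        assert g1.events.equals(g2.events)

    def test_noise_does_not_change_ground_truth(self):
        base = dict(n_frames=4, image_shape=(256, 256), seed=2, coloc_rho=0.4,
                    boundary_kinematics=[KinematicPulse("protrusion", 1, 3, 20.0, 12.0, 0.08)])
        _, g1 = generate_cell_movie(SimConfig(noise_sd=3.0, **base))
        _, g2 = generate_cell_movie(SimConfig(noise_sd=6.0, **base))
        assert np.array_equal(g1.sector_velocity_um_per_frame, g2.sector_velocity_um_per_frame)
        assert np.array_equal(g1.radii_um, g2.radii_um)
        assert np.array_equal(g1.region_rho, g2.region_rho)

    def test_geometry_rejection(self):
        cfg = SimConfig(
            n_frames=30,
            image_shape=(128, 128),
            cell_radius_um=10.0,
            boundary_kinematics=[KinematicPulse("retraction", 1, 29, 15.0, 30.0, 0.5)],
        )
        with pytest.raises(SimulationError):
            generate_cell_movie(cfg)

    def test_self_consistency_velocity_recovery(self):
        """Tracking the planted boundary polylines recovers planted speeds."""
        cfg = SimConfig(
            n_frames=10,
            image_shape=(360, 360),
            boundary_kinematics=[KinematicPulse("protrusion", 1, 8, 35.0, 26.0, 0.1)],
        )
        _, gt = generate_cell_movie(cfg)
        boundaries = []
        for f in range(cfg.n_frames):
            b = boundary_from_polyline(gt.boundary_xy_um(f), cfg.pixel_size_um, f)
            discretize_sectors(b, 10.0, n_sectors=gt.n_sectors)
            boundaries.append(b)
        disps = [track_sectors(boundaries[f], boundaries[f + 1])
                 for f in range(cfg.n_frames - 1)]
        hm = build_velocity_heatmap(disps, cfg.frame_interval_s)
        planted = gt.sector_velocity_um_per_frame
        step = 0.1 * cfg.frame_interval_s
        plateau = np.isclose(planted, step, rtol=1e-6)
        assert plateau.any()
        err = np.abs(hm.raw[plateau] - step) / step
        assert err.max() < 0.10


class TestAdhesionFrame:
    def test_circular_site_ground_truth(self):
        cfg = SimConfig(
            image_shape=(300, 300),
            adhesion_sites=[AdhesionSpec(center_um=(30.0, 18.0), semi_axes_um=(1.0, 1.0))],
        )
        _, gt = generate_adhesion_frame(cfg)
        row = gt.adhesion_sites.iloc[0]
        assert row["distance_to_membrane_um"] == pytest.approx(3.0, abs=0.01)
        assert row["area_um2"] == pytest.approx(math.pi, rel=0.05)
        assert row["major_axis_um"] == pytest.approx(2.0, rel=0.05)

    def test_overlapping_sites_merge(self):
        cfg = SimConfig(
            image_shape=(300, 300),
            adhesion_sites=[
                AdhesionSpec(center_um=(30.0, 25.0), semi_axes_um=(1.0, 1.0)),
                AdhesionSpec(center_um=(31.0, 25.0), semi_axes_um=(1.0, 1.0)),
            ],
        )
        _, gt = generate_adhesion_frame(cfg)
        assert len(gt.adhesion_sites) == 1
        # union area below the sum of the two circle areas but above one
        area = gt.adhesion_sites.iloc[0]["area_um2"]
        assert math.pi < area < 2 * math.pi

    def test_determinism(self):
        sites = [AdhesionSpec(center_um=(15.0 + 4 * i, 25.0), semi_axes_um=(0.8, 0.5))
                 for i in range(10)]
        cfg = SimConfig(image_shape=(300, 300), adhesion_sites=sites, noise_sd=5.0, seed=6)
        f1, g1 = generate_adhesion_frame(cfg)
        f2, g2 = generate_adhesion_frame(cfg)
        assert np.array_equal(f1.data, f2.data)
        assert g1.adhesion_sites.equals(g2.adhesion_sites)

    def test_site_outside_mask_rejected(self):
        cfg = SimConfig(
            image_shape=(300, 300),
            adhesion_sites=[AdhesionSpec(center_um=(30.0, 5.0), semi_axes_um=(1.0, 1.0))],
        )
        with pytest.raises(SimulationError, match="outside"):
            generate_adhesion_frame(cfg)

    def test_empty_sites_rejected(self):
        with pytest.raises(SimulationError):
            generate_adhesion_frame(SimConfig())


class TestTracks:
    def test_full_persistence_is_straight(self):
        pos, gt = generate_tracks(SimConfig(n_frames=20, track_persistence=1.0, seed=4), 3)
        assert np.allclose(gt.track_table["meandering_index"], 1.0, atol=1e-9)

    def test_out_and_back_is_zero(self):
        track = Track(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 0.0]]), 5.0)
        assert meandering_index(track) == 0.0

    def test_ground_truth_matches_direct_recomputation(self):
        # oracle: displacement / summed step lengths on the stored positions
        pos, gt = generate_tracks(SimConfig(n_frames=101, track_persistence=0.5, seed=7), 5)
        for i in range(5):
            steps = np.linalg.norm(np.diff(pos[i], axis=0), axis=1).sum()
            disp = np.linalg.norm(pos[i, -1] - pos[i, 0])
            assert gt.track_table["meandering_index"][i] == pytest.approx(disp / steps, abs=1e-12)

    def test_determinism(self):
        cfg = SimConfig(n_frames=50, track_persistence=0.3, seed=12)
        p1, _ = generate_tracks(cfg, 4)
        p2, _ = generate_tracks(cfg, 4)
        assert np.array_equal(p1, p2)


class TestWoundSeries:
    def test_zero_rate_constant_area(self):
        masks, gt = generate_wound_series(
            SimConfig(n_frames=5, frame_interval_s=3600.0, image_shape=(100, 100),
                      wound_closure_rate=0.0)
        )
        assert np.all(gt.wound_area_um2 == gt.wound_area_um2[0])

    def test_full_closure_from_frame_k(self):
        # rate 0.5/h with 1 h frames: closed from frame 2 onward
        masks, gt = generate_wound_series(
            SimConfig(n_frames=5, frame_interval_s=3600.0, image_shape=(100, 100),
                      wound_closure_rate=0.5)
        )
        assert gt.wound_area_um2[2] == 0
        assert np.all(gt.wound_area_um2[2:] == 0)
        assert np.all(gt.wound_area_um2[:2] > 0)

    def test_areas_match_pixel_counts(self):
        # oracle: count cell-free pixels in the rendered masks
        cfg = SimConfig(n_frames=6, frame_interval_s=1800.0, image_shape=(120, 150),
                        wound_closure_rate=0.37, seed=5)
        masks, gt = generate_wound_series(cfg)
        for f in range(6):
            assert gt.wound_area_um2[f] == (~masks[f]).sum() * cfg.pixel_size_um**2


class TestRandomEventConfig:
    def test_all_seeds_have_pulses(self):
        for seed in range(20):
            cfg = random_event_config(seed)
            assert cfg.boundary_kinematics

    def test_ground_truth_heatmap_matches_movie_ground_truth(self):
        cfg = random_event_config(3)
        _, gt = generate_cell_movie(cfg)
        hm = ground_truth_velocity_heatmap(cfg)
        assert np.allclose(hm.raw, gt.sector_velocity_um_per_frame)
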