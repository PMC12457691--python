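"""Generators: ground-truth structure, closed-form moments, determinism."""

import numpy as np
import pandas as pd
import pytest

import rodtrack as rt
from rodtrack.errors import ConfigError


class TestTrajectories:
    def test_degenerate_no_motion_gives_constant_positions(self):
        cfg = rt.TrajectorySimConfig(
            n_traj=5, frac_directed=0.5, d_slow=0.0, d_fast=0.0, speed=0.0,
            loc_noise_sd=0.0, n_frames=8, seed=3,
        )
        tracks, _ = rt.simulate_trajectories(cfg)
        for _, grp in tracks.groupby("traj_id"):
            assert grp["x_um"].nunique() == 1 and grp["y_um"].nunique() == 1

    def test_single_frame_squared_displacement_matches_4_d_dt(self):
        # E[r^2] = 4 D dt for 2-D Brownian motion
        cfg = rt.TrajectorySimConfig(
            n_traj=1000, frac_directed=0.0, frac_slow=1.0, d_slow=0.0024,
            d_fast=0.0147, t_lag=0.1, loc_noise_sd=0.0, n_frames=30, seed=7,
        )
        tracks, _ = rt.simulate_trajectories(cfg)
        r2 = []
        for _, grp in tracks.groupby("traj_id"):
            xy = grp[["x_um", "y_um"]].to_numpy()
            d = np.diff(xy, axis=0)
            r2.append(np.sum(d * d, axis=1))
        r2 = np.concatenate(r2)
        expected = 4 * 0.0024 * 0.1
        se = r2.std() / np.sqrt(len(r2))
        assert abs(r2.mean() - expected) < 3 * se

    def test_seed_determinism_byte_identical(self):
        cfg = rt.TrajectorySimConfig(n_traj=40, seed=9)
        a, _ = rt.simulate_trajectories(cfg)
        b, _ = rt.simulate_trajectories(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_directed_zero_noise_displacement_exactly_linear(self):
        cfg = rt.TrajectorySimConfig(
            n_traj=10, frac_directed=1.0, speed=0.0565, t_lag=1.0,
            loc_noise_sd=0.0, n_frames=20, seed=2,
        )
        tracks, _ = rt.simulate_trajectories(cfg)
        for _, grp in tracks.groupby("traj_id"):
            xy = grp[["x_um", "y_um"]].to_numpy()
            for n in (1, 3, 7):
                d = np.linalg.norm(xy[n:] - xy[:-n], axis=1)
                assert np.allclose(d, 0.0565 * n, atol=1e-12)

    def test_class_proportions_within_binomial_error(self):
        cfg = rt.TrajectorySimConfig(n_traj=4000, frac_directed=0.12, seed=21)
        _, truth = rt.simulate_trajectories(cfg)
        frac = (truth.per_trajectory["true_class"] == "directed").mean()
        se = np.sqrt(0.12 * 0.88 / 4000)
        assert abs(frac - 0.12) < 4 * se

    def test_pure_brownian_msd_matches_theory_at_small_lags(self):
        cfg = rt.TrajectorySimConfig(
            n_traj=500, frac_directed=0.0, frac_slow=1.0, d_slow=0.01,
            d_fast=0.01, t_lag=1.0, loc_noise_sd=0.0, n_frames=20, seed=13,
        )
        tracks, _ = rt.simulate_trajectories(cfg)
        for lag in range(1, 6):
            sq = []
            for _, grp in tracks.groupby("traj_id"):
                xy = grp[["x_um", "y_um"]].to_numpy()
                d = xy[lag:] - xy[:-lag]
                sq.append(np.sum(d * d, axis=1))
            sq = np.concatenate(sq)
            # correlated overlapping pairs: conservative SE via per-track means
            expected = 4 * 0.01 * lag
            se = sq.std() / np.sqrt(500)
            assert abs(sq.mean() - expected) < 3 * se

    def test_geometric_lengths_truncated_and_filterable(self):
        cfg = rt.TrajectorySimConfig(
            n_traj=300, n_frames=40, length_dist="geometric", mean_frames=12, seed=5
        )
        tracks, truth = rt.simulate_trajectories(cfg)
        lengths = truth.per_trajectory["n_frames"]
        assert lengths.min() >= 2 and lengths.max() <= 40
        kept, counts = rt.filter_tracks(tracks, min_frames=10)
        assert 0 < counts["n_kept"] < 300
        assert counts["n_kept"] + counts["n_dropped_short"] == counts["n_input"]

    @pytest.mark.parametrize(
        "field,value",
        [
            ("frac_directed", 1.5),
            ("frac_slow", -0.1),
            ("n_frames", 1),
            ("t_lag", 0.0),
            ("loc_noise_sd", -1.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = rt.TrajectorySimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            rt.simulate_trajectories(cfg)

    def test_d_slow_above_d_fast_rejected(self):
        cfg = rt.TrajectorySimConfig(d_slow=0.02, d_fast=0.01)
        with pytest.raises(ConfigError, match="d_slow"):
            rt.simulate_trajectories(cfg)


class TestMovies:
    def _quiet_cfg(self, **kw):
        fp = rt.stadium_footprint((3.0, 1.5), 4.0, 1.0)
        tcfg = rt.TrajectorySimConfig(
            n_traj=kw.pop("n_traj", 1), frac_directed=0.0, d_slow=0.0, d_fast=0.0,
            speed=0.0, loc_noise_sd=0.0, t_lag=0.1, n_frames=2, seed=1,
        )
        base = dict(
            frame_shape=(32, 64), pixel_size=0.1, n_frames=5, cell_footprints=[fp],
            psf_sigma=0.12, spot_amplitude=1000.0, background=50.0,
            poisson_gain=0.0, gaussian_sd=0.0, trajectory_config=tcfg, seed=4,
        )
        base.update(kw)
        return rt.MovieSimConfig(**base)

    def test_zero_foci_zero_noise_is_flat_background(self):
        tcfg = rt.TrajectorySimConfig(
            n_traj=1, frac_directed=0.0, d_slow=0.0, d_fast=0.0, speed=0.0,
            loc_noise_sd=0.0, t_lag=0.1, n_frames=2, seed=1,
        )
        cfg = self._quiet_cfg(spot_amplitude=0.0, trajectory_config=tcfg)
        stack, _ = rt.simulate_movie(cfg)
        assert np.allclose(stack.pixels, 50.0)

    def test_stationary_focus_argmax_at_true_pixel(self):
        cfg = self._quiet_cfg()
        stack, gt = rt.simulate_movie(cfg)
        x, y = gt.detections.iloc[0][["x_um", "y_um"]]
        for f in range(stack.n_frames):
            r, c = np.unravel_index(np.argmax(stack.pixels[f]), stack.frame_shape)
            assert abs(c * 0.1 - x) <= 0.05 + 1e-9
            assert abs(r * 0.1 - y) <= 0.05 + 1e-9

    def test_integrated_intensity_equals_amplitude(self):
        cfg = self._quiet_cfg()
        stack, _ = rt.simulate_movie(cfg)
        above = stack.pixels[0] - 50.0
        assert abs(above.sum() - 1000.0) < 1.0  # < 0.1% flux loss in the window

    def test_footprint_outside_frame_rejected(self):
        fp = rt.stadium_footprint((10.0, 1.5), 8.0, 1.0)
        cfg = self._quiet_cfg()
        cfg.cell_footprints = [fp]
        with pytest.raises(ConfigError, match="footprint"):
            rt.simulate_movie(cfg)

    def test_ground_truth_links_every_rendered_focus(self):
        cfg = self._quiet_cfg(n_traj=3)
        cfg.trajectory_config.n_traj = 3
        stack, gt = rt.simulate_movie(cfg)
        assert set(gt.detections["traj_id"]) == set(gt.per_trajectory["traj_id"])
        assert gt.detections.groupby("frame").size().max() <= 3


class TestContours:
    def test_stadium_max_chord_equals_length(self, stadium):
        poly, _ = stadium
        xy = np.asarray(poly.exterior.coords)
        from scipy.spatial.distance import pdist

        assert abs(pdist(xy).max() - 4.0) < 1e-3

    def test_bent_area_matches_closed_form(self):
        # offset band of an arc keeps area (shaft length)*(width); caps add a disc
        cfg = rt.ContourSimConfig(length=4.0, width=0.8, curvature=0.2)
        poly, _ = rt.simulate_bent_rod_contour(cfg)
        expected = (4.0 - 0.8) * 0.8 + np.pi * 0.4**2
        assert abs(poly.area - expected) / expected < 0.01

    def test_mirrored_curvature_is_reflection(self):
        a, _ = rt.simulate_bent_rod_contour(rt.ContourSimConfig(curvature=0.2))
        b, _ = rt.simulate_bent_rod_contour(rt.ContourSimConfig(curvature=-0.2))
        import shapely.affinity

        b_ref = shapely.affinity.scale(b, xfact=1, yfact=-1, origin=(0, 0))
        assert a.symmetric_difference(b_ref).area < 1e-6 * a.area

    def test_excessive_curvature_rejected(self):
        with pytest.raises(ConfigError, match="curvature"):
            rt.simulate_bent_rod_contour(rt.ContourSimConfig(length=8.0, width=0.8, curvature=1.2))

    def test_polygon_simple_with_width_noise(self):
        poly, _ = rt.simulate_bent_rod_contour(
            rt.ContourSimConfig(curvature=0.1, width_noise_sd=0.05, seed=8)
        )
        assert poly.is_valid and poly.is_simple
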