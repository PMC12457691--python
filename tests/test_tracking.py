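"""Spot detection, LAP linking against a brute-force oracle, track filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

import rodtrack as rt
from rodtrack.errors import ConfigError
from rodtrack.imaging import ImageStack
from rodtrack.synthetic import _render_spots
from rodtrack.tracking import _assign_frame_pair, detect_spots, filter_tracks, link_detections


def brute_force_links(prev_xy, curr_xy, max_dist):
    """Enumerate all partial matchings; minimize total squared displacement
    plus max_dist² per unmatched endpoint-pair event (same objective as the
    LAP formulation)."""
    n1, n2 = len(prev_xy), len(curr_xy)
    cap = max_dist**2
    best_cost, best = np.inf, []
    idx2 = list(range(n2))
    for k in range(0, min(n1, n2) + 1):
        for rows in itertools.combinations(range(n1), k):
            for cols in itertools.permutations(idx2, k):
                pairs = list(zip(rows, cols))
                d2 = [np.sum((prev_xy[r] - curr_xy[c]) ** 2) for r, c in pairs]
                if any(d > cap for d in d2):
                    continue
                cost = sum(d2) + cap * ((n1 - k) + (n2 - k))
                if cost < best_cost - 1e-12:
                    best_cost, best = cost, sorted(pairs)
    return best


def spot_stack(per_frame_positions, shape=(24, 48), px=0.1, amp=2000.0):
    """Noise-free stack with given per-frame spot positions (µm)."""
    pixels = np.zeros((len(per_frame_positions), *shape))
    for k, pos in enumerate(per_frame_positions):
        if len(pos):
            pos = np.asarray(pos, dtype=float)
            _render_spots(pixels[k], pos[:, 0] / px, pos[:, 1] / px, 1.2, amp)
    return ImageStack(pixels, pixel_size=px, t_lag=1.0)


class TestDetect:
    def test_blank_frames_give_zero_detections(self):
        stack = spot_stack([[], []])
        dets = detect_spots(stack, 0.25, threshold=10.0)
        assert len(dets) == 0

    def test_single_spot_localized_within_half_pixel(self):
        truth = (2.13, 1.27)
        stack = spot_stack([[truth]])
        dets = detect_spots(stack, 0.25, threshold=10.0)
        assert len(dets) == 1
        assert abs(dets.iloc[0]["x_um"] - truth[0]) < 0.05
        assert abs(dets.iloc[0]["y_um"] - truth[1]) < 0.05

    def test_two_well_separated_spots_detected(self):
        stack = spot_stack([[(1.0, 1.0), (2.25, 1.0)]])  # 5 x radius apart
        dets = detect_spots(stack, 0.25, threshold=10.0)
        assert len(dets) == 2

    def test_radius_below_pixel_rejected(self):
        stack = spot_stack([[(1.0, 1.0)]])
        with pytest.raises(ConfigError, match="radius"):
            detect_spots(stack, radius_um=0.05)

    def test_threshold_suppresses_detection(self):
        stack = spot_stack([[(1.0, 1.0)]])
        assert len(detect_spots(stack, 0.25, threshold=1e9)) == 0


def dets_frame(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


class TestLink:
    def test_single_particle_spans_all_frames(self):
        rows = [(f, 0.1 * f, 0.0) for f in range(6)]
        tracks = link_detections(dets_frame(rows), max_dist_um=0.4)
        assert tracks["traj_id"].nunique() == 1
        assert list(tracks["frame"]) == list(range(6))

    def test_jump_beyond_max_dist_splits_track(self):
        rows = [(0, 0.0, 0.0), (1, 0.5, 0.0)]
        tracks = link_detections(dets_frame(rows), max_dist_um=0.4)
        assert tracks["traj_id"].nunique() == 2

    def test_jump_at_max_dist_links(self):
        rows = [(0, 0.0, 0.0), (1, 0.39, 0.0)]
        tracks = link_detections(dets_frame(rows), max_dist_um=0.4)
        assert tracks["traj_id"].nunique() == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_frame_pair_assignment_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 5, size=2)
        prev_xy = rng.uniform(0, 1.2, size=(n1, 2))
        curr_xy = rng.uniform(0, 1.2, size=(n2, 2))
        got = sorted(_assign_frame_pair(prev_xy, curr_xy, 0.4))
        assert got == brute_force_links(prev_xy, curr_xy, 0.4)

    def test_crossing_particles_three_frame_toy(self):
        # two particles approach and cross; optimal matching keeps each on
        # its smooth course rather than swapping
        rows = [
            (0, 0.0, 0.00), (0, 0.6, 0.00),
            (1, 0.3, 0.05), (1, 0.3, -0.05),
            (2, 0.6, 0.10), (2, 0.0, -0.10),
        ]
        tracks = link_detections(dets_frame(rows), max_dist_um=0.4)
        assert tracks["traj_id"].nunique() == 2
        for _, grp in tracks.groupby("traj_id"):
            assert len(grp) == 3
            # each track's per-frame displacement stays admissible and smooth
            xy = grp.sort_values("frame")[["x_um", "y_um"]].to_numpy()
            steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
            assert (steps <= 0.4 + 1e-9).all()

    def test_permutation_invariance_of_input_order(self):
        rng = np.random.default_rng(5)
        rows = [(f, x, y) for f in range(4) for x, y in rng.uniform(0, 2, size=(3, 2))]
        base = link_detections(dets_frame(rows), 0.8)
        shuf = link_detections(dets_frame(rows).sample(frac=1, random_state=1), 0.8)
        a = set(map(tuple, base.groupby("traj_id")[["frame", "x_um"]].apply(lambda g: tuple(map(tuple, g.to_numpy())))))
        b = set(map(tuple, shuf.groupby("traj_id")[["frame", "x_um"]].apply(lambda g: tuple(map(tuple, g.to_numpy())))))
        assert a == b

    def test_empty_input_gives_empty_output(self):
        out = link_detections(pd.DataFrame(columns=["frame", "x_um", "y_um"]))
        assert out.empty

    def test_gap_closing_not_supported(self):
        with pytest.raises(ConfigError, match="gap"):
            link_detections(dets_frame([(0, 0.0, 0.0)]), max_gap=1)

    def test_recovery_on_well_separated_movie(self):
        # sparse diffusive foci: >=95% of ground-truth tracks recovered with
        # >=90% of their points correctly linked
        fp = rt.stadium_footprint((4.0, 1.5), 7.0, 2.0)
        tcfg = rt.TrajectorySimConfig(
            n_traj=3, frac_directed=0.0, frac_slow=1.0, d_slow=0.005, d_fast=0.005,
            t_lag=0.1, loc_noise_sd=0.0, n_frames=2, seed=0,
        )
        cfg = rt.MovieSimConfig(
            frame_shape=(32, 96), pixel_size=0.1, n_frames=40, cell_footprints=[fp],
            psf_sigma=0.12, spot_amplitude=3000.0, background=100.0,
            poisson_gain=1.0, gaussian_sd=5.0, trajectory_config=tcfg, seed=17,
        )
        stack, gt = rt.simulate_movie(cfg)
        pre = rt.preprocess_stack(stack)
        dets = detect_spots(pre, 0.25, threshold=40.0)
        tracks = link_detections(dets, 0.4, t_lag=0.1)
        kept, _ = filter_tracks(tracks, min_frames=10)
        n_rec = 0
        for tid, g in gt.detections.groupby("traj_id"):
            # match recovered track by nearest positions frame-by-frame
            best_frac = 0.0
            for _, h in kept.groupby("traj_id"):
                merged = g.merge(h, on="frame", suffixes=("_t", ""))
                if len(merged) == 0:
                    continue
                d = np.hypot(merged["x_um_t"] - merged["x_um"], merged["y_um_t"] - merged["y_um"])
                frac = (d < 0.1).sum() / (len(g) - 1)  # preprocessing drops last frame
                best_frac = max(best_frac, frac)
            if best_frac >= 0.9:
                n_rec += 1
        assert n_rec >= 0.95 * gt.per_trajectory.shape[0]


class TestFilter:
    def _track(self, tid, n):
        return pd.DataFrame(
            {"traj_id": tid, "frame": range(n), "t_s": np.arange(n, dtype=float),
             "x_um": np.zeros(n), "y_um": np.zeros(n)}
        )

    def test_min_duration_boundary(self):
        tracks = pd.concat([self._track(0, 9), self._track(1, 10)])
        kept, counts = filter_tracks(tracks, min_frames=10)
        assert set(kept["traj_id"]) == {1}
        assert counts == {"n_input": 2, "n_kept": 1, "n_dropped_short": 1, "n_dropped_outside": 0}

    def test_empty_input(self):
        kept, counts = filter_tracks(pd.DataFrame(columns=["traj_id", "frame", "x_um", "y_um"]))
        assert kept.empty and counts["n_input"] == 0

    def test_mask_keeps_inside_tracks(self):
        from shapely.geometry import Polygon

        box = Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        tracks = pd.concat([self._track(0, 12), self._track(1, 12).assign(x_um=5.0)])
        kept, counts = filter_tracks(tracks, 10, mask=box)
        assert set(kept["traj_id"]) == {0}
        assert counts["n_dropped_outside"] == 1

    def test_all_inside_mask_is_identity(self):
        from shapely.geometry import Polygon

        box = Polygon([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        tracks = self._track(0, 15)
        kept, _ = filter_tracks(tracks, 10, mask=box)
        pd.testing.assert_frame_equal(kept, tracks.reset_index(drop=True))
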