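"""Eigen-shape metrics: oracles, invariances, simulator properties."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from divebottom3d import bottom_shape as bs
from divebottom3d.dive_segmentation import DiveRecord
from divebottom3d.dead_reckoning import Track3D


def _track(positions):
    positions = np.asarray(positions, float)
    return Track3D(
        times=np.arange(len(positions), dtype=float),
        positions=positions,
        anchor_xy=positions[0, :2],
    )


class TestEigenShape:
    def test_collinear_horizontal_points(self):
        s = np.linspace(0, 100, 50)
        pts = np.column_stack([s * 0.6, s * 0.8, np.zeros_like(s)])
        evals, evecs = bs.eigen_shape(pts)
        assert evals[0] / evals.sum() == pytest.approx(1.0)
        v1 = evecs[:, 0]
        assert np.hypot(v1[0], v1[1]) == pytest.approx(1.0)

    def test_isotropic_cloud_shares_one_third(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((100_000, 3))
        evals, _ = bs.eigen_shape(pts)
        shares = evals / evals.sum()
        assert np.abs(shares - 1 / 3).max() < 0.01

    def test_known_covariance_recovered(self):
        rng = np.random.default_rng(1)
        cov = np.diag([25.0, 9.0, 1.0])
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        cov = rot @ cov @ rot.T
        pts = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        evals, _ = bs.eigen_shape(pts)
        np.testing.assert_allclose(evals, [25.0, 9.0, 1.0], rtol=0.02)

    def test_v1_sign_follows_net_displacement(self):
        s = np.linspace(0, 50, 40)
        pts = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
        _, evecs = bs.eigen_shape(pts)
        assert evecs[0, 0] > 0
        _, evecs_rev = bs.eigen_shape(pts[::-1])
        assert evecs_rev[0, 0] < 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            bs.eigen_shape(np.zeros((3, 3)))

    def test_total_dispersion_equals_covariance_trace(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, [5, 2, 1], size=(500, 3))
        evals, _ = bs.eigen_shape(pts)
        trace = np.trace(np.cov(pts, rowvar=False, ddof=1))
        assert abs(evals.sum() - trace) / trace < 1e-9


class TestMc1Extents:
    def test_uniform_horizontal_segment(self):
        s = np.linspace(0, 100, 1001)
        pts = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
        h, v = bs.mc1_extents(pts, np.array([1.0, 0.0, 0.0]))
        assert h == pytest.approx(80.0, abs=0.01)  # q90 - q10 of uniform
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_45_degree_line_splits_evenly(self):
        s = np.linspace(0, 100, 1001)
        v1 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        pts = s[:, None] * v1
        h, v = bs.mc1_extents(pts, v1)
        assert h == pytest.approx(v)
        assert h == pytest.approx(80.0 / np.sqrt(2), abs=0.01)

    def test_point_cluster_has_zero_extent(self):
        pts = np.tile([3.0, 4.0, -5.0], (20, 1))
        h, v = bs.mc1_extents(pts, np.array([1.0, 0.0, 0.0]))
        assert h == 0.0 and v == 0.0


class TestPlaneWidths:
    def test_straight_line_has_zero_widths(self):
        s = np.linspace(0, 60, 100)
        pts = np.column_stack([s, 0.3 * s, np.zeros_like(s)])
        _, evecs = bs.eigen_shape(pts)
        h, v, flagged = bs.plane_widths(pts, evecs[:, 0])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-9)
        assert not flagged

    def test_horizontal_zigzag_matches_waveform_quantile_oracle(self):
        t = np.linspace(0, 40, 4001)
        a = 5.0
        lateral = a * (2 * np.abs(2 * (t % 1) - 1) - 1)  # triangle wave +-a
        pts = np.column_stack([t * 20, lateral, np.zeros_like(t)])
        _, evecs = bs.eigen_shape(pts)
        h, v, _ = bs.plane_widths(pts, evecs[:, 0])
        oracle = np.quantile(lateral, 0.9) - np.quantile(lateral, 0.1)
        assert h == pytest.approx(oracle, rel=1e-3)
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_vertical_sinusoid_matches_quantile_oracle(self):
        t = np.linspace(0, 40, 4001)
        b = 4.0
        z = b * np.sin(2 * np.pi * t)
        pts = np.column_stack([t * 25, np.zeros_like(t), z])
        _, evecs = bs.eigen_shape(pts)
        h, v, _ = bs.plane_widths(pts, evecs[:, 0])
        # v1 carries a tiny vertical tilt from the finite track, so the
        # plane distances differ from raw z by a factor cos(tilt)
        oracle = np.quantile(z, 0.9) - np.quantile(z, 0.1)
        assert v == pytest.approx(oracle, rel=5e-3)
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_projection_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.normal(0, [10, 3, 2], size=(rng.integers(10, 1000), 3))
            evals, evecs = bs.eigen_shape(pts)
            v1 = evecs[:, 0]
            h, v, flagged = bs.plane_widths(pts, v1)
            if flagged:
                continue
            centered = pts - pts.mean(axis=0)
            n_a = np.cross(v1, [0.0, 0.0, 1.0])
            n_a /= np.linalg.norm(n_a)
            n_b = np.cross(v1, n_a)
            n_b /= np.linalg.norm(n_b)
            h_oracle = np.quantile(centered @ n_a, 0.9) - np.quantile(centered @ n_a, 0.1)
            v_oracle = np.quantile(centered @ n_b, 0.9) - np.quantile(centered @ n_b, 0.1)
            assert h == pytest.approx(h_oracle, abs=1e-9)
            assert v == pytest.approx(v_oracle, abs=1e-9)

    def test_vertical_v1_flagged(self):
        s = np.linspace(0, 50, 60)
        pts = np.column_stack([0.001 * s, np.zeros_like(s), -s])
        _, evecs = bs.eigen_shape(pts)
        _, _, flagged = bs.plane_widths(pts, evecs[:, 0])
        assert flagged


class TestInvariances:
    def test_metrics_invariant_under_horizontal_rotation_and_translation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, [12, 4, 2], size=(400, 3))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        moved = pts @ rot.T + np.array([100.0, -50.0, 7.0])
        for a, b in [(pts, moved)]:
            ev_a, vec_a = bs.eigen_shape(a)
            ev_b, vec_b = bs.eigen_shape(b)
            np.testing.assert_allclose(ev_a, ev_b, rtol=1e-9)
            np.testing.assert_allclose(
                bs.mc1_extents(a, vec_a[:, 0]), bs.mc1_extents(b, vec_b[:, 0]),
                rtol=1e-9, atol=1e-9,
            )
            np.testing.assert_allclose(
                bs.plane_widths(a, vec_a[:, 0])[:2],
                bs.plane_widths(b, vec_b[:, 0])[:2],
                rtol=1e-9, atol=1e-9,
            )


class TestAssembleMetrics:
    def _dive_and_track(self, positions, n_pad=10):
        n = len(positions)
        pad = np.tile(positions[0], (n_pad, 1))
        full = np.vstack([pad, positions, pad])
        dive = DiveRecord(
            dive_id=0, start=0, end=len(full) - 1,
            descent_end=n_pad, ascent_start=n_pad + n - 1,
            max_depth=float(-full[:, 2].min()),
        )
        return dive, _track(full)

    def test_linear_bottom_dominates_first_component(self):
        from divebottom3d.synthetic_data import SimConfig, simulate_deployment

        cfg = SimConfig(
            seed=13, n_dives=2, bottom_linearity=1.0, prey_intensity=0.0,
            drift_dive_fraction=0.0, current_velocity=(0.0, 0.0),
        )
        _, _, truth = simulate_deployment(cfg)
        for a, b in truth.true_bottom_intervals:
            evals, _ = bs.eigen_shape(truth.true_positions[a : b + 1])
            assert evals[0] / evals.sum() > 0.99

    def test_no_bottom_events_gives_zero_count(self):
        rng = np.random.default_rng(5)
        positions = np.cumsum(rng.normal(0, 1, (100, 3)), axis=0)
        positions[:, 2] -= 400
        dive, track = self._dive_and_track(positions)
        metrics = bs.assemble_metrics(dive, track, np.ones(len(track)), [])
        assert metrics.pee_count == 0
        assert metrics.total_dispersion == pytest.approx(
            float(np.trace(np.cov(track.positions[10:110], rowvar=False, ddof=1))),
            rel=1e-9,
        )
        assert 1 / 3 <= metrics.mc1_dispersion <= 1.0
        assert 0.0 <= metrics.horizontality <= 1.0

    def test_vertical_width_tracks_layer_thickness(self):
        """Thicker prey layers produce wider vertical wander at bottom."""
        from divebottom3d.synthetic_data import SimConfig, simulate_deployment

        means = []
        for i, thickness in enumerate([10.0, 30.0, 60.0, 100.0]):
            cfg = SimConfig(
                seed=500 + i, n_dives=50, layer_thickness=thickness,
                prey_intensity=0.0, drift_dive_fraction=0.0, duty_cycle=12.0,
            )
            _, _, truth = simulate_deployment(cfg)
            widths = []
            for a, b in truth.true_bottom_intervals:
                pts = truth.true_positions[a : b + 1]
                _, evecs = bs.eigen_shape(pts)
                _, v, _ = bs.plane_widths(pts, evecs[:, 0])
                widths.append(v)
            means.append(np.mean(widths))
        rho, _ = spearmanr([10.0, 30.0, 60.0, 100.0], means)
        assert rho > 0.9
        assert all(np.diff(means) > 0)
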