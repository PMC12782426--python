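"""Feature-extraction operators: temporal derivatives, local quadratic
surface fits, KDE density, ratio images, table assembly and feature
cross-correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erkmech import (
    CellTrack,
    SmoothingConfig,
    assemble_feature_table,
    feature_crosscorrelation,
    kde_density,
    local_quadratic_fit,
    ratio_image,
    savgol_derivatives,
)
from conftest import make_sheet_tracks


def track_from_x(x, cell_id="a"):
    n = len(x)
    return CellTrack(cell_id, np.arange(n), np.column_stack([x, np.zeros(n)]), np.ones(n))


class TestSavgolDerivatives:
    @pytest.mark.parametrize(
        "coeffs,d1,d2",
        [
            ((0.0, 0.0, 1.0), lambda t: 2 * t, lambda t: np.full_like(t, 2.0)),
            ((5.0, 0.0, 0.0), lambda t: np.zeros_like(t), lambda t: np.zeros_like(t)),
            ((1.0, -3.0, 0.5), lambda t: -3 + t, lambda t: np.full_like(t, 1.0)),
        ],
    )
    def test_exact_on_quadratics(self, coeffs, d1, d2):
        """The order-2 filter reproduces derivatives of any quadratic
        trajectory to machine precision."""
        t = np.arange(40, dtype=float)
        c0, c1, c2 = coeffs
        res = savgol_derivatives(track_from_x(c0 + c1 * t + c2 * t**2), SmoothingConfig())
        tt = res.frames.astype(float)
        np.testing.assert_allclose(res.vel[:, 0], d1(tt), atol=1e-9)
        np.testing.assert_allclose(res.acc[:, 0], d2(tt), atol=1e-9)

    def test_matches_per_window_polynomial_oracle(self):
        """On a cubic, the filter equals an explicit least-squares
        quadratic fit over each centered window."""
        t = np.arange(25, dtype=float)
        x = 0.02 * t**3
        cfg = SmoothingConfig()
        res = savgol_derivatives(track_from_x(x), cfg)
        half = cfg.sg_window // 2
        u = np.arange(-half, half + 1, dtype=float)
        design = np.column_stack([np.ones_like(u), u, u**2])
        for k, frame in enumerate(res.frames):
            window = x[frame - half : frame + half + 1]
            c = np.linalg.lstsq(design, window, rcond=None)[0]
            assert res.vel[k, 0] == pytest.approx(c[1], abs=1e-9)
            assert res.acc[k, 0] == pytest.approx(2 * c[2], abs=1e-9)

    def test_edge_frames_dropped(self):
        res = savgol_derivatives(track_from_x(np.arange(30.0)), SmoothingConfig())
        assert len(res.frames) == 30 - 10
        assert res.frames[0] == 5 and res.frames[-1] == 24

    def test_short_track_error_names_track(self):
        with pytest.raises(ValueError, match="'tiny'"):
            savgol_derivatives(track_from_x(np.arange(5.0), cell_id="tiny"), SmoothingConfig())

    def test_frame_interval_unit_conversion(self):
        """Converting px/frame output with a doubled frame interval halves
        velocities and quarters accelerations in per-minute units."""
        t = np.arange(40, dtype=float)
        res = savgol_derivatives(track_from_x(3 * t + 0.1 * t**2), SmoothingConfig())
        for dt_min in (2.0, 4.0):
            v_min = res.vel / dt_min
            a_min = res.acc / dt_min**2
            np.testing.assert_allclose(v_min * dt_min, res.vel)
            np.testing.assert_allclose(a_min * dt_min**2, res.acc)
        v2, a2 = res.vel / 4.0, res.acc / 16.0
        np.testing.assert_allclose(v2, (res.vel / 2.0) / 2.0)
        np.testing.assert_allclose(a2, (res.acc / 4.0) / 4.0)


class TestLocalQuadraticFit:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.pts = rng.uniform(-5, 5, size=(20, 2))

    def test_linear_field(self):
        vals = 3 * self.pts[:, 0] + 2 * self.pts[:, 1]
        fit = local_quadratic_fit(np.zeros(2), self.pts, vals, radius=10)
        assert fit.usable
        np.testing.assert_allclose(fit.grad, [3.0, 2.0], atol=1e-9)
        np.testing.assert_allclose(fit.second, [0.0, 0.0], atol=1e-9)

    def test_pure_x_squared(self):
        vals = self.pts[:, 0] ** 2
        center = np.array([1.5, 0.0])
        fit = local_quadratic_fit(center, self.pts, vals, radius=10)
        np.testing.assert_allclose(fit.grad, [3.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(fit.second, [2.0, 0.0], atol=1e-8)
        assert fit.value == pytest.approx(1.5**2, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        vals = (
            1.0
            + 0.5 * self.pts[:, 0]
            - 0.2 * self.pts[:, 1]
            + 0.3 * self.pts[:, 0] ** 2
            + rng.normal(0, 0.05, 20)
        )
        center = np.array([0.7, -0.4])
        fit = local_quadratic_fit(center, self.pts, vals, radius=100)
        d = self.pts - center
        A = np.column_stack(
            [np.ones(20), d[:, 0], d[:, 1], d[:, 0] ** 2, d[:, 0] * d[:, 1], d[:, 1] ** 2]
        )
        coef = np.linalg.solve(A.T @ A, A.T @ vals)
        assert fit.value == pytest.approx(coef[0], rel=1e-8)
        np.testing.assert_allclose(fit.grad, coef[1:3], rtol=1e-8)
        np.testing.assert_allclose(fit.second, [2 * coef[3], 2 * coef[5]], rtol=1e-8)

    def test_too_few_points_flagged_unusable(self):
        fit = local_quadratic_fit(np.zeros(2), self.pts[:5], np.ones(5), radius=100)
        assert not fit.usable and np.isnan(fit.value)

    def test_degenerate_collinear_points_unusable(self):
        pts = np.column_stack([np.linspace(-3, 3, 10), np.zeros(10)])
        fit = local_quadratic_fit(np.zeros(2), pts, pts[:, 0] ** 2, radius=100)
        assert not fit.usable

    @settings(deadline=None, max_examples=25)
    @given(
        shift=st.tuples(
            st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
        )
    )
    def test_translation_invariance(self, shift):
        """Shifting the coordinate origin leaves gradients and second
        derivatives of a quadratic field unchanged."""
        vals = 0.4 * self.pts[:, 0] ** 2 - 0.1 * self.pts[:, 0] * self.pts[:, 1]
        center = np.array([0.5, 0.5])
        base = local_quadratic_fit(center, self.pts, vals, radius=100)
        moved = local_quadratic_fit(
            center + shift, self.pts + shift, vals, radius=100
        )
        np.testing.assert_allclose(moved.grad, base.grad, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(moved.second, base.second, rtol=1e-6, atol=1e-8)


class TestKdeDensity:
    def test_single_cell_peak(self):
        pos = np.array([[10.0, 20.0]])
        rho = kde_density(pos, pos, kde_sigma=25.0)
        assert rho[0] == pytest.approx(1.0 / (2 * np.pi * 625.0), rel=1e-12)

    def test_distant_cells_independent(self):
        pos = np.array([[0.0, 0.0], [1000.0, 0.0]])
        rho = kde_density(pos, pos, kde_sigma=25.0)
        np.testing.assert_allclose(rho, 1.0 / (2 * np.pi * 625.0), rtol=1e-12)

    def test_integrates_to_cell_count(self, rng):
        """Quadrature of the density field over a generous grid recovers
        the number of cells to 1%."""
        n = 50
        pos = rng.uniform(100, 400, size=(n, 2))
        sigma = 25.0
        grid = np.linspace(-150, 650, 401)
        h = grid[1] - grid[0]
        gx, gy = np.meshgrid(grid, grid)
        queries = np.column_stack([gx.ravel(), gy.ravel()])
        total = kde_density(pos, queries, sigma).sum() * h * h
        assert total == pytest.approx(n, rel=0.01)

    def test_empty_frame_and_nonnegativity(self, rng):
        assert np.all(kde_density(np.empty((0, 2)), rng.uniform(0, 1, (5, 2)), 25.0) == 0)
        rho = kde_density(rng.uniform(0, 100, (30, 2)), rng.uniform(0, 100, (40, 2)), 10.0)
        assert np.all(rho >= 0)


class TestRatioImage:
    def test_constant_field_identities(self):
        cfp = np.full((3, 16, 16), 50.0)
        res = ratio_image(2 * cfp, cfp)
        np.testing.assert_allclose(res.ratio, 2.0, rtol=1e-12)
        assert res.n_invalid == 0
        res1 = ratio_image(cfp, cfp)
        np.testing.assert_allclose(res1.ratio, 1.0, rtol=1e-12)

    def test_matches_direct_convolution_oracle(self, rng):
        """Smoothing agrees with a brute-force discrete Gaussian
        convolution on the frame interior (away from boundary padding)."""
        fret = rng.uniform(50, 200, size=(24, 24))
        cfp = rng.uniform(50, 200, size=(24, 24))
        sigma = 1.0
        res = ratio_image(fret, cfp, background=(5.0, 5.0))
        r = 4  # truncated kernel radius (scipy default truncate=4 sigma)
        u = np.arange(-r, r + 1)
        k1 = np.exp(-(u**2) / (2 * sigma**2))
        kern = np.outer(k1, k1)
        kern /= kern.sum()

        def smooth(img):
            out = np.zeros_like(img)
            for i in range(r, img.shape[0] - r):
                for j in range(r, img.shape[1] - r):
                    out[i, j] = (img[i - r : i + r + 1, j - r : j + r + 1] * kern).sum()
            return out

        expected = (smooth(fret) - 5.0) / (smooth(cfp) - 5.0)
        interior = (slice(r, 24 - r), slice(r, 24 - r))
        np.testing.assert_allclose(res.ratio[interior], expected[interior], rtol=1e-10)

    def test_nonpositive_denominator_masked_and_counted(self):
        fret = np.full((8, 8), 100.0)
        cfp = np.full((8, 8), 100.0)
        res = ratio_image(fret, cfp, background=(0.0, 150.0))
        assert res.n_invalid == 64
        assert np.isnan(res.ratio).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            ratio_image(np.ones((4, 4)), np.ones((5, 5)))

    def test_tiff_stack_round_trip(self, tmp_path, rng):
        """FRET/CFP stacks written as multi-page TIFF load back and
        ratio correctly through the pipeline entry point."""
        import tifffile
        from erkmech import read_stack

        cfp = rng.uniform(80, 150, size=(3, 12, 12)).astype(np.float32)
        fret = 1.6 * cfp
        tifffile.imwrite(tmp_path / "fret.tif", fret, photometric="minisblack")
        tifffile.imwrite(tmp_path / "cfp.tif", cfp, photometric="minisblack")
        res = ratio_image(read_stack(tmp_path / "fret.tif"), read_stack(tmp_path / "cfp.tif"))
        assert res.ratio.shape == (3, 12, 12)
        np.testing.assert_allclose(res.ratio, 1.6, rtol=1e-6)


class TestAssembleFeatureTable:
    def test_isolated_cell_yields_no_records(self):
        n = 30
        track = CellTrack(
            "lone", np.arange(n), np.column_stack([np.arange(n, dtype=float), np.zeros(n)]),
            np.ones(n),
        )
        df = assemble_feature_table([track], SmoothingConfig(), axis="orthogonal")
        assert len(df) == 0
        assert df.attrs["drops"]["erk_fit"] > 0

    def test_linear_erk_field_gradient(self):
        g = 0.02
        tracks = make_sheet_tracks(erk_gradient=g)
        cfg = SmoothingConfig(fit_radius_erk=15.0, fit_radius_vel=15.0)
        df = assemble_feature_table(tracks, cfg, axis="orthogonal")
        assert len(df) > 100
        np.testing.assert_allclose(df["x2_erk_grad"], g, rtol=1e-6)

    def test_uniform_drift_velocity_and_zero_accel(self):
        drift = 0.1
        tracks = make_sheet_tracks(drift=drift)
        cfg = SmoothingConfig(fit_radius_erk=15.0, fit_radius_vel=15.0)
        df = assemble_feature_table(tracks, cfg, axis="orthogonal")
        np.testing.assert_allclose(df["x1_vel"], drift, atol=1e-9)
        np.testing.assert_allclose(df["accel"], 0.0, atol=1e-9)
        np.testing.assert_allclose(df["x4_d2v_dx2"], 0.0, atol=1e-9)

    def test_permutation_invariance(self):
        tracks = make_sheet_tracks(n_side=5, n_frames=20)
        cfg = SmoothingConfig(fit_radius_erk=15.0, fit_radius_vel=15.0)
        a = assemble_feature_table(tracks, cfg)
        b = assemble_feature_table(tracks[::-1], cfg)
        pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-12)

    def test_parallel_axis_uses_y_component(self):
        """For the parallel axis the velocity component and the
        differentiation direction both switch to y."""
        tracks = make_sheet_tracks(erk_gradient=0.02)
        # add a y-drift so the parallel velocity is nonzero
        for t in tracks:
            t.pos[:, 1] = t.pos[:, 1] + 0.05 * t.frames
        cfg = SmoothingConfig(fit_radius_erk=15.0, fit_radius_vel=15.0)
        df = assemble_feature_table(tracks, cfg, axis="parallel")
        np.testing.assert_allclose(df["x1_vel"], 0.05, atol=1e-9)
        # ERK = g*x has no y-gradient
        np.testing.assert_allclose(df["x2_erk_grad"], 0.0, atol=1e-8)

    def test_no_tracks_is_error(self):
        with pytest.raises(ValueError):
            assemble_feature_table([], SmoothingConfig())


class TestFeatureCrosscorrelation:
    @staticmethod
    def toy_table(n_cells=4, n=150, seed=0, shift=None):
        rng = np.random.default_rng(seed)
        parts = []
        for c in range(n_cells):
            base = rng.normal(size=n + 10)
            d = {
                "cell_id": f"c{c}",
                "frame": np.arange(n),
                "axis": "orthogonal",
                "accel": rng.normal(size=n),
                "x1_vel": base[:n],
                "x2_erk_grad": base[5 : n + 5] if shift else rng.normal(size=n),
                "x3_rho_grad": base[:n] if shift else rng.normal(size=n),
                "x4_d2v_dx2": rng.normal(size=n),
                "x5_d2v_dy2": rng.normal(size=n),
                "rho": np.ones(n),
            }
            parts.append(pd.DataFrame(d))
        return pd.concat(parts, ignore_index=True)

    def test_self_correlation_at_zero_lag(self):
        out = feature_crosscorrelation(self.toy_table(), max_lag_minutes=40)
        row = out[(out.feature_a == "x1_vel") & (out.feature_b == "x1_vel") & (out.lag_min == 0)]
        assert row["corr"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_shifted_copy_peaks_at_lag(self):
        """x2(t) = x3(t - 5 frames): their cross-correlation peaks at a
        10-minute lag with value 1."""
        out = feature_crosscorrelation(self.toy_table(shift=True), max_lag_minutes=40)
        sub = out[(out.feature_a == "x2_erk_grad") & (out.feature_b == "x3_rho_grad")]
        peak = sub.loc[sub["corr"].idxmax()]
        assert peak["lag_min"] == pytest.approx(10.0)
        assert peak["corr"] == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_bound(self):
        """Mean correlations of independent white-noise features stay
        within the 3/sqrt(n_cells) sampling band at every lag."""
        n_cells = 100
        out = feature_crosscorrelation(
            self.toy_table(n_cells=n_cells, n=220, seed=5), max_lag_minutes=40
        )
        offdiag = out[out.feature_a != out.feature_b]
        assert np.nanmax(np.abs(offdiag["corr"])) < 3 / np.sqrt(n_cells)

    def test_short_series_skipped(self):
        out = feature_crosscorrelation(self.toy_table(n=80), max_lag_minutes=100)
        assert out.attrs["skipped_cells"] == 4
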