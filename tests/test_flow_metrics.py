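"""Flow statistics: angles, autocorrelation (vs literal double-loop oracle),
FTLE analytic flows, coarse-graining scale fits, radial profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sheetflow.flow import (
    DirectionSample,
    MetricError,
    angular_deviation,
    characteristic_length_scale,
    characteristic_time_scale,
    fit_time_scale_curve,
    ftle,
    local_coordination,
    mean_speed,
    percent_positive,
    radial_direction_angles,
    radial_profile,
    radial_velocity_autocorrelation,
    temporal_coarse_grain_curve,
)
from sheetflow.geometry import SheetGeometry
from sheetflow.piv import FlowField, FlowFieldSequence
from sheetflow.synthetic import SyntheticParams, generate_flow_sequence


def make_seq(u, v, n_frames=1, spacing=10.0, frame_interval=3.0, center=(0.0, -1000.0)):
    u = np.asarray(u, float)
    ny, nx = u.shape
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    ones = np.ones((ny, nx), bool)
    fields = [
        FlowField(x=x, y=y, u=u.copy(), v=np.asarray(v, float).copy(),
                  snr=np.full((ny, nx), np.inf), valid=ones.copy())
        for _ in range(n_frames)
    ]
    geom = SheetGeometry(center=center, radius=np.full(n_frames, 2000.0),
                         frame_interval=frame_interval)
    return FlowFieldSequence(fields=fields, frame_interval=frame_interval, geometry=geom)


def eq2_bruteforce(points, v):
    """Literal double loop over unordered site pairs, binned at unit spacing.

    Independent reference for the radial-velocity autocorrelation.
    """
    n = len(points)
    sums = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(points[i] - points[j]))
            b = int(d / 10.0 + 0.5)
            num, da, db, cnt = sums.get(b, (0.0, 0.0, 0.0, 0))
            sums[b] = (num + v[i] * v[j], da + v[i] ** 2, db + v[j] ** 2, cnt + 1)
    out = {}
    for b, (num, da, db, _) in sums.items():
        out[b] = num / np.sqrt(da * db)
    return out


class TestSpeedAndAngles:
    def test_uniform_speed(self):
        seq = make_seq(np.full((4, 4), 2.0), np.zeros((4, 4)))
        assert mean_speed(seq) == pytest.approx(2.0)

    def test_mixed_speeds_average(self):
        u = np.zeros((2, 4)); v = np.zeros((2, 4))
        u[0] = 3.0  # speed 3
        v[1] = 4.0  # speed 4
        assert mean_speed(make_seq(u, v)) == pytest.approx(3.5)

    def test_no_valid_vectors_errors(self):
        seq = make_seq(np.ones((3, 3)), np.zeros((3, 3)))
        for f in seq.fields:
            f.valid[:] = False
        with pytest.raises(MetricError):
            mean_speed(seq)

    def test_eastern_site_north_vector_is_plus_half_pi(self):
        # single site due east of the center; velocity pointing north
        seq = make_seq(np.zeros((1, 2)), np.ones((1, 2)), center=(-50.0, 0.0))
        th = radial_direction_angles(seq).angles
        assert np.allclose(th, np.pi / 2)

    def test_outward_and_inward_limits(self):
        u = np.zeros((3, 3)); v = np.ones((3, 3))
        seq = make_seq(u, v, center=(10.0, -500.0))  # outward ≈ +y
        assert np.abs(radial_direction_angles(seq).angles).max() < 0.1
        seq_in = make_seq(u, -v, center=(10.0, -500.0))
        assert np.abs(radial_direction_angles(seq_in).angles).min() > np.pi - 0.1


class TestAngularDeviation:
    def test_aligned_is_zero(self):
        assert angular_deviation(np.zeros(100)) == 0.0

    def test_perfect_cancellation_is_sqrt2(self):
        assert angular_deviation(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])) == pytest.approx(
            np.sqrt(2.0)
        )

    def test_two_orthogonal_angles(self):
        # z = √2/2 → √(2(1−z)) ≈ 0.76537
        assert angular_deviation(np.array([0.0, np.pi / 2])) == pytest.approx(0.76537, abs=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-np.pi, np.pi, allow_nan=False), min_size=1, max_size=50))
    def test_bounds_invariant(self, angles):
        d = angular_deviation(np.array(angles))
        assert -1e-12 <= d <= np.sqrt(2.0) + 1e-12


class TestAutocorrelation:
    def test_uniform_field_is_one_everywhere(self):
        seq = make_seq(np.zeros((6, 6)), np.full((6, 6), 2.0), center=(25.0, -5000.0))
        curve = radial_velocity_autocorrelation(seq)
        ok = np.isfinite(curve.c)
        assert np.allclose(curve.c[ok], 1.0, atol=1e-9)

    def test_zero_separation_is_exactly_one(self, rng):
        u = rng.normal(0, 1, (6, 6)); v = rng.normal(0, 1, (6, 6))
        curve = radial_velocity_autocorrelation(make_seq(u, v))
        assert curve.c[0] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_decorrelates(self, rng):
        u = np.zeros((12, 12))
        v = rng.normal(0, 1, (12, 12))
        seq = make_seq(u, v, center=(55.0, -50000.0))  # far center: radial ≈ +y
        curve = radial_velocity_autocorrelation(seq)
        ok = np.isfinite(curve.c) & (curve.delta_r > 0) & (curve.pair_counts > 50)
        assert np.all(np.abs(curve.c[ok]) <= 3.0 / np.sqrt(curve.pair_counts[ok]) + 0.15)

    def test_cosine_field_autocorrelation(self):
        # v(x) = cos(2πx/L) on a line of sites → C(Δr) ≈ cos(2πΔr/L)
        nx, L = 64, 320.0
        x = np.arange(nx) * 10.0
        v = np.cos(2 * np.pi * x / L)[None, :]
        seq = make_seq(np.zeros((1, nx)), v, center=(315.0, -1e7))
        curve = radial_velocity_autocorrelation(seq)
        sel = np.isfinite(curve.c) & (curve.delta_r < 200)
        assert np.allclose(curve.c[sel], np.cos(2 * np.pi * curve.delta_r[sel] / L), atol=0.12)

    def test_matches_bruteforce_oracle_to_1e12(self, rng):
        ny, nx = 7, 9  # 63 sites
        u = rng.normal(0, 1, (ny, nx))
        v = rng.normal(0, 1, (ny, nx))
        center = (40.0, -300.0)
        seq = make_seq(u, v, center=center)
        curve = radial_velocity_autocorrelation(seq)
        pts = seq.fields[0].sites()
        geom = seq.geometry
        e = geom.radial_unit(pts)
        vr = u.ravel() * e[:, 0] + v.ravel() * e[:, 1]
        ref = eq2_bruteforce(pts, vr)
        for b, c_ref in ref.items():
            assert curve.c[b] == pytest.approx(c_ref, abs=1e-12)

    def test_local_coordination_limits(self, rng):
        uniform = make_seq(np.zeros((15, 15)), np.full((15, 15), 1.5), center=(70.0, -1e6))
        assert local_coordination(radial_velocity_autocorrelation(uniform)) == pytest.approx(1.0, abs=1e-9)
        noise = make_seq(np.zeros((15, 15)), rng.normal(0, 1, (15, 15)), center=(70.0, -1e6))
        assert abs(local_coordination(radial_velocity_autocorrelation(noise))) < 0.35

    def test_missing_bins_near_radius_error(self):
        seq = make_seq(np.ones((2, 2)), np.ones((2, 2)), spacing=5.0)
        curve = radial_velocity_autocorrelation(seq)
        with pytest.raises(MetricError):
            local_coordination(curve, radius=100.0)


class TestFTLE:
    def _analytic_seq(self, fu, fv, n=30, T=40, spacing=10.0):
        x = (np.arange(n) - n / 2) * spacing
        y = (np.arange(n) - n / 2) * spacing
        X, Y = np.meshgrid(x, y)
        ones = np.ones((n, n), bool)
        fields = [FlowField(x=x, y=y, u=fu(X, Y), v=fv(X, Y),
                            snr=np.full((n, n), np.inf), valid=ones) for _ in range(T)]
        return FlowFieldSequence(fields=fields, frame_interval=3.0)

    def test_uniform_translation_zero_everywhere(self):
        seq = self._analytic_seq(lambda X, Y: np.full_like(X, 0.5), lambda X, Y: np.zeros_like(X))
        m = ftle(seq, 120.0)
        assert np.nanmax(np.abs(m.lam[m.valid])) <= 1e-9
        assert percent_positive(m) == 0.0

    def test_saddle_flow_matches_closed_form(self):
        k = 0.01  # /min, kT = 1.2 → λ = 2.4
        seq = self._analytic_seq(lambda X, Y: k * X, lambda X, Y: -k * Y)
        m = ftle(seq, 120.0)
        interior = m.lam[0][5:-5, 5:-5]
        assert np.nanmean(interior) == pytest.approx(2.4, rel=0.05)

    def test_rigid_rotation_is_isometric(self):
        om = 2e-3  # rad/min
        seq = self._analytic_seq(lambda X, Y: -om * Y, lambda X, Y: om * X)
        m = ftle(seq, 120.0, integrator="rk4")
        interior = np.abs(m.lam[0][5:-5, 5:-5])
        assert np.nanmax(interior) <= 0.05

    def test_percent_positive_galilean_invariant(self, rng):
        base = rng.normal(0, 0.05, (2, 20, 20))
        x = np.arange(20) * 10.0
        ones = np.ones((20, 20), bool)

        def seq_with_drift(u0):
            fields = [FlowField(x=x, y=x, u=base[0] + u0, v=base[1],
                                snr=np.full((20, 20), np.inf), valid=ones) for _ in range(40)]
            return FlowFieldSequence(fields=fields, frame_interval=3.0)

        p0 = percent_positive(ftle(seq_with_drift(0.0), 120.0))
        p1 = percent_positive(ftle(seq_with_drift(0.2), 120.0))
        assert p0 == pytest.approx(p1, abs=2.0)

    def test_all_tracers_leaving_is_an_error(self):
        seq = self._analytic_seq(lambda X, Y: np.full_like(X, 50.0), lambda X, Y: np.zeros_like(X), n=16)
        with pytest.raises(MetricError):
            ftle(seq, 120.0)


class TestScaleFits:
    def test_static_field_degenerate(self, rng):
        u = rng.normal(0, 1, (16, 16))
        seq = make_seq(u, -u, n_frames=30)
        fit = characteristic_time_scale(seq)
        assert fit.degenerate and np.isnan(fit.scale)

    def test_time_scale_against_dense_bruteforce_fit(self):
        p = SyntheticParams(seed=11, n_frames=120, persistence_time=30.0, direction_concentration=2.0)
        seq, _ = generate_flow_sequence(p, grid_shape=(20, 20))
        fit = characteristic_time_scale(seq)
        # dense brute-force oracle: scan t_c, solve the linear amplitudes by
        # non-negative least squares at each candidate
        from scipy.optimize import nnls

        t, sigma = fit.grid, fit.sigma
        best = (np.inf, None)
        for tc in np.geomspace(1.0, 500.0, 400):
            A = np.column_stack([np.exp(-t / tc), 1.0 / np.sqrt(t / 3.0), np.ones_like(t)])
            coef, res = nnls(A, sigma)
            if res < best[0]:
                best = (res, tc)
        assert fit.scale == pytest.approx(best[1], rel=0.25)

    def test_time_scale_speed_invariant(self):
        fits = []
        for speed in (0.4, 0.8):
            p = SyntheticParams(seed=21, n_frames=100, mean_speed=speed,
                                persistence_time=30.0, direction_concentration=2.0)
            seq, _ = generate_flow_sequence(p, grid_shape=(16, 16))
            fits.append(characteristic_time_scale(seq).scale)
        assert fits[1] == pytest.approx(fits[0], rel=0.10)

    def test_uniform_field_length_degenerate(self):
        seq = make_seq(np.full((20, 20), 1.0), np.zeros((20, 20)), n_frames=2)
        fit = characteristic_length_scale(seq)
        assert fit.degenerate

    def test_white_noise_length_near_resolution(self, rng):
        u = rng.normal(0, 1, (5, 24, 24))
        x = np.arange(24) * 10.0
        ones = np.ones((24, 24), bool)
        fields = [FlowField(x=x, y=x, u=u[t], v=-u[t], snr=np.full((24, 24), np.inf), valid=ones)
                  for t in range(5)]
        seq = FlowFieldSequence(fields=fields, frame_interval=3.0)
        fit = characteristic_length_scale(seq)
        assert not fit.degenerate
        assert fit.scale < 2.5 * 10.0  # near the grid spacing

    def test_scales_monotone_in_generating_parameters(self):
        # 3-point sweeps: recovered t_c and l_c increase with the generator's
        # persistence time and correlation length
        tcs = []
        for tau in (10.0, 30.0, 90.0):
            p = SyntheticParams(seed=5, n_frames=120, persistence_time=tau, direction_concentration=2.0)
            seq, _ = generate_flow_sequence(p, grid_shape=(16, 16))
            tcs.append(characteristic_time_scale(seq).scale)
        assert tcs[0] < tcs[1] < tcs[2]
        lcs = []
        for cl in (15.0, 30.0, 60.0):
            p = SyntheticParams(seed=6, n_frames=60, correlation_length=cl, direction_concentration=2.0)
            seq, _ = generate_flow_sequence(p, grid_shape=(32, 32))
            lcs.append(characteristic_length_scale(seq).scale)
        assert lcs[0] < lcs[1] < lcs[2]


class TestRadialProfile:
    def _geometry(self):
        return SheetGeometry(center=(0.0, 0.0), radius=np.array([100.0]))

    def test_constant_map(self):
        sites = np.column_stack([np.linspace(5, 95, 50), np.zeros(50)])
        centers, means = radial_profile(np.full(50, 7.0), sites, self._geometry())
        assert np.allclose(means[np.isfinite(means)], 7.0)

    def test_identity_map_matches_bin_centers(self):
        r = np.linspace(1, 99, 500)
        sites = np.column_stack([r, np.zeros_like(r)])
        centers, means = radial_profile(r / 100.0, sites, self._geometry())
        ok = np.isfinite(means)
        assert np.allclose(means[ok], centers[ok], atol=0.025)

    def test_outer_elevation_peaks_in_last_bin(self):
        r = np.linspace(1, 99, 200)
        sites = np.column_stack([r, np.zeros_like(r)])
        lam = np.where(r / 100.0 > 0.95, 3.0, 0.1)
        centers, means = radial_profile(lam, sites, self._geometry())
        ok = np.isfinite(means) & (centers <= 1.0)
        assert centers[ok][np.argmax(means[ok])] > 0.95

    def test_far_sites_excluded(self):
        sites = np.array([[50.0, 0.0], [500.0, 0.0]])
        _, means = radial_profile(np.array([1.0, 99.0]), sites, self._geometry())
        assert np.nansum(means) == pytest.approx(1.0)
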