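"""Functional metric suite: Eulerian averaging, D(R), R0 fits, CPB, CBF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciliaflow.flow_metrics import (
    DirectionalityCurve,
    EulerianFlow,
    clearance_speed,
    compute_cpb,
    directionality_at,
    directionality_curve,
    estimate_cbf,
    eulerian_average,
    fit_correlation_length,
    bootstrap_r0,
)
from ciliaflow.synthetic import synth_cbf_movie, synth_tracks


def straight_track(speed=5.0, n=20, y=10.0):
    return pd.DataFrame(
        {
            "TRACK_ID": 0,
            "FRAME": np.arange(n),
            "POSITION_X": speed * np.arange(n),
            "POSITION_Y": np.full(n, y),
        }
    )


class TestEulerianAverage:
    def test_straight_track_fills_bins_with_its_speed(self):
        flow = eulerian_average(straight_track(speed=5.0), bin_size=5.0)
        mag = np.hypot(flow.u, flow.v)[flow.occupied]
        assert np.allclose(mag, 5.0)

    def test_opposite_tracks_cancel(self):
        fwd = straight_track(speed=5.0)
        bwd = straight_track(speed=5.0).assign(
            TRACK_ID=1, POSITION_X=lambda d: d["POSITION_X"].iloc[::-1].to_numpy()
        )
        flow = eulerian_average(pd.concat([fwd, bwd]), bin_size=5.0)
        shared = flow.counts >= 2
        assert shared.any()
        assert np.abs(flow.u[shared]).max() < 1e-9

    def test_vortex_field_recovered_within_discretization(self):
        tracks, truth = synth_tracks(
            "vortex", speed=4.0, diffusivity=0.0, n_tracks=800, n_frames=40, seed=2
        )
        flow = eulerian_average(tracks, bin_size=10.0)
        # compare against the generating field at bin centers
        from ciliaflow.synthetic import _analytic_field

        vfun = _analytic_field("vortex", 4.0, 200.0)
        ny, nx = flow.u.shape
        yc = flow.origin[1] + (np.arange(ny) + 0.5) * flow.bin_size
        xc = flow.origin[0] + (np.arange(nx) + 0.5) * flow.bin_size
        X, Y = np.meshgrid(xc, yc)
        ref = vfun(np.column_stack([X.ravel(), Y.ravel()]))
        occ = flow.occupied.ravel() & (np.hypot(ref[:, 0], ref[:, 1]) > 0.5)
        est = np.column_stack([flow.u.ravel()[occ], flow.v.ravel()[occ]])
        rms = np.sqrt(np.mean((est - ref[occ]) ** 2))
        assert rms < 0.10 * np.sqrt(np.mean(ref[occ] ** 2)) * 2  # RMS < ~10-20%

    def test_singleton_tracks_rejected(self):
        df = pd.DataFrame(
            {"TRACK_ID": [0], "FRAME": [0], "POSITION_X": [1.0], "POSITION_Y": [2.0]}
        )
        with pytest.raises(ValueError):
            eulerian_average(df)


class TestDirectionality:
    def test_uniform_field_gives_exactly_one(self):
        flow = EulerianFlow(
            u=np.ones((40, 40)), v=np.zeros((40, 40)),
            counts=np.ones((40, 40)), bin_size=2.0,
        )
        curve = directionality_curve(flow, R_um=np.array([4.0, 10.0, 20.0, 40.0]))
        assert np.allclose(curve.D, 1.0)

    def test_isotropic_vectors_decorrelate(self, rng):
        ang = rng.uniform(0, 2 * np.pi, (60, 60))
        flow = EulerianFlow(
            u=np.cos(ang), v=np.sin(ang), counts=np.ones((60, 60)), bin_size=1.0
        )
        curve = directionality_curve(flow, R_um=np.array([20.0, 30.0, 60.0]))
        assert np.all(curve.D <= 0.1)

    def test_global_rotation_invariance(self, rng):
        ang = rng.uniform(0, 2 * np.pi, (32, 32))
        mag = rng.uniform(0.5, 2.0, (32, 32))
        base = EulerianFlow(
            u=mag * np.cos(ang), v=mag * np.sin(ang),
            counts=np.ones((32, 32)), bin_size=1.0,
        )
        phi = 1.1
        rot = EulerianFlow(
            u=mag * np.cos(ang + phi), v=mag * np.sin(ang + phi),
            counts=np.ones((32, 32)), bin_size=1.0,
        )
        R = np.array([4.0, 8.0, 16.0, 32.0])
        d0 = directionality_curve(base, R_um=R).D
        d1 = directionality_curve(rot, R_um=R).D
        assert np.allclose(d0, d1, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_directionality_bounded_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(16, 16))
        v = rng.normal(size=(16, 16))
        counts = (rng.random((16, 16)) < 0.8).astype(float)
        flow = EulerianFlow(u=u, v=v, counts=counts, bin_size=1.0)
        if not flow.occupied.any():
            return
        curve = directionality_curve(flow, R_um=np.array([2.0, 4.0, 8.0, 16.0]))
        assert np.all((curve.D >= 0) & (curve.D <= 1 + 1e-12))

    def test_window_below_bin_size_rejected(self):
        flow = EulerianFlow(
            u=np.ones((8, 8)), v=np.zeros((8, 8)), counts=np.ones((8, 8)), bin_size=2.0
        )
        with pytest.raises(ValueError):
            directionality_curve(flow, R_um=np.array([1.0]))


class TestCorrelationLengthFit:
    def test_exact_exponential_recovered(self):
        R = np.arange(4.0, 120.0, 4.0)
        curve = DirectionalityCurve(R_um=R, D=np.exp(-R / 30.0))
        r0, r2, accepted = fit_correlation_length(curve)
        assert accepted and r2 > 0.999
        assert r0 == pytest.approx(30.0, rel=0.02)

    def test_offset_exponential_recovered_after_plateau_handling(self):
        R = np.arange(4.0, 200.0, 4.0)
        curve = DirectionalityCurve(R_um=R, D=np.exp(-R / 30.0) + 0.2)
        r0, _, accepted = fit_correlation_length(curve)
        assert accepted
        assert r0 == pytest.approx(30.0, abs=1.0)

    def test_poor_fit_rejected_by_threshold(self, rng):
        R = np.arange(4.0, 80.0, 4.0)
        noisy = np.clip(np.exp(-R / 25.0) + rng.normal(0, 0.4, R.size), 0, 1)
        curve = DirectionalityCurve(R_um=R, D=noisy)
        _, r2, accepted = fit_correlation_length(curve)
        assert (r2 > 0.8) == accepted  # the acceptance rule is exactly the threshold

    def test_non_decaying_curve_not_accepted_no_exception(self, rng):
        R = np.arange(4.0, 80.0, 4.0)
        curve = DirectionalityCurve(R_um=R, D=np.full(R.size, 0.5) + rng.normal(0, 0.01, R.size))
        _, _, accepted = fit_correlation_length(curve)
        assert accepted is False

    def test_bootstrap_spread_brackets_r0(self, rng):
        R = np.arange(4.0, 120.0, 4.0)
        windows = [np.clip(np.exp(-r / 30.0) + rng.normal(0, 0.02, 25), 0, 1) for r in R]
        curve = DirectionalityCurve(
            R_um=R, D=np.array([w.mean() for w in windows]), window_values=windows
        )
        boot = bootstrap_r0(curve, n_boot=200, seed=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assert lo < 30.0 < hi
        assert (hi - lo) < 10.0


class TestSummaries:
    def test_dr80_closed_form(self):
        R = np.arange(4.0, 160.0, 4.0)
        curve = DirectionalityCurve(R_um=R, D=np.exp(-R / 23.0))
        assert directionality_at(curve, 80.0) == pytest.approx(np.exp(-80 / 23), abs=1e-3)

    def test_dr80_uniform_is_one(self):
        flow = EulerianFlow(
            u=np.ones((50, 50)), v=np.zeros((50, 50)),
            counts=np.ones((50, 50)), bin_size=2.0,
        )
        curve = directionality_curve(flow)
        assert curve.dr80 == pytest.approx(1.0)

    def test_decay_monotonicity_dr80_below_d40(self):
        R = np.arange(4.0, 160.0, 4.0)
        curve = DirectionalityCurve(R_um=R, D=np.exp(-R / 23.0))
        assert directionality_at(curve, 80.0) <= directionality_at(curve, 40.0)

    def test_clearance_speed_straight_track(self):
        assert clearance_speed(straight_track(speed=5.0), frame_interval=1.0) == 5.0

    def test_clearance_speed_stationary(self):
        df = straight_track(speed=0.0)
        assert clearance_speed(df, frame_interval=0.5) == 0.0

    def test_brownian_speed_scaling(self):
        """Pure diffusion: mean step speed ~ sqrt(pi D / dt) (2-D Rayleigh mean)."""
        D, fps = 2.0, 5.0
        tracks, _ = synth_tracks(
            "uniform", speed=0.0, diffusivity=D, n_tracks=400, n_frames=40,
            fps=fps, seed=4,
        )
        est = clearance_speed(tracks, frame_interval=1 / fps)
        expected = np.sqrt(np.pi * D * fps)  # E|step|/dt for 2-D Gaussian steps
        assert est == pytest.approx(expected, rel=0.05)

    def test_cpb_arithmetic(self):
        assert compute_cpb(5.0, 5.0) == 1.0

    def test_cpb_human_means(self):
        """Ratio of the human grand means: 11.6 um/s over 2.9 Hz = 4 um/beat."""
        assert compute_cpb(11.6, 2.9) == pytest.approx(4.0, abs=0.01)

    def test_cpb_requires_positive_cbf(self):
        with pytest.raises(ValueError):
            compute_cpb(5.0, 0.0)


class TestCBF:
    def test_single_frequency_recovered(self):
        fmap = np.zeros((24, 24))
        fmap[4:20, 4:20] = 8.0
        movie, _ = synth_cbf_movie(fmap, fps=140.0, n_frames=280, noise_sd=0.05, seed=0)
        cbf_map, mean_cbf = estimate_cbf(movie, fps=140.0)
        assert mean_cbf == pytest.approx(8.0, abs=0.5)

    def test_two_region_movie_is_bimodal(self):
        """Two patches beating at 6 and 12 Hz in a static background resolve
        into a bimodal CBF map with the correct region means."""
        fmap = np.zeros((48, 48))
        fmap[10:38, 4:17] = 6.0
        fmap[10:38, 31:44] = 12.0
        movie, _ = synth_cbf_movie(fmap, fps=140.0, n_frames=280, noise_sd=0.05, seed=1)
        cbf_map, _ = estimate_cbf(movie, fps=140.0)
        left = np.nanmean(cbf_map[10:38, 4:17])
        right = np.nanmean(cbf_map[10:38, 31:44])
        assert left == pytest.approx(6.0, abs=0.5)
        assert right == pytest.approx(12.0, abs=0.5)

    def test_noisy_pixels_still_recovered(self):
        """SNR 1/2 (noise sd equal to signal amplitude) leaves the spectral
        peak intact; the variance threshold still separates beating pixels."""
        fmap = np.zeros((24, 24))
        fmap[4:20, 4:20] = 8.0
        movie, _ = synth_cbf_movie(fmap, fps=140.0, n_frames=280, noise_sd=1.0,
                                   amplitude=1.0, seed=2)
        _, mean_cbf = estimate_cbf(movie, fps=140.0, variance_factor=1.15)
        assert mean_cbf == pytest.approx(8.0, abs=0.5)

    def test_static_movie_raises_no_signal(self, rng):
        movie = np.broadcast_to(rng.random((16, 16)), (100, 16, 16)).copy()
        with pytest.raises(ValueError):
            estimate_cbf(movie, fps=100.0)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_cbf(rng.random((32, 8, 8)), fps=100.0)
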