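"""Wall-bounded regularized Stokeslet flow: boundary condition, decay, assembly."""

import numpy as np
import pytest

from ciliaflow.epithelium import EpitheliumSpec, generate_epithelium
from ciliaflow.hydrodynamics import (
    StokesletSystem,
    assemble_stokeslets,
    compute_velocity_field,
    evaluate_velocity,
    free_space_stokeslet,
    stokeslet_velocity_halfspace,
)

H = 7.0
EPS = 2.5
FORCE = np.array([1.0, 0.4, 0.0])


class TestWallKernel:
    def test_no_slip_on_the_wall(self, rng):
        """Velocity vanishes on z=0 to machine precision relative to the peak."""
        wall = np.column_stack([rng.uniform(-80, 80, (300, 2)), np.zeros(300)])
        u_wall = stokeslet_velocity_halfspace(wall, [0, 0, H], FORCE, EPS)
        tip = np.column_stack([rng.uniform(-80, 80, (300, 2)), np.full(300, H)])
        u_tip = stokeslet_velocity_halfspace(tip, [0, 0, H], FORCE, EPS)
        assert np.abs(u_wall).max() < 1e-10 * np.abs(u_tip).max()

    def test_regular_at_the_singularity_location(self):
        u = stokeslet_velocity_halfspace([[0.0, 0.0, H]], [0, 0, H], FORCE, EPS)
        assert np.all(np.isfinite(u))

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            stokeslet_velocity_halfspace([[0, 0, -1.0]], [0, 0, H], FORCE, EPS)

    def test_far_field_quadratic_decay(self):
        """Away from the wall plane the image system decays as a stresslet, 1/r^2."""
        d = np.logspace(2.0, 3.2, 12)
        pts = np.column_stack([d / np.sqrt(2), np.zeros(12), d / np.sqrt(2)])
        speed = np.linalg.norm(
            stokeslet_velocity_halfspace(pts, [0, 0, H], [1, 0, 0], EPS), axis=1
        )
        slope = np.polyfit(np.log(d), np.log(speed), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_wall_plane_decay_is_cubic(self):
        """At fixed height the wall screens interactions to 1/r^3 (stronger
        than free space), the screening that justifies truncating periodic
        sums at one image."""
        d = np.logspace(2.0, 3.2, 12)
        pts = np.column_stack([d, np.zeros(12), np.full(12, H)])
        speed = np.linalg.norm(
            stokeslet_velocity_halfspace(pts, [0, 0, H], [1, 0, 0], EPS), axis=1
        )
        slope = np.polyfit(np.log(d), np.log(speed), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.1)

    def test_matches_free_space_form_far_from_wall(self):
        """With the wall far below, the image corrections become negligible."""
        h_far = 5000.0
        pts = np.column_stack(
            [np.linspace(-30, 30, 11), np.linspace(-20, 20, 11), np.full(11, h_far)]
        )
        u_wall = stokeslet_velocity_halfspace(pts, [0, 0, h_far], FORCE, EPS)
        u_free = free_space_stokeslet(pts, [0, 0, h_far], FORCE, EPS)
        assert np.abs(u_wall - u_free).max() < 0.01 * np.abs(u_free).max()


class TestAssembly:
    def test_no_ciliated_cells_gives_zero_field(self):
        spec = EpitheliumSpec(n_rows=6, n_cols=6, coverage=0.0, seed=0)
        from ciliaflow.epithelium import assign_ciliated_patches, build_cell_lattice

        cells = build_cell_lattice(spec)
        assign_ciliated_patches(cells)
        system = assemble_stokeslets(cells)
        field = compute_velocity_field(system, grid_spacing=5.0)
        assert np.all(field.u == 0) and np.all(field.v == 0)

    def test_force_linearity(self, small_epithelium):
        s1 = assemble_stokeslets(small_epithelium, force_constant=1.0)
        s2 = assemble_stokeslets(small_epithelium, force_constant=2.0)
        f1 = compute_velocity_field(s1, grid_spacing=10.0)
        f2 = compute_velocity_field(s2, grid_spacing=10.0)
        assert np.allclose(f2.u, 2 * f1.u, rtol=1e-12, atol=1e-14)

    def test_aligned_angles_give_pure_x_net_force(self):
        spec = EpitheliumSpec(
            n_rows=8, n_cols=8, coverage=0.5, beat_order_target=1.0, seed=1
        )
        cells = generate_epithelium(spec)
        system = assemble_stokeslets(cells)
        assert np.allclose(system.forces[:, 1], 0.0)
        assert np.allclose(system.forces[:, 2], 0.0)
        assert np.all(system.forces[:, 0] > 0)

    def test_superposition_of_systems(self, rng):
        """Field of a concatenated system equals the sum of the parts."""
        extent = (200.0, 200.0)
        p1 = np.column_stack([rng.uniform(0, 200, (5, 2)), np.full(5, H)])
        p2 = np.column_stack([rng.uniform(0, 200, (4, 2)), np.full(4, H)])
        f1 = np.column_stack([rng.normal(size=(5, 2)), np.zeros(5)])
        f2 = np.column_stack([rng.normal(size=(4, 2)), np.zeros(4)])
        pts = np.column_stack([rng.uniform(0, 200, (30, 2)), np.full(30, H)])
        kw = dict(epsilon=EPS, extent=extent)
        ua = evaluate_velocity(StokesletSystem(p1, f1, **kw), pts)
        ub = evaluate_velocity(StokesletSystem(p2, f2, **kw), pts)
        uc = evaluate_velocity(
            StokesletSystem(np.vstack([p1, p2]), np.vstack([f1, f2]), **kw), pts
        )
        assert np.allclose(uc, ua + ub, rtol=1e-12, atol=1e-14)


class TestPeriodicField:
    def test_translation_by_one_period_is_invariant(self, small_epithelium):
        s = assemble_stokeslets(small_epithelium)
        ref = compute_velocity_field(s, grid_spacing=10.0)
        shifted = StokesletSystem(
            s.positions + np.array([s.extent[0], 0.0, 0.0]),
            s.forces,
            epsilon=s.epsilon,
            extent=s.extent,
            truncation_radius=s.truncation_radius,
        )
        out = compute_velocity_field(shifted, grid_spacing=10.0, height=ref.height)
        assert np.allclose(out.u, ref.u, rtol=1e-10, atol=1e-13)

    def test_truncation_matches_brute_force_images(self):
        """Truncated periodic sum vs direct 5x5-image summation near the source."""
        extent = (120.0, 120.0)
        pos = np.array([[60.0, 60.0, H]])
        force = np.array([[1.0, 0.0, 0.0]])
        sys_tr = StokesletSystem(pos, force, epsilon=EPS, extent=extent,
                                 truncation_radius=250.0)
        pts = np.column_stack(
            [np.linspace(40, 80, 9), np.linspace(40, 80, 9), np.full(9, H)]
        )
        u_tr = evaluate_velocity(sys_tr, pts)
        u_bf = np.zeros_like(u_tr)
        for i in range(-2, 3):
            for j in range(-2, 3):
                u_bf += stokeslet_velocity_halfspace(
                    pts, pos[0] + np.array([i * 120.0, j * 120.0, 0.0]), force[0], EPS
                )
        assert np.abs(u_tr - u_bf).max() < 0.02 * np.abs(u_bf).max()

    def test_mirror_pair_has_no_net_flow(self):
        """Mirror-image Stokeslets with opposite forces cancel the mean flow."""
        extent = (100.0, 100.0)
        pos = np.array([[50.0, 30.0, H], [50.0, 70.0, H]])
        force = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        system = StokesletSystem(pos, force, epsilon=EPS, extent=extent)
        field = compute_velocity_field(system, grid_spacing=2.5, height=H)
        assert abs(field.u.mean()) < 1e-10 * np.abs(field.u).max()

    def test_interpolation_error_small_against_direct_evaluation(self, rng):
        spec = EpitheliumSpec(n_rows=12, n_cols=12, coverage=0.6, seed=3)
        cells = generate_epithelium(spec)
        system = assemble_stokeslets(cells)
        field = compute_velocity_field(system, grid_spacing=2.5)
        pts2d = rng.uniform(0, 120, (100, 2))
        interp = field.interpolate(pts2d)
        direct = evaluate_velocity(
            system, np.column_stack([pts2d, np.full(100, field.height)])
        )[:, :2]
        scale = np.abs(direct).max()
        assert np.percentile(np.abs(interp - direct), 95) < 0.03 * scale


class TestFieldProperties:
    def test_mean_flow_aligns_with_beat_direction_at_high_order(self):
        spec = EpitheliumSpec(
            n_rows=15, n_cols=15, coverage=0.8, beat_order_target=1.0,
            mean_beat_direction=0.0, seed=2,
        )
        cells = generate_epithelium(spec)
        field = compute_velocity_field(assemble_stokeslets(cells), grid_spacing=5.0)
        angle = np.arctan2(field.v.mean(), field.u.mean())
        assert abs(np.degrees(angle)) < 2.0

    def test_no_slip_for_full_assembly(self, small_epithelium, rng):
        system = assemble_stokeslets(small_epithelium)
        wall_pts = np.column_stack([rng.uniform(0, 200, (100, 2)), np.zeros(100)])
        tip_pts = np.column_stack(
            [rng.uniform(0, 200, (100, 2)), np.full(100, system.positions[0, 2])]
        )
        u_wall = evaluate_velocity(system, wall_pts)
        u_tip = evaluate_velocity(system, tip_pts)
        assert np.abs(u_wall).max() < 1e-6 * np.abs(u_tip).max()
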