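"""Structure-analysis tests: density fields, phase classification against
constructed reference morphologies, diffusivity on constructed random walks,
and the pressure-tensor tension estimator."""

import numpy as np
import pytest

from cubiphase.dpd_engine import (BeadSystem, DPDParams, Trajectory,
                                  box_for_counts, run)
from cubiphase.struct_analysis import (DensityField, classify_phase,
                                       percolates, surface_tension,
                                       water_density_field,
                                       water_diffusivity)
from cubiphase.synthetic_data import gen_density_field


def make_water_traj(frames, box, unwrapped=None, pressure=None):
    nw = frames.shape[1]
    return Trajectory(frames=frames, unwrapped=unwrapped if unwrapped is not None
                      else frames.copy(),
                      velocities=None, times=np.arange(1.0, len(frames) + 1),
                      types=np.full(nw, 2), box=np.asarray(box, float),
                      pressure_diag=pressure)


class TestDensityField:
    def test_conserves_water_count(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 10, (6, 2000, 3))
        fld = water_density_field(make_water_traj(frames, [10, 10, 10]), grid_n=12)
        assert fld.total_count() == pytest.approx(2000, rel=1e-9)

    def test_uniform_box_voxel_statistics_are_poissonian(self):
        """Coefficient of variation of voxel counts ~ 1/sqrt(mean count)."""
        rng = np.random.default_rng(5)
        n_frames, nw = 5, 3000
        frames = rng.uniform(0, 10, (n_frames, nw, 3))
        fld = water_density_field(make_water_traj(frames, [10, 10, 10]), grid_n=10)
        counts = fld.grid * fld.voxel_volume          # mean beads per voxel
        cv = counts.std() / counts.mean()
        expected = 1.0 / np.sqrt(n_frames * nw / 1000)
        assert cv == pytest.approx(expected, rel=0.2)

    def test_empty_region_stays_zero(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 5, (3, 500, 3))      # all beads in one octant
        fld = water_density_field(make_water_traj(frames, [10, 10, 10]), grid_n=10)
        assert fld.grid[5:, :, :].sum() == 0.0

    def test_averaging_static_frames_is_idempotent(self):
        rng = np.random.default_rng(2)
        one = rng.uniform(0, 10, (1, 800, 3))
        many = np.repeat(one, 7, axis=0)
        f1 = water_density_field(make_water_traj(one, [10, 10, 10]), grid_n=8)
        f7 = water_density_field(make_water_traj(many, [10, 10, 10]), grid_n=8)
        np.testing.assert_allclose(f1.grid, f7.grid)

    def test_requires_water(self):
        t = make_water_traj(np.zeros((1, 4, 3)), [10, 10, 10])
        t.types = np.full(4, 1)                       # all tail beads
        with pytest.raises(ValueError, match="water"):
            water_density_field(t)


class TestPercolation:
    def test_full_and_empty(self):
        full = np.ones((8, 8, 8), bool)
        assert all(percolates(full, ax) for ax in range(3))
        assert not any(percolates(~full, ax) for ax in range(3))

    def test_slab_spans_in_plane_only(self):
        slab = np.zeros((8, 8, 8), bool)
        slab[:, :, 2:4] = True
        assert percolates(slab, 0) and percolates(slab, 1)
        assert not percolates(slab, 2)

    def test_periodic_face_contact_merges_components(self):
        """Two half-columns joined only across the periodic x-face span z."""
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, 0:5] = True       # half-column at x=0
        mask[7, 0, 3:8] = True       # half-column at x=7, overlapping in z
        assert percolates(mask, 2)   # connected through the x-boundary
        disjoint = np.zeros((8, 8, 8), bool)
        disjoint[0, 0, 0:4] = True
        disjoint[7, 0, 5:8] = True   # no shared face across the boundary
        assert not percolates(disjoint, 2)


class TestClassifyPhase:
    def test_single_cosine_is_lamellar(self):
        z = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        grid = 1.0 + np.cos(z)[None, None, :] * np.ones((32, 32, 1))
        call = classify_phase(DensityField(grid=grid, box=np.array([8.0, 8.0, 8.0])))
        assert call.label == "lamellar"
        assert call.diagnostics["dominant_axis_power_frac"] > 0.99

    def test_schwarz_d_nodal_field_is_bicontinuous(self):
        """Both level sets of the D nodal surface percolate triply."""
        fld, _ = gen_density_field("bicontinuous_cubic", grid_n=32)
        call = classify_phase(fld)
        assert call.label == "bicontinuous_cubic"
        assert all(call.diagnostics["percolation_water_rich"])
        assert all(call.diagnostics["percolation_water_poor"])

    def test_white_noise_is_disordered(self):
        rng = np.random.default_rng(3)
        grid = 1.0 + rng.normal(0, 0.05, (32, 32, 32))
        call = classify_phase(DensityField(grid=np.maximum(grid, 0),
                                           box=np.array([8.0, 8.0, 8.0])))
        assert call.label == "disordered"
        assert call.diagnostics["spectrum_flat"]

    def test_constant_field_is_disordered_with_warning(self):
        call = classify_phase(DensityField(grid=np.full((16, 16, 16), 2.0),
                                           box=np.array([8.0, 8.0, 8.0])))
        assert call.label == "disordered"
        assert "warning" in call.diagnostics

    @pytest.mark.parametrize("phase", ["bicontinuous_cubic", "lamellar"])
    def test_axis_relabeling_preserves_label(self, phase):
        fld, _ = gen_density_field(phase, grid_n=32, noise=0.02, seed=4)
        base = classify_phase(fld).label
        for perm in [(1, 2, 0), (2, 0, 1), (1, 0, 2)]:
            rotated = DensityField(grid=np.transpose(fld.grid, perm),
                                   box=fld.box[list(perm)])
            assert classify_phase(rotated).label == base


class TestDiffusivity:
    def test_frozen_beads_have_zero_diffusivity(self):
        frames = np.repeat(np.random.default_rng(0).uniform(0, 10, (1, 200, 3)),
                           20, axis=0)
        res = water_diffusivity(make_water_traj(frames, [10, 10, 10]))
        assert res.D_water == pytest.approx(0.0, abs=1e-12)
        assert res.msd_curve[0] == 0.0

    @pytest.mark.parametrize("D", [0.05, 0.25, 1.0])
    def test_recovers_constructed_random_walk(self, D):
        """Random walk with per-axis step variance 2 D dt recovers D within 5%."""
        rng = np.random.default_rng(int(1000 * D))
        nf, nw, dt = 5000, 500, 1.0
        steps = rng.normal(0, np.sqrt(2 * D * dt), (nf, nw, 3))
        unw = np.cumsum(steps, axis=0)
        box = np.array([50.0, 50.0, 50.0])
        traj = make_water_traj(unw % box, box, unwrapped=unw)
        res = water_diffusivity(traj)
        assert res.D_water == pytest.approx(D, rel=0.05)

    def test_msd_of_diffusive_walk_is_nondecreasing_smoothed(self):
        rng = np.random.default_rng(9)
        unw = np.cumsum(rng.normal(0, 0.5, (400, 300, 3)), axis=0)
        box = np.array([30.0, 30.0, 30.0])
        res = water_diffusivity(make_water_traj(unw % box, box, unwrapped=unw))
        smooth = np.convolve(res.msd_curve, np.ones(9) / 9, mode="valid")
        assert np.all(np.diff(smooth) > -1e-6 * smooth.max())

    def test_wrapped_only_trajectory_rejected(self):
        frames = np.random.default_rng(0).uniform(0, 10, (20, 50, 3))
        traj = make_water_traj(frames, [10, 10, 10])
        traj.unwrapped = None
        with pytest.raises(ValueError, match="unwrapped"):
            water_diffusivity(traj)


class TestSurfaceTension:
    def test_estimator_formula_on_known_pressure(self):
        p = np.tile([2.0, 1.0, 4.0], (10, 1))
        traj = make_water_traj(np.zeros((10, 5, 3)), [8.0, 8.0, 10.0], pressure=p)
        res = surface_tension(traj, axis=2)
        # gamma = L/2 * (Pzz - (Pxx+Pyy)/2) = 5 * (4 - 1.5) = 12.5
        assert res.gamma_mean == pytest.approx(12.5)
        res_x = surface_tension(traj, axis=0)
        assert res_x.gamma_mean == pytest.approx(4.0 * (2.0 - 2.5))

    def test_homogeneous_fluid_tension_vanishes(self, pure_water_run):
        traj, _ = pure_water_run
        for ax in range(3):
            assert abs(surface_tension(traj, axis=ax).gamma_mean) < 0.05

    def test_estimator_isotropic_for_homogeneous_fluid(self, pure_water_run):
        traj, _ = pure_water_run
        g = [surface_tension(traj, axis=ax).gamma_mean for ax in range(3)]
        assert max(g) - min(g) < 0.1

    def test_demixed_slab_has_positive_tension(self, demixed_slab_run):
        traj = demixed_slab_run
        res = surface_tension(traj, axis=2)
        assert res.gamma_mean > 0.5

    def test_missing_pressure_rejected(self):
        traj = make_water_traj(np.zeros((3, 4, 3)), [8, 8, 8])
        with pytest.raises(ValueError, match="pressure"):
            surface_tension(traj)


def test_single_step_matches_python_integration_oracle(small_mixed_system,
                                                       a_default):
    """One modified-velocity-Verlet step, including the stored kinetic
    temperature and pressure tensor, equals a pure-python re-derivation
    built on the all-pairs force oracle."""
    from test_dpd_engine import brute_forces

    system, _ = small_mixed_system
    params = DPDParams(seed=11, n_steps=1, equil_steps=0, sample_every=1)
    traj = run(system, params, a_default)

    pos0, vel0 = system.positions.copy(), system.velocities.copy()
    f0, _ = brute_forces(system, params, a_default, step=0, seed=params.seed)
    dt = params.dt
    pos1 = (pos0 + dt * vel0 + 0.5 * dt * dt * f0) % system.box
    vtilde = vel0 + params.lam * dt * f0
    stepped = BeadSystem(box=system.box, positions=pos1, velocities=vtilde,
                         types=system.types, bonds=system.bonds)
    f1, vir1 = brute_forces(stepped, params, a_default, step=1, seed=params.seed)
    vel1 = vel0 + 0.5 * dt * (f0 + f1)
    n = system.n_beads
    vol = float(np.prod(system.box))
    np.testing.assert_allclose(traj.frames[0], pos1, atol=1e-10)
    np.testing.assert_allclose(traj.velocities[0], vel1, atol=1e-10)
    assert traj.kinetic_T[0] == pytest.approx(np.sum(vel1**2) / (3 * n), abs=1e-10)
    p_expected = (np.sum(vel1**2, axis=0) + vir1) / vol
    np.testing.assert_allclose(traj.pressure_diag[0], p_expected, atol=1e-10)
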