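"""DPD engine tests: composition mapping, initialization, forces (against a
brute-force pair-enumeration oracle), integration properties and I/O."""

import numpy as np
import pytest

from cubiphase.dpd_engine import (BeadSystem, DPDParams, Formulation,
                                  box_for_counts, init_system,
                                  map_composition, pair_forces, pair_theta,
                                  read_formulation_table, read_xyz, run,
                                  write_xyz)
from cubiphase.synthetic_data import default_formulation_table


def brute_forces(system, params, a_mat, step=0, seed=None, random=True,
                 dissipative=True):
    """Test-local oracle: enumerate all pairs, no neighbor lists."""
    seed = params.seed if seed is None else seed
    n = system.n_beads
    pos, vel, box = system.positions, system.velocities, system.box
    f = np.zeros((n, 3))
    virial = np.zeros(3)
    inv_sqrt_dt = 1.0 / np.sqrt(params.dt)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d)
            if r >= 1.0 or r < 1e-12:
                continue
            e = d / r
            w = 1.0 - r
            a = a_mat[system.types[i], system.types[j]]
            fc = a * w
            virial += fc * e * d
            fmag = fc
            if dissipative:
                fmag -= params.gamma * w * w * np.dot(e, vel[i] - vel[j])
            if random:
                fmag += params.sigma * w * pair_theta(seed, step, i, j, n) * inv_sqrt_dt
            f[i] += fmag * e
            f[j] -= fmag * e
    for i, j in system.bonds:
        d = pos[i] - pos[j]
        d -= box * np.rint(d / box)
        r = np.linalg.norm(d)
        fb = -params.bond_k * (r - params.bond_r0) * d / r
        f[i] += fb
        f[j] -= fb
        virial += fb * d
    return f, virial


class TestMapComposition:
    def test_no_ethanol_formulation_maps_to_zero_ethanol_beads(self):
        f1 = default_formulation_table()[0]
        counts, _ = map_composition(f1, n_target=3000)
        assert counts["ETHANOL"] == 0

    def test_pure_water_hits_target(self):
        f = Formulation("w", {"GMO": 0, "ETHANOL": 0, "WATER": 100, "MET": 0})
        counts, _ = map_composition(f, n_target=1000)
        assert counts["WATER"] == 1000
        assert counts["A"] == counts["B"] == counts["MET"] == 0

    def test_f4_water_share_of_non_gmo_beads(self):
        # mole arithmetic with one water bead = 3 waters:
        # water 30/54 = 0.5556, ethanol 6/46.1, Met 5/165.6 -> water ~78%
        f4 = default_formulation_table()[3]
        counts, _ = map_composition(f4, n_target=3000)
        non_gmo = counts["WATER"] + counts["ETHANOL"] + counts["MET"]
        assert counts["WATER"] / non_gmo == pytest.approx(0.78, abs=0.02)

    def test_ab_counts_equal_and_total_near_target(self):
        for f in default_formulation_table():
            counts, fracs = map_composition(f, n_target=2000)
            assert counts["A"] == counts["B"]
            assert abs(sum(counts.values()) - 2000) <= 100
            assert sum(fracs.values()) == pytest.approx(1.0)

    def test_small_target_rejected(self):
        with pytest.raises(ValueError, match="n_target"):
            map_composition(default_formulation_table()[0], n_target=50)


class TestInitSystem:
    def test_momentum_zero_and_deterministic(self):
        params = DPDParams(seed=5)
        counts = {"A": 50, "B": 50, "WATER": 250}
        box = box_for_counts(counts)
        s1 = init_system(counts, box, params, seed=5)
        s2 = init_system(counts, box, params, seed=5)
        assert np.abs(s1.velocities.sum(axis=0)).max() < 1e-10
        np.testing.assert_array_equal(s1.positions, s2.positions)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)

    def test_equipartition_at_init(self):
        params = DPDParams(seed=6)
        counts = {"WATER": 3000}
        s = init_system(counts, box_for_counts(counts), params, seed=6)
        ke_per_bead = 0.5 * np.sum(s.velocities**2) / 3000
        assert ke_per_bead == pytest.approx(1.5 * params.kT, rel=0.05)

    def test_bond_partners_at_rest_length(self):
        params = DPDParams(seed=7)
        counts = {"A": 30, "B": 30, "WATER": 120}
        s = init_system(counts, box_for_counts(counts), params, seed=7)
        for i, j in s.bonds:
            d = s.positions[i] - s.positions[j]
            d -= s.box * np.rint(d / s.box)
            assert np.linalg.norm(d) == pytest.approx(params.bond_r0, abs=1e-9)

    def test_inconsistent_box_density_rejected(self):
        params = DPDParams()
        with pytest.raises(ValueError, match="inconsistent"):
            init_system({"WATER": 300}, np.array([20.0, 20.0, 20.0]), params, seed=0)


class TestPairForces:
    def test_conservative_magnitude_at_half_cutoff(self):
        # two like beads at r = 0.5: |F_C| = 25 * (1 - 0.5) = 12.5
        params = DPDParams()
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
        s = BeadSystem(box=np.array([4.0, 4.0, 4.0]), positions=pos,
                       velocities=np.zeros((2, 3)), types=np.array([2, 2]),
                       bonds=np.empty((0, 2), int))
        f, _ = pair_forces(s, params, np.full((5, 5), 25.0),
                           include_random=False, include_dissipative=False)
        assert np.linalg.norm(f[0]) == pytest.approx(12.5, abs=1e-12)
        np.testing.assert_allclose(f[0], -f[1], atol=1e-15)

    def test_zero_beyond_cutoff(self):
        params = DPDParams()
        pos = np.array([[1.0, 1.0, 1.0], [2.2, 1.0, 1.0]])
        s = BeadSystem(box=np.array([5.0, 5.0, 5.0]), positions=pos,
                       velocities=np.ones((2, 3)), types=np.array([2, 2]),
                       bonds=np.empty((0, 2), int))
        f, _ = pair_forces(s, params, np.full((5, 5), 25.0))
        np.testing.assert_array_equal(f, 0.0)

    def test_newtons_third_law_with_noise(self, small_mixed_system, a_default):
        system, params = small_mixed_system
        f, _ = pair_forces(system, params, a_default, step=17, seed=99)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_cell_list_matches_brute_force_oracle(self, small_mixed_system, a_default):
        """Cell-list forces (box >= 3 r_c) equal all-pairs enumeration,
        including the dissipative, random and (stretched) bond terms."""
        system, params = small_mixed_system
        # integrate briefly so bonds are away from their rest length and
        # velocities are correlated with structure
        p = DPDParams(seed=11, n_steps=100, equil_steps=0, sample_every=100)
        traj = run(system, p, a_default)
        evolved = BeadSystem(box=system.box, positions=traj.frames[-1],
                             velocities=traj.velocities[-1], types=system.types,
                             bonds=system.bonds)
        bond_r = [np.linalg.norm(
            (evolved.positions[i] - evolved.positions[j] + evolved.box / 2)
            % evolved.box - evolved.box / 2) for i, j in evolved.bonds]
        assert np.std(bond_r) > 1e-4    # genuinely stretched/compressed bonds
        f, vir = pair_forces(evolved, params, a_default, step=5, seed=42)
        f_ref, vir_ref = brute_forces(evolved, params, a_default, step=5, seed=42)
        np.testing.assert_allclose(f, f_ref, atol=1e-12)
        np.testing.assert_allclose(vir, vir_ref, atol=1e-10)

    def test_three_bead_fixture_matches_oracle(self):
        params = DPDParams(seed=0)
        pos = np.array([[0.2, 0.2, 0.2], [0.8, 0.3, 0.2], [0.5, 0.9, 0.6]])
        s = BeadSystem(box=np.array([2.0, 2.0, 2.0]), positions=pos,
                       velocities=np.array([[0.1, 0.0, -0.2], [0.0, 0.3, 0.0],
                                            [-0.1, -0.3, 0.2]]),
                       types=np.array([2, 3, 4]), bonds=np.empty((0, 2), int))
        a = np.full((5, 5), 30.0)
        f, vir = pair_forces(s, params, a, step=1, seed=7)
        f_ref, vir_ref = brute_forces(s, params, a, step=1, seed=7)
        np.testing.assert_allclose(f, f_ref, atol=1e-12)
        np.testing.assert_allclose(vir, vir_ref, atol=1e-12)


class TestRun:
    def test_deterministic_for_fixed_seed(self, a_uniform):
        params = DPDParams(seed=21, n_steps=300, equil_steps=100, sample_every=100)
        counts = {"WATER": 375}
        box = box_for_counts(counts)
        t1 = run(init_system(counts, box, params, seed=21), params, a_uniform)
        t2 = run(init_system(counts, box, params, seed=21), params, a_uniform)
        np.testing.assert_array_equal(t1.frames, t2.frames)
        np.testing.assert_array_equal(t1.pressure_diag, t2.pressure_diag)

    def test_thermostat_holds_unit_temperature(self, pure_water_run):
        traj, params = pure_water_run
        assert traj.kinetic_T.mean() == pytest.approx(1.0, rel=0.03)

    def test_momentum_conserved(self, pure_water_run):
        traj, _ = pure_water_run
        assert np.abs(traj.momentum).max() < 1e-8

    def test_ideal_gas_pressure(self):
        """With a_ij = 0 the virial vanishes on average: P -> rho*kT."""
        params = DPDParams(seed=9, n_steps=1500, equil_steps=500, sample_every=150)
        counts = {"WATER": 648}
        box = box_for_counts(counts)
        traj = run(init_system(counts, box, params, seed=9), params,
                   np.zeros((5, 5)))
        p_mean = traj.pressure_diag.mean()
        assert p_mean == pytest.approx(params.rho * params.kT
                                       * traj.kinetic_T.mean(), rel=0.02)

    def test_stretched_dimer_oscillates_about_rest_length(self):
        """Zero-noise, zero-repulsion bonded dimer: harmonic motion about r0."""
        params = DPDParams(gamma=0.0, sigma=0.0, dt=0.01, seed=0,
                           n_steps=400, equil_steps=0, sample_every=10)
        delta = 0.1
        pos = np.array([[2.0, 2.0, 2.0], [2.0 + params.bond_r0 + delta, 2.0, 2.0]])
        s = BeadSystem(box=np.array([4.0, 4.0, 4.0]), positions=pos,
                       velocities=np.zeros((2, 3)), types=np.array([0, 1]),
                       bonds=np.array([[0, 1]]))
        traj = run(s, params, np.zeros((5, 5)))
        d = traj.unwrapped[:, 0, :] - traj.unwrapped[:, 1, :]
        r = np.linalg.norm(d, axis=1)
        assert r.max() <= params.bond_r0 + delta + 1e-6   # energy bounded
        assert r.min() >= params.bond_r0 - delta - 1e-6
        assert r.mean() == pytest.approx(params.bond_r0, abs=0.02)
        assert r.min() < params.bond_r0 < r.max()          # actually oscillates

    def test_nonfinite_coordinates_abort_with_step(self):
        # an (extreme but finite) velocity overflows the first displacement;
        # the wrapped coordinate becomes NaN and the run must abort
        params = DPDParams(dt=50.0, seed=0, n_steps=10, equil_steps=0,
                           sample_every=1)
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
        s = BeadSystem(box=np.array([3.0, 3.0, 3.0]), positions=pos,
                       velocities=np.array([[1e308, 0, 0], [-1e308, 0, 0]]),
                       types=np.array([2, 2]), bonds=np.empty((0, 2), int))
        with pytest.raises(FloatingPointError, match="step"):
            run(s, params, np.zeros((5, 5)))


class TestFluctuationDissipation:
    def test_violating_sigma_rejected(self):
        with pytest.raises(ValueError, match="fluctuation"):
            DPDParams(gamma=4.5, sigma=1.0)

    def test_sigma_derived_from_gamma(self):
        assert DPDParams(gamma=4.5).sigma == pytest.approx(3.0)
        assert DPDParams(gamma=2.0).sigma == pytest.approx(2.0)


class TestIO:
    def test_xyz_round_trip(self, small_mixed_system, a_default, tmp_path):
        system, params = small_mixed_system
        p = DPDParams(seed=11, n_steps=200, equil_steps=0, sample_every=100)
        traj = run(system, p, a_default)
        path = tmp_path / "traj.xyz"
        write_xyz(traj, path)
        back = read_xyz(path)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-6)
        np.testing.assert_allclose(back.unwrapped, traj.unwrapped, atol=1e-6)
        np.testing.assert_allclose(back.box, traj.box, atol=1e-6)
        np.testing.assert_array_equal(back.types, traj.types)

    def test_formulation_table_round_trip(self, tmp_path):
        import pandas as pd

        table = default_formulation_table()
        path = tmp_path / "forms.csv"
        pd.DataFrame([{"name": f.name, "gmo": f.mass_parts["GMO"],
                       "ethanol": f.mass_parts["ETHANOL"],
                       "water": f.mass_parts["WATER"],
                       "met": f.mass_parts["MET"]} for f in table]
                     ).to_csv(path, index=False)
        back = read_formulation_table(path)
        assert [f.name for f in back] == [f.name for f in table]
        assert back[3].mass_parts == table[3].mass_parts


def test_formulation_invariants():
    with pytest.raises(ValueError):
        Formulation("bad", {"GMO": -1, "ETHANOL": 0, "WATER": 30, "MET": 5})
    with pytest.raises(ValueError):
        Formulation("bad", {"GMO": 0, "ETHANOL": 5, "WATER": 0, "MET": 1})
    f = Formulation("ok", {"GMO": 64, "ETHANOL": 6, "WATER": 30, "MET": 5})
    assert f.total == 105
    assert f.mass_fraction("MET") == pytest.approx(5 / 105)
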