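"""Trajectory operators against brute-force oracles and closed forms."""

import numpy as np
import pytest

from thermoflim.constants import KB_AMU_A2_PS2
from thermoflim import mdpost
from thermoflim.mdpost import (
    HBondCriteria,
    count_hydrogen_bonds,
    fit_chain_length_model,
    fit_relaxation_time,
    kinetic_temperature,
    msd_diffusivity,
    radial_distribution,
    radius_of_gyration,
    select_hydration_shell,
)
from thermoflim.synthetic import (
    RelaxationTruth,
    simulate_brownian_tracers,
    simulate_particle_config,
    simulate_relaxation_series,
)
from thermoflim.trajectory import TemperatureSeries, Trajectory, default_atoms_table


def min_image(v, box):
    return v - box * np.round(v / box)


class TestKineticTemperature:
    def test_zero_velocities_give_zero_kelvin(self):
        assert kinetic_temperature(np.zeros((10, 3)), np.ones(10)) == 0.0

    def test_single_atom_closed_form(self):
        # speed chosen so (1/2) m v^2 = (3/2) k_B 300
        m = 18.0
        v = np.sqrt(3 * KB_AMU_A2_PS2 * 300.0 / m)
        T = kinetic_temperature(np.array([[v, 0.0, 0.0]]), np.array([m]))
        assert T == pytest.approx(300.0, rel=1e-12)

    def test_maxwell_boltzmann_sample_recovers_bath(self):
        rng = np.random.default_rng(3)
        n = 100_000  # temperature sampling SD is T*sqrt(2/(3n)) ~ 1 K
        m = np.full(n, 18.0)
        sd = np.sqrt(KB_AMU_A2_PS2 * 400.0 / m)
        v = rng.normal(0, sd[:, None], size=(n, 3))
        assert kinetic_temperature(v, m) == pytest.approx(400.0, abs=2.0)

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            kinetic_temperature(np.zeros((0, 3)), np.zeros(0))


class TestRelaxationFit:
    def test_noiseless_tau_exact(self):
        s = simulate_relaxation_series(RelaxationTruth(tau_relax=5.0, duration=50.0))
        fit = fit_relaxation_time(s)
        assert fit.converged
        assert fit.tau_relax == pytest.approx(5.0, abs=1e-6)

    def test_constant_series_flagged_not_fitted(self):
        s = TemperatureSeries("c", np.arange(100.0), np.full(100, 300.0))
        fit = fit_relaxation_time(s)
        assert not fit.converged
        assert np.isnan(fit.tau_relax)

    def test_noisy_recovery_within_five_percent(self):
        s = simulate_relaxation_series(
            RelaxationTruth(tau_relax=5.0, noise_sd=2.0, seed=7)
        )
        fit = fit_relaxation_time(s)
        assert fit.tau_relax == pytest.approx(5.0, rel=0.05)

    def test_free_bath_fit_recovers_bath_temperature(self):
        s = simulate_relaxation_series(
            RelaxationTruth(tau_relax=8.0, noise_sd=1.0, seed=2)
        )
        fit = fit_relaxation_time(s, fix_T_bath=None)
        assert fit.converged
        assert fit.T_bath == pytest.approx(300.0, abs=1.0)
        assert fit.tau_relax == pytest.approx(8.0, rel=0.05)


class TestChainLengthModel:
    def test_two_points_interpolate_exactly(self):
        model = fit_chain_length_model(np.array([[6.0, 2.0], [30.0, 6.0]]), predict_at=42.0)
        assert model.slope == pytest.approx(4.0 / 24.0)
        assert model.prediction == pytest.approx(2.0 + 36.0 * 4.0 / 24.0)
        assert model.extrapolated

    def test_collinear_points_zero_residual(self):
        x = np.array([6.0, 30.0, 80.0])
        pts = np.column_stack([x, 1.0 + 0.07 * x])
        model = fit_chain_length_model(pts, predict_at=42.0)
        assert model.slope == pytest.approx(0.07, abs=1e-12)
        assert model.prediction == pytest.approx(1.0 + 0.07 * 42.0, abs=1e-10)
        assert not model.extrapolated

    def test_noisy_fit_equals_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        x = np.array([6.0, 30.0, 80.0, 120.0])
        y = 1.5 + 0.06 * x + rng.normal(0, 0.3, x.size)
        model = fit_chain_length_model(np.column_stack([x, y]), predict_at=None)
        # closed-form least squares
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], rel=1e-12)
        assert model.slope == pytest.approx(beta[1], rel=1e-12)

    def test_degenerate_lengths_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_chain_length_model(np.array([[6.0, 2.0], [6.0, 3.0]]))


class TestRadialDistribution:
    def test_fixed_pair_occupies_single_bin(self):
        traj, _ = simulate_particle_config("fixed_pair", {"d": 3.0, "box": 20.0})
        res = radial_distribution(traj, np.array([0]), np.array([1]), r_max=5.0)
        nz = np.flatnonzero(res.counts)
        assert nz.size == 1
        assert res.edges[nz[0]] <= 3.0 <= res.edges[nz[0] + 1]

    def test_ideal_gas_tends_to_unity(self):
        traj, _ = simulate_particle_config("ideal_gas", {"n": 1000, "box": 20.0}, seed=4)
        idx = np.arange(1000)
        res = radial_distribution(traj, idx, idx, r_max=9.5, bin_width=0.5)
        assert np.abs(res.g[4:] - 1.0).max() < 0.15

    def test_bin_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        box = np.array([8.0, 9.0, 10.0])
        coords = rng.uniform(0, box, size=(1, 10, 3))
        atoms = default_atoms_table(10)
        traj = Trajectory(coords=coords, atoms=atoms, box=box, dt=1.0)
        a = np.array([0, 1, 2, 3])
        b = np.array([2, 3, 4, 5, 6, 7, 8, 9])
        res = radial_distribution(traj, a, b, r_max=3.9, bin_width=0.2)
        oracle = np.zeros_like(res.counts)
        for i in a:
            for j in b:
                if i == j:
                    continue
                r = np.linalg.norm(min_image(coords[0, i] - coords[0, j], box))
                k = int(r // 0.2)
                if k < oracle.size:
                    oracle[k] += 1
        np.testing.assert_array_equal(res.counts, oracle)

    def test_minimum_image_violating_range_rejected(self):
        traj, _ = simulate_particle_config("ideal_gas", {"n": 10, "box": 10.0})
        with pytest.raises(ValueError, match="half"):
            radial_distribution(traj, np.arange(10), np.arange(10), r_max=6.0)


class TestHydrogenBonds:
    def test_no_acceptors_counts_zero(self):
        frame = np.zeros((2, 3))
        assert count_hydrogen_bonds(frame, np.array([0]), np.array([1]),
                                    np.array([], dtype=int)) == 0

    def test_constructed_scene_matches_truth(self):
        traj, truth = simulate_particle_config("hbond_scene", seed=5)
        hyd = traj.select("is_hydrogen")
        donors = traj.atoms["donor_index"].to_numpy()[hyd]
        n = count_hydrogen_bonds(
            traj.coords[0], donors, hyd, traj.select("is_acceptor"),
            HBondCriteria(), traj.box,
        )
        assert n == truth["n_true_bonds"]

    def test_random_scene_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        box = np.array([12.0, 12.0, 12.0])
        n_d = 10
        donors = np.arange(n_d)
        hydrogens = np.arange(n_d, 2 * n_d)
        acceptors = np.arange(2 * n_d, 2 * n_d + 30)
        coords = rng.uniform(0, 12.0, size=(50, 3))
        # put each hydrogen ~1 A from its donor so angles are meaningful
        coords[hydrogens] = coords[donors] + rng.normal(0, 0.5, (n_d, 3))
        crit = HBondCriteria(da_cutoff=4.5, angle_cutoff=120.0)
        got = count_hydrogen_bonds(coords, donors, hydrogens, acceptors, crit, box)
        expected = 0
        for d, h in zip(donors, hydrogens):
            for a in acceptors:
                r_da = np.linalg.norm(min_image(coords[d] - coords[a], box))
                v1 = min_image(coords[d] - coords[h], box)
                v2 = min_image(coords[a] - coords[h], box)
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if r_da <= crit.da_cutoff and ang >= crit.angle_cutoff:
                    expected += 1
        assert got == expected

    def test_hydrogen_without_donor_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(ValueError, match="donor"):
            count_hydrogen_bonds(frame, np.array([0]), np.array([1, 2]),
                                 np.array([0]))


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]]), np.array([0]),
                                  np.array([12.0])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        frame = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        rg = radius_of_gyration(frame, np.array([0, 1]), np.array([1.0, 1.0]))
        assert rg == pytest.approx(1.0, rel=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        frame = rng.normal(0, 5, size=(20, 3))
        masses = rng.uniform(1, 16, size=20)
        sel = np.arange(20)
        rg = radius_of_gyration(frame, sel, masses)
        com = (masses[:, None] * frame).sum(0) / masses.sum()
        oracle = np.sqrt((masses * ((frame - com) ** 2).sum(1)).sum() / masses.sum())
        assert rg == pytest.approx(oracle, rel=1e-12)

    def test_rigid_transform_invariance(self, rng):
        frame = rng.normal(0, 3, size=(15, 3))
        masses = rng.uniform(1, 20, size=15)
        sel = np.arange(15)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = frame @ R.T + np.array([5.0, -3.0, 11.0])
        assert radius_of_gyration(moved, sel, masses) == pytest.approx(
            radius_of_gyration(frame, sel, masses), rel=1e-10
        )

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            radius_of_gyration(np.zeros((2, 3)), np.array([0, 1]), np.zeros(2))

    def test_against_mdanalysis_reference(self, rng):
        mda = pytest.importorskip("MDAnalysis")
        frame = rng.normal(0, 4, size=(12, 3))
        masses = rng.uniform(1, 16, size=12)
        u = mda.Universe.empty(12, trajectory=True)
        u.add_TopologyAttr("masses", masses)
        u.atoms.positions = frame
        ours = radius_of_gyration(frame, np.arange(12), masses)
        assert ours == pytest.approx(float(u.atoms.radius_of_gyration()), rel=1e-6)


class TestHydrationShell:
    def test_tiny_cutoff_empty_selection(self):
        frame = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        sel = select_hydration_shell(frame, np.array([0]), np.array([1]), cutoff=1e-9)
        assert sel.size == 0

    def test_boundary_is_closed(self):
        frame = np.array([[0.0, 0, 0], [3.5, 0, 0]])
        sel = select_hydration_shell(frame, np.array([0]), np.array([1]), cutoff=3.5)
        assert list(sel) == [1]

    def test_matches_brute_force_distance_scan(self, rng):
        box = np.array([10.0, 10.0, 10.0])
        frame = rng.uniform(0, 10, size=(40, 3))
        protein = np.arange(10)
        waters = np.arange(10, 40)
        got = select_hydration_shell(frame, protein, waters, cutoff=3.0, box=box)
        expected = [
            w for w in waters
            if min(np.linalg.norm(min_image(frame[w] - frame[p], box))
                   for p in protein) <= 3.0
        ]
        assert list(got) == expected

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            select_hydration_shell(np.zeros((2, 3)), np.array([], dtype=int),
                                   np.array([0, 1]))


class TestMSD:
    def test_stationary_tracers_zero_diffusivity(self):
        traj = simulate_brownian_tracers(0.0, n_tracers=4, n_steps=50, seed=0)
        res = msd_diffusivity(traj)
        assert res.D == 0.0
        np.testing.assert_allclose(res.msd, 0.0, atol=1e-12)

    def test_ballistic_motion_flagged_non_diffusive(self):
        t = np.arange(100.0)
        coords = np.zeros((100, 1, 3))
        coords[:, 0, 0] = 2.0 * t  # constant velocity
        traj = Trajectory(coords=coords, atoms=default_atoms_table(1), dt=1.0)
        res = msd_diffusivity(traj)
        assert not res.diffusive
        # MSD = v^2 t^2 exactly under all-origin averaging
        lag = 10
        assert res.msd[lag] == pytest.approx((2.0 * lag) ** 2, rel=1e-9)

    def test_all_origin_msd_matches_naive_double_loop(self, rng):
        x = rng.normal(0, 1, size=(40, 1, 3)).cumsum(axis=0)
        traj = Trajectory(coords=x, atoms=default_atoms_table(1), dt=1.0)
        res = msd_diffusivity(traj)
        for lag in (1, 5, 17):
            disp = x[lag:, 0, :] - x[:-lag, 0, :]
            assert res.msd[lag] == pytest.approx((disp**2).sum(1).mean(), rel=1e-9)

    def test_brownian_recovery_within_five_percent(self):
        traj = simulate_brownian_tracers(2.8e-5, n_tracers=100, dt_ps=1.0,
                                         n_steps=1000, seed=1)
        res = msd_diffusivity(traj)
        assert res.D == pytest.approx(2.8e-5, rel=0.05)
        assert res.diffusive

    def test_wrapped_without_box_rejected(self):
        traj = simulate_brownian_tracers(1e-5, n_tracers=2, n_steps=10, seed=0)
        traj.wrapped = True
        with pytest.raises(ValueError, match="box"):
            msd_diffusivity(traj)

    def test_unwrapping_recovers_diffusivity_from_wrapped_coords(self):
        traj = simulate_brownian_tracers(2.8e-5, n_tracers=50, dt_ps=1.0,
                                         n_steps=500, seed=3)
        box = np.array([15.0, 15.0, 15.0])
        wrapped = Trajectory(
            coords=np.mod(traj.coords, box), atoms=traj.atoms, box=box,
            dt=1.0, wrapped=True,
        )
        res = msd_diffusivity(wrapped)
        assert res.D == pytest.approx(2.8e-5, rel=0.08)
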