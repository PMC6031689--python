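"""Integrator, thermostat, orientation and rigid-body dynamics."""

import dataclasses
import numpy as np
import pytest

from gelperm.dynamics import (RigidState, RunConfig, langevin_kick,
                              propagate_rigid, run_simulation, update_normals,
                              velocity_verlet_step)
from gelperm.forcefield import ForceFieldParams, compute_forces, np_pair
from gelperm.system import build_np_shell, place_nps

from conftest import free_bead_system


class TestVelocityVerlet:
    def test_zero_forces_zero_velocity_is_static(self):
        sys_ = free_bead_system(4, 12.0)
        sys_.velocities[:] = 0.0
        before = sys_.positions.copy()
        velocity_verlet_step(sys_, np.zeros((4, 3)), 0.01)
        assert np.array_equal(sys_.positions, before)

    def test_constant_force_gives_uniform_acceleration(self):
        sys_ = free_bead_system(1, 12.0)
        sys_.velocities[:] = 0.0
        start = sys_.positions.copy()
        f = np.array([[0.5, 0.0, 0.0]])
        n, dt = 200, 0.01
        for _ in range(n):
            velocity_verlet_step(sys_, f, dt)
        expected = 0.5 * 0.5 * (n * dt) ** 2
        assert np.isclose(sys_.positions[0, 0] - start[0, 0], expected,
                          rtol=0.01)

    def test_harmonic_oscillator_period(self):
        # k = m = 1: period 2 pi, recovered within 1% at dt = 0.01
        sys_ = free_bead_system(1, 40.0)
        sys_.velocities[:] = 0.0
        x0 = sys_.positions[0, 0]
        sys_.positions[0, 0] = x0 + 1.0
        center = x0

        def spring(s):
            f = np.zeros((1, 3))
            f[0, 0] = -(s.positions[0, 0] - center)
            return f

        dt = 0.01
        f = spring(sys_)
        prev = sys_.positions[0, 0] - center
        crossings = []
        for step in range(2000):
            _, f = velocity_verlet_step(sys_, f, dt, recompute=spring)
            x = sys_.positions[0, 0] - center
            if prev > 0 >= x:
                crossings.append(step * dt)
            prev = x
        period = crossings[1] - crossings[0]
        assert np.isclose(period, 2 * np.pi, rtol=0.01)

    def test_blow_up_guard(self):
        sys_ = free_bead_system(1, 12.0)
        sys_.velocities[0] = (100.0, 0.0, 0.0)
        with pytest.raises(RuntimeError):
            velocity_verlet_step(sys_, np.zeros((1, 3)), 0.01)


class TestLangevinKick:
    def test_zero_temperature_is_pure_damping(self):
        sys_ = free_bead_system(3, 12.0)
        sys_.velocities[:] = 1.0
        rng = np.random.default_rng(0)
        langevin_kick(sys_, gamma=2.0, temperature=0.0, dt=0.01, rng=rng)
        assert np.allclose(sys_.velocities, 1.0 * (1 - 2.0 * 0.01))

    def test_noise_variance_obeys_fluctuation_dissipation(self):
        sys_ = free_bead_system(2000, 200.0)
        sys_.velocities[:] = 0.0
        rng = np.random.default_rng(1)
        langevin_kick(sys_, gamma=1.0, temperature=0.5, dt=0.01, rng=rng)
        var = sys_.velocities.var()
        assert np.isclose(var, 2 * 1.0 * 0.5 * 0.01, rtol=0.05)


class TestNormals:
    def test_zero_torque_zero_noise_keeps_normals(self, small_mixed_system):
        before = small_mixed_system.normals.copy()
        update_normals(small_mixed_system,
                       np.zeros_like(before), 0.01)
        assert np.allclose(small_mixed_system.normals, before)

    def test_normals_stay_unit_after_any_update(self, small_mixed_system):
        rng = np.random.default_rng(0)
        tq = rng.normal(size=small_mixed_system.normals.shape)
        update_normals(small_mixed_system, tq, 0.05, temperature=0.3, rng=rng)
        sel = small_mixed_system.bead_type == 2
        norms = np.linalg.norm(small_mixed_system.normals[sel], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_pair_relaxes_to_energy_minimum_at_zero_temperature(self, ff):
        # two beads at fixed separation: normals relax to the minimizer
        from scipy.optimize import minimize

        r_vec = np.array([ff.np_rmin * 1.1, 0.0, 0.0])
        ni = np.array([0.6, 0.0, 0.8])
        nj = np.array([0.0, 0.6, 0.8])

        def pair_energy(angles):
            t1, p1, t2, p2 = angles
            a = np.array([np.sin(t1) * np.cos(p1), np.sin(t1) * np.sin(p1),
                          np.cos(t1)])
            b = np.array([np.sin(t2) * np.cos(p2), np.sin(t2) * np.sin(p2),
                          np.cos(t2)])
            return np_pair(r_vec, a, b, ff)[0]

        best = min(
            (minimize(pair_energy, x0, method="Nelder-Mead").fun
             for x0 in ([0.1, 0.1, 0.2, 0.3], [1.5, 0.0, 1.5, 0.0],
                        [0.9, 2.0, 2.2, 1.0])),
        )

        n1, n2 = ni.copy(), nj.copy()
        for _ in range(4000):
            _, _, _, g1, g2 = np_pair(r_vec, n1, n2, ff)
            for n, g in ((n1, g1), (n2, g2)):
                g = 0.02 * (g - (g @ n) * n)
                n += g
                n /= np.linalg.norm(n)
        relaxed = np_pair(r_vec, n1, n2, ff)[0]
        assert relaxed <= best + 1e-4


class TestRigidBody:
    @staticmethod
    def _state():
        body = build_np_shell(6.0, 1.8).bead_positions
        inertia = np.array([np.sum(body[:, 1]**2 + body[:, 2]**2),
                            np.sum(body[:, 0]**2 + body[:, 2]**2),
                            np.sum(body[:, 0]**2 + body[:, 1]**2)])
        return RigidState(com=np.zeros(3), velocity=np.zeros(3),
                          quat=np.array([1.0, 0, 0, 0]),
                          omega_body=np.zeros(3), inertia_body=inertia,
                          body_positions=body, mass=float(len(body)))

    def test_free_body_preserves_geometry_exactly(self):
        st = self._state()
        st.omega_body[:] = (0.3, -0.2, 0.5)
        st.velocity[:] = (0.1, 0.0, -0.05)
        d0 = np.linalg.norm(st.bead_positions()[0] - st.bead_positions()[5])
        for _ in range(500):
            st = propagate_rigid(st, np.zeros(3), np.zeros(3), 0.01)
        d1 = np.linalg.norm(st.bead_positions()[0] - st.bead_positions()[5])
        assert np.isclose(d0, d1, atol=1e-9)

    def test_constant_torque_spins_up_linearly(self):
        st = self._state()
        torque = np.array([0.0, 0.0, 2.0])   # about a principal axis
        n, dt = 1000, 0.01
        for _ in range(n):
            st = propagate_rigid(st, np.zeros(3), torque, dt)
        expected = torque[2] * n * dt / st.inertia_body[2]
        assert np.isclose(st.omega_body[2], expected, rtol=1e-3)

    def test_rigid_ellipsoid_keeps_exact_aspect_ratio_in_thermostat(self, ff):
        from gelperm.system import build_rigid_ellipsoid
        from gelperm.analysis import shape_metrics

        sys_ = free_bead_system(1, 30.0)
        sys_.positions[0] = 1.0
        model = build_rigid_ellipsoid(8.0, 2.0, 2.0)
        sys_ = place_nps(sys_, model, 1, min_clearance=0.0, seed=2)
        run = RunConfig(total_time=50.0, langevin_gamma=1.0, seed=3,
                        output_interval=100, centroid_interval=100)
        traj = run_simulation(sys_, ff, run)
        sh = shape_metrics(traj)
        assert np.isclose(sh.aspect_ratio.std(), 0.0, atol=1e-9)
        ar0 = sh.aspect_ratio[0, 0]
        assert np.allclose(sh.aspect_ratio, ar0, atol=1e-9)


class TestRunSimulation:
    def test_same_seed_is_bitwise_identical(self, small_mixed_system, ff):
        run = RunConfig(total_time=20.0, seed=9, output_interval=200,
                        centroid_interval=100)
        t1 = run_simulation(small_mixed_system.copy(), ff, run)
        t2 = run_simulation(small_mixed_system.copy(), ff, run)
        assert np.array_equal(t1.wrapped_positions, t2.wrapped_positions)
        assert np.array_equal(t1.energies, t2.energies)
        t3 = run_simulation(small_mixed_system.copy(), ff,
                            dataclasses.replace(run, seed=10))
        assert not np.array_equal(t1.wrapped_positions, t3.wrapped_positions)

    def test_unwrapped_equals_wrapped_modulo_box(self, small_mixed_system, ff):
        run = RunConfig(total_time=30.0, seed=4, output_interval=300,
                        centroid_interval=100)
        traj = run_simulation(small_mixed_system, ff, run)
        delta = traj.unwrapped_positions - traj.wrapped_positions
        ratio = delta / traj.box_length
        assert np.allclose(ratio, np.round(ratio), atol=1e-9)

    def test_blow_up_is_reported(self, small_mixed_system, ff):
        small_mixed_system.velocities[0] = (200.0, 0.0, 0.0)
        run = RunConfig(total_time=1.0, seed=1)
        with pytest.raises(RuntimeError, match="blow-up"):
            run_simulation(small_mixed_system, ff, run)

    def test_free_nanoparticle_is_diffusive_at_long_lags(self, ff):
        # a single shell NP without any network: MSD slope ~1 on log-log
        from gelperm.analysis import msd_3d

        sys_ = free_bead_system(1, 30.0)
        sys_.positions[0] = 1.0
        sys_ = place_nps(sys_, build_np_shell(6.0, 1.8), 1,
                         min_clearance=0.0, seed=6)
        run = RunConfig(total_time=2000.0, langevin_gamma=0.2, seed=5,
                        output_interval=0, centroid_interval=50,
                        store_frames=False)
        traj = run_simulation(sys_, ff, run)
        res = msd_3d(traj.np_centroids_unwrapped[:, :1, :],
                     traj.centroid_times, max_lag_fraction=0.25)
        # fit log-log slope over the upper lag decade
        sel = res.lags > res.lags[-1] / 10
        slope = np.polyfit(np.log(res.lags[sel]), np.log(res.msd[sel]), 1)[0]
        assert 0.8 < slope < 1.2
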