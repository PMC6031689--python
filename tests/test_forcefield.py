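"""Pair potentials and full-system force evaluation."""

import dataclasses
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelperm.forcefield import (ForceFieldParams, compute_forces,
                                harmonic_bond, lj_pair, np_pair)
from gelperm.system import place_nps, build_np_shell

from conftest import brute_force_reference, free_bead_system


class TestHarmonicBond:
    def test_rest_length(self):
        e, f = harmonic_bond(1.0, 100.0, 1.0)
        assert e == 0.0 and f == 0.0

    def test_direct_substitution(self):
        e, f = harmonic_bond(1.1, 100.0, 1.0)
        assert np.isclose(e, 1.0)
        assert np.isclose(abs(f), 2 * 100.0 * 0.1)
        assert f < 0  # restoring toward shorter r

    @given(st.floats(0.2, 3.0), st.floats(1.0, 200.0), st.floats(0.5, 2.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_force_is_negative_energy_gradient(self, r, k, r0):
        h = 1e-6
        _, f = harmonic_bond(r, k, r0)
        num = -(harmonic_bond(r + h, k, r0)[0]
                - harmonic_bond(r - h, k, r0)[0]) / (2 * h)
        assert np.isclose(f, num, atol=1e-5)


class TestLJ:
    def test_truncation(self):
        assert lj_pair(2.5, 1.0, 1.0, 2.5) == (0.0, 0.0)
        assert lj_pair(5.0, 1.0, 1.0, 2.5) == (0.0, 0.0)

    def test_unshifted_minimum(self):
        e, f = lj_pair(2 ** (1 / 6), 1.0, 1.0, 1e6)
        assert np.isclose(e, -1.0, atol=1e-9)
        assert np.isclose(f, 0.0, atol=1e-9)

    def test_energy_continuous_at_cutoff(self):
        e, _ = lj_pair(2.5 - 1e-9, 0.3, 1.0, 2.5)
        assert abs(e) < 1e-6

    @given(st.floats(0.8, 2.4), st.floats(0.01, 2.0), st.floats(0.8, 1.2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_force_is_negative_energy_gradient(self, r, eps, sigma):
        h = 1e-7
        _, f = lj_pair(r, eps, sigma, 2.5)
        num = -(lj_pair(r + h, eps, sigma, 2.5)[0]
                - lj_pair(r - h, eps, sigma, 2.5)[0]) / (2 * h)
        assert np.isclose(f, num, rtol=1e-4, atol=1e-5)


class TestShellPair:
    def test_zero_beyond_cutoff(self, ff):
        out = np_pair(np.array([ff.np_rcut + 0.1, 0, 0]),
                      np.array([0, 0, 1.0]), np.array([0, 0, 1.0]), ff)
        assert out[0] == 0.0
        for v in out[1:]:
            assert np.allclose(v, 0.0)

    def test_aligned_pair_sits_at_well_depth(self):
        # side-by-side beads, parallel normals perpendicular to r, theta0 = 0
        p = ForceFieldParams(np_theta0=0.0)
        u, fi, fj, gi, gj = np_pair(np.array([p.np_rmin, 0, 0]),
                                    np.array([0, 0, 1.0]),
                                    np.array([0, 0, 1.0]), p)
        assert np.isclose(u, -p.np_eps, atol=1e-12)

    def test_rejects_non_unit_normals(self, ff):
        with pytest.raises(ValueError):
            np_pair(np.array([2.0, 0, 0]), np.array([0, 0, 1.5]),
                    np.array([0, 0, 1.0]), ff)

    @pytest.mark.parametrize("theta0", [0.0, 0.26])
    def test_gradients_match_finite_differences(self, theta0):
        p = ForceFieldParams(np_theta0=theta0)
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(100):
            r_vec = rng.normal(size=3)
            r_vec *= rng.uniform(0.5 * p.np_rmin, p.np_rcut * 0.999) \
                / np.linalg.norm(r_vec)
            ni = rng.normal(size=3)
            ni /= np.linalg.norm(ni)
            nj = rng.normal(size=3)
            nj /= np.linalg.norm(nj)
            u, fi, fj, gi, gj = np_pair(r_vec, ni, nj, p, eps=2.5)
            for d in range(3):
                dv = np.zeros(3)
                dv[d] = h
                up = np_pair(r_vec + dv, ni, nj, p, eps=2.5)[0]
                um = np_pair(r_vec - dv, ni, nj, p, eps=2.5)[0]
                assert np.isclose(fj[d], -(up - um) / (2 * h), atol=1e-5)
                # torque: tangential derivative wrt the normal
                nip = (ni + dv) / np.linalg.norm(ni + dv)
                nim = (ni - dv) / np.linalg.norm(ni - dv)
                up = np_pair(r_vec, nip, nj, p, eps=2.5)[0]
                um = np_pair(r_vec, nim, nj, p, eps=2.5)[0]
                tang = gi - (gi @ ni) * ni
                assert np.isclose(tang[d], -(up - um) / (2 * h), atol=1e-4)

    def test_energy_and_force_continuous_at_rmin_and_rcut(self, ff):
        ni = np.array([0.3, 0.4, np.sqrt(1 - 0.25)])
        nj = np.array([0, 1.0, 0])
        for r0 in (ff.np_rmin, ff.np_rcut):
            lo = np_pair(np.array([r0 - 1e-8, 0, 0]), ni, nj, ff)
            hi = np_pair(np.array([r0 + 1e-8, 0, 0]), ni, nj, ff)
            assert np.isclose(lo[0], hi[0], atol=1e-6)
            assert np.allclose(lo[1], hi[1], atol=1e-5)


class TestComputeForces:
    def test_single_bead_no_interactions(self, ff):
        sys_ = free_bead_system(1, 12.0)
        res = compute_forces(sys_, ff)
        assert res.potential_energy == 0.0
        assert np.allclose(res.forces, 0.0)

    def test_matches_brute_force_on_mixed_system(self, small_mixed_system, ff):
        res = compute_forces(small_mixed_system, ff)
        e_ref, f_ref, tq_ref = brute_force_reference(small_mixed_system, ff)
        assert np.isclose(res.potential_energy, e_ref, rtol=1e-9, atol=1e-9)
        assert np.allclose(res.forces, f_ref, atol=1e-9)
        # torques agree up to components along the normals (immaterial)
        nrm = small_mixed_system.normals
        t1 = res.normal_torques - (res.normal_torques * nrm).sum(1, keepdims=True) * nrm
        t2 = tq_ref - (tq_ref * nrm).sum(1, keepdims=True) * nrm
        assert np.allclose(t1, t2, atol=1e-9)

    def test_newtons_third_law_without_tethers(self, ff):
        sys_ = free_bead_system(30, 14.0, seed=3)
        # squeeze beads together so they interact
        rng = np.random.default_rng(0)
        sys_.positions = np.mod(rng.uniform(4, 10, size=(30, 3)), 14.0)
        res = compute_forces(sys_, ff)
        assert np.abs(res.forces.sum(axis=0)).max() < 1e-8 * 30

    def test_breakdown_sums_to_total(self, small_mixed_system, ff):
        res = compute_forces(small_mixed_system, ff)
        assert np.isclose(sum(res.breakdown.values()), res.potential_energy,
                          atol=1e-9)

    def test_displaced_node_feels_harmonic_tether(self, small_network, ff):
        i = int(small_network.tether_idx[0])
        small_network.positions[i] += np.array([0.3, 0.0, 0.0])
        res = compute_forces(small_network, ff)
        # only the tether contributes at the anchor (bonds stay ~at rest
        # length only if neighbors moved too; so compare with the reference)
        _, f_ref, _ = brute_force_reference(small_network, ff)
        assert np.allclose(res.forces[i], f_ref[i], atol=1e-9)
        assert np.isclose(res.breakdown["tether"],
                          small_network.tether_k[0] * 0.3**2, atol=1e-9)

    def test_energy_invariant_under_rigid_motion(self, small_mixed_system, ff):
        # translating everything (tether anchors included) leaves E unchanged
        e0 = compute_forces(small_mixed_system, ff).potential_energy
        moved = small_mixed_system.copy()
        shift = np.array([1.7, -2.2, 0.9])
        moved.positions = np.mod(moved.positions + shift, moved.box_length)
        moved.tether_anchor = moved.tether_anchor + shift
        e1 = compute_forces(moved, ff).potential_energy
        assert np.isclose(e0, e1, atol=1e-9)

    def test_stiffer_shell_pays_more_for_the_same_dimple(self):
        # press a dimple into a shell: energy cost grows with np_eps
        shell = build_np_shell(8.0, 2.0)
        costs = []
        for eps in (1.0, 2.0, 4.0, 8.0):
            p = ForceFieldParams(np_rmin=2.0, np_rcut=3.4, np_eps=eps,
                                 eps_by_class={})
            sys_ = free_bead_system(1, 20.0)
            sys_.positions[0] = 1.0   # park the lone network bead far away
            sys_ = place_nps(sys_, shell, 1, min_clearance=0.0, seed=1)
            sys_.positions[1:] = np.mod(
                shell.bead_positions + 10.0, 20.0)   # reset: undo random rotation
            sys_.normals[1:] = shell.bead_normals
            e0 = compute_forces(sys_, p).potential_energy
            dimpled = sys_.copy()
            sel = shell.bead_positions[:, 2] > 3.2
            idx = 1 + np.flatnonzero(sel)
            dimpled.positions[idx, 2] -= 1.0
            e1 = compute_forces(dimpled, p).potential_energy
            costs.append(e1 - e0)
        assert all(b > a for a, b in zip(costs, costs[1:]))

    def test_rejects_box_smaller_than_twice_cutoff(self, ff):
        sys_ = free_bead_system(2, 6.0)
        with pytest.raises(ValueError):
            compute_forces(sys_, ff)
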