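"""Network, shell and placement construction."""

import numpy as np
import pytest

from gelperm.system import (NetworkSpec, NODE, NP_BEAD, build_network,
                            build_np_shell, build_rigid_ellipsoid, place_nps)


class TestNetwork:
    def test_reference_geometry_counts(self):
        # 98 sigma box with 16 sigma mesh: 6 cells/axis, 108 chains, 216 nodes
        spec = NetworkSpec(box_length=98.0, mesh_size=16.0)
        sys_ = build_network(spec)
        assert spec.n_chains == 108
        assert sys_.n_chains == 108
        assert int((sys_.bead_type == NODE).sum()) == 6**3

    @pytest.mark.parametrize("n", range(1, 9))
    def test_chain_count_formula(self, n):
        spec = (NetworkSpec(box_length=16.0, mesh_size=12.0, bead_spacing=2.0)
                if n == 1 else
                NetworkSpec(box_length=16.0 * n, mesh_size=16.0,
                            bead_spacing=2.0))
        assert spec.n_cells == n
        sys_ = build_network(spec)
        assert sys_.n_chains == 3 * n**2
        assert int((sys_.bead_type == NODE).sum()) == n**3

    def test_single_cell_lattice(self):
        # one mesh cell per axis: 3 chains crossing at a single shared node
        spec = NetworkSpec(box_length=16.0, mesh_size=12.0, bead_spacing=2.0)
        assert spec.n_cells == 1
        sys_ = build_network(spec)
        assert sys_.n_chains == 3
        assert int((sys_.bead_type == NODE).sum()) == 1

    def test_bond_rest_lengths_match_generated_spacing(self, small_network,
                                                       small_network_spec):
        s = small_network_spec.effective_spacing
        assert np.allclose(small_network.bond_r0, s, atol=1e-9)
        # and the actual generated distances equal the rest length
        pos = small_network.positions
        box = small_network.box_length
        d = pos[small_network.bond_i] - pos[small_network.bond_j]
        d -= box * np.round(d / box)
        assert np.allclose(np.linalg.norm(d, axis=1), s, atol=1e-9)

    def test_network_is_periodic(self, small_network):
        # shifting all beads by one box length maps the bead set onto itself
        pos = small_network.positions
        box = small_network.box_length
        for axis in range(3):
            shifted = pos.copy()
            shifted[:, axis] = np.mod(shifted[:, axis] + box, box)
            a = np.round(np.sort(pos, axis=0), 9)
            b = np.round(np.sort(shifted, axis=0), 9)
            assert np.allclose(a, b, atol=1e-9)

    def test_every_node_has_one_tether_at_initial_position(self, small_network):
        nodes = np.flatnonzero(small_network.bead_type == NODE)
        assert sorted(small_network.tether_idx) == sorted(nodes)
        assert np.allclose(small_network.tether_anchor,
                           small_network.positions[small_network.tether_idx])

    def test_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            NetworkSpec(box_length=10.0, mesh_size=16.0)
        with pytest.raises(ValueError):
            NetworkSpec(box_length=98.0, mesh_size=16.0, bead_spacing=-1.0)
        with pytest.raises(ValueError):
            # spacing larger than the mesh itself
            NetworkSpec(box_length=98.0, mesh_size=16.0, bead_spacing=16.5)


class TestShell:
    def test_every_bead_on_the_sphere(self):
        m = build_np_shell(10.0, 2.0)
        r = np.linalg.norm(m.bead_positions, axis=1)
        assert np.allclose(r, 5.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(m.bead_normals, axis=1), 1.0,
                           atol=1e-9)

    def test_bead_count_tracks_surface_area(self):
        # ~ pi d^2 / spacing^2 sites (area 100 pi at unit spacing)
        m = build_np_shell(10.0, 1.0)
        assert 251 <= m.n_beads <= 377

    def test_quasi_uniform_covering_is_balanced(self):
        m = build_np_shell(10.0, 1.0)
        assert np.linalg.norm(m.bead_normals.mean(axis=0)) < 0.05

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_np_shell(10.0, 6.0)   # < 12 beads
        with pytest.raises(ValueError):
            build_np_shell(-1.0, 1.0)


class TestEllipsoid:
    @pytest.mark.parametrize("ar", [2.0, 3.0])
    def test_equal_volume_semi_axes(self, ar):
        m = build_rigid_ellipsoid(10.0, ar, 1.5)
        r = 5.0
        a_exp = r * ar ** (2 / 3)
        b_exp = r * ar ** (-1 / 3)
        # every bead lies on the implicit surface with those semi-axes
        q = (m.bead_positions / np.array([a_exp, b_exp, b_exp]))**2
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-9)
        # exact closed-form volume equality
        assert np.isclose(a_exp * b_exp**2, r**3, atol=1e-9)

    def test_ar_one_degenerates_to_the_sphere(self):
        e = build_rigid_ellipsoid(10.0, 1.0, 1.5)
        s = build_np_shell(10.0, 1.5)
        assert np.allclose(e.bead_positions, s.bead_positions, atol=1e-9)

    def test_normals_are_outward_surface_normals(self):
        m = build_rigid_ellipsoid(10.0, 2.0, 1.5)
        # gradient of (x/a)^2+(y/b)^2+(z/b)^2 is parallel to the normal
        a = 5.0 * 2 ** (2 / 3)
        b = 5.0 * 2 ** (-1 / 3)
        grad = m.bead_positions / np.array([a * a, b * b, b * b])
        grad /= np.linalg.norm(grad, axis=1, keepdims=True)
        assert np.allclose(grad, m.bead_normals, atol=1e-9)

    def test_rejects_oblate_request(self):
        with pytest.raises(ValueError):
            build_rigid_ellipsoid(10.0, 0.5, 1.5)


class TestPlacement:
    def test_zero_count_is_identity(self, small_network):
        before = small_network.positions.copy()
        out = place_nps(small_network, build_np_shell(6.0, 2.0), 0, seed=1)
        assert out is small_network
        assert np.array_equal(out.positions, before)

    def test_clearance_holds_under_minimum_image(self):
        # the full-scale composition: 27 NPs of diameter 10 in the 98 box
        spec = NetworkSpec(box_length=98.0, mesh_size=16.0, bead_spacing=1.75)
        sys_ = build_network(spec)
        model = build_np_shell(10.0, 2.6)
        out = place_nps(sys_, model, 27, min_clearance=1.0, seed=3)
        assert out.n_nps == 27
        assert len(set(range(out.n_nps))) == 27
        box = out.box_length
        new = out.positions[out.np_membership >= 0]
        # brute-force double loop over (new bead, any other bead) pairs
        memb = out.np_membership
        pos = out.positions
        nb = model.n_beads
        start = sys_.n_beads
        for k in range(27):
            mine = pos[start + k * nb: start + (k + 1) * nb]
            other_sel = np.ones(out.n_beads, dtype=bool)
            other_sel[start + k * nb: start + (k + 1) * nb] = False
            others = pos[other_sel]
            d = mine[:, None, :] - others[None, :, :]
            d -= box * np.round(d / box)
            assert np.sqrt((d * d).sum(-1)).min() >= 1.0 - 1e-9

    def test_impossible_packing_raises(self, small_network):
        model = build_np_shell(10.0, 2.0)
        with pytest.raises(RuntimeError):
            place_nps(small_network, model, 50, min_clearance=2.0, seed=1,
                      max_attempts=200)

    def test_same_seed_reproduces_the_system(self, small_network):
        m = build_np_shell(6.0, 2.0)
        a = place_nps(small_network.copy(), m, 2, seed=11)
        b = place_nps(small_network.copy(), m, 2, seed=11)
        c = place_nps(small_network.copy(), m, 2, seed=12)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        assert not np.array_equal(a.positions, c.positions)
        # the network itself is identical across seeds
        nbead = small_network.n_beads
        assert np.array_equal(a.positions[:nbead], c.positions[:nbead])

    def test_velocities_are_thermal_with_zero_momentum(self, small_network):
        out = place_nps(small_network, build_np_shell(6.0, 2.0), 2, seed=5,
                        temperature=0.23)
        p = (out.masses[:, None] * out.velocities).sum(axis=0)
        assert np.allclose(p, 0.0, atol=1e-10)
        kinetic_temp = (out.masses[:, None]
                        * out.velocities**2).sum() / (3.0 * out.n_beads)
        assert np.isclose(kinetic_temp, 0.23, rtol=0.15)
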