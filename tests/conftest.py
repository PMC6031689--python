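"""Shared fixtures: small systems built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gelperm.forcefield import ForceFieldParams
from gelperm.system import (BeadSystem, NetworkSpec, build_network,
                            build_np_shell, place_nps)


@pytest.fixture(scope="session")
def ff() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture(scope="session")
def small_network_spec() -> NetworkSpec:
    # 2x2x2 mesh cells, 12 chains, box comfortably above twice the max cutoff
    return NetworkSpec(box_length=24.0, mesh_size=12.0, bead_spacing=1.5)


@pytest.fixture()
def small_network(small_network_spec) -> BeadSystem:
    return build_network(small_network_spec)


@pytest.fixture()
def small_mixed_system(small_network) -> BeadSystem:
    """Network plus one deformable and one rigid-ish NP, ~400 beads."""
    shell = build_np_shell(6.0, 1.8, rigidity_class="semi_elastic")
    return place_nps(small_network, shell, 2, min_clearance=0.8, seed=7)


def free_bead_system(n: int, box: float, seed: int = 0,
                     temperature: float = 0.23) -> BeadSystem:
    """n well-separated free beads (no bonds, no tethers)."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n ** (1 / 3)))
    grid = (np.stack(np.meshgrid(*[np.arange(side)] * 3), -1)
            .reshape(-1, 3)[:n] + 0.5) * (box / side)
    sys_ = BeadSystem(
        positions=np.mod(grid.astype(float), box),
        velocities=np.zeros((n, 3)),
        normals=np.zeros((n, 3)),
        bead_type=np.zeros(n, dtype=np.int8),
        np_membership=np.full(n, -1, dtype=np.int32),
        bond_i=np.zeros(0, dtype=np.int32),
        bond_j=np.zeros(0, dtype=np.int32),
        bond_k=np.zeros(0),
        bond_r0=np.zeros(0),
        tether_idx=np.zeros(0, dtype=np.int32),
        tether_anchor=np.zeros((0, 3)),
        tether_k=np.zeros(0),
        box_length=box,
        masses=np.ones(n),
    )
    from gelperm.system import maxwell_velocities
    sys_.velocities = maxwell_velocities(n, temperature, sys_.masses, rng)
    return sys_


def brute_force_reference(system: BeadSystem, params: ForceFieldParams):
    """O(N^2) all-pairs energy/force/torque reference built from the scalar
    pair functions; the independent oracle for the cell-list engine."""
    from gelperm.forcefield import lj_pair, np_pair, harmonic_bond, tether_force
    from gelperm.system import NP_BEAD

    n = system.n_beads
    box = system.box_length
    pos = system.positions
    f = np.zeros((n, 3))
    tq = np.zeros((n, 3))
    energy = 0.0
    bonded = {(min(i, j), max(i, j))
              for i, j in zip(system.bond_i, system.bond_j)}
    bead_eps = params.bead_np_eps(system)

    for b in range(len(system.bond_i)):
        i, j = int(system.bond_i[b]), int(system.bond_j[b])
        d = pos[i] - pos[j]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d)
        e, fr = harmonic_bond(r, system.bond_k[b], system.bond_r0[b])
        energy += e
        f[i] += fr * d / r
        f[j] -= fr * d / r
    for t in range(len(system.tether_idx)):
        i = int(system.tether_idx[t])
        d = pos[i] - system.tether_anchor[t]
        d -= box * np.round(d / box)
        e = system.tether_k[t] * float(d @ d)
        energy += e
        f[i] += -2.0 * system.tether_k[t] * d
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d)
            ti, tj = system.bead_type[i], system.bead_type[j]
            if ti == NP_BEAD and tj == NP_BEAD:
                if system.np_membership[i] == system.np_membership[j] and \
                        system.np_rigid[system.np_membership[i]]:
                    continue
                if r >= params.np_rcut:
                    continue
                eps = np.sqrt(bead_eps[i] * bead_eps[j])
                u, fi, fj, gi, gj = np_pair(d, system.normals[i],
                                            system.normals[j], params, eps=eps)
                energy += u
                f[i] += fi
                f[j] += fj
                tq[i] += gi
                tq[j] += gj
            elif ti == NP_BEAD or tj == NP_BEAD:
                from gelperm.forcefield import lj_pair
                e, fr = lj_pair(r, params.eps_pn, params.sigma_pn,
                                params.cutoff_pn)
                energy += e
                f[i] += -fr * d / r
                f[j] += fr * d / r
            else:
                if (min(i, j), max(i, j)) in bonded:
                    continue
                e, fr = lj_pair(r, params.eps_pp, params.sigma_pp,
                                params.cutoff_pp)
                energy += e
                f[i] += -fr * d / r
                f[j] += fr * d / r
    return energy, f, tq
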