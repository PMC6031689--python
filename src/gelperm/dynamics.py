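"""Time integration: velocity-Verlet, Langevin thermostat, orientation
dynamics and rigid-body propagation.

The production path is the compiled loop in :mod:`gelperm._kernels`;
the step functions here are the reference definitions of the individual
updates and are used directly in small-system tests.

The combination "NVE velocity-Verlet updates under a Langevin thermostat"
means: a standard half-kick/drift/half-kick step with the conservative
forces, followed by a per-bead friction + noise kick with the
fluctuation-dissipation variance 2 gamma kT dt / m^2 per velocity component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams
from .system import NP_BEAD, BeadSystem


@dataclass
class RunConfig:
    """Parameters of one simulation run (reduced LJ units).

    The default fit window (1.3e6, 1.8e6) tau matches the full-length
    protocol (total_time 2e6 tau); shorter runs scale it proportionally.
    """

    total_time: float
    dt: float = 0.01
    temperature: float = 0.23
    langevin_gamma: float = 1.0
    gamma_normal: float = 10.0
    seed: int = 0
    output_interval: int = 1000      # steps between stored frames
    centroid_interval: int = 100     # steps between stored NP centroids
    msd_fit_window: tuple[float, float] | None = None
    skin: float = 1.0
    store_frames: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.total_time < self.dt:
            raise ValueError("total_time must cover at least one step")
        win = self.fit_window
        if not (0 <= win[0] < win[1] <= self.total_time):
            raise ValueError("fit window must lie within [0, total_time]")

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    @property
    def fit_window(self) -> tuple[float, float]:
        if self.msd_fit_window is not None:
            return self.msd_fit_window
        # the full protocol fits 1.3e6..1.8e6 of 2e6 tau; scale proportionally
        return (0.65 * self.total_time, 0.9 * self.total_time)


@dataclass
class Trajectory:
    """Time-ordered frames of system state plus finely sampled NP centroids."""

    times: np.ndarray                       # (F,)
    wrapped_positions: np.ndarray           # (F, N, 3)
    unwrapped_positions: np.ndarray         # (F, N, 3)
    normals: np.ndarray                     # (F, N, 3)
    centroid_times: np.ndarray              # (C,)
    np_centroids_unwrapped: np.ndarray      # (C, n_np, 3)
    energies: np.ndarray                    # (F,) potential
    kinetic_energies: np.ndarray            # (F,)
    box_length: float
    bead_type: np.ndarray
    np_membership: np.ndarray
    np_class: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def temperature(self, n_dof: int) -> np.ndarray:
        """Instantaneous kinetic temperature per frame (kT in epsilon)."""
        return 2.0 * self.kinetic_energies / n_dof


# ---------------------------------------------------------------------------
# reference step operations
# ---------------------------------------------------------------------------

def velocity_verlet_step(system: BeadSystem, forces: np.ndarray, dt: float,
                         recompute=None):
    """One velocity-Verlet step (in place).  ``forces`` must be consistent
    with the current positions; ``recompute(system)`` supplies the forces at
    the new positions (defaults to reusing ``forces``, i.e. a constant field).

    Returns ``(system, new_forces)``.  Aborts if any bead moves more than
    0.5 sigma in one step.
    """
    m = system.masses[:, None]
    system.velocities += 0.5 * dt * forces / m
    disp = dt * system.velocities
    if np.max(np.abs(disp)) * math.sqrt(3.0) > _kernels.MAX_STEP_DISPLACEMENT:
        raise RuntimeError(
            "integration blow-up: a bead moved more than 0.5 sigma in one step"
        )
    system.positions = np.mod(system.positions + disp, system.box_length)
    new_forces = recompute(system) if recompute is not None else forces
    system.velocities += 0.5 * dt * new_forces / m
    return system, new_forces


def langevin_kick(system: BeadSystem, gamma: float, temperature: float,
                  dt: float, rng: np.random.Generator) -> BeadSystem:
    """Per-bead friction + Gaussian noise with the fluctuation-dissipation
    variance ``2 gamma kT dt / m^2`` per velocity component (momentum is not
    re-zeroed: the thermostat acts independently on each bead)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    m = system.masses[:, None]
    noise = rng.normal(0.0, 1.0, size=system.velocities.shape)
    system.velocities += (-gamma * system.velocities * dt / m
                          + noise * np.sqrt(2.0 * gamma * temperature * dt) / m)
    return system


def update_normals(system: BeadSystem, torques: np.ndarray, dt: float,
                   gamma_normal: float = 10.0, temperature: float = 0.0,
                   rng: np.random.Generator | None = None) -> BeadSystem:
    """First-order overdamped rotational Langevin update of shell normals.

    The generalized force ``-dU/dn`` (projected perpendicular to n) rotates
    each normal; thermal noise shares the thermostat temperature.  Normals
    are renormalized to unit length afterwards.
    """
    sel = system.bead_type == NP_BEAD
    n = system.normals[sel]
    g = torques[sel] * (dt / gamma_normal)
    if temperature > 0 and rng is not None:
        g = g + rng.normal(0.0, math.sqrt(2.0 * temperature * dt / gamma_normal),
                           size=g.shape)
    g -= (g * n).sum(axis=1, keepdims=True) * n
    n = n + g
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    system.normals[sel] = n
    return system


@dataclass
class RigidState:
    """Center-of-mass + orientation state of one rigid particle."""

    com: np.ndarray
    velocity: np.ndarray
    quat: np.ndarray                 # (w, x, y, z)
    omega_body: np.ndarray
    inertia_body: np.ndarray         # principal moments
    body_positions: np.ndarray       # (nb, 3) principal frame
    mass: float

    def rotation(self) -> np.ndarray:
        m = np.empty((3, 3))
        _quat_to_mat_py(self.quat, m)
        return m

    def bead_positions(self) -> np.ndarray:
        return self.com + self.body_positions @ self.rotation().T


def _quat_to_mat_py(q, m):
    w, x, y, z = q
    m[0] = (1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y))
    m[1] = (2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x))
    m[2] = (2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y))


def propagate_rigid(state: RigidState, force: np.ndarray, torque: np.ndarray,
                    dt: float) -> RigidState:
    """One rigid-body velocity-Verlet step under constant force/torque.

    Translation is ordinary velocity-Verlet on the center of mass; rotation
    advances the quaternion with the body-frame angular velocity (Euler terms
    included).  Internal geometry is preserved exactly.
    """
    state = replace(state, com=state.com.copy(), velocity=state.velocity.copy(),
                    quat=state.quat.copy(), omega_body=state.omega_body.copy())
    R = state.rotation()
    t_body = R.T @ torque
    I = state.inertia_body
    w = state.omega_body
    euler = np.array([(I[2] - I[1]) * w[1] * w[2],
                      (I[0] - I[2]) * w[2] * w[0],
                      (I[1] - I[0]) * w[0] * w[1]])
    w += 0.5 * dt * (t_body - euler) / I
    state.velocity += 0.5 * dt * force / state.mass
    state.com += dt * state.velocity
    w_space = R @ w
    ang = np.linalg.norm(w_space) * dt
    if ang > 1e-14:
        axis = w_space / np.linalg.norm(w_space)
        h = 0.5 * ang
        dq = np.array([math.cos(h), *(math.sin(h) * axis)])
        state.quat = _quat_mul(dq, state.quat)
        state.quat /= np.linalg.norm(state.quat)
    R = state.rotation()
    t_body = R.T @ torque
    w = state.omega_body
    euler = np.array([(I[2] - I[1]) * w[1] * w[2],
                      (I[0] - I[2]) * w[2] * w[0],
                      (I[1] - I[0]) * w[0] * w[1]])
    w += 0.5 * dt * (t_body - euler) / I
    state.velocity += 0.5 * dt * force / state.mass
    return state


def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


# ---------------------------------------------------------------------------
# production run
# ---------------------------------------------------------------------------

def run_simulation(system: BeadSystem, params: ForceFieldParams,
                   config: RunConfig) -> Trajectory:
    """Integrate the system and return the sampled trajectory.

    Deterministic for a given seed.  Raises ``RuntimeError`` on integrator
    blow-up (a displacement above 0.5 sigma in one step) or non-finite
    energies.
    """
    packed = _kernels.pack_system(system, params)
    n_steps = config.n_steps
    fe = config.output_interval if config.store_frames else 0
    ce = config.centroid_interval
    n_frames = n_steps // fe if fe else 0
    n_cents = n_steps // ce if ce else 0
    n = system.n_beads
    n_np = max(system.n_nps, 1)

    frames_pos = np.zeros((n_frames, n, 3))
    frames_img = np.zeros((n_frames, n, 3), dtype=np.int64)
    frames_nrm = np.zeros((n_frames, n, 3))
    frames_pe = np.zeros(n_frames)
    frames_ke = np.zeros(n_frames)
    cents = np.zeros((n_cents, n_np, 3))
    cent_times = np.zeros(n_cents)
    list_counts = np.zeros(4, dtype=np.int64)

    pp, n_pp, pn, n_pn, nn, n_nn, nn_eps = _kernels.build_pair_lists(
        packed, config.skin)
    r_pp, r_pn, r_nn = _kernels._list_radii(packed.ff, config.skin)
    ncell, cell_nbrs = _kernels.make_cell_table(packed.box,
                                                max(r_pp, r_pn, r_nn))

    status, steps_done = _kernels.run_loop(
        packed.pos, packed.img, packed.vel, packed.nrm, packed.masses,
        packed.btype, packed.np_id, packed.rigid_bead, packed.bead_eps,
        packed.bond_i, packed.bond_j, packed.bond_k, packed.bond_r0,
        packed.teth_i, packed.teth_anchor, packed.teth_k, packed.excl,
        packed.np_start, packed.np_count, packed.np_rigid,
        packed.body_pos, packed.body_nrm,
        packed.quat, packed.com, packed.com_vel, packed.omega, packed.inertia,
        packed.box, packed.ff,
        config.dt, config.langevin_gamma, config.gamma_normal,
        config.temperature, n_steps, np.uint64(config.seed & 0x7FFFFFFFFFFFFFFF),
        config.skin,
        ncell, cell_nbrs,
        pp, pn, nn, nn_eps, list_counts,
        fe, ce,
        frames_pos, frames_img, frames_nrm, frames_pe, frames_ke,
        cents, cent_times,
    )
    if status == _kernels.STATUS_BLOWUP:
        raise RuntimeError(
            f"integration blow-up at step {steps_done}: displacement per step "
            f"exceeded {_kernels.MAX_STEP_DISPLACEMENT} sigma"
        )
    if status == _kernels.STATUS_NAN:
        raise RuntimeError(f"non-finite energy at step {steps_done}")
    if status != _kernels.STATUS_OK:
        raise RuntimeError(f"neighbor-list overflow at step {steps_done}")

    # write final state back into the system
    system.positions[:] = packed.pos
    system.velocities[:] = packed.vel
    system.normals[:] = packed.nrm

    times = config.dt * fe * np.arange(1, n_frames + 1) if fe else np.zeros(0)
    box = system.box_length
    return Trajectory(
        times=times,
        wrapped_positions=frames_pos,
        unwrapped_positions=frames_pos + frames_img * box,
        normals=frames_nrm,
        centroid_times=cent_times,
        np_centroids_unwrapped=cents,
        energies=frames_pe,
        kinetic_energies=frames_ke,
        box_length=box,
        bead_type=system.bead_type.copy(),
        np_membership=system.np_membership.copy(),
        np_class=list(system.np_class),
    )
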