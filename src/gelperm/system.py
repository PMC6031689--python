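"""Construction of the cross-linked polymer network and shell nanoparticles.

The model system is a regular cubic lattice of bead-spring fibers (mesh size
``a = box/n`` with ``n = round(box/mesh)``) in which fibers parallel to the
three axes cross at shared, tethered node beads, plus nanoparticles (NPs)
represented as one-particle-thick closed shells of orientable beads.

All quantities are in reduced Lennard-Jones units: length sigma, mass m,
time tau, energy epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

# bead type codes
POLYMER = 0
NODE = 1
NP_BEAD = 2

BEAD_TYPE_NAMES = {POLYMER: "polymer", NODE: "node", NP_BEAD: "np_bead"}

RIGIDITY_CLASSES = ("soft", "semi_elastic", "hard", "rigid_sphere", "rigid_ellipsoid")
RIGID_CLASSES = ("rigid_sphere", "rigid_ellipsoid")

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class NetworkSpec:
    """Geometry and spring constants of the regular cross-linked network.

    Parameters
    ----------
    box_length:
        Cubic box edge (sigma).
    mesh_size:
        Requested fiber-to-fiber spacing (sigma).  The effective mesh is
        ``box_length / round(box_length / mesh_size)`` so that the network
        tiles the periodic box exactly.
    bead_spacing:
        Requested spacing of beads along each fiber (sigma); snapped so that
        an integer number of beads fits in each mesh cell (nodes must sit on
        the bead grid).
    bond_k:
        Harmonic bond constant (epsilon/sigma^2), energy ``k (r - r0)^2``.
    tether_k:
        Spring constant tethering each node bead to its initial position.
    """

    box_length: float = 98.0
    mesh_size: float = 16.0
    bead_spacing: float = 1.0
    bond_k: float = 100.0
    tether_k: float = 10.0

    def __post_init__(self) -> None:
        if not (self.box_length > self.mesh_size > self.bead_spacing > 0):
            raise ValueError("require box_length > mesh_size > bead_spacing > 0")
        if self.n_cells < 1:
            raise ValueError("mesh size larger than the box")
        if self.beads_per_cell < 1:
            raise ValueError(
                "bead_spacing does not fit the effective mesh: at least one "
                "bead per mesh cell is required"
            )
        if self.bond_k <= 0 or self.tether_k < 0:
            raise ValueError("spring constants must be positive")

    @property
    def n_cells(self) -> int:
        return int(round(self.box_length / self.mesh_size))

    @property
    def effective_mesh(self) -> float:
        return self.box_length / self.n_cells

    @property
    def beads_per_cell(self) -> int:
        return int(round(self.effective_mesh / self.bead_spacing))

    @property
    def effective_spacing(self) -> float:
        return self.effective_mesh / self.beads_per_cell

    @property
    def n_chains(self) -> int:
        return 3 * self.n_cells**2


@dataclass
class NPModel:
    """Body-frame template of one nanoparticle.

    Bead positions are centered on the origin and aligned with the particle's
    principal axes; normals are outward unit surface normals.
    """

    bead_positions: np.ndarray
    bead_normals: np.ndarray
    nominal_diameter: float
    rigidity_class: str
    aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.bead_positions = np.ascontiguousarray(self.bead_positions, dtype=np.float64)
        self.bead_normals = np.ascontiguousarray(self.bead_normals, dtype=np.float64)
        if self.rigidity_class not in RIGIDITY_CLASSES:
            raise ValueError(f"unknown rigidity class {self.rigidity_class!r}")
        if len(self.bead_positions) == 0:
            raise ValueError("NP model needs at least one bead")
        norms = np.linalg.norm(self.bead_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("bead normals must be unit length")

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def is_rigid(self) -> bool:
        return self.rigidity_class in RIGID_CLASSES


@dataclass
class BeadSystem:
    """Complete particle-level state of a simulation system.

    Positions are stored wrapped into ``[0, box_length)``; the integrator
    maintains a parallel unwrapped record via per-bead image counts.
    """

    positions: np.ndarray            # (N, 3) wrapped
    velocities: np.ndarray           # (N, 3)
    normals: np.ndarray              # (N, 3); zero rows for non-NP beads
    bead_type: np.ndarray            # (N,) int8
    np_membership: np.ndarray        # (N,) int32, -1 for network beads
    bond_i: np.ndarray               # (B,) int32
    bond_j: np.ndarray               # (B,) int32
    bond_k: np.ndarray               # (B,) float64
    bond_r0: np.ndarray              # (B,) float64
    tether_idx: np.ndarray           # (T,) int32 node bead indices
    tether_anchor: np.ndarray        # (T, 3)
    tether_k: np.ndarray             # (T,)
    box_length: float
    masses: np.ndarray               # (N,)
    n_chains: int = 0
    np_class: list[str] = field(default_factory=list)      # per NP
    np_rigid: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    np_start: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    np_count: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    body_positions: list[np.ndarray] = field(default_factory=list)  # per NP body frame
    body_normals: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if np.any(self.positions < 0) or np.any(self.positions >= self.box_length):
            raise ValueError("positions must be wrapped into [0, box_length)")
        if len(self.bond_i):
            if self.bond_i.min() < 0 or max(self.bond_i.max(), self.bond_j.max()) >= n:
                raise ValueError("bond index out of range")
            if np.any(self.bond_i == self.bond_j):
                raise ValueError("bond joins a bead to itself")
        node_idx = np.flatnonzero(self.bead_type == NODE)
        if sorted(self.tether_idx.tolist()) != sorted(node_idx.tolist()):
            raise ValueError("every node bead must have exactly one tether anchor")
        if len(self.np_class) != len(self.np_start):
            raise ValueError("per-NP metadata length mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_nps(self) -> int:
        return len(self.np_class)

    def np_slice(self, i: int) -> slice:
        return slice(int(self.np_start[i]), int(self.np_start[i] + self.np_count[i]))

    def copy(self) -> "BeadSystem":
        return replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            normals=self.normals.copy(),
            bead_type=self.bead_type.copy(),
            np_membership=self.np_membership.copy(),
            bond_i=self.bond_i.copy(),
            bond_j=self.bond_j.copy(),
            bond_k=self.bond_k.copy(),
            bond_r0=self.bond_r0.copy(),
            tether_idx=self.tether_idx.copy(),
            tether_anchor=self.tether_anchor.copy(),
            tether_k=self.tether_k.copy(),
            masses=self.masses.copy(),
            np_class=list(self.np_class),
            np_rigid=self.np_rigid.copy(),
            np_start=self.np_start.copy(),
            np_count=self.np_count.copy(),
            body_positions=[b.copy() for b in self.body_positions],
            body_normals=[b.copy() for b in self.body_normals],
        )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(spec: NetworkSpec) -> BeadSystem:
    """Build the regular cross-linked fiber network.

    Fibers run parallel to each axis on every grid line of the transverse
    n x n lattice and close on themselves through the periodic boundary.
    A single node bead is shared by the three fibers crossing at each lattice
    point and is tethered to its initial position.  Chain count is ``3 n^2``.
    """
    n = spec.n_cells
    a = spec.effective_mesh
    bpc = spec.beads_per_cell
    s = spec.effective_spacing
    m = n * bpc                     # beads per fiber
    box = spec.box_length

    n_nodes = n**3
    # node index (i, j, k) -> bead index
    def node_id(i: int, j: int, k: int) -> int:
        return (i % n) * n * n + (j % n) * n + (k % n)

    positions = [np.zeros((n_nodes, 3))]
    node_pos = positions[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                node_pos[node_id(i, j, k)] = (i * a, j * a, k * a)

    bead_count = n_nodes
    extra_pos: list[tuple[float, float, float]] = []
    bonds: list[tuple[int, int]] = []

    for axis in range(3):
        for u in range(n):
            for v in range(n):
                fiber: list[int] = []
                for t in range(m):
                    along = t * s
                    if t % bpc == 0:
                        c = t // bpc
                        ijk = [0, 0, 0]
                        ijk[axis] = c
                        ijk[(axis + 1) % 3] = u
                        ijk[(axis + 2) % 3] = v
                        fiber.append(node_id(*ijk))
                    else:
                        coord = [0.0, 0.0, 0.0]
                        coord[axis] = along
                        coord[(axis + 1) % 3] = u * a
                        coord[(axis + 2) % 3] = v * a
                        extra_pos.append(tuple(coord))
                        fiber.append(bead_count)
                        bead_count += 1
                for t in range(m):
                    bonds.append((fiber[t], fiber[(t + 1) % m]))

    pos = np.vstack([node_pos, np.asarray(extra_pos, dtype=np.float64).reshape(-1, 3)])
    pos = np.mod(pos, box)
    n_beads = len(pos)

    bead_type = np.full(n_beads, POLYMER, dtype=np.int8)
    bead_type[:n_nodes] = NODE
    bond_arr = np.asarray(bonds, dtype=np.int32)

    return BeadSystem(
        positions=pos,
        velocities=np.zeros((n_beads, 3)),
        normals=np.zeros((n_beads, 3)),
        bead_type=bead_type,
        np_membership=np.full(n_beads, -1, dtype=np.int32),
        bond_i=bond_arr[:, 0].copy(),
        bond_j=bond_arr[:, 1].copy(),
        bond_k=np.full(len(bonds), spec.bond_k),
        bond_r0=np.full(len(bonds), s),
        tether_idx=np.arange(n_nodes, dtype=np.int32),
        tether_anchor=node_pos.copy(),
        tether_k=np.full(n_nodes, spec.tether_k),
        box_length=box,
        masses=np.ones(n_beads),
        n_chains=spec.n_chains,
    )


# ---------------------------------------------------------------------------
# NP shells
# ---------------------------------------------------------------------------

def _fibonacci_sphere(count: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere covering (Fibonacci lattice)."""
    i = np.arange(count, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / count
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = _GOLDEN_ANGLE * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def build_np_shell(
    diameter: float,
    target_spacing: float,
    rigidity_class: str = "semi_elastic",
) -> NPModel:
    """Build a one-particle-thick spherical shell of orientable beads.

    Bead count is ``round(pi d^2 / spacing^2)`` (one bead per ``spacing^2`` of
    surface area); normals point radially outward.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not (0 < target_spacing < diameter):
        raise ValueError("require 0 < target_spacing < diameter")
    count = int(round(math.pi * diameter**2 / target_spacing**2))
    if count < 12:
        raise ValueError(
            f"target_spacing {target_spacing} yields only {count} beads (< 12)"
        )
    unit = _fibonacci_sphere(count)
    radius = diameter / 2.0
    return NPModel(
        bead_positions=radius * unit,
        bead_normals=unit,
        nominal_diameter=diameter,
        rigidity_class=rigidity_class,
        aspect_ratio=1.0,
    )


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    # Thomsen's approximation, exact for spheres, <1.1% error otherwise
    p = 1.6075
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def build_rigid_ellipsoid(
    reference_diameter: float,
    aspect_ratio: float,
    target_spacing: float,
) -> NPModel:
    """Build a rigid prolate spheroid of the same volume as the reference sphere.

    Semi-axes (a, b, b) with a/b = AR and (4/3) pi a b^2 = (4/3) pi r^3,
    i.e. b = r AR^(-1/3), a = r AR^(2/3).  Beads are a Fibonacci covering of
    the sphere mapped affinely onto the spheroid; normals are outward surface
    normals of the spheroid.
    """
    if aspect_ratio < 1.0:
        raise ValueError("aspect_ratio must be >= 1")
    r = reference_diameter / 2.0
    b = r * aspect_ratio ** (-1.0 / 3.0)
    a = r * aspect_ratio ** (2.0 / 3.0)
    count = int(round(_ellipsoid_area(a, b, b) / target_spacing**2))
    if count < 12:
        raise ValueError("target_spacing too coarse for this spheroid")
    unit = _fibonacci_sphere(count)
    pos = unit * np.array([a, b, b])
    normals = pos / np.array([a * a, b * b, b * b])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return NPModel(
        bead_positions=pos,
        bead_normals=normals,
        nominal_diameter=reference_diameter,
        rigidity_class="rigid_ellipsoid",
        aspect_ratio=aspect_ratio,
    )


# ---------------------------------------------------------------------------
# NP placement
# ---------------------------------------------------------------------------

def maxwell_velocities(
    n: int, temperature: float, masses: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at kT = temperature, net momentum zeroed."""
    v = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(temperature / masses)[:, None]
    p = (masses[:, None] * v).sum(axis=0)
    v -= p / masses.sum()
    return v


def place_nps(
    system: BeadSystem,
    model: NPModel,
    count: int,
    min_clearance: float = 1.0,
    seed: int = 0,
    temperature: float = 0.23,
    max_attempts: int = 10000,
    label: str | None = None,
) -> BeadSystem:
    """Insert ``count`` copies of ``model`` at random positions and orientations.

    Placements are rejected when any new bead lies within ``min_clearance`` of
    any existing bead under the minimum-image convention.  On success (count
    > 0) all bead velocities are redrawn from the Maxwell-Boltzmann
    distribution at ``temperature`` with the total momentum zeroed.
    Raises ``RuntimeError`` after ``max_attempts`` rejected placements.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if min_clearance < 0:
        raise ValueError("min_clearance must be >= 0")
    if count == 0:
        return system

    rng = np.random.default_rng(seed)
    box = system.box_length
    sys_ = system.copy()

    positions = [sys_.positions]
    normals = [sys_.normals]
    new_np_pos: list[np.ndarray] = []
    new_np_nrm: list[np.ndarray] = []
    placed = 0
    attempts = 0
    tree = cKDTree(np.mod(np.vstack(positions), box), boxsize=box)
    while placed < count:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {placed}/{count} NPs after {max_attempts} attempts; "
                "the packing is too dense for the requested clearance"
            )
        attempts += 1
        rot = Rotation.from_quat(_random_quaternion(rng))
        center = rng.uniform(0.0, box, size=3)
        pos = np.mod(rot.apply(model.bead_positions) + center, box)
        if min_clearance > 0:
            hits = tree.query_ball_point(pos, r=min_clearance)
            if any(len(h) for h in hits):
                continue
        nrm = rot.apply(model.bead_normals)
        new_np_pos.append(pos)
        new_np_nrm.append(nrm)
        positions.append(pos)
        normals.append(nrm)
        tree = cKDTree(np.mod(np.vstack(positions), box), boxsize=box)
        placed += 1

    n_old = sys_.n_beads
    nb = model.n_beads
    all_pos = np.vstack(positions)
    all_nrm = np.vstack(normals)
    n_new_total = count * nb
    n_total = n_old + n_new_total

    np_idx_offset = sys_.n_nps
    membership = np.concatenate(
        [sys_.np_membership,
         np.repeat(np.arange(np_idx_offset, np_idx_offset + count, dtype=np.int32), nb)]
    )
    bead_type = np.concatenate([sys_.bead_type, np.full(n_new_total, NP_BEAD, dtype=np.int8)])
    masses = np.concatenate([sys_.masses, np.ones(n_new_total)])

    sys_.positions = all_pos
    sys_.normals = all_nrm
    sys_.bead_type = bead_type
    sys_.np_membership = membership
    sys_.masses = masses
    sys_.np_class = sys_.np_class + [label or model.rigidity_class] * count
    sys_.np_rigid = np.concatenate([sys_.np_rigid, np.full(count, model.is_rigid)])
    sys_.np_start = np.concatenate(
        [sys_.np_start,
         (n_old + nb * np.arange(count)).astype(np.int32)]
    ).astype(np.int32)
    sys_.np_count = np.concatenate(
        [sys_.np_count, np.full(count, nb, dtype=np.int32)]
    ).astype(np.int32)
    sys_.body_positions = sys_.body_positions + [model.bead_positions.copy() for _ in range(count)]
    sys_.body_normals = sys_.body_normals + [model.bead_normals.copy() for _ in range(count)]
    sys_.velocities = maxwell_velocities(n_total, temperature, masses, rng)
    sys_.validate()
    return sys_


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
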