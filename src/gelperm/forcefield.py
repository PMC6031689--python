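"""Interaction model: bonds, tethers, Lennard-Jones pairs, and the
orientation-weighted soft-core potential between nanoparticle shell beads.

Shell beads carry an outward unit normal ``n`` and interact through the
one-particle-thick membrane potential

    u(r, n_i, n_j) = u_R(r) + [1 - phi] eps_np          for r < r_min
    u(r, n_i, n_j) = u_A(r) phi                         for r_min <= r < r_cut

    u_R(r) = eps_np [ (r_min/r)^4 - 2 (r_min/r)^2 ]
    u_A(r) = -eps_np cos^(2 zeta)( (pi/2) (r - r_min) / (r_cut - r_min) )
    phi    = 1 + mu (a - 1)
    a      = (n_i x rhat).(n_j x rhat) + sin(theta0) (n_j - n_i).rhat
             - sin^2(theta0)

``eps_np`` (the depth of the aligned-pair well) is the rigidity dial: a stiff
shell resists bending because misaligning neighbor normals costs ``mu eps_np``
per pair.  The potential and its first derivative vanish continuously at
``r_cut``; forces and normal torques are exact gradients of ``u``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .system import NP_BEAD, BeadSystem

SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)

#: Presets mapping the rigidity taxonomy onto the shell interaction strength
#: (in epsilon).  Calibrated on the shape taxonomy in the gel: the hard shell
#: stays spherical (aspect ratio within ~2% of the constructed shell's), the
#: semi-elastic shell transiently buckles into ellipsoids, and the soft shell
#: deforms persistently and irregularly (AR drifting >15% above the
#: constructed shell) while wrapping the fibers it adheres to.
RIGIDITY_PRESETS: dict[str, float] = {
    "soft": 0.2,
    "semi_elastic": 1.0,
    "hard": 6.0,
}


@dataclass
class ForceFieldParams:
    """All interaction constants, in reduced LJ units.

    ``eps_pn`` is the polymer-NP attraction (the robustness scans cover
    0.02-0.2 epsilon); polymer-polymer contacts are purely repulsive (WCA).
    ``np_eps`` is the default shell-bead interaction strength used when an NP
    carries no rigidity-class preset.
    """

    eps_pp: float = 1.0            # polymer-polymer WCA strength
    eps_pn: float = 0.1            # polymer-NP LJ well depth (adhesion)
    sigma_pp: float = 1.0
    sigma_pn: float = 1.5          # mean of polymer bead (1) and shell bead (~2)
    cutoff_pp: float = SIXTH_ROOT_2  # WCA: repulsive-only
    cutoff_pn: float = 3.75        # 2.5 sigma_pn
    np_eps: float = 4.0            # shell-bead pair strength (rigidity dial)
    np_rmin: float = 2.6           # shell-bead equilibrium spacing
    np_rcut: float = 4.42          # 1.7 np_rmin
    np_zeta: int = 4
    np_mu: float = 3.0
    np_theta0: float = 0.0
    bond_k: float = 100.0
    tether_k: float = 10.0
    eps_by_class: dict[str, float] = field(default_factory=lambda: dict(RIGIDITY_PRESETS))

    def __post_init__(self) -> None:
        for name in ("eps_pp", "eps_pn", "np_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.np_rmin < self.np_rcut):
            raise ValueError("require 0 < np_rmin < np_rcut")
        if self.cutoff_pp <= 0 or self.cutoff_pn <= 0:
            raise ValueError("LJ cutoffs must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoff_pp * self.sigma_pp / self.sigma_pp,
                   self.cutoff_pn, self.np_rcut)

    @property
    def lj_eps(self) -> dict[tuple[str, str], float]:
        """Type-pair map view of the LJ strengths."""
        return {("polymer", "polymer"): self.eps_pp, ("polymer", "np_bead"): self.eps_pn}

    def bead_np_eps(self, system: BeadSystem) -> np.ndarray:
        """Per-bead shell interaction strength (0 for network beads)."""
        eps = np.zeros(system.n_beads)
        for i in range(system.n_nps):
            cls = system.np_class[i]
            eps[system.np_slice(i)] = self.eps_by_class.get(cls, self.np_eps)
        return eps


@dataclass
class ForceResult:
    """Forces, orientation torques and the per-term energy breakdown."""

    forces: np.ndarray
    normal_torques: np.ndarray
    potential_energy: float
    breakdown: dict[str, float]


# ---------------------------------------------------------------------------
# scalar pair kernels (the reference definitions; the compiled engine in
# _kernels.py evaluates the same expressions)
# ---------------------------------------------------------------------------

def harmonic_bond(r: float, k: float, r0: float) -> tuple[float, float]:
    """Energy ``k (r - r0)^2`` and scalar radial force ``-dU/dr``."""
    if r <= 0:
        raise ValueError("r must be positive")
    return k * (r - r0) ** 2, -2.0 * k * (r - r0)


def lj_pair(r: float, eps: float, sigma: float, cutoff: float) -> tuple[float, float]:
    """Cut-and-shifted 12-6 Lennard-Jones energy and radial force ``-dU/dr``."""
    if r <= 0:
        raise ValueError("r must be positive")
    if r >= cutoff:
        return 0.0, 0.0
    sr6 = (sigma / r) ** 6
    sc6 = (sigma / cutoff) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (sc6 * sc6 - sc6)
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return e, f


def np_pair(
    r_vec: np.ndarray,
    n_i: np.ndarray,
    n_j: np.ndarray,
    params: ForceFieldParams,
    eps: float | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Orientation-weighted soft-core interaction of two shell beads.

    ``r_vec`` points from bead i to bead j.  Returns
    ``(energy, force_on_i, force_on_j, torque_on_n_i, torque_on_n_j)`` where
    the torques are the generalized forces ``-dU/dn`` on the orientation
    vectors (their component along ``n`` is immaterial: the integrator keeps
    normals unit length).
    """
    r_vec = np.asarray(r_vec, dtype=np.float64)
    n_i = np.asarray(n_i, dtype=np.float64)
    n_j = np.asarray(n_j, dtype=np.float64)
    if abs(np.linalg.norm(n_i) - 1.0) > 1e-6 or abs(np.linalg.norm(n_j) - 1.0) > 1e-6:
        raise ValueError("normals must be unit vectors")
    e = params.np_eps if eps is None else eps
    rmin, rcut = params.np_rmin, params.np_rcut
    zeta, mu, theta0 = params.np_zeta, params.np_mu, params.np_theta0

    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise ValueError("zero separation")
    zero = np.zeros(3)
    if r >= rcut:
        return 0.0, zero, zero.copy(), zero.copy(), zero.copy()

    rhat = r_vec / r
    st0 = math.sin(theta0)
    ni_r = float(n_i @ rhat)
    nj_r = float(n_j @ rhat)
    a = float(n_i @ n_j) - ni_r * nj_r + st0 * (nj_r - ni_r) - st0 * st0
    phi = 1.0 + mu * (a - 1.0)

    if r < rmin:
        x2 = (rmin / r) ** 2
        u = e * (x2 * x2 - 2.0 * x2) + (1.0 - phi) * e
        du_dr = e * (-4.0 * x2 * x2 + 4.0 * x2) / r
        du_da = -mu * e
    else:
        psi = 0.5 * math.pi * (r - rmin) / (rcut - rmin)
        c = math.cos(psi)
        ua = -e * c ** (2 * zeta)
        dua_dr = e * 2 * zeta * c ** (2 * zeta - 1) * math.sin(psi) \
            * 0.5 * math.pi / (rcut - rmin)
        u = phi * ua
        du_dr = phi * dua_dr
        du_da = mu * ua

    # gradients of a
    da_dni = n_j - nj_r * rhat - st0 * rhat
    da_dnj = n_i - ni_r * rhat + st0 * rhat
    da_drhat = -(nj_r * n_i + ni_r * n_j) + st0 * (n_j - n_i)
    # dU/d(r_vec): radial part + orientation part through rhat
    grad = du_dr * rhat + du_da * (da_drhat - (da_drhat @ rhat) * rhat) / r
    f_j = -grad          # r_vec = r_j - r_i
    f_i = grad
    g_i = -du_da * da_dni
    g_j = -du_da * da_dnj
    return u, f_i, f_j, g_i, g_j


def tether_force(pos: np.ndarray, anchor: np.ndarray, k: float) -> tuple[float, np.ndarray]:
    """Harmonic tether ``k |x - anchor|^2``; force ``-2k (x - anchor)``."""
    d = pos - anchor
    return k * float(d @ d), -2.0 * k * d


# ---------------------------------------------------------------------------
# full-system evaluation
# ---------------------------------------------------------------------------

def compute_forces(system: BeadSystem, params: ForceFieldParams) -> ForceResult:
    """Evaluate all forces, normal torques and the energy breakdown.

    Pair terms are evaluated under the minimum-image convention with a
    cell-list neighbor search; bonded (1-2) pairs are excluded from non-bonded
    terms, shell-bead pairs use the orientation-weighted potential, all other
    non-bonded pairs use (possibly purely repulsive) Lennard-Jones.
    """
    from . import _kernels

    if system.box_length < 2.0 * params.max_cutoff:
        raise ValueError("box must be at least twice the largest cutoff")
    packed = _kernels.pack_system(system, params)
    f, tq, terms = _kernels.evaluate_forces(packed)
    breakdown = {
        "bond": terms[0], "tether": terms[1], "wca": terms[2],
        "lj": terms[3], "np": terms[4],
    }
    return ForceResult(
        forces=f,
        normal_torques=tq,
        potential_energy=float(sum(breakdown.values())),
        breakdown=breakdown,
    )
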