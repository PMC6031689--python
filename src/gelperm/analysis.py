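"""Simulation observables: 3D MSD, fitted diffusivity (D = k/6), NP-polymer
contact counts, and gyration-tensor shape metrics.

MSD uses all time origins (sliding-window average) and averages over all
particles supplied; the diffusivity is the ordinary least-squares slope k of
MSD versus lag over the fit window, divided by 6.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .system import NP_BEAD, BeadSystem
from .dynamics import Trajectory


@dataclass
class MSDResult:
    lags: np.ndarray            # (L,) lag times (tau)
    msd: np.ndarray             # (L,) ensemble MSD (sigma^2)
    n_particles: int
    diffusivity: float | None = None
    fit_slope: float | None = None
    fit_window: tuple[float, float] | None = None


@dataclass
class ContactSeries:
    times: np.ndarray
    per_np_contacts: np.ndarray    # (F, n_np) int
    cutoff: float


@dataclass
class ShapeSeries:
    times: np.ndarray
    aspect_ratio: np.ndarray       # (F, n_np)
    gyration_eigenvalues: np.ndarray  # (F, n_np, 3) ascending
    degenerate: np.ndarray         # (F, n_np) bool


def msd_3d(centroids_unwrapped: np.ndarray, times: np.ndarray,
           lags: np.ndarray | None = None, box_length: float | None = None,
           max_lag_fraction: float = 0.5) -> MSDResult:
    """Ensemble- and time-origin-averaged 3D MSD.

    Parameters
    ----------
    centroids_unwrapped:
        ``(F, P, 3)`` unwrapped particle centers at uniformly spaced times.
    times:
        ``(F,)`` sample times.
    lags:
        Lag times to evaluate (rounded to the frame grid); default is every
        frame interval up to ``max_lag_fraction`` of the duration.
    box_length:
        If given, input is rejected when any single-frame jump exceeds half
        the box (a wrapped-coordinate heuristic).
    """
    x = np.asarray(centroids_unwrapped, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    f = len(times)
    if x.shape[0] != f:
        raise ValueError("times and frames disagree")
    if f < 2:
        raise ValueError("need at least two frames")
    if box_length is not None:
        jump = np.abs(np.diff(x, axis=0)).max() if f > 1 else 0.0
        if jump > 0.5 * box_length:
            raise ValueError(
                "coordinates look wrapped (a single-frame jump exceeds "
                "box/2); msd_3d requires unwrapped input"
            )
    dt = times[1] - times[0]
    if lags is None:
        max_idx = max(1, int(f * max_lag_fraction))
        idx = np.arange(1, max_idx + 1)
    else:
        idx = np.unique(np.maximum(1, np.round(np.asarray(lags) / dt).astype(int)))
        idx = idx[idx < f]
        if len(idx) == 0:
            raise ValueError("no requested lag fits inside the trajectory")
    out = np.empty(len(idx))
    for k, ell in enumerate(idx):
        d = x[ell:] - x[:-ell]
        out[k] = np.mean(np.sum(d * d, axis=-1))
    return MSDResult(lags=idx * dt, msd=out, n_particles=x.shape[1])


def fit_diffusivity(result: MSDResult,
                    window: tuple[float, float] | None = None) -> MSDResult:
    """OLS fit of MSD versus lag inside ``window``; D = slope / 6."""
    if window is None:
        window = (result.lags[0], result.lags[-1])
    lo, hi = window
    sel = (result.lags >= lo) & (result.lags <= hi)
    if sel.sum() < 2:
        raise ValueError("fit window must contain at least two lags")
    k, _ = np.polyfit(result.lags[sel], result.msd[sel], 1)
    return replace(result, diffusivity=float(k) / 6.0, fit_slope=float(k),
                   fit_window=(float(lo), float(hi)))


def contact_counts(traj: Trajectory, cutoff: float = 3.0,
                   mode: str = "bead") -> ContactSeries:
    """Per-frame, per-NP contact counts with the polymer network.

    ``mode="bead"`` (default) counts NP beads having at least one
    polymer/node bead within ``cutoff`` under the minimum image; each NP bead
    counts at most once.  ``mode="pair"`` counts every bead-bead pair within
    the cutoff instead.
    """
    if mode not in ("bead", "pair"):
        raise ValueError("mode must be 'bead' or 'pair'")
    box = traj.box_length
    is_np = traj.bead_type == NP_BEAD
    net_sel = ~is_np
    np_ids = np.unique(traj.np_membership[is_np])
    n_np = len(np_ids)
    counts = np.zeros((traj.n_frames, n_np), dtype=np.int64)
    membership = traj.np_membership[is_np]
    for fidx in range(traj.n_frames):
        pos = np.mod(traj.wrapped_positions[fidx], box)
        tree = cKDTree(pos[net_sel], boxsize=box)
        hits = tree.query_ball_point(pos[is_np], r=cutoff)
        for b, h in enumerate(hits):
            if len(h) == 0:
                continue
            k = int(np.searchsorted(np_ids, membership[b]))
            counts[fidx, k] += 1 if mode == "bead" else len(h)
    return ContactSeries(times=traj.times.copy(), per_np_contacts=counts,
                         cutoff=cutoff)


def gyration_shape(points: np.ndarray, degeneracy_rtol: float = 1e-10):
    """Gyration eigenvalues (ascending) and AR = sqrt(max/min) of one bead set."""
    c = points.mean(axis=0)
    q = points - c
    g = q.T @ q / len(points)
    w = np.linalg.eigvalsh(g)
    w = np.maximum(w, 0.0)
    degenerate = w[0] <= degeneracy_rtol * max(w[2], 1e-300)
    ar = np.sqrt(w[2] / w[0]) if not degenerate else np.nan
    return w, ar, degenerate


def shape_metrics(traj: Trajectory) -> ShapeSeries:
    """Per-frame gyration-tensor shape of every NP.

    Beads are made coherent relative to the first bead of each NP under the
    minimum image before the gyration tensor is formed.  Coplanar or collinear
    bead sets are flagged degenerate (AR reported as NaN).
    """
    box = traj.box_length
    is_np = traj.bead_type == NP_BEAD
    np_ids = np.unique(traj.np_membership[is_np])
    n_np = len(np_ids)
    f = traj.n_frames
    ar = np.full((f, n_np), np.nan)
    eig = np.zeros((f, n_np, 3))
    deg = np.zeros((f, n_np), dtype=bool)
    for k, np_id in enumerate(np_ids):
        sel = traj.np_membership == np_id
        if sel.sum() < 4:
            raise ValueError("shape metrics need at least 4 beads per NP")
        for fidx in range(f):
            pos = traj.wrapped_positions[fidx][sel]
            rel = pos - pos[0]
            rel -= box * np.round(rel / box)
            w, a, d = gyration_shape(rel)
            eig[fidx, k] = w
            ar[fidx, k] = a
            deg[fidx, k] = d
    return ShapeSeries(times=traj.times.copy(), aspect_ratio=ar,
                       gyration_eigenvalues=eig, degenerate=deg)


# ---------------------------------------------------------------------------
# per-class aggregation helpers
# ---------------------------------------------------------------------------

def class_indices(np_class: list[str]) -> dict[str, np.ndarray]:
    """Map rigidity class -> indices of NPs in that class."""
    out: dict[str, np.ndarray] = {}
    arr = np.asarray(np_class)
    for cls in dict.fromkeys(np_class):
        out[cls] = np.flatnonzero(arr == cls)
    return out


def class_diffusivity(traj: Trajectory, equilibration_fraction: float = 0.4,
                      max_lag_fraction: float = 0.4,
                      fit_last_fraction: float = 0.25,
                      ) -> dict[str, MSDResult]:
    """Fitted diffusivity per rigidity class from the NP centroid record.

    Time origins start after ``equilibration_fraction`` of the run; lags
    extend to ``max_lag_fraction`` of the sampled span and the fit uses the
    final ``fit_last_fraction`` of the lag range, mirroring the full-length
    protocol (equilibration 8e5 of 2e6 tau; fit 1.3e6-1.8e6 tau).
    """
    t = traj.centroid_times
    start = np.searchsorted(t, t[0] + equilibration_fraction * (t[-1] - t[0]))
    cents = traj.np_centroids_unwrapped[start:]
    times = t[start:]
    results: dict[str, MSDResult] = {}
    for cls, idx in class_indices(traj.np_class).items():
        res = msd_3d(cents[:, idx, :], times, box_length=None,
                     max_lag_fraction=max_lag_fraction)
        lo = res.lags[-1] * (1.0 - fit_last_fraction)
        results[cls] = fit_diffusivity(res, (lo, res.lags[-1]))
    return results
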