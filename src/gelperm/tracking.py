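"""2D multi-particle-tracking statistics and a synthetic track generator.

The experimental pipeline computes, per particle, the time-origin-averaged
squared 2D displacement at a lag t,

    MSD_t = sum[ (x_t - x_0)^2 + (y_t - y_0)^2 ] / n ,

and the effective diffusivity at a stated time scale (1 s by convention),

    D_eff = sum[ MSD_t / (4 t) ] / n ,

where n is the number of particles (ensemble averages divide by n; the
per-particle quantities are reported individually as well).  The generator
emulates a typical video-microscopy acquisition: 100 particles, 32.6 ms frame
interval, 10 s movies, per-particle diffusivities drawn from a heterogeneous
(log-normal mixture) distribution spanning the sub-0.1 to >0.1 um^2/s range,
with ~10 nm Gaussian localization noise and optional circular confinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FRAME_INTERVAL = 0.0326   # s
DEFAULT_DURATION = 10.0           # s
DEFAULT_N_PARTICLES = 100
DEFAULT_LOCALIZATION_SD = 0.01    # um (~10 nm tracking resolution)

#: Default heterogeneous mobility model: a slow-dominated log-normal mixture
#: (weights, median D in um^2/s, sigma of log10 D).
DEFAULT_D_DISTRIBUTION = {
    "type": "lognormal_mixture",
    "weights": [0.7, 0.3],
    "medians": [0.02, 0.15],
    "sigmas_log10": [0.5, 0.3],
}


@dataclass
class TrackSet:
    """A set of 2D trajectories on a uniform time grid.

    ``positions`` is (n_particles, n_frames, 2) in micrometers; all tracks
    share the frame grid ``times`` (seconds).
    """

    times: np.ndarray
    positions: np.ndarray
    true_d: np.ndarray | None = None    # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("track times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (particle_id, frame, t_s, x_um, y_um)."""
        n, f, _ = self.positions.shape
        return pd.DataFrame({
            "particle_id": np.repeat(np.arange(n), f),
            "frame": np.tile(np.arange(f), n),
            "t_s": np.tile(self.times, n),
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrackSet":
        ids = np.sort(df["particle_id"].unique())
        frames = np.sort(df["frame"].unique())
        pos = np.full((len(ids), len(frames), 2), np.nan)
        times = None
        for k, pid in enumerate(ids):
            sub = df[df["particle_id"] == pid].sort_values("frame")
            pos[k, sub["frame"].to_numpy(), 0] = sub["x_um"].to_numpy()
            pos[k, sub["frame"].to_numpy(), 1] = sub["y_um"].to_numpy()
            if times is None:
                times = sub["t_s"].to_numpy()
        return cls(times=times, positions=pos)


@dataclass
class TrackStats:
    """Per-particle and ensemble tracking statistics."""

    lag: float
    per_particle_msd: np.ndarray
    ensemble_msd: float
    time_scale: float | None = None
    d_eff: np.ndarray | None = None
    mean_d_eff: float | None = None
    fraction_above: float | None = None
    threshold: float | None = None
    log10_hist: tuple[np.ndarray, np.ndarray] | None = None


def track_msd(tracks: TrackSet, lag: float,
              multi_origin: bool = True) -> tuple[np.ndarray, float]:
    """Per-particle squared 2D displacement at ``lag`` and the ensemble mean.

    The lag is snapped to the nearest multiple of the frame interval (a stated
    time scale like 1 s need not be commensurate with a 32.6 ms frame clock);
    it must round to at least one frame and lie within the track duration.
    With ``multi_origin`` (default) the per-particle MSD averages over all
    valid time origins; otherwise only the first frame is used as origin.
    """
    dt = tracks.frame_interval
    k = int(round(lag / dt))
    if k < 1 or abs(k * dt - lag) > 0.5 * dt + 1e-12:
        raise ValueError(f"lag {lag} does not round to a positive multiple of "
                         f"the frame interval {dt}")
    if k >= tracks.positions.shape[1]:
        raise ValueError("lag exceeds the track duration")
    x = tracks.positions
    if multi_origin:
        d = x[:, k:, :] - x[:, :-k, :]
        per = np.mean(np.sum(d * d, axis=-1), axis=1)
    else:
        d = x[:, k, :] - x[:, 0, :]
        per = np.sum(d * d, axis=-1)
    return per, float(per.mean())


def effective_diffusivity(per_particle_msd: np.ndarray,
                          time_scale: float = 1.0) -> tuple[np.ndarray, float]:
    """Per-particle D_eff = MSD(t)/(4 t) at the stated time scale, and the
    ensemble mean (the sum over particles divided by n)."""
    if time_scale <= 0:
        raise ValueError("time_scale must be positive")
    per = np.asarray(per_particle_msd, dtype=float) / (4.0 * time_scale)
    return per, float(per.mean())


def deff_distribution(d_eff: np.ndarray, threshold: float = 0.1,
                      bins: int | np.ndarray = 30):
    """Histogram of log10(D_eff) and the fraction strictly above threshold.

    Non-positive D_eff values cannot be log-binned; they are excluded from
    the histogram (reported via the returned zero count) but still enter the
    threshold fraction.
    """
    d = np.asarray(d_eff, dtype=float)
    if d.size == 0:
        raise ValueError("empty D_eff input")
    positive = d[d > 0]
    n_nonpositive = int(d.size - positive.size)
    hist, edges = np.histogram(np.log10(positive), bins=bins)
    fraction_above = float((d > threshold).mean())
    return hist, edges, fraction_above, n_nonpositive


def analyze_tracks(tracks: TrackSet, time_scale: float = 1.0,
                   threshold: float = 0.1) -> TrackStats:
    """Full pipeline: MSD at the time scale, per-particle D_eff, distribution.

    The time scale is snapped to the frame grid; D_eff divides by the snapped
    value so the estimator stays unbiased.
    """
    dt = tracks.frame_interval
    actual = max(1, int(round(time_scale / dt))) * dt
    per, ens = track_msd(tracks, actual)
    d_eff, mean_d = effective_diffusivity(per, actual)
    hist, edges, frac, _ = deff_distribution(d_eff, threshold=threshold)
    return TrackStats(lag=actual, per_particle_msd=per, ensemble_msd=ens,
                      time_scale=actual, d_eff=d_eff, mean_d_eff=mean_d,
                      fraction_above=frac, threshold=threshold,
                      log10_hist=(hist, edges))


def _draw_diffusivities(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    if isinstance(spec, (list, tuple, np.ndarray)):
        d = np.asarray(spec, dtype=float)
        if len(d) != n:
            raise ValueError("per-particle D list length mismatch")
        return d
    if spec["type"] == "lognormal_mixture":
        w = np.asarray(spec["weights"], dtype=float)
        w = w / w.sum()
        comp = rng.choice(len(w), size=n, p=w)
        med = np.asarray(spec["medians"], dtype=float)
        sig = np.asarray(spec["sigmas_log10"], dtype=float)
        return 10.0 ** (np.log10(med[comp]) + sig[comp] * rng.normal(size=n))
    raise ValueError(f"unknown D distribution spec {spec!r}")


def generate_tracks(
    n_particles: int = DEFAULT_N_PARTICLES,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    duration: float = DEFAULT_DURATION,
    d_distribution=None,
    localization_sd: float = DEFAULT_LOCALIZATION_SD,
    confinement_radius: float | None = None,
    seed: int = 0,
) -> TrackSet:
    """Simulate a synthetic 2D tracking experiment.

    Each particle draws a diffusivity D from ``d_distribution`` (a scalar, a
    per-particle array, or a log-normal-mixture spec) and performs Gaussian
    steps with per-axis variance ``2 D dt``; independent Gaussian localization
    noise of standard deviation ``localization_sd`` is added to every stored
    position.  With a confinement radius the true path is reflected at a
    circular boundary around the origin.  Deterministic given the seed.
    """
    if frame_interval <= 0 or duration <= 0:
        raise ValueError("frame_interval and duration must be positive")
    rng = np.random.default_rng(seed)
    if d_distribution is None:
        d_distribution = DEFAULT_D_DISTRIBUTION
    n_frames = int(round(duration / frame_interval)) + 1
    d = _draw_diffusivities(d_distribution, n_particles, rng)
    sd_step = np.sqrt(2.0 * d * frame_interval)
    steps = rng.normal(size=(n_particles, n_frames - 1, 2)) * sd_step[:, None, None]
    path = np.concatenate(
        [np.zeros((n_particles, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if confinement_radius is not None:
        if confinement_radius <= 0:
            raise ValueError("confinement_radius must be positive")
        path = _reflect_in_disk(steps, confinement_radius)
    pos = path
    if localization_sd > 0:
        pos = pos + rng.normal(scale=localization_sd, size=pos.shape)
    times = frame_interval * np.arange(n_frames)
    return TrackSet(times=times, positions=pos, true_d=d)


def _reflect_in_disk(steps: np.ndarray, radius: float) -> np.ndarray:
    """Walk each track step by step, reflecting radially at the disk boundary."""
    n, m, _ = steps.shape
    out = np.zeros((n, m + 1, 2))
    cur = np.zeros((n, 2))
    for t in range(m):
        cur = cur + steps[:, t, :]
        r = np.linalg.norm(cur, axis=1)
        over = r > radius
        if np.any(over):
            # radial mirror: r -> 2R - r
            scale = (2.0 * radius - r[over]) / r[over]
            cur[over] *= scale[:, None]
            r2 = np.linalg.norm(cur[over], axis=1)
            clip = r2 > radius   # pathological large steps: clamp to boundary
            if np.any(clip):
                idx = np.flatnonzero(over)[clip]
                cur[idx] *= (radius / np.linalg.norm(cur[idx], axis=1))[:, None]
        out[:, t + 1, :] = cur
    return out
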