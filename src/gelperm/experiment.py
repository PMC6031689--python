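"""End-to-end experiment orchestration: build, simulate, analyze, summarize.

The default (desk-scale) protocol preserves the controlling geometry of the
full-length study — effective mesh 16.33 sigma against NP diameter 10 sigma —
in a 49 sigma box (3 mesh cells per axis, 27 chains), with 4 NPs of each
rigidity class co-resident in the box, 3 independent seeds, and 2e4 tau of
Langevin dynamics at kT = 0.23, dt = 0.01 tau.  NPs occupy ~5% of the box
volume, dilute enough that the classes do not interact appreciably, so
co-residency mainly buys each class the same network realization.  The
friction constant gamma = 0.2 m/tau sets the free-particle diffusivity high
enough that NP displacements pass the pore scale within the shortened runs;
diffusivity ratios between classes, not absolute values, are the observable
of interest.  The full-length protocol (98 sigma box, 108 chains, 27 NPs,
2e6 tau, fit window 1.3e6-1.8e6 tau) is available as a config preset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (class_diffusivity, class_indices, contact_counts,
                       shape_metrics)
from .dynamics import RunConfig, Trajectory, run_simulation
from .forcefield import ForceFieldParams
from .io import config_hash, save_config_yaml, write_manifest
from .system import (BeadSystem, NetworkSpec, build_network, build_np_shell,
                     build_rigid_ellipsoid, place_nps)

DEFAULT_CLASSES = ("soft", "semi_elastic", "hard")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    network: NetworkSpec = field(default_factory=NetworkSpec)
    run: RunConfig = field(default_factory=lambda: RunConfig(total_time=2e4))
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    classes: tuple[str, ...] = DEFAULT_CLASSES
    nps_per_class: int = 4
    np_diameter: float = 10.0
    np_bead_spacing: float = 2.6
    ellipsoid_aspect_ratios: tuple[float, ...] = ()   # AR study instead of classes
    seeds: tuple[int, ...] = (1, 2, 3)
    min_clearance: float = 1.0
    contact_cutoff: float = 3.0
    equilibration_fraction: float = 0.4
    max_lag_fraction: float = 0.4
    fit_last_fraction: float = 0.25
    output_dir: str | None = None


def matched_curvature_ff(np_diameter: float = 10.0,
                         np_bead_spacing: float = 2.6,
                         **overrides) -> ForceFieldParams:
    """Force field whose shell potential prefers the NP's own curvature.

    The spontaneous-curvature angle theta0 is set so that two neighboring
    shell beads at the construction spacing on the sphere of the given
    diameter sit exactly at the orientation-weight maximum (sin theta0 =
    spacing / diameter).  Without this, a coarsely discretized shell pays a
    large bending penalty for being spherical and weak shells crumple.
    """
    theta0 = math.asin(np_bead_spacing / np_diameter)
    kw = dict(np_rmin=np_bead_spacing, np_rcut=1.7 * np_bead_spacing,
              np_theta0=theta0)
    kw.update(overrides)
    return ForceFieldParams(**kw)


def scaled_protocol(seeds: tuple[int, ...] = (1, 2, 3),
                    total_time: float = 2e4,
                    nps_per_class: int = 4,
                    output_dir: str | None = None) -> ExperimentConfig:
    """The desk-scale rigidity experiment (see module docstring)."""
    return ExperimentConfig(
        network=NetworkSpec(box_length=49.0, mesh_size=16.0, bead_spacing=1.75),
        run=RunConfig(total_time=total_time, langevin_gamma=0.2,
                      output_interval=2000, centroid_interval=200),
        forcefield=matched_curvature_ff(),
        seeds=tuple(seeds),
        nps_per_class=nps_per_class,
        output_dir=output_dir,
    )


def paper_protocol(seeds: tuple[int, ...] = (1, 2, 3)) -> ExperimentConfig:
    """The full-length protocol: 98 sigma box, 27 NPs, 2e6 tau (hours of CPU).

    The fit window 1.3e6-1.8e6 tau follows from RunConfig's proportional
    default at total_time = 2e6 tau.
    """
    return ExperimentConfig(
        network=NetworkSpec(box_length=98.0, mesh_size=16.0, bead_spacing=1.75),
        run=RunConfig(total_time=2e6, langevin_gamma=1.0,
                      output_interval=20000, centroid_interval=2000),
        forcefield=matched_curvature_ff(),
        nps_per_class=9,
        seeds=tuple(seeds),
    )


def ellipsoid_protocol(aspect_ratios: tuple[float, ...] = (1.0, 2.0, 3.0),
                       seeds: tuple[int, ...] = (1, 2, 3),
                       nps_per_class: int = 3,
                       total_time: float = 2e4) -> ExperimentConfig:
    """Equal-volume rigid spheroids (AR study) in the scaled network."""
    cfg = scaled_protocol(seeds=seeds, total_time=total_time,
                          nps_per_class=nps_per_class)
    return replace(cfg, ellipsoid_aspect_ratios=tuple(aspect_ratios), classes=())


def _groups(config: ExperimentConfig):
    """(label, model) pairs for every NP group in the experiment."""
    out = []
    for ar in config.ellipsoid_aspect_ratios:
        model = build_rigid_ellipsoid(config.np_diameter, ar,
                                      config.np_bead_spacing)
        out.append((f"AR{ar:g}", model))
    for cls in config.classes:
        model = build_np_shell(config.np_diameter, config.np_bead_spacing,
                               rigidity_class=cls)
        out.append((cls, model))
    return out


def build_experiment_system(config: ExperimentConfig, seed: int) -> BeadSystem:
    """Network plus all NP groups, placed with a seed-derived RNG stream."""
    system = build_network(config.network)
    for g, (label, model) in enumerate(_groups(config)):
        system = place_nps(
            system, model, config.nps_per_class,
            min_clearance=config.min_clearance,
            seed=int(np.random.SeedSequence([seed, g]).generate_state(1)[0]
                     & 0x7FFFFFFF),
            temperature=config.run.temperature,
            label=label,
        )
    return system


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    diffusivities: pd.DataFrame      # columns: cls, seed, D
    contacts: pd.DataFrame           # columns: cls, seed, mean_contacts
    shapes: pd.DataFrame             # columns: cls, seed, mean_ar, ar_rel_fluct
    msd_curves: pd.DataFrame         # columns: cls, seed, lag, msd
    summary: dict

    def class_mean(self, column: str, table: str = "diffusivities") -> dict:
        df = getattr(self, table)
        return df.groupby("cls")[column].mean().to_dict()


def analyze_run(traj: Trajectory, config: ExperimentConfig, seed: int):
    """Per-class observables of one trajectory."""
    msd_by_class = class_diffusivity(
        traj,
        equilibration_fraction=config.equilibration_fraction,
        max_lag_fraction=config.max_lag_fraction,
        fit_last_fraction=config.fit_last_fraction,
    )
    cseries = contact_counts(traj, cutoff=config.contact_cutoff)
    shapes = shape_metrics(traj)
    idx = class_indices(traj.np_class)
    start = int(config.equilibration_fraction * traj.n_frames)

    rows_d, rows_c, rows_s, rows_m = [], [], [], []
    for cls, res in msd_by_class.items():
        rows_d.append(dict(cls=cls, seed=seed, D=res.diffusivity,
                           fit_slope=res.fit_slope))
        for lag, m in zip(res.lags, res.msd):
            rows_m.append(dict(cls=cls, seed=seed, lag=lag, msd=m))
        sel = idx[cls]
        rows_c.append(dict(
            cls=cls, seed=seed,
            mean_contacts=float(cseries.per_np_contacts[start:, sel].mean())))
        ar = shapes.aspect_ratio[start:, sel]
        rows_s.append(dict(cls=cls, seed=seed,
                           mean_ar=float(np.nanmean(ar)),
                           ar_rel_fluct=float(np.nanstd(ar) / np.nanmean(ar))))
    return rows_d, rows_c, rows_s, rows_m


def run_experiment(config: ExperimentConfig, verbose: bool = False
                   ) -> ExperimentResult:
    """Build, simulate and analyze every seed; emit per-class summaries.

    With an ``output_dir``, writes tidy CSV tables, a machine-readable
    ``summary.json`` (including the semi/hard and semi/soft diffusivity
    ratios when those classes are present), the config, and a manifest.
    """
    rows_d, rows_c, rows_s, rows_m = [], [], [], []
    for seed in config.seeds:
        system = build_experiment_system(config, seed)
        run = replace(config.run, seed=seed)
        if run.n_steps == 0 or system.n_nps == 0:
            continue
        traj = run_simulation(system, config.forcefield, run)
        d, c, s, m = analyze_run(traj, config, seed)
        rows_d += d
        rows_c += c
        rows_s += s
        rows_m += m
        if verbose:
            for row in d:
                print(f"seed {seed} {row['cls']}: D = {row['D']:.3e}")

    cols_d = ["cls", "seed", "D", "fit_slope"]
    cols_c = ["cls", "seed", "mean_contacts"]
    cols_s = ["cls", "seed", "mean_ar", "ar_rel_fluct"]
    cols_m = ["cls", "seed", "lag", "msd"]
    result = ExperimentResult(
        config=config,
        diffusivities=pd.DataFrame(rows_d, columns=cols_d),
        contacts=pd.DataFrame(rows_c, columns=cols_c),
        shapes=pd.DataFrame(rows_s, columns=cols_s),
        msd_curves=pd.DataFrame(rows_m, columns=cols_m),
        summary={},
    )
    result.summary = _summarize(result)
    if config.output_dir:
        _write_outputs(result)
    return result


def _summarize(result: ExperimentResult) -> dict:
    df = result.diffusivities
    summary: dict = {"n_runs": int(df["seed"].nunique()) if len(df) else 0,
                     "config_hash": config_hash(result.config)}
    if len(df) == 0:
        return summary
    by_cls = df.groupby("cls")["D"]
    summary["D_mean"] = by_cls.mean().to_dict()
    summary["D_sd"] = by_cls.std(ddof=1).fillna(0.0).to_dict()
    cmeans = result.contacts.groupby("cls")["mean_contacts"].mean().to_dict()
    summary["contacts_mean"] = cmeans
    smeans = result.shapes.groupby("cls")[["mean_ar", "ar_rel_fluct"]].mean()
    summary["shape_mean"] = smeans.to_dict(orient="index")
    d = summary["D_mean"]
    ratios = {}
    if "semi_elastic" in d:
        if "hard" in d and d["hard"] > 0:
            ratios["semi_over_hard"] = d["semi_elastic"] / d["hard"]
        if "soft" in d and d["soft"] > 0:
            ratios["semi_over_soft"] = d["semi_elastic"] / d["soft"]
    if "soft" in cmeans:
        for other in ("hard", "semi_elastic"):
            if other in cmeans and cmeans[other] > 0:
                ratios[f"soft_contacts_over_{other}"] = \
                    cmeans["soft"] / cmeans[other]
    summary["ratios"] = ratios
    return summary


def _write_outputs(result: ExperimentResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.diffusivities.to_csv(out / "diffusivities.csv", index=False)
    result.contacts.to_csv(out / "contacts.csv", index=False)
    result.shapes.to_csv(out / "shapes.csv", index=False)
    result.msd_curves.to_csv(out / "msd_curves.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2,
                                                 sort_keys=True))
    save_config_yaml(out / "config.yaml", result.config)
    write_manifest(out / "manifest.json", result.config, result.config.seeds)
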