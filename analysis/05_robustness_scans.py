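#!/usr/bin/env python
"""Robustness scans: polymer-NP adhesion and network pore size.

Re-runs a reduced rigidity experiment while (a) sweeping the polymer-NP
attraction eps_pn over 0.02-0.2 eps and (b) sweeping the requested mesh size
over 14-18 sigma (the box scales with it, keeping 3 cells per axis), and
records per-class diffusivities and contacts for each condition.  Reduced
settings (1 seed, 8e3 tau per run by default) keep the whole scan to roughly
half an hour; pass --seeds/--time to harden it.

Writes results/robustness/{adhesion,pore}_scan.csv.
"""

import argparse
import dataclasses
import time
from pathlib import Path

import pandas as pd

from gelperm.experiment import run_experiment, scaled_protocol
from gelperm.system import NetworkSpec

ROOT = Path(__file__).resolve().parents[1]


def run_condition(cfg, label, value):
    res = run_experiment(cfg)
    rows = []
    for cls in cfg.classes:
        rows.append(dict(
            scan=label, value=value, cls=cls,
            D=res.summary["D_mean"][cls],
            D_sd=res.summary["D_sd"][cls],
            contacts=res.summary["contacts_mean"][cls],
            mean_ar=res.summary["shape_mean"][cls]["mean_ar"],
        ))
    return rows


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, nargs="+", default=[1])
    ap.add_argument("--time", type=float, default=8e3)
    args = ap.parse_args()

    out = ROOT / "results" / "robustness"
    out.mkdir(parents=True, exist_ok=True)
    base = scaled_protocol(seeds=tuple(args.seeds), total_time=args.time)

    t0 = time.time()
    rows = []
    for eps_pn in (0.02, 0.05, 0.1, 0.2):
        ff = dataclasses.replace(base.forcefield, eps_pn=eps_pn)
        cfg = dataclasses.replace(base, forcefield=ff)
        rows += run_condition(cfg, "adhesion_eps_pn", eps_pn)
        print(f"eps_pn={eps_pn}: " + ", ".join(
            f"{r['cls']} D={r['D']:.2e} c={r['contacts']:.1f}"
            for r in rows[-3:]))
    pd.DataFrame(rows).to_csv(out / "adhesion_scan.csv", index=False)

    rows = []
    for mesh in (14.0, 16.0, 18.0):
        net = NetworkSpec(box_length=3 * mesh + 1.0, mesh_size=mesh,
                          bead_spacing=1.75)
        cfg = dataclasses.replace(base, network=net)
        rows += run_condition(cfg, "pore_mesh_sigma", mesh)
        print(f"mesh={mesh}: " + ", ".join(
            f"{r['cls']} D={r['D']:.2e} c={r['contacts']:.1f}"
            for r in rows[-3:]))
    pd.DataFrame(rows).to_csv(out / "pore_scan.csv", index=False)
    print(f"finished in {(time.time() - t0) / 60:.1f} min; wrote {out}/")


if __name__ == "__main__":
    main()
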