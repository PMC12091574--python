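#!/usr/bin/env python
"""Hydration-shell exchange kinetics and water mobility.

Computes the stable-state-picture survival C(t) for waters H-bonded to
surface hydroxyls (3.5 A / 35 deg reactant, 5.3 A first-passage product),
fits the bi-exponential C1 e^{-t/tau1} + C2 e^{-t/tau2} and reports the
amplitude-weighted mean residence time tau; the Poisson exchanger with
k_exit = 0.02/ps must return tau ~= 50 ps.  Also recovers the diffusion
coefficient of a Brownian water box from the MSD slope (Einstein relation).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from hydroshell import dynamics as dyn
from hydroshell import synthetic as syn
from hydroshell.hbond import hydroxyl_donors_from_sites


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    traj, spec = syn.gen_exchange_trajectory(
        0.02, 0.0, n_waters=800, dt=1.0, n_frames=400, seed=args.seed
    )
    og = traj.site_set("og", resname="THR", atom_name="OG1")
    donors = hydroxyl_donors_from_sites(traj, og)
    curve = dyn.ssp_survival(
        traj, donors, og.indices, max_lag=150, origin_stride=25
    )
    fit = dyn.fit_biexponential(curve)
    curve.as_frame().to_csv(args.out / "survival_poisson.csv", index=False)
    print(
        f"Poisson exchanger: tau = {fit.tau:.1f} ps "
        f"(truth {spec.ground_truth['mean_residence_ps']:.0f} ps; "
        f"C1={fit.c1:.2f} tau1={fit.tau1:.1f}, C2={fit.c2:.2f} tau2={fit.tau2:.1f})"
    )

    # no-rebinding mixture: later origins over-sample the slow population,
    # so the survival is taken from the t0 = 0 origin only
    mix_traj, mix_spec = syn.gen_exchange_mixture(
        (10.0, 100.0), (0.7, 0.3), n_waters=1500, dt=1.0, n_frames=450,
        seed=args.seed + 1,
    )
    og2 = mix_traj.site_set("og", resname="THR", atom_name="OG1")
    donors2 = hydroxyl_donors_from_sites(mix_traj, og2)
    curve2 = dyn.ssp_survival(
        mix_traj, donors2, og2.indices, max_lag=400, origin_stride=10**6
    )
    fit2 = dyn.fit_biexponential(curve2)
    curve2.as_frame().to_csv(args.out / "survival_mixture.csv", index=False)
    print(
        f"two-population exchanger: tau = {fit2.tau:.1f} ps "
        f"(truth {mix_spec.ground_truth['mean_residence_ps']:.0f} ps)"
    )

    btraj, bspec = syn.gen_brownian_box(
        0.2, n_waters=1000, dt=1.0, n_frames=300, seed=args.seed + 2
    )
    m = dyn.msd(btraj.coords[:, btraj.waters.o], 100, btraj.dt, boxes=btraj.boxes)
    m.to_csv(args.out / "msd_brownian.csv", index=False)
    d_fit = dyn.diffusion_coefficient(m)
    print(
        f"Brownian box: D = {d_fit:.4f} A^2/ps "
        f"(truth {bspec.ground_truth['diffusion']})"
    )

    with open(args.out / "kinetics_fits.json", "w") as fh:
        json.dump(
            {"poisson": fit.as_dict(), "mixture": fit2.as_dict(),
             "diffusion_A2_per_ps": d_fit},
            fh, indent=2,
        )


if __name__ == "__main__":
    main()
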