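#!/usr/bin/env python
"""Protein-side geometry of the toy ice-binding surface.

Reports the side (theta_S) and top (theta_T) orientation angles of the
hydroxyl-bearing pseudo-threonines, side-chain RMSD after backbone
superposition, and ladder Calpha spacings in both readings (consecutive
rungs vs TxT within a strand).  On the rigid toy construction both angles
are exactly 90 deg and the rung spacing equals the build register
(7.4 A), confirming the metrics read out the geometry that was put in.
"""

import argparse
from pathlib import Path

import numpy as np

from hydroshell import synthetic as syn
from hydroshell.pipeline import RunConfig, run_protein_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    traj, spec = syn.gen_toy_ibs(
        n_frames=40, n_waters=12, n_pinned=2, seed=args.seed
    )
    n_sites = spec.ground_truth["n_sites"]
    cfg = RunConfig.from_dict(
        {"ladder_resids": [1, 2], "axis_residue_pair": [1, n_sites],
         "output_dir": str(args.out)}
    )
    rep = run_protein_pipeline(cfg, traj=traj)
    ts = rep["theta_s"][0]
    tt = rep["theta_t"][0]
    print(
        f"theta_S = {ts.angles.mean():.1f} deg (truth "
        f"{spec.ground_truth['theta_S_deg']:.0f}), theta_T = "
        f"{tt.angles.mean():.1f} deg (truth {spec.ground_truth['theta_T_deg']:.0f})"
    )
    print(f"ladder spacing: { {k: round(v, 2) for k, v in rep['spacing'].items()} } "
          f"(build register {spec.params['spacing']} A)")
    rmsd = rep["rmsd"]
    print(
        f"side-chain RMSD: mean {rmsd['rmsd'].mean():.3f} A over "
        f"{rmsd['resid'].nunique()} residues x {rmsd['frame'].nunique()} frames "
        f"(rigid pseudo-residues: ~0)"
    )


if __name__ == "__main__":
    main()
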