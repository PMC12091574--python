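#!/usr/bin/env python
"""Per-water rotational entropy: estimator checks and the ranked profile.

First validates the T*S_rot estimator against its closed forms (uniform,
half-domain, single-bin, exp(kappa cos theta)), then builds the ranked
per-water entropy profile on the toy ice-binding surface: waters pinned in
an H-bond to a surface hydroxyl with frozen orientation occupy the lowest
ranks, the freely reorienting slab waters sit near zero — the qualitative
signature expected of strongly ordering surfaces.
"""

import argparse
import math
from pathlib import Path

import numpy as np
import pandas as pd

from hydroshell import synthetic as syn
from hydroshell.entropy import KB_KCAL, rotational_entropy
from hydroshell.pipeline import RunConfig, run_entropy_pipeline

T = 273.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for law, truth in [
        ("uniform", 0.0),
        ("half_domain", -KB_KCAL * T * math.log(2.0)),
        ("concentrated", None),
    ]:
        th, ch, spec = syn.gen_oriented_waters(law, 10**6, seed=args.seed)
        est = rotational_entropy(th, ch, T)
        truth = spec.ground_truth["ts_rot"] if truth is None else truth
        rows.append({"law": law, "ts_rot_estimate": est, "ts_rot_truth": truth})
        print(f"{law:>12}: TS_rot = {est:+.4f} kcal/mol (truth {truth:+.4f})")
    pd.DataFrame(rows).to_csv(args.out / "entropy_closed_forms.csv", index=False)

    traj, spec = syn.gen_toy_ibs(
        n_frames=40, n_waters=12, n_pinned=2, seed=args.seed
    )
    cfg = RunConfig.from_dict({"min_samples": 1, "n_nearest": 12,
                               "output_dir": str(args.out)})
    rep = run_entropy_pipeline(cfg, traj=traj)
    prof = rep["profile"]
    pinned = spec.ground_truth["pinned_waters"]
    print(
        f"\ntoy IBS: {len(prof)} waters ranked; pinned labels {pinned} occupy "
        f"ranks {sorted(prof[prof.water_label.isin(pinned)]['rank'])} "
        f"(lowest TS_rot = {prof['ts_rot'].iloc[0]:+.3f} kcal/mol); "
        f"free waters span {prof['ts_rot'].iloc[len(pinned):].min():+.3f} to "
        f"{prof['ts_rot'].max():+.3f} kcal/mol"
    )
    print(f"hydroxyl-H-bonded subset: {list(rep['hydroxyl_bonded'].water_label)}")


if __name__ == "__main__":
    main()
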