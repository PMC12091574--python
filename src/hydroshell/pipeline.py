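"""Configuration-driven orchestration of the hydration-shell analyses.

Each ``run_*`` function reproduces one analysis sequence on an arbitrary
trajectory: per-water entropy ranking, water structure + exchange
dynamics, and protein-side IBS geometry.  Every default that fills a gap
in the configuration is recorded in the JSON manifest written next to the
CSV outputs, so a run is fully auditable and bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dynamics as dyn
from . import entropy as ent
from . import hbond as hb
from . import protein as prot
from . import structure as struct
from .permutation import permute_trajectory, permuted_water_coords
from .trajectory import SiteSet, Trajectory, load_trajectory, nearest_waters_to_sites

log = logging.getLogger("hydroshell")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


_DEFAULTS = {
    "temperature": 273.0,
    "n_nearest": 100,
    "reference_frame": 0,
    "grid": [30, 30],
    "voxels": [10, 10, 10],
    "hbond_r_cut": 3.5,
    "hbond_angle_cut": 30.0,
    "residence_angle_cut": 35.0,
    "product_cutoff": 5.3,
    "occupancy_min": 0.5,
    "r_neighbor": 3.5,
    "min_samples": 1,
    "max_lag": None,
    "origin_stride": 10,
    "hydroxyl_resname": "THR",
    "hydroxyl_o_name": "OG1",
    "hydroxyl_h_name": "HG1",
    "ca_name": "CA",
    "seed": 0,
}

_REQUIRED_PROTEIN_KEYS = ("ladder_resids", "axis_residue_pair")


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)
    defaults_applied: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(_DEFAULTS) | {
            "topology", "trajectory", "output_dir", "ladder_resids",
            "axis_residue_pair", "tyr_resids", "ser_gly_loops",
            "water_residue_names", "dt_override",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values = dict(raw)
        defaults = {}
        for key, val in _DEFAULTS.items():
            if key not in values:
                values[key] = val
                defaults[key] = val
        return cls(values=values, defaults_applied=defaults)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


def _load(config: RunConfig, traj: Trajectory | None) -> Trajectory:
    if traj is not None:
        return traj
    if "topology" not in config.values:
        raise PipelineError("load", "no trajectory given and no 'topology' in config")
    return load_trajectory(
        config["topology"], config.get("trajectory"),
        dt_override=config.get("dt_override"),
    )


def _hydroxyl_sites(config: RunConfig, traj: Trajectory) -> tuple[SiteSet, list]:
    og = traj.site_set(
        "hydroxyl_o", resname=config["hydroxyl_resname"],
        atom_name=config["hydroxyl_o_name"],
    )
    donors = hb.hydroxyl_donors_from_sites(traj, og, config["hydroxyl_h_name"])
    return og, donors


def _manifest(config: RunConfig, outdir: Path, stages: dict, name: str) -> dict:
    manifest = {
        "pipeline": name,
        "config": {
            k: v for k, v in config.values.items()
            if not isinstance(v, (np.ndarray,))
        },
        "defaults_applied": config.defaults_applied,
        "stages": stages,
    }
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_entropy_pipeline(
    config: RunConfig, traj: Trajectory | None = None, output_dir: str | None = None
) -> dict:
    """Nearest-k selection -> permutation reduction -> ranked TS_rot/TS_trans.

    Writes the full ranked table and the hydroxyl-bonded subset table.
    """
    outdir = Path(output_dir or config.get("output_dir", "results"))
    stages: dict = {}
    stage = "load"
    try:
        traj = _load(config, traj)
        stages["load"] = {"n_frames": traj.n_frames, "n_waters": traj.waters.n_waters}
        stage = "site_selection"
        og, donors = _hydroxyl_sites(config, traj)
        stages["site_selection"] = {"n_hydroxyls": len(og)}
        stage = "nearest_waters"
        k = min(config["n_nearest"], traj.waters.n_waters)
        nearest = nearest_waters_to_sites(traj, og, k, config["reference_frame"])
        stages["nearest_waters"] = {"k": int(k)}
        stage = "permutation_reduction"
        pmap = permute_trajectory(traj, config["reference_frame"])
        stages["permutation_reduction"] = {
            "mean_cost": float(pmap.costs.mean()),
            "reference_frame": int(config["reference_frame"]),
        }
        stage = "entropy"
        profile = ent.entropy_profile(
            traj, pmap, nearest, og,
            temperature=config["temperature"],
            grid=tuple(config["grid"]), voxels=tuple(config["voxels"]),
            min_samples=config["min_samples"],
        )
        stage = "hydroxyl_subset"
        crit = hb.HBondCriterion(config["hbond_r_cut"], config["hbond_angle_cut"])
        bonded = hb.waters_hbonded_to_hydroxyls(
            traj, pmap, donors, crit, config["occupancy_min"]
        )
        subset = profile[profile["water_label"].isin(bonded)]
        stages["hydroxyl_subset"] = {"n_bonded": int(len(subset))}
        outdir.mkdir(parents=True, exist_ok=True)
        profile.to_csv(outdir / "entropy_ranked.csv", index=False)
        subset.to_csv(outdir / "entropy_hydroxyl_bonded.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    manifest = _manifest(config, outdir, stages, "entropy")
    return {"profile": profile, "hydroxyl_bonded": subset, "manifest": manifest}


def run_structure_dynamics_pipeline(
    config: RunConfig, traj: Trajectory | None = None, output_dir: str | None = None
) -> dict:
    """O-O-O distribution, per-water H-bond means, t_h, MSD, C(t) + fit."""
    outdir = Path(output_dir or config.get("output_dir", "results"))
    stages: dict = {}
    stage = "load"
    try:
        traj = _load(config, traj)
        stages["load"] = {"n_frames": traj.n_frames, "n_waters": traj.waters.n_waters}
        stage = "site_selection"
        og, donors = _hydroxyl_sites(config, traj)
        stage = "permutation_reduction"
        pmap = permute_trajectory(traj, config["reference_frame"])
        stage = "central_waters"
        centrals = struct.central_waters_near_sites(traj, og)
        stage = "ooo_angles"
        ooo = struct.ooo_angle_distribution(traj, centrals, config["r_neighbor"])
        stages["ooo_angles"] = {"mode_deg": ooo.mode, "n": ooo.n_samples}
        stage = "tetrahedral"
        th = struct.conditional_tetrahedral(traj, centrals, config["r_neighbor"])
        stages["tetrahedral"] = {
            "mean_t_h": float(th.values.mean()) if len(th.values) else None,
            "n_excluded": th.n_excluded,
        }
        stage = "hbond_counts"
        crit = hb.HBondCriterion(config["hbond_r_cut"], config["hbond_angle_cut"])
        bonded_labels = hb.waters_hbonded_to_hydroxyls(
            traj, pmap, donors, crit, config["occupancy_min"]
        )
        if bonded_labels.size:
            hbonds = hb.avg_hbonds_per_water(
                traj, pmap, bonded_labels, crit,
                extra_donors=donors,
                extra_acceptor_os=og.indices,
            )
        else:
            import pandas as pd

            hbonds = pd.DataFrame(columns=["water_label", "mean_hbonds"])
        stages["hbond_counts"] = {"n_labels": int(len(hbonds))}
        stage = "msd"
        max_lag = config["max_lag"] or (traj.n_frames - 1) // 2
        pos = permuted_water_coords(traj, pmap, "o")
        msd_table = dyn.msd(pos, max_lag, traj.dt, boxes=traj.boxes)
        stage = "survival"
        state = dyn.StateDefinition(
            hb.HBondCriterion(config["hbond_r_cut"], config["residence_angle_cut"]),
            config["product_cutoff"],
        )
        curve = dyn.ssp_survival(
            traj, donors, og.indices, state,
            max_lag=max_lag, origin_stride=config["origin_stride"],
        )
        stage = "fit"
        try:
            fit = dyn.fit_biexponential(curve).as_dict()
        except dyn.DynamicsError as exc:
            fit = {"error": str(exc)}
        stages["fit"] = fit
        outdir.mkdir(parents=True, exist_ok=True)
        ooo.as_frame().to_csv(outdir / "ooo_angles.csv", index=False)
        th.per_water.to_csv(outdir / "t_h_per_water.csv", index=False)
        hbonds.to_csv(outdir / "hbonds_per_water.csv", index=False)
        msd_table.to_csv(outdir / "msd.csv", index=False)
        curve.as_frame().to_csv(outdir / "survival.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    manifest = _manifest(config, outdir, stages, "structure_dynamics")
    return {
        "ooo": ooo, "t_h": th, "hbonds": hbonds, "msd": msd_table,
        "survival": curve, "fit": fit, "manifest": manifest,
    }


def run_protein_pipeline(
    config: RunConfig, traj: Trajectory | None = None, output_dir: str | None = None
) -> dict:
    """theta_S/theta_T distributions, side-chain RMSD, spacings, stacking."""
    outdir = Path(output_dir or config.get("output_dir", "results"))
    stages: dict = {}
    missing = [k for k in _REQUIRED_PROTEIN_KEYS if k not in config.values]
    if missing:
        raise PipelineError(
            "config", f"missing required protein config keys: {missing}"
        )
    stage = "load"
    try:
        traj = _load(config, traj)
        ladder = prot.ThrLadder(list(config["ladder_resids"]))
        stage = "theta_s"
        ts = prot.theta_S(traj, ladder, tuple(config["axis_residue_pair"]),
                          config["ca_name"])
        stage = "theta_t"
        tt = prot.theta_T(traj, ladder)
        stages["angles"] = {"n_theta_s": len(ts), "n_theta_t": len(tt)}
        stage = "sidechain_rmsd"
        # superpose on every residue that carries a CA, not just the ladder
        all_ca = traj.atoms.loc[traj.atoms["name"] == "CA", "resid"]
        rmsd = prot.sidechain_rmsd(
            traj, ladder.resids, config["reference_frame"],
            superpose_residues=sorted(all_ca.unique()),
        )
        stage = "ladder_spacing"
        spacing = {
            mode: prot.ladder_spacing(traj, ladder, mode).attrs["overall_mean"]
            for mode in ("inter_strand_ladder", "intra_strand_TxT")
            if _has_pairs(ladder, mode)
        }
        stages["ladder_spacing"] = spacing
        stage = "stacking"
        stacking = None
        if config.get("tyr_resids"):
            stacking = prot.stacking_distances(traj, list(config["tyr_resids"]))
        stage = "ser_gly"
        sergly = None
        if config.get("ser_gly_loops"):
            sergly = prot.ser_gly_distances(
                traj, [tuple(p) for p in config["ser_gly_loops"]]
            )
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.concat(
            [s.distribution.assign(resid=s.resid, angle_name=s.name)
             for s in ts + tt],
            ignore_index=True,
        ).to_csv(outdir / "theta_distributions.csv", index=False)
        rmsd.to_csv(outdir / "sidechain_rmsd.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    manifest = _manifest(config, outdir, stages, "protein")
    return {
        "theta_s": ts, "theta_t": tt, "rmsd": rmsd, "spacing": spacing,
        "stacking": stacking, "ser_gly": sergly, "manifest": manifest,
    }


def _has_pairs(ladder: prot.ThrLadder, mode: str) -> bool:
    if mode == "inter_strand_ladder":
        return len(ladder.resids) >= 2
    return any(
        abs(b - a) == 2 for a, b in zip(ladder.resids[:-1], ladder.resids[1:])
    )
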