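"""Geometric hydrogen-bond detection and per-water H-bond statistics.

A donor-acceptor pair is bonded when the donor-O to acceptor-O
minimum-image distance is within ``r_cut`` (default 3.5 A) and the
O-H...O angle criterion holds.  Two conventions are supported:

* ``donor_deviation`` (default): the angle between the O_d->H and
  O_d->O_a vectors is <= ``angle_cut`` (default 30 deg) — the common
  trajectory-analysis convention;
* ``dha``: the D-H...A angle at the hydrogen is >= 180 - ``angle_cut``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Frame, SiteSet, Trajectory, minimum_image
from .permutation import PermutationMap


class HBondError(ValueError):
    pass


@dataclass(frozen=True)
class HBondCriterion:
    r_cut: float = 3.5
    angle_cut: float = 30.0
    angle_def: str = "donor_deviation"  # or "dha"

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise HBondError("r_cut must be positive")
        if not 0 < self.angle_cut < 90:
            raise HBondError("angle_cut must lie in (0, 90) degrees")
        if self.angle_def not in ("donor_deviation", "dha"):
            raise HBondError(f"unknown angle definition {self.angle_def!r}")


#: criterion used for residence-time reactant selection (35 deg)
RESIDENCE_CRITERION = HBondCriterion(r_cut=3.5, angle_cut=35.0)


@dataclass(frozen=True)
class Donor:
    """A donor oxygen with its covalently bound hydrogens."""

    o: int
    hs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.hs) == 0:
            raise HBondError(f"donor O atom {self.o} carries no hydrogen")


def water_donors(traj: Trajectory) -> list[Donor]:
    w = traj.waters
    return [Donor(int(o), (int(h1), int(h2)))
            for o, h1, h2 in zip(w.o, w.h1, w.h2)]


def hydroxyl_donors(og_indices: np.ndarray, hg_indices: np.ndarray) -> list[Donor]:
    return [Donor(int(o), (int(h),)) for o, h in zip(og_indices, hg_indices)]


def detect_hbonds(
    frame: Frame,
    donors: list[Donor],
    acceptor_os: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
    frame_index: int = 0,
) -> pd.DataFrame:
    """All H-bonds in one frame as a table (donor O, H, acceptor O, r, angle)."""
    from MDAnalysis.lib.distances import capped_distance
    from MDAnalysis.lib.mdamath import triclinic_box

    acceptor_os = np.asarray(acceptor_os, int)
    box = frame.box
    coords = frame.coords
    donor_o = np.array([d.o for d in donors], int)
    # cell-list candidate donor-acceptor pairs within the distance cutoff
    cand, cand_r = capped_distance(
        coords[donor_o], coords[acceptor_os], criterion.r_cut,
        box=triclinic_box(box[0], box[1], box[2]), return_distances=True,
    )
    rows = []
    for (di, ai), r in zip(cand, cand_r):
        donor = donors[di]
        a_idx = int(acceptor_os[ai])
        if donor.o == a_idx:
            continue
        oa = minimum_image(coords[a_idx] - coords[donor.o], box)
        best = None
        for h in donor.hs:
            oh = minimum_image(coords[h] - coords[donor.o], box)
            if criterion.angle_def == "donor_deviation":
                cosang = np.dot(oh, oa) / (np.linalg.norm(oh) * r)
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            else:  # angle at H, expressed as deviation from linear
                ho = -oh
                ha = oa - oh
                cosang = np.dot(ho, ha) / (
                    np.linalg.norm(ho) * np.linalg.norm(ha)
                )
                ang = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang <= criterion.angle_cut and (best is None or ang < best[1]):
                best = (h, ang)
        if best is not None:
            rows.append(
                {"frame": frame_index, "donor_o": donor.o, "h": best[0],
                 "acceptor_o": a_idx, "distance": float(r),
                 "angle": float(best[1])}
            )
    return pd.DataFrame(
        rows, columns=["frame", "donor_o", "h", "acceptor_o", "distance", "angle"]
    )


def _per_o_bond_counts(
    frame: Frame,
    donors: list[Donor],
    acceptor_os: np.ndarray,
    criterion: HBondCriterion,
) -> dict[int, int]:
    """Donated + accepted bond count per oxygen atom index in one frame."""
    table = detect_hbonds(frame, donors, acceptor_os, criterion)
    counts: dict[int, int] = {}
    for _, row in table.iterrows():
        counts[row["donor_o"]] = counts.get(row["donor_o"], 0) + 1
        counts[row["acceptor_o"]] = counts.get(row["acceptor_o"], 0) + 1
    return counts


def avg_hbonds_per_water(
    traj: Trajectory,
    pmap: PermutationMap,
    water_labels: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
    extra_donors: list[Donor] | None = None,
    extra_acceptor_os: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean (donated + accepted) H-bonds per permutation-reduced water label.

    Water-water bonds are always counted; protein partners (e.g. threonine
    hydroxyl/carbonyl oxygens) enter through the explicit extra donor and
    acceptor lists, so the pure-water and IBS contexts are both expressible.
    """
    water_labels = np.asarray(water_labels, int)
    if water_labels.size == 0:
        raise HBondError("empty water label set")
    w = traj.waters
    donors = water_donors(traj) + list(extra_donors or [])
    acceptors = np.asarray(w.o, int)
    if extra_acceptor_os is not None:
        acceptors = np.concatenate([acceptors, np.asarray(extra_acceptor_os, int)])
    totals = np.zeros(len(water_labels))
    for t in range(traj.n_frames):
        counts = _per_o_bond_counts(traj.frame(t), donors, acceptors, criterion)
        o_of_label = w.o[pmap.perms[t][water_labels]]
        totals += np.array([counts.get(int(o), 0) for o in o_of_label])
    return pd.DataFrame(
        {"water_label": water_labels, "mean_hbonds": totals / traj.n_frames}
    )


def bonded_to_hydroxyls(
    traj: Trajectory,
    hydroxyl: list[Donor],
    criterion: HBondCriterion = RESIDENCE_CRITERION,
    frames: np.ndarray | None = None,
) -> np.ndarray:
    """Bool (n_frames, n_waters): water H-bonded to any hydroxyl (either direction).

    Both donor directions count: water O-H ... O(hydroxyl) and hydroxyl
    O-H ... O(water).  Uses a cell-list candidate search, so it scales to
    thousands of waters; raw (unpermuted) water indexing.
    """
    from MDAnalysis.lib.distances import capped_distance
    from MDAnalysis.lib.mdamath import triclinic_box

    w = traj.waters
    hyd_o = np.array([d.o for d in hydroxyl], int)
    hyd_h = [np.array(d.hs, int) for d in hydroxyl]
    frame_list = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    out = np.zeros((len(frame_list), w.n_waters), bool)
    cosmax = np.cos(np.radians(criterion.angle_cut))
    for row, t in enumerate(frame_list):
        coords = traj.coords[t]
        box = traj.boxes[t]
        mbox = triclinic_box(box[0], box[1], box[2])
        pairs, dists = capped_distance(
            coords[w.o], coords[hyd_o], criterion.r_cut,
            box=mbox, return_distances=True,
        )
        def passes(o_pos, h, oa, r):
            oh = minimum_image(coords[h] - o_pos, box)
            if criterion.angle_def == "donor_deviation":
                return np.dot(oh, oa) / (np.linalg.norm(oh) * r) >= cosmax
            ho, ha = -oh, oa - oh
            cosang = np.dot(ho, ha) / (np.linalg.norm(ho) * np.linalg.norm(ha))
            return 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1))) \
                <= criterion.angle_cut

        for (wi, hi), r in zip(pairs, dists):
            if r < 1e-9 or out[row, wi]:
                continue
            oa = minimum_image(coords[hyd_o[hi]] - coords[w.o[wi]], box)
            for h in (w.h1[wi], w.h2[wi]):  # water as donor
                if passes(coords[w.o[wi]], h, oa, r):
                    out[row, wi] = True
                    break
            if out[row, wi]:
                continue
            for h in hyd_h[hi]:  # hydroxyl as donor
                if passes(coords[hyd_o[hi]], h, -oa, r):
                    out[row, wi] = True
                    break
    return out


def hydroxyl_bond_fraction(
    traj: Trajectory,
    pmap: PermutationMap,
    hydroxyl: list[Donor],
    criterion: HBondCriterion = HBondCriterion(),
) -> np.ndarray:
    """Fraction of frames each water label is H-bonded to any listed hydroxyl."""
    raw = bonded_to_hydroxyls(traj, hydroxyl, criterion)
    bound = np.take_along_axis(raw, pmap.perms, axis=1)
    return bound.mean(axis=0)


def waters_hbonded_to_hydroxyls(
    traj: Trajectory,
    pmap: PermutationMap,
    hydroxyl: list[Donor],
    criterion: HBondCriterion = HBondCriterion(),
    occupancy_min: float = 0.5,
) -> np.ndarray:
    """Labels whose hydroxyl-bond occupancy is >= ``occupancy_min``.

    ``occupancy_min = 0`` selects every label bonded in at least one frame.
    """
    if not hydroxyl:
        raise HBondError("empty hydroxyl site set")
    frac = hydroxyl_bond_fraction(traj, pmap, hydroxyl, criterion)
    if occupancy_min <= 0:
        return np.flatnonzero(frac > 0)
    return np.flatnonzero(frac >= occupancy_min)


def hydroxyl_donors_from_sites(
    traj: Trajectory, og_set: SiteSet, hg_name: str = "HG1"
) -> list[Donor]:
    """Pair each hydroxyl O site with the H atom of the same residue."""
    donors = []
    for o_idx in og_set.indices:
        resid = traj.atoms.loc[o_idx, "resid"]
        h = traj.atoms.index[
            (traj.atoms["resid"] == resid) & (traj.atoms["name"] == hg_name)
        ]
        if len(h) != 1:
            raise HBondError(
                f"hydroxyl O atom {o_idx}: cannot resolve hydrogen {hg_name!r}"
            )
        donors.append(Donor(int(o_idx), (int(h[0]),)))
    return donors
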