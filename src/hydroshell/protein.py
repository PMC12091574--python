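"""Protein-side ice-binding-surface (IBS) geometry metrics.

Solenoid AFP/INP ice-binding surfaces carry ladders of threonine residues
(TxT repeats) whose hydroxyl spacing registers with ice lattice planes.
Rigidity of these side chains correlates with how strongly the surface
orders nearby water, so the metrics here quantify side-chain orientation
(theta_S, theta_T), side-chain RMSD after backbone superposition, ladder
Calpha spacings, tyrosine-stacking distances and Ser(OH)-Gly(C=O)
distances on the conserved loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .trajectory import Trajectory, minimum_image


class ProteinGeometryError(ValueError):
    pass


@dataclass
class ThrLadder:
    """Ordered threonine residue ids forming one IBS ladder."""

    resids: list[int]
    side: str = "left"

    def __post_init__(self) -> None:
        if len(self.resids) < 2:
            raise ProteinGeometryError("ladder needs at least 2 residues")


def atom_index(traj: Trajectory, resid: int, name: str) -> int:
    hits = traj.atoms.index[
        (traj.atoms["resid"] == resid) & (traj.atoms["name"] == name)
    ]
    if len(hits) != 1:
        raise ProteinGeometryError(
            f"cannot resolve atom {name!r} of residue {resid} "
            f"({len(hits)} matches)"
        )
    return int(hits[0])


def _vector_series(traj: Trajectory, i: int, j: int) -> np.ndarray:
    """Per-frame minimum-image vector from atom i to atom j, (n_frames, 3)."""
    out = np.empty((traj.n_frames, 3))
    for t in range(traj.n_frames):
        out[t] = minimum_image(
            traj.coords[t, j] - traj.coords[t, i], traj.boxes[t]
        )
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    dot = np.einsum("...i,...i->...", a, b)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    return np.degrees(np.arccos(np.clip(dot / (na * nb), -1.0, 1.0)))


def _angle_distribution(series: np.ndarray, bin_width: float = 2.0) -> pd.DataFrame:
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts = np.histogram(series, bins=edges)[0]
    density = counts / max(len(series), 1) / bin_width
    return pd.DataFrame(
        {"angle": 0.5 * (edges[:-1] + edges[1:]), "density": density}
    )


@dataclass
class AngleSeries:
    resid: int
    name: str  # "theta_S" or "theta_T"
    angles: np.ndarray  # degrees per frame
    distribution: pd.DataFrame = field(default=None)  # 2-deg-bin density

    def __post_init__(self) -> None:
        if self.distribution is None:
            self.distribution = _angle_distribution(self.angles)


def theta_S(
    traj: Trajectory,
    ladder: ThrLadder,
    axis_residue_pair: tuple[int, int],
    axis_atom_name: str = "CA",
) -> list[AngleSeries]:
    """Side angle: ladder axis (Calpha of the two x-residues bounding the
    ladder) vs the Cbeta -> hydroxyl-O vector of each threonine."""
    ai = atom_index(traj, axis_residue_pair[0], axis_atom_name)
    aj = atom_index(traj, axis_residue_pair[1], axis_atom_name)
    axis = _vector_series(traj, ai, aj)
    out = []
    for resid in ladder.resids:
        try:
            cb = atom_index(traj, resid, "CB")
            og = atom_index(traj, resid, "OG1")
        except ProteinGeometryError:
            continue  # residue missing atoms: skipped
        sc = _vector_series(traj, cb, og)
        out.append(AngleSeries(resid, "theta_S", _angle_deg(axis, sc)))
    return out


def theta_T(traj: Trajectory, ladder: ThrLadder) -> list[AngleSeries]:
    """Top angle: neighbouring-threonine Calpha axis vs Cbeta -> OG1.

    The last residue of the ladder has no forward neighbour and is skipped.
    """
    out = []
    for resid, nxt in zip(ladder.resids[:-1], ladder.resids[1:]):
        ca_i = atom_index(traj, resid, "CA")
        ca_j = atom_index(traj, nxt, "CA")
        cb = atom_index(traj, resid, "CB")
        og = atom_index(traj, resid, "OG1")
        axis = _vector_series(traj, ca_i, ca_j)
        sc = _vector_series(traj, cb, og)
        out.append(AngleSeries(resid, "theta_T", _angle_deg(axis, sc)))
    return out


# ----------------------------------------------------------------------- RMSD
def _superpose(mobile: np.ndarray, ref: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Least-squares rotation + centroids aligning ``mobile`` onto ``ref``."""
    import warnings

    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    with warnings.catch_warnings():
        # planar/collinear atom sets make the rotation non-unique; any
        # optimal rotation gives the same RMSD
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot, mc, rc


def sidechain_rmsd(
    traj: Trajectory,
    residues: list[int],
    reference_frame: int = 0,
    backbone_names: tuple[str, ...] = ("CA", "C", "N"),
    sidechain_exclude: tuple[str, ...] = ("CA", "C", "N", "O"),
    superpose_residues: list[int] | None = None,
) -> pd.DataFrame:
    """Per-residue, per-frame side-chain heavy-atom RMSD (A).

    Each frame is first superposed on the reference via the backbone atoms
    of ``superpose_residues`` (default: the listed residues; Kabsch), so
    global rigid motion contributes nothing; the RMSD is then taken over
    non-hydrogen side-chain atoms.
    """
    bb_idx = []
    for resid in superpose_residues if superpose_residues is not None else residues:
        for name in backbone_names:
            try:
                bb_idx.append(atom_index(traj, resid, name))
            except ProteinGeometryError:
                continue  # pseudo-residues may carry a reduced backbone
    if len(bb_idx) < 3:
        raise ProteinGeometryError("need at least 3 backbone atoms to superpose")
    bb_idx = np.array(bb_idx)
    sc_idx = {
        resid: traj.atoms.index[
            (traj.atoms["resid"] == resid)
            & (~traj.atoms["name"].isin(sidechain_exclude))
            & (traj.atoms["element"] != "H")
        ].to_numpy()
        for resid in residues
    }
    ref = traj.coords[reference_frame]
    rows = []
    for t in range(traj.n_frames):
        cur = traj.coords[t]
        rot, mc, rc = _superpose(cur[bb_idx], ref[bb_idx])
        for resid in residues:
            idx = sc_idx[resid]
            if idx.size == 0:
                continue
            moved = rot.apply(cur[idx] - mc) + rc
            d = moved - ref[idx]
            rows.append(
                {"frame": t, "resid": resid,
                 "rmsd": float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- spacings
def ladder_spacing(
    traj: Trajectory, ladder: ThrLadder, mode: str = "inter_strand_ladder"
) -> pd.DataFrame:
    """Trajectory-mean Calpha-Calpha distances of ladder threonine pairs.

    ``inter_strand_ladder``: consecutive rungs (adjacent coils) of the
    ladder list.  ``intra_strand_TxT``: pairs whose residue ids differ by 2
    (threonines separated by one residue on the same strand).
    """
    if mode == "inter_strand_ladder":
        pairs = list(zip(ladder.resids[:-1], ladder.resids[1:]))
    elif mode == "intra_strand_TxT":
        pairs = [
            (a, b)
            for a, b in zip(ladder.resids[:-1], ladder.resids[1:])
            if abs(b - a) == 2
        ]
    else:
        raise ProteinGeometryError(f"unknown spacing mode {mode!r}")
    if not pairs:
        raise ProteinGeometryError(f"no qualifying residue pairs for mode {mode!r}")
    rows = []
    for a, b in pairs:
        ia = atom_index(traj, a, "CA")
        ib = atom_index(traj, b, "CA")
        d = np.linalg.norm(_vector_series(traj, ia, ib), axis=1)
        rows.append({"res_a": a, "res_b": b, "mean_distance": float(d.mean()),
                     "std": float(d.std())})
    df = pd.DataFrame(rows)
    df.attrs["mode"] = mode
    df.attrs["overall_mean"] = float(df["mean_distance"].mean())
    return df


def _pair_distance_distributions(
    traj: Trajectory, atom_pairs: list[tuple[int, int]], labels: list[str]
) -> pd.DataFrame:
    rows = []
    for (ia, ib), label in zip(atom_pairs, labels):
        d = np.linalg.norm(_vector_series(traj, ia, ib), axis=1)
        q1, q3 = np.percentile(d, [25, 75])
        rows.append(
            {"pair": label, "mean": float(d.mean()), "std": float(d.std()),
             "iqr": float(q3 - q1), "distances": d}
        )
    return pd.DataFrame(rows)


def stacking_distances(traj: Trajectory, tyr_resids: list[int]) -> pd.DataFrame:
    """Adjacent-pair tyrosine Cbeta-Cbeta distance distributions.

    Stacked aromatic rings give sharp distributions at a common position;
    unstacked loops give broad, shifted ones.
    """
    if len(tyr_resids) < 2:
        raise ProteinGeometryError("need at least 2 tyrosine residues")
    if len(set(tyr_resids)) != len(tyr_resids):
        raise ProteinGeometryError("duplicate residue in tyrosine list")
    pairs, labels = [], []
    for a, b in zip(tyr_resids[:-1], tyr_resids[1:]):
        pairs.append((atom_index(traj, a, "CB"), atom_index(traj, b, "CB")))
        labels.append(f"{a}-{b}")
    return _pair_distance_distributions(traj, pairs, labels)


def ser_gly_distances(
    traj: Trajectory, loops: list[tuple[int, int]]
) -> pd.DataFrame:
    """Per-loop Ser hydroxyl-O to Gly carbonyl-O distance distributions.

    ``loops`` lists (ser_resid, gly_resid) per conserved loop; sharp vs
    broad distributions (summarised by the IQR) distinguish a stable
    intra-loop H-bond from a fluctuating one.
    """
    pairs, labels = [], []
    for ser, gly in loops:
        pairs.append((atom_index(traj, ser, "OG"), atom_index(traj, gly, "O")))
        labels.append(f"S{ser}-G{gly}")
    return _pair_distance_distributions(traj, pairs, labels)
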