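"""Water-structure order metrics: O-O-O angles and conditional tetrahedrality.

The conditional tetrahedral order parameter t_h scores the angular
arrangement of a central water's k nearest oxygen neighbours (2 <= k <= 4,
within 3.5 A by default).  With n_p = k(k-1)/2 neighbour pairs and pair
angles psi,

    t_h = 1 - (9/4) * (1/n_p) * sum (cos psi + 1/3)^2 .

The per-pair normalisation fixes t_h = 1 for perfect tetrahedral angles and
E[t_h] = 0 for isotropically random neighbours at every k, so values are
comparable across neighbour counts; for k = 4 it coincides with the
Errington-Debenedetti q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import SiteSet, Trajectory, minimum_image, pair_distances


@dataclass
class AngleDistribution:
    edges: np.ndarray          # degrees
    density: np.ndarray        # per-degree density, integrates to 1
    n_samples: int
    mode: float                # left edge (deg) of the maximal bin
    n_skipped: int = 0         # central waters with < 2 neighbours

    def as_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.edges[:-1] + self.edges[1:])
        return pd.DataFrame({"angle": mid, "density": self.density})


@dataclass
class TetrahedralResult:
    values: np.ndarray         # all t_h samples
    neighbor_counts: np.ndarray
    per_water: pd.DataFrame    # mean t_h per central-water label
    n_excluded: int = 0        # centrals with < 2 neighbours


def tetrahedral_order(vectors: np.ndarray) -> float:
    """t_h from k neighbour direction vectors (k x 3) around one centre."""
    v = np.asarray(vectors, float)
    k = len(v)
    if k < 2:
        raise ValueError("t_h requires at least 2 neighbours")
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    cos = u @ u.T
    iu = np.triu_indices(k, 1)
    terms = (cos[iu] + 1.0 / 3.0) ** 2
    return 1.0 - 2.25 * float(terms.mean())


def _mda_box(box: np.ndarray) -> np.ndarray:
    from MDAnalysis.lib.mdamath import triclinic_box

    return triclinic_box(box[0], box[1], box[2])


def central_waters_near_sites(
    traj: Trajectory, site_set: SiteSet
) -> np.ndarray:
    """Per frame, the water O nearest each site atom: shape (n_frames, n_sites)."""
    from MDAnalysis.lib.distances import distance_array

    w = traj.waters
    out = np.empty((traj.n_frames, len(site_set)), int)
    for t in range(traj.n_frames):
        d = distance_array(
            traj.coords[t][site_set.indices], traj.coords[t][w.o],
            box=_mda_box(traj.boxes[t]),
        )
        out[t] = np.argmin(d, axis=1)
    return out


def _frame_neighbor_lists(
    o_pos: np.ndarray, box: np.ndarray, r_neighbor: float
) -> dict[int, np.ndarray]:
    """Water-O neighbour indices within ``r_neighbor`` for every water, one frame."""
    from MDAnalysis.lib.distances import capped_distance

    pairs = capped_distance(
        o_pos, o_pos, r_neighbor, box=_mda_box(box), return_distances=False
    )
    nbrs: dict[int, list[int]] = {}
    for i, j in pairs:
        if i != j:
            nbrs.setdefault(int(i), []).append(int(j))
    return {k: np.array(v) for k, v in nbrs.items()}


def _neighbor_vectors(
    o_pos: np.ndarray, center: int, box: np.ndarray,
    nbrs: dict[int, np.ndarray], max_neighbors: int | None = None,
) -> np.ndarray:
    idx = nbrs.get(center)
    if idx is None:
        return np.empty((0, 3))
    d = minimum_image(o_pos[idx] - o_pos[center], box)
    if max_neighbors is not None and len(idx) > max_neighbors:
        r = np.linalg.norm(d, axis=1)
        d = d[np.argsort(r, kind="stable")[:max_neighbors]]
    return d


def ooo_angle_distribution(
    traj: Trajectory,
    central_waters: np.ndarray,
    r_neighbor: float = 3.5,
    bin_width: float = 1.0,
) -> AngleDistribution:
    """Histogram of O-O-O angles at central waters, over frames.

    ``central_waters`` is (n_frames, n_central) water indices — typically
    the water nearest each threonine O per frame (`central_waters_near_sites`),
    or all waters tiled for bulk systems.  For each central O every pair of
    water-O neighbours within ``r_neighbor`` contributes one angle.
    """
    w = traj.waters
    central_waters = np.atleast_2d(np.asarray(central_waters, int))
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_skipped = 0
    for t in range(traj.n_frames):
        o_pos = traj.coords[t][w.o]
        box = traj.boxes[t]
        nbrs = _frame_neighbor_lists(o_pos, box, r_neighbor)
        for c in np.unique(central_waters[t]):
            vec = _neighbor_vectors(o_pos, int(c), box, nbrs)
            if len(vec) < 2:
                n_skipped += 1
                continue
            u = vec / np.linalg.norm(vec, axis=1, keepdims=True)
            cos = np.clip((u @ u.T)[np.triu_indices(len(u), 1)], -1, 1)
            ang = np.degrees(np.arccos(cos))
            counts += np.histogram(ang, bins=edges)[0]
    n = int(counts.sum())
    density = counts / max(n, 1) / bin_width
    mode = float(edges[np.argmax(counts)])
    return AngleDistribution(edges, density, n, mode, n_skipped)


def conditional_tetrahedral(
    traj: Trajectory,
    central_waters: np.ndarray,
    r_neighbor: float = 3.5,
    max_neighbors: int = 4,
) -> TetrahedralResult:
    """t_h of each central water per frame (k in 2..4 nearest O within cutoff).

    Central waters with fewer than 2 neighbours are excluded and counted.
    """
    w = traj.waters
    central_waters = np.atleast_2d(np.asarray(central_waters, int))
    values, ks, labels = [], [], []
    n_excluded = 0
    for t in range(traj.n_frames):
        o_pos = traj.coords[t][w.o]
        box = traj.boxes[t]
        nbrs = _frame_neighbor_lists(o_pos, box, r_neighbor)
        for c in central_waters[t]:
            vec = _neighbor_vectors(o_pos, int(c), box, nbrs, max_neighbors)
            if len(vec) < 2:
                n_excluded += 1
                continue
            values.append(tetrahedral_order(vec))
            ks.append(len(vec))
            labels.append(int(c))
    values = np.asarray(values)
    ks = np.asarray(ks, int)
    per_water = (
        pd.DataFrame({"water": labels, "t_h": values})
        .groupby("water")["t_h"].mean().reset_index()
        if len(values)
        else pd.DataFrame(columns=["water", "t_h"])
    )
    return TetrahedralResult(values, ks, per_water, n_excluded)
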