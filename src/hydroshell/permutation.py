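"""Permutation reduction of water identities.

Waters are indistinguishable, so any per-molecule time series is scrambled
by diffusive exchange.  Relabelling each frame against a reference
configuration with the permutation that minimises the total squared
(minimum-image) O-O displacement makes every label occupy a localised
spatial slot, which is what per-water entropy and structure statistics
require.  The assignment is solved exactly as a linear assignment problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .trajectory import Trajectory, minimum_image


@dataclass
class PermutationMap:
    """Per-frame optimal relabelling against a reference frame.

    ``perms[t, label]`` is the index (into the trajectory's water list) of
    the water occupying reference slot ``label`` at frame ``t``.
    ``costs[t]`` is the minimised total squared displacement in A^2;
    ``identity_costs[t]`` the cost of keeping raw labels.
    """

    reference_frame: int
    perms: np.ndarray
    costs: np.ndarray
    identity_costs: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.perms.shape[0]

    @property
    def n_waters(self) -> int:
        return self.perms.shape[1]


def _sq_distance_matrix(ref: np.ndarray, cur: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = minimum_image(cur[None, :, :] - ref[:, None, :], box)
    return np.einsum("ijk,ijk->ij", d, d)


def relabel_frame(
    frame_o: np.ndarray, reference_o: np.ndarray, box: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal permutation of one frame's water O positions onto the reference.

    Returns ``(perm, cost)`` where ``perm[label]`` indexes ``frame_o`` and
    ``cost`` is the minimised sum of squared minimum-image distances.
    """
    frame_o = np.asarray(frame_o, float)
    reference_o = np.asarray(reference_o, float)
    if frame_o.shape != reference_o.shape:
        raise ValueError("mismatched water counts between frame and reference")
    cost = _sq_distance_matrix(reference_o, frame_o, box)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(frame_o), dtype=int)
    perm[rows] = cols
    return perm, float(cost[rows, cols].sum())


def permute_trajectory(traj: Trajectory, reference_frame: int = 0) -> PermutationMap:
    """Relabel every frame of a trajectory against one reference frame."""
    w = traj.waters
    n = traj.n_frames
    perms = np.empty((n, w.n_waters), dtype=int)
    costs = np.empty(n)
    id_costs = np.empty(n)
    ref_o = traj.coords[reference_frame][w.o]
    for t in range(n):
        box = traj.boxes[t]
        cur_o = traj.coords[t][w.o]
        cost = _sq_distance_matrix(ref_o, cur_o, box)
        rows, cols = linear_sum_assignment(cost)
        perms[t, rows] = cols
        costs[t] = cost[rows, cols].sum()
        id_costs[t] = np.trace(cost)
    return PermutationMap(reference_frame, perms, costs, id_costs)


def permuted_water_coords(
    traj: Trajectory, pmap: PermutationMap, which: str = "o"
) -> np.ndarray:
    """Per-slot coordinate series (n_frames, n_waters, 3) under permuted labels.

    ``which`` selects the atom within each water: "o", "h1" or "h2".
    """
    w = traj.waters
    atom_idx = {"o": w.o, "h1": w.h1, "h2": w.h2}[which]
    out = np.empty((traj.n_frames, w.n_waters, 3))
    for t in range(traj.n_frames):
        out[t] = traj.coords[t][atom_idx[pmap.perms[t]]]
    return out
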