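"""Per-water rotational and translational entropy.

Rotational entropy of a single water is estimated from the 2-D distribution
p(theta, chi) of its orientation relative to a solute reference point:

* theta -- angle between the water-O -> solute vector and the water dipole
  (O -> midpoint of the two H atoms), in [0, 180] deg;
* chi   -- angle between the normal of the (O->solute, dipole) plane and the
  H-H vector, in [0, 180] deg.

With the angular measure d(mu) = sin(theta) dtheta dchi and total measure
c = 2*pi (theta, chi both spanning [0, pi] radians), the entropy relative to
the uniform orientation density is

    S_rot = -k_B * sum_bins  p_hat * ln(p_hat * c) * mu_bin,

with p_hat the measure-normalised histogram density.  S_rot is 0 for an
exactly uniform distribution and negative otherwise; results are reported
as T*S in kcal/mol.  The translational analogue is the voxel-histogram
differential entropy of one label's permutation-reduced positions,
referenced to the uniform density over the label's bounding cell
("method: voxel-3D").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import SiteSet, Trajectory, minimum_image, pair_distances
from .permutation import PermutationMap, permuted_water_coords

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

DEFAULT_GRID = (30, 30)
DEFAULT_MIN_SAMPLES = 10_000


class EntropyError(ValueError):
    pass


@dataclass
class OrientationSamples:
    """Orientation angle series for one water (degrees), with degeneracy flags."""

    theta: np.ndarray
    chi: np.ndarray
    degenerate: np.ndarray  # bool mask of excluded (undefined-normal) samples

    @property
    def n(self) -> int:
        return int((~self.degenerate).sum())


@dataclass
class EntropyResult:
    water_label: int
    ts_rot: float
    ts_trans: float
    n_samples: int
    temperature: float
    n_degenerate: int = 0
    rank: int | None = None


def orientation_angles(
    o: np.ndarray,
    h1: np.ndarray,
    h2: np.ndarray,
    solute: np.ndarray,
    box: np.ndarray | None = None,
    tol: float = 1e-10,
) -> OrientationSamples:
    """Compute (theta, chi) for stacked coordinates of shape (..., 3).

    ``solute`` is the per-sample solute reference point.  When a periodic box
    is given, all internal vectors use minimum-image displacements so wrapped
    molecules are handled.  Samples whose plane normal is undefined (dipole
    parallel to the solute vector, or zero-length vectors) are flagged and
    excluded from entropy estimation, with a counter.
    """
    o, h1, h2, solute = (np.asarray(x, float) for x in (o, h1, h2, solute))

    def disp(v):
        return minimum_image(v, box) if box is not None else v

    s = disp(solute - o)
    oh1 = disp(h1 - o)
    oh2 = disp(h2 - o)
    dip = 0.5 * (oh1 + oh2)
    hh = oh2 - oh1

    def unit(v):
        n = np.linalg.norm(v, axis=-1, keepdims=True)
        return np.divide(v, n, out=np.zeros_like(v), where=n > tol), n[..., 0]

    s_u, s_n = unit(s)
    d_u, d_n = unit(dip)
    normal = np.cross(s_u, d_u)
    n_u, n_n = unit(normal)
    hh_u, hh_n = unit(hh)
    degenerate = (s_n <= tol) | (d_n <= tol) | (n_n <= tol) | (hh_n <= tol)

    def angle(a, b):
        dot = np.clip(np.einsum("...i,...i->...", a, b), -1.0, 1.0)
        return np.degrees(np.arccos(dot))

    theta = angle(s_u, d_u)
    chi = angle(n_u, hh_u)
    return OrientationSamples(theta=theta, chi=chi, degenerate=np.atleast_1d(degenerate))


# ------------------------------------------------------------------ rotational
def grid_bin_measures(
    grid: tuple[int, int] = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(theta_edges_rad, chi_edges_rad, bin_measures, total_measure c).

    Bin measure uses the exact integral of sin(theta) over each theta bin,
    so piecewise-uniform closed forms hold analytically on the grid.
    """
    nt, nc = grid
    t_edges = np.linspace(0.0, np.pi, nt + 1)
    c_edges = np.linspace(0.0, np.pi, nc + 1)
    t_meas = np.cos(t_edges[:-1]) - np.cos(t_edges[1:])
    c_meas = np.diff(c_edges)
    measures = t_meas[:, None] * c_meas[None, :]
    return t_edges, c_edges, measures, float(measures.sum())


def rotational_entropy(
    theta_deg: np.ndarray,
    chi_deg: np.ndarray,
    temperature: float = 273.0,
    grid: tuple[int, int] = DEFAULT_GRID,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> float:
    """T*S_rot in kcal/mol from orientation angle samples (degrees).

    Empty bins contribute zero (0*ln 0 := 0).  The estimate is exactly 0 for
    a distribution uniform w.r.t. sin(theta) dtheta dchi, and negative for
    any concentration of orientations (plug-in estimator; small negative
    sampling bias that shrinks as n grows).
    """
    theta = np.radians(np.asarray(theta_deg, float).ravel())
    chi = np.radians(np.asarray(chi_deg, float).ravel())
    n = theta.size
    if n == 0:
        raise EntropyError("no orientation samples")
    if n < min_samples:
        raise EntropyError(f"n={n} below minimum sample count {min_samples}")
    t_edges, c_edges, measures, c_total = grid_bin_measures(grid)
    if np.any(measures <= 0):
        raise EntropyError("grid contains zero-measure bins")
    counts, _, _ = np.histogram2d(theta, chi, bins=(t_edges, c_edges))
    f = counts / n
    occ = f > 0
    s = -KB_KCAL * float(
        np.sum(f[occ] * np.log(f[occ] * c_total / measures[occ]))
    )
    return temperature * s


def entropy_convergence(
    theta_deg: np.ndarray,
    chi_deg: np.ndarray,
    fractions: np.ndarray | None = None,
    **kwargs,
) -> pd.DataFrame:
    """T*S_rot on growing prefixes of the sample series (convergence check)."""
    theta = np.asarray(theta_deg).ravel()
    chi = np.asarray(chi_deg).ravel()
    if fractions is None:
        fractions = np.array([0.125, 0.25, 0.5, 1.0])
    rows = []
    for frac in fractions:
        m = max(1, int(round(frac * theta.size)))
        rows.append(
            {"fraction": frac, "n": m,
             "ts_rot": rotational_entropy(theta[:m], chi[:m], **kwargs)}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- translational
def translational_entropy(
    positions: np.ndarray,
    temperature: float = 273.0,
    voxels: tuple[int, int, int] = (10, 10, 10),
    cell: tuple[np.ndarray, np.ndarray] | None = None,
    min_samples: int = 100,
) -> float:
    """T*S_trans in kcal/mol from one label's permutation-reduced positions.

    Voxel-histogram differential entropy over the label's local bounding
    cell, referenced to the uniform density over that cell (uniform => 0).
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    if len(pos) < min_samples:
        raise EntropyError(f"n={len(pos)} below minimum sample count {min_samples}")
    if cell is None:
        lo, hi = pos.min(axis=0), pos.max(axis=0)
        pad = 1e-9 + 1e-9 * np.abs(hi)
        lo, hi = lo - pad, hi + pad
    else:
        lo, hi = (np.asarray(x, float) for x in cell)
    extent = hi - lo
    if np.any(extent <= 0):
        raise EntropyError("degenerate bounding cell (zero volume)")
    edges = [np.linspace(lo[i], hi[i], voxels[i] + 1) for i in range(3)]
    counts, _ = np.histogramdd(pos, bins=edges)
    f = counts / len(pos)
    n_vox = int(np.prod(voxels))  # cell/voxel volume ratio
    occ = f > 0
    s = -KB_KCAL * float(np.sum(f[occ] * np.log(f[occ] * n_vox)))
    return temperature * s


# -------------------------------------------------------------------- profile
def water_orientation_series(
    traj: Trajectory,
    pmap: PermutationMap,
    label: int,
    solute_positions: np.ndarray,
) -> OrientationSamples:
    """Orientation samples for one permutation-reduced water label.

    ``solute_positions`` is (n_frames, 3): the per-frame solute reference
    point (a tracked protein atom, or a fixed point tiled over frames).
    """
    w = traj.waters
    idx = pmap.perms[:, label]
    frames = np.arange(traj.n_frames)
    o = traj.coords[frames, w.o[idx]]
    h1 = traj.coords[frames, w.h1[idx]]
    h2 = traj.coords[frames, w.h2[idx]]
    # per-frame boxes are near-constant in NVT; use frame 0 box for folding
    return orientation_angles(o, h1, h2, solute_positions, box=traj.boxes[0])


def entropy_profile(
    traj: Trajectory,
    pmap: PermutationMap,
    water_labels: np.ndarray,
    solute_sites: SiteSet | np.ndarray,
    temperature: float = 273.0,
    grid: tuple[int, int] = DEFAULT_GRID,
    voxels: tuple[int, int, int] = (10, 10, 10),
    min_samples: int = 1,
) -> pd.DataFrame:
    """Ranked per-water T*S_rot / T*S_trans table, ascending in T*S_rot.

    For each tracked label the solute reference is the nearest site atom at
    the permutation reference frame (tracked per frame thereafter); passing
    a fixed 3-vector instead of a SiteSet uses that static point everywhere.
    """
    w = traj.waters
    ref = pmap.reference_frame
    pos_perm = permuted_water_coords(traj, pmap, "o")
    results = []
    for label in np.asarray(water_labels, int):
        if isinstance(solute_sites, SiteSet):
            d = pair_distances(
                traj.coords[ref][w.o[[label]]],
                traj.coords[ref][solute_sites.indices],
                traj.boxes[ref],
            )[0]
            site_atom = int(solute_sites.indices[np.argmin(d)])
            solute_pos = traj.coords[:, site_atom]
        else:
            solute_pos = np.tile(np.asarray(solute_sites, float), (traj.n_frames, 1))
        samples = water_orientation_series(traj, pmap, label, solute_pos)
        ok = ~samples.degenerate
        ts_rot = rotational_entropy(
            samples.theta[ok], samples.chi[ok],
            temperature=temperature, grid=grid, min_samples=min_samples,
        )
        # positions unwrapped into the reference cell for a tight bounding box
        rel = minimum_image(
            pos_perm[:, label] - pos_perm[ref, label], traj.boxes[0]
        )
        ts_trans = translational_entropy(
            rel, temperature=temperature, voxels=voxels,
            min_samples=min(min_samples, len(rel)),
        )
        results.append(
            EntropyResult(
                water_label=int(label), ts_rot=ts_rot, ts_trans=ts_trans,
                n_samples=samples.n, temperature=temperature,
                n_degenerate=int(samples.degenerate.sum()),
            )
        )
    df = pd.DataFrame([vars(r) for r in results]).sort_values(
        "ts_rot", kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
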