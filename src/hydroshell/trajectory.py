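"""Periodic MD trajectories: loading, water indexing, and geometric queries.

All coordinates are stored in angstroms and all times in picoseconds,
regardless of the on-disk format (GRO/XTC are nm-based; MDAnalysis converts
on read).  The box is a 3x3 matrix whose *rows* are the lattice vectors
(GROMACS convention: first vector along x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WATER_RESNAMES = ("SOL", "HOH", "WAT", "TIP3", "TIP4", "TIP5", "T5P")

# all 27 integer lattice shifts, used for exact minimum image in skewed boxes
_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


class TrajectoryError(ValueError):
    """Raised for malformed or unsupported trajectory input."""


@dataclass
class Frame:
    """A single time point: box matrix (3x3, A) and per-atom coordinates (A)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if np.linalg.det(self.box) <= 0:
            raise TrajectoryError("degenerate box: volume <= 0")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("non-finite coordinates in frame")


@dataclass
class WaterIndexing:
    """Atom indices of each water: O, H1, H2 and any extra (lone-pair) sites.

    Extra sites (TIP4P/TIP5P virtual sites) are carried but ignored by every
    geometric criterion, which reference O and H atoms only.
    """

    o: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    extra: list[np.ndarray] = field(default_factory=list)
    resids: np.ndarray | None = None

    @property
    def n_waters(self) -> int:
        return len(self.o)


@dataclass
class SiteSet:
    """A named selection of atom indices (e.g. IBS threonine hydroxyl oxygens)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise TrajectoryError(f"site set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.indices)


class Trajectory:
    """In-memory trajectory: coords (n_frames, n_atoms, 3) A, boxes, atom table."""

    def __init__(
        self,
        coords: np.ndarray,
        boxes: np.ndarray,
        atoms: pd.DataFrame,
        dt: float = 0.1,
        times: np.ndarray | None = None,
        water_resnames: tuple[str, ...] = DEFAULT_WATER_RESNAMES,
        require_waters: bool = True,
    ) -> None:
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        self.boxes = np.asarray(boxes, dtype=float)
        if self.boxes.ndim == 2:
            self.boxes = np.repeat(self.boxes[None], len(self.coords), axis=0)
        self.atoms = atoms.reset_index(drop=True)
        if len(self.atoms) != self.coords.shape[1]:
            raise TrajectoryError("atom table length does not match coordinates")
        self.dt = float(dt)
        if times is None:
            times = np.arange(len(self.coords)) * self.dt
        self.times = np.asarray(times, dtype=float)
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise TrajectoryError("frame times must be strictly increasing")
            if np.ptp(steps) > 1e-6:
                raise TrajectoryError("non-uniform frame spacing")
            self.dt = float(steps[0])
        self.water_resnames = tuple(water_resnames)
        self._waters: WaterIndexing | None = None
        if require_waters:
            _ = self.waters  # fail early if no waters are present

    # ---------------------------------------------------------------- basics
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.times[i], self.boxes[i], self.coords[i])

    @property
    def waters(self) -> WaterIndexing:
        if self._waters is None:
            self._waters = detect_waters(
                self.atoms, self.coords[0], self.boxes[0], self.water_resnames
            )
        return self._waters

    def site_set(self, name: str, resname: str | None = None,
                 atom_name: str | None = None,
                 resids: list[int] | None = None) -> SiteSet:
        """Build a SiteSet by residue name / atom name / residue id filters."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if resname is not None:
            mask &= (self.atoms["resname"] == resname).to_numpy()
        if atom_name is not None:
            mask &= (self.atoms["name"] == atom_name).to_numpy()
        if resids is not None:
            mask &= self.atoms["resid"].isin(resids).to_numpy()
        return SiteSet(name, np.flatnonzero(mask))

    def mda_box(self, frame_index: int = 0) -> np.ndarray:
        """Box as ``[lx, ly, lz, alpha, beta, gamma]`` for MDAnalysis helpers."""
        from MDAnalysis.lib.mdamath import triclinic_box

        b = self.boxes[frame_index]
        return triclinic_box(b[0], b[1], b[2])


# ------------------------------------------------------------------ geometry
def _is_diagonal(box: np.ndarray) -> bool:
    return bool(np.allclose(box, np.diag(np.diag(box))))


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) ``d`` (..., 3) under a periodic box.

    For orthorhombic boxes this is plain fractional rounding; for triclinic
    boxes the rounded image is refined by an exact search over the 27
    neighbouring images (sufficient for any reduced MD box).
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.linalg.det(box) <= 0:
        raise TrajectoryError("degenerate box: volume <= 0")
    frac = d @ np.linalg.inv(box)
    frac = frac - np.round(frac)
    out = frac @ box
    if _is_diagonal(box):
        return out
    cand = out[..., None, :] + (_SHIFTS @ box)  # (..., 27, 3)
    best = np.argmin(np.einsum("...ki,...ki->...k", cand, cand), axis=-1)
    return np.take_along_axis(cand, best[..., None, None], axis=-2)[..., 0, :]


def minimum_image_vector(frame: Frame, i: int, j: int) -> np.ndarray:
    """Displacement from atom ``i`` to atom ``j`` under minimum image."""
    return minimum_image(frame.coords[j] - frame.coords[i], frame.box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All pairwise minimum-image distances |b_j - a_i|, shape (len(a), len(b))."""
    d = minimum_image(b[None, :, :] - a[:, None, :], box)
    return np.linalg.norm(d, axis=-1)


# ------------------------------------------------------------- water indexing
def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def detect_waters(
    atoms: pd.DataFrame,
    coords0: np.ndarray,
    box0: np.ndarray,
    water_resnames: tuple[str, ...] = DEFAULT_WATER_RESNAMES,
) -> WaterIndexing:
    """Identify water molecules by residue name, robust to atom order.

    Each water residue must contain exactly one oxygen and two hydrogens;
    additional sites (virtual/lone-pair) are collected as extras.  The O-H
    distances are sanity-checked (0.8-1.2 A) on the supplied frame.
    """
    if "element" in atoms.columns:
        elements = atoms["element"].astype(str).str.upper()
    else:
        elements = atoms["name"].map(_guess_element)
    is_water = atoms["resname"].isin(water_resnames).to_numpy()
    if not is_water.any():
        raise TrajectoryError("no waters detected")
    o_list, h1_list, h2_list, extras = [], [], [], []
    sub = atoms[is_water]
    for resid, grp in sub.groupby("resid", sort=True):
        idx = grp.index.to_numpy()
        el = elements.loc[idx].to_numpy()
        o_idx = idx[el == "O"]
        h_idx = idx[el == "H"]
        if len(o_idx) != 1 or len(h_idx) != 2:
            raise TrajectoryError(
                f"water resid {resid}: expected 1 O and 2 H, "
                f"found {len(o_idx)} O / {len(h_idx)} H"
            )
        o_list.append(o_idx[0])
        h1_list.append(h_idx[0])
        h2_list.append(h_idx[1])
        extras.append(idx[(el != "O") & (el != "H")])
    o = np.array(o_list)
    h1 = np.array(h1_list)
    h2 = np.array(h2_list)
    for h in (h1, h2):
        doh = np.linalg.norm(
            minimum_image(coords0[h] - coords0[o], box0), axis=-1
        )
        if np.any((doh < 0.8) | (doh > 1.2)):
            bad = int(np.flatnonzero((doh < 0.8) | (doh > 1.2))[0])
            raise TrajectoryError(
                f"water {bad}: O-H distance {doh[bad]:.3f} A outside 0.8-1.2 A"
            )
    resids = sub.groupby("resid", sort=True).ngroup()  # noqa: F841 (order only)
    return WaterIndexing(
        o=o, h1=h1, h2=h2, extra=extras,
        resids=np.array(sorted(sub["resid"].unique())),
    )


# ------------------------------------------------------------------- loading
def load_trajectory(
    topology_path: str,
    trajectory_path: str | None = None,
    dt_override: float | None = None,
    water_resnames: tuple[str, ...] = DEFAULT_WATER_RESNAMES,
    require_waters: bool = True,
) -> Trajectory:
    """Load a topology (+ optional trajectory) file pair into a Trajectory.

    Supported pairs: PDB/GRO topology with XTC/DCD/multi-model-PDB frames.
    A multi-model PDB alone supplies both.  Times default to the file's
    metadata; ``dt_override`` (ps) replaces them when formats carry no time.
    """
    import MDAnalysis as mda
    from MDAnalysis.lib.mdamath import triclinic_vectors

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(topology_path)
            else:
                u = mda.Universe(topology_path, trajectory_path)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise TrajectoryError(f"unreadable trajectory input: {exc}") from exc
    n_frames = len(u.trajectory)
    if n_frames == 0:
        raise TrajectoryError("zero frames in trajectory")
    coords = np.empty((n_frames, len(u.atoms), 3))
    boxes = np.empty((n_frames, 3, 3))
    times = np.empty(n_frames)
    for k, ts in enumerate(u.trajectory):
        if ts.positions.shape[0] != len(u.atoms):
            raise TrajectoryError(f"inconsistent atom count at frame {k}")
        coords[k] = ts.positions
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise TrajectoryError(f"frame {k} carries no periodic box")
        boxes[k] = triclinic_vectors(ts.dimensions)
        times[k] = ts.time
    atoms = pd.DataFrame(
        {
            "name": u.atoms.names,
            "resname": u.atoms.resnames,
            "resid": u.atoms.resids,
        }
    )
    atoms["element"] = atoms["name"].map(_guess_element)
    if dt_override is not None:
        times = np.arange(n_frames) * dt_override
        dt = dt_override
    elif n_frames > 1 and np.ptp(np.diff(times)) < 1e-6 and np.diff(times)[0] > 0:
        dt = float(np.diff(times)[0])
    else:
        dt = 0.1
        times = np.arange(n_frames) * dt
    return Trajectory(
        coords, boxes, atoms, dt=dt, times=times,
        water_resnames=water_resnames, require_waters=require_waters,
    )


# ------------------------------------------------------------------- queries
def nearest_waters_to_sites(
    traj: Trajectory, site_set: SiteSet, k: int, frame_index: int = 0
) -> np.ndarray:
    """The ``k`` waters nearest to a site set, ranked at one reference frame.

    Distance is min over site atoms to the water O atom; ties break on water
    id.  Identities are then tracked downstream via permutation reduction.
    """
    w = traj.waters
    if k > w.n_waters:
        raise TrajectoryError(f"k={k} exceeds water count {w.n_waters}")
    frame = traj.frame(frame_index)
    d = pair_distances(frame.coords[w.o], frame.coords[site_set.indices], frame.box)
    dmin = d.min(axis=1)
    order = np.lexsort((np.arange(w.n_waters), dmin))
    return order[:k]


def site_water_rdf(
    traj: Trajectory, site_set: SiteSet, r_max: float, dr: float
) -> pd.DataFrame:
    """Shell-volume-normalised g(r) of water oxygens around the site atoms.

    Used to justify product-state distance cutoffs for shell-exchange
    kinetics (first-minimum placement).
    """
    if dr <= 0:
        raise TrajectoryError("dr must be positive")
    half_min = 0.5 * min(
        np.linalg.norm(traj.boxes[0][i]) for i in range(3)
    )
    if r_max >= half_min:
        raise TrajectoryError(f"r_max={r_max} must be < half box ({half_min:.2f})")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    w = traj.waters
    vol = 0.0
    for fi in range(traj.n_frames):
        frame = traj.frame(fi)
        d = pair_distances(
            frame.coords[site_set.indices], frame.coords[w.o], frame.box
        ).ravel()
        counts += np.histogram(d, bins=edges)[0]
        vol += np.linalg.det(frame.box)
    vol /= traj.n_frames
    rho = w.n_waters / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = rho * shell * len(site_set) * traj.n_frames
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r": r_mid, "g": g, "count": counts})
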