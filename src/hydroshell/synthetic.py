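"""Synthetic trajectories with analytic ground truth.

Every generator emulates one feature of a hydration-shell MD trajectory —
ice-like tetrahedral ordering, prescribed orientation distributions,
two-state shell-exchange kinetics, free diffusion, or a toy planar
ice-binding surface — and records its exact expected observables in a
:class:`SyntheticSpec`, so every pipeline stage can be validated without
running MD.  Trajectories can be written to standard formats (GRO + XTC,
or multi-model PDB) to exercise the full I/O path.

Water geometry is rigid 3-site (O-H 0.9572 A, H-O-H 104.52 deg), except in
the tetrahedral-lattice generator, where hydrogens point along donated
neighbour directions (ice rules), giving the 109.47 deg lattice angle.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .entropy import KB_KCAL, grid_bin_measures
from .trajectory import Trajectory

OH_BOND = 0.9572  # A
HOH_ANGLE = 104.52  # deg
TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...


@dataclass
class SyntheticSpec:
    """Declarative record of a generated system and its analytic ground truth."""

    generator: str
    params: dict
    seed: int
    ground_truth: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=default)


# ---------------------------------------------------------------- primitives
def _water_h_positions(o: np.ndarray, dipole_u: np.ndarray, hh_u: np.ndarray):
    """H1, H2 of a rigid water from its O, unit dipole and unit H-H direction."""
    half = math.radians(HOH_ANGLE / 2.0)
    h1 = o + OH_BOND * (math.cos(half) * dipole_u - math.sin(half) * hh_u)
    h2 = o + OH_BOND * (math.cos(half) * dipole_u + math.sin(half) * hh_u)
    return h1, h2


def _water_atom_table(n_waters: int, prefix_rows: list[dict] | None = None) -> pd.DataFrame:
    rows = list(prefix_rows or [])
    start = (rows[-1]["resid"] + 1) if rows else 1
    for i in range(n_waters):
        resid = start + i
        rows.append({"name": "OW", "resname": "SOL", "resid": resid, "element": "O"})
        rows.append({"name": "HW1", "resname": "SOL", "resid": resid, "element": "H"})
        rows.append({"name": "HW2", "resname": "SOL", "resid": resid, "element": "H"})
    return pd.DataFrame(rows)


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _perpendicular_unit(rng: np.random.Generator, d: np.ndarray) -> np.ndarray:
    v = rng.normal(size=d.shape)
    v -= (np.einsum("ij,ij->i", v, d))[:, None] * d
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# -------------------------------------------------- independent H-bond oracle
def brute_force_hbond_counts(
    coords: np.ndarray,
    box_l: float,
    o_idx: np.ndarray,
    h_idx: np.ndarray,
    r_cut: float = 3.5,
    angle_cut: float = 30.0,
) -> np.ndarray:
    """Per-water donated+accepted H-bond count by exhaustive pair scan.

    Deliberately self-contained (plain loops, cubic-box wrapping, raw
    trigonometry) so it is an oracle independent of the hbond module.
    ``h_idx`` is (n_waters, 2).
    """
    n = len(o_idx)
    counts = np.zeros(n, dtype=int)
    cos_cut = math.cos(math.radians(angle_cut))
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[o_idx[j]] - coords[o_idx[i]]
            d = d - box_l * np.round(d / box_l)
            r = math.sqrt(d @ d)
            if r > r_cut or r < 1e-9:
                continue
            # i donating to j
            bonded = False
            for h in h_idx[i]:
                oh = coords[h] - coords[o_idx[i]]
                oh = oh - box_l * np.round(oh / box_l)
                if (oh @ d) / (math.sqrt(oh @ oh) * r) >= cos_cut:
                    bonded = True
                    break
            if bonded:
                counts[i] += 1
                counts[j] += 1
            # j donating to i
            bonded = False
            for h in h_idx[j]:
                oh = coords[h] - coords[o_idx[j]]
                oh = oh - box_l * np.round(oh / box_l)
                if (oh @ -d) / (math.sqrt(oh @ oh) * r) >= cos_cut:
                    bonded = True
                    break
            if bonded:
                counts[i] += 1
                counts[j] += 1
    return counts


# --------------------------------------------------------- tetrahedral lattice
def gen_tetrahedral_lattice(
    oo_distance: float = 2.76,
    n_cells: int = 2,
    jitter_sigma: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    dt: float = 0.1,
) -> tuple[Trajectory, SyntheticSpec]:
    """Periodic diamond-cubic water lattice with ice-rule proton placement.

    Every O has four neighbours at ``oo_distance``; a balanced Eulerian
    orientation of the neighbour graph assigns each water two donated
    bonds, so at zero jitter every water donates 2 and accepts 2 perfect
    H-bonds and every O-O-O angle is the tetrahedral angle.  Gaussian
    translational jitter of the rigid molecules perturbs both.
    """
    import networkx as nx
    from MDAnalysis.lib.distances import capped_distance

    if oo_distance <= 0:
        raise ValueError("oo_distance must be positive")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    if n_cells < 2:
        raise ValueError("box smaller than 2 cells")
    a = 4.0 * oo_distance / math.sqrt(3.0)
    basis = np.array(
        [[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0],
         [0.25, 0.25, 0.25], [0.25, 0.75, 0.75], [0.75, 0.25, 0.75],
         [0.75, 0.75, 0.25]]
    )
    cells = np.array(
        [[i, j, k] for i in range(n_cells) for j in range(n_cells)
         for k in range(n_cells)], dtype=float
    )
    frac = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) / n_cells
    box_l = a * n_cells
    o_pos = frac * box_l
    n_w = len(o_pos)
    mda_box = np.array([box_l, box_l, box_l, 90.0, 90.0, 90.0])
    pairs = capped_distance(
        o_pos, o_pos, 1.05 * oo_distance, box=mda_box, return_distances=False
    )
    g = nx.Graph()
    g.add_nodes_from(range(n_w))
    g.add_edges_from((int(i), int(j)) for i, j in pairs if i < j)
    degs = dict(g.degree())
    if set(degs.values()) != {4}:
        raise RuntimeError("lattice construction failed: graph is not 4-regular")
    # balanced orientation: walk an Eulerian circuit; out-degree = 2 everywhere
    donated: dict[int, list[int]] = {i: [] for i in range(n_w)}
    for u, v in nx.eulerian_circuit(g):
        donated[u].append(v)
    coords0 = np.empty((3 * n_w, 3))
    for i in range(n_w):
        coords0[3 * i] = o_pos[i]
        for slot, j in enumerate(donated[i]):
            d = o_pos[j] - o_pos[i]
            d = d - box_l * np.round(d / box_l)
            coords0[3 * i + 1 + slot] = o_pos[i] + OH_BOND * d / np.linalg.norm(d)
    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, 3 * n_w, 3))
    for t in range(n_frames):
        jit = rng.normal(scale=jitter_sigma, size=(n_w, 3)) if jitter_sigma else 0.0
        fr = coords0.copy()
        if jitter_sigma:
            fr += np.repeat(jit, 3, axis=0)  # rigid translation per molecule
        coords[t] = fr
    atoms = _water_atom_table(n_w)
    traj = Trajectory(coords, np.diag([box_l] * 3), atoms, dt=dt)
    w = traj.waters
    h_pairs = np.stack([w.h1, w.h2], axis=1)
    brute = np.array(
        [brute_force_hbond_counts(coords[t], box_l, w.o, h_pairs)
         for t in range(n_frames)]
    )
    spec = SyntheticSpec(
        generator="tetrahedral_lattice",
        params=dict(oo_distance=oo_distance, n_cells=n_cells,
                    jitter_sigma=jitter_sigma, n_frames=n_frames, dt=dt),
        seed=seed,
        ground_truth=dict(
            n_waters=n_w,
            box_length=box_l,
            lattice_angle=TETRAHEDRAL_ANGLE,
            ooo_mode_deg=109.0,  # 1-degree binning of 109.47
            t_h_ideal=1.0,
            hbonds_per_water_ideal=4.0,
            brute_force_hbond_counts=brute,
        ),
    )
    return traj, spec


# ------------------------------------------------------- orientation sampling
def concentrated_ts_quadrature(
    kappa: float, temperature: float = 273.0, n_points: int = 1_000_000
) -> float:
    """T*S_rot of p(theta,chi) ~ exp(kappa cos theta) by numeric quadrature."""
    u = np.linspace(-1.0, 1.0, n_points)
    zu = np.trapezoid(np.exp(kappa * u), u)
    integrand = np.exp(kappa * u) / zu * np.log(2.0 * np.exp(kappa * u) / zu)
    return -KB_KCAL * temperature * float(np.trapezoid(integrand, u))


def gen_oriented_waters(
    law: str,
    n_samples: int,
    seed: int = 0,
    temperature: float = 273.0,
    kappa: float = 4.0,
    bin_index: tuple[int, int] = (3, 7),
    grid: tuple[int, int] = (30, 30),
) -> tuple[np.ndarray, np.ndarray, SyntheticSpec]:
    """Orientation-angle samples (theta, chi in degrees) with analytic T*S_rot.

    Laws: ``uniform`` (T*S = 0), ``half_domain`` (theta < 90; -k_B T ln 2),
    ``single_bin`` (all mass in one grid bin; -k_B T ln(c/dOmega)),
    ``concentrated`` (p ~ exp(kappa cos theta); quadrature oracle).
    """
    rng = np.random.default_rng(seed)
    chi = rng.uniform(0.0, 180.0, n_samples)
    t_edges, c_edges, measures, c_total = grid_bin_measures(grid)
    if law == "uniform":
        u = rng.uniform(-1.0, 1.0, n_samples)
        ts = 0.0
    elif law == "half_domain":
        u = rng.uniform(0.0, 1.0, n_samples)
        ts = -KB_KCAL * temperature * math.log(2.0)
    elif law == "single_bin":
        bi, bj = bin_index
        u = rng.uniform(
            math.cos(t_edges[bi + 1]), math.cos(t_edges[bi]), n_samples
        )
        chi = np.degrees(rng.uniform(c_edges[bj], c_edges[bj + 1], n_samples))
        ts = -KB_KCAL * temperature * math.log(c_total / measures[bi, bj])
    elif law == "concentrated":
        # inverse-CDF sampling of u = cos(theta) ~ exp(kappa u) on [-1, 1]
        r = rng.uniform(size=n_samples)
        u = np.log(
            math.exp(-kappa) + r * (math.exp(kappa) - math.exp(-kappa))
        ) / kappa
        ts = concentrated_ts_quadrature(kappa, temperature)
    else:
        raise ValueError(f"unknown orientation law {law!r}")
    theta = np.degrees(np.arccos(np.clip(u, -1.0, 1.0)))
    spec = SyntheticSpec(
        generator="oriented_waters",
        params=dict(law=law, n_samples=n_samples, temperature=temperature,
                    kappa=kappa, bin_index=list(bin_index), grid=list(grid)),
        seed=seed,
        ground_truth=dict(ts_rot=ts),
    )
    return theta, chi, spec


def gen_orientation_mixture(
    kappas: list[float],
    n_samples: int,
    seed: int = 0,
    temperature: float = 273.0,
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], SyntheticSpec]:
    """One orientation stream per label, each with its own concentration kappa.

    Larger kappa means a more orientationally confined (lower-entropy) water,
    so the ground-truth T*S ordering is the reverse of the kappa ordering.
    """
    streams = {}
    truths = []
    for i, k in enumerate(kappas):
        if k == 0:
            th, ch, sp = gen_oriented_waters(
                "uniform", n_samples, seed=seed + i, temperature=temperature
            )
        else:
            th, ch, sp = gen_oriented_waters(
                "concentrated", n_samples, seed=seed + i,
                temperature=temperature, kappa=k,
            )
        streams[i] = (th, ch)
        truths.append(sp.ground_truth["ts_rot"])
    spec = SyntheticSpec(
        generator="orientation_mixture",
        params=dict(kappas=list(kappas), n_samples=n_samples,
                    temperature=temperature),
        seed=seed,
        ground_truth=dict(ts_rot_per_label=truths),
    )
    return streams, spec


# ------------------------------------------------------- shell-exchange system
def _site_grid(n_sites: int, spacing: float, z: float) -> tuple[np.ndarray, np.ndarray]:
    nx_ = math.ceil(math.sqrt(n_sites))
    ny_ = math.ceil(n_sites / nx_)
    pos = np.array(
        [[((i % nx_) + 0.5) * spacing, ((i // nx_) + 0.5) * spacing, z]
         for i in range(n_sites)]
    )
    box = np.diag([nx_ * spacing, ny_ * spacing, 40.0])
    return pos, box


def gen_exchange_trajectory(
    k_exit: float | np.ndarray,
    k_return: float = 0.0,
    n_waters: int = 200,
    dt: float = 1.0,
    n_frames: int = 400,
    seed: int = 0,
    far_offset: float = 10.0,
    site_spacing: float = 20.0,
) -> tuple[Trajectory, SyntheticSpec]:
    """Markov two-state shell exchanger with exact bound/free ground truth.

    Each water has its own hydroxyl pseudo-residue (THR with OG1/HG1).  In
    the bound state the water O sits 2.8 A from its hydroxyl O donating a
    perfectly linear H-bond; in the free state it sits ``far_offset`` A away
    (beyond the 5.3 A product shell).  Exit/return are Poisson with rates
    ``k_exit`` / ``k_return`` per ps; with no return, survival is
    exp(-k_exit t) and the mean residence time is 1/k_exit.
    """
    k_exit = np.broadcast_to(np.asarray(k_exit, float), (n_waters,)).copy()
    if np.any(k_exit < 0) or k_return < 0:
        raise ValueError("rates must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.max(k_exit) * dt > 0.1:
        warnings.warn("dt*k_exit > 0.1: time step too coarse for clean kinetics")
    rng = np.random.default_rng(seed)
    site_pos, box = _site_grid(n_waters, site_spacing, z=10.0)
    p_exit = 1.0 - np.exp(-k_exit * dt)
    p_ret = 1.0 - math.exp(-k_return * dt)
    states = np.empty((n_frames, n_waters), dtype=bool)
    states[0] = True
    for t in range(1, n_frames):
        u = rng.uniform(size=n_waters)
        stay_bound = states[t - 1] & (u >= p_exit)
        rebind = (~states[t - 1]) & (u < p_ret)
        states[t] = stay_bound | rebind
    # geometry: site OG1/HG1 + water (O, H1 donating downward, H2)
    half = math.radians(HOH_ANGLE)
    h2_dir = np.array([math.sin(half), 0.0, -math.cos(half)])
    site_rows = []
    for i in range(n_waters):
        site_rows.append({"name": "OG1", "resname": "THR", "resid": i + 1,
                          "element": "O"})
        site_rows.append({"name": "HG1", "resname": "THR", "resid": i + 1,
                          "element": "H"})
    atoms = _water_atom_table(n_waters, prefix_rows=site_rows)
    n_site_atoms = 2 * n_waters
    coords = np.empty((n_frames, n_site_atoms + 3 * n_waters, 3))
    for i in range(n_waters):
        coords[:, 2 * i] = site_pos[i]
        coords[:, 2 * i + 1] = site_pos[i] + np.array([OH_BOND, 0, 0])
    bound_o = site_pos + np.array([0, 0, 2.8])
    free_o = site_pos + np.array([0, 0, 2.8 + far_offset])
    for t in range(n_frames):
        o = np.where(states[t][:, None], bound_o, free_o)
        base = n_site_atoms
        coords[t, base + 0 :: 3] = o
        coords[t, base + 1 :: 3] = o + np.array([0, 0, -OH_BOND])
        coords[t, base + 2 :: 3] = o + OH_BOND * h2_dir
    traj = Trajectory(coords, box, atoms, dt=dt)
    tau_true = float(np.mean(1.0 / np.maximum(k_exit, 1e-12)))
    spec = SyntheticSpec(
        generator="exchange",
        params=dict(k_exit=k_exit, k_return=k_return, n_waters=n_waters,
                    dt=dt, n_frames=n_frames, far_offset=far_offset),
        seed=seed,
        ground_truth=dict(
            mean_residence_ps=tau_true,
            analytic_survival="exp(-k_exit*t)" if k_return == 0 else None,
            states=states,
        ),
    )
    return traj, spec


def gen_exchange_mixture(
    taus: tuple[float, float] = (10.0, 100.0),
    weights: tuple[float, float] = (0.7, 0.3),
    n_waters: int = 200,
    dt: float = 1.0,
    n_frames: int = 400,
    seed: int = 0,
) -> tuple[Trajectory, SyntheticSpec]:
    """Two-population exchanger: C(t) = w1 e^{-t/tau1} + w2 e^{-t/tau2}."""
    n1 = int(round(weights[0] * n_waters))
    k = np.empty(n_waters)
    k[:n1] = 1.0 / taus[0]
    k[n1:] = 1.0 / taus[1]
    traj, spec = gen_exchange_trajectory(
        k, 0.0, n_waters=n_waters, dt=dt, n_frames=n_frames, seed=seed
    )
    spec.generator = "exchange_mixture"
    spec.params.update(dict(taus=list(taus), weights=list(weights)))
    spec.ground_truth["mean_residence_ps"] = float(
        weights[0] * taus[0] + weights[1] * taus[1]
    )
    spec.ground_truth["amplitudes"] = list(weights)
    spec.ground_truth["taus"] = list(taus)
    return traj, spec


# ------------------------------------------------------------- Brownian waters
def gen_brownian_box(
    diffusion: float = 0.2,
    n_waters: int = 100,
    dt: float = 1.0,
    n_frames: int = 200,
    seed: int = 0,
    box_length: float = 30.0,
) -> tuple[Trajectory, SyntheticSpec]:
    """Independent 3-D Brownian waters, wrapped into a cubic box.

    Per-axis step variance is 2*D*dt (Einstein relation: MSD = 6 D t).  The
    unwrapped coordinates are kept in the ground truth.
    """
    if diffusion < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0, box_length, size=(n_waters, 3))
    steps = rng.normal(
        scale=math.sqrt(2.0 * diffusion * dt), size=(n_frames - 1, n_waters, 3)
    ) if n_frames > 1 else np.zeros((0, n_waters, 3))
    unwrapped = np.concatenate(
        [start[None], start[None] + np.cumsum(steps, axis=0)], axis=0
    )
    o = np.mod(unwrapped, box_length)
    coords = np.empty((n_frames, 3 * n_waters, 3))
    coords[:, 0::3] = o
    coords[:, 1::3] = o + np.array([0, 0, OH_BOND])
    half = math.radians(HOH_ANGLE)
    coords[:, 2::3] = o + OH_BOND * np.array(
        [math.sin(half), 0.0, math.cos(half)]
    )
    atoms = _water_atom_table(n_waters)
    traj = Trajectory(coords, np.diag([box_length] * 3), atoms, dt=dt)
    spec = SyntheticSpec(
        generator="brownian_box",
        params=dict(diffusion=diffusion, n_waters=n_waters, dt=dt,
                    n_frames=n_frames, box_length=box_length),
        seed=seed,
        ground_truth=dict(diffusion=diffusion, unwrapped_o=unwrapped),
    )
    return traj, spec


# ------------------------------------------------------------------- toy IBS
def gen_toy_ibs(
    grid: tuple[int, int] = (2, 3),
    spacing: float = 7.4,
    n_waters: int = 10,
    n_pinned: int = 2,
    n_frames: int = 50,
    seed: int = 0,
    free_jitter: float = 0.8,
    pinned_jitter: float = 0.05,
    dt: float = 0.1,
) -> tuple[Trajectory, SyntheticSpec]:
    """Planar grid of hydroxyl-bearing pseudo-threonines under a water slab.

    Each pseudo-residue has CA (z=0), CB (z=1.5), OG1 (z=3.0) and HG1, so
    the CB->OG1 side-chain vector points along +z; in-plane ladder axes make
    the analytic theta_S = theta_T = 90 deg.  The first ``n_pinned`` waters
    are pinned in perfect H-bond geometry above the first hydroxyls with a
    frozen orientation; the rest jitter around slab home positions with a
    fresh random orientation every frame.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n_pinned > min(n_waters, grid[0] * grid[1]):
        raise ValueError("more pinned waters than sites/waters")
    rng = np.random.default_rng(seed)
    nx_, ny_ = grid
    n_sites = nx_ * ny_
    box = np.diag([nx_ * spacing, ny_ * spacing, 30.0])
    site_xy = np.array(
        [[(i % nx_ + 0.5) * spacing, (i // nx_ + 0.5) * spacing]
         for i in range(n_sites)]
    )
    rows = []
    for i in range(n_sites):
        for name, el in (("CA", "C"), ("CB", "C"), ("OG1", "O"), ("HG1", "H")):
            rows.append({"name": name, "resname": "THR", "resid": i + 1,
                         "element": el})
    atoms = _water_atom_table(n_waters, prefix_rows=rows)
    n_prot = 4 * n_sites
    coords = np.empty((n_frames, n_prot + 3 * n_waters, 3))
    for i, (x, y) in enumerate(site_xy):
        coords[:, 4 * i + 0] = [x, y, 0.0]
        coords[:, 4 * i + 1] = [x, y, 1.5]
        coords[:, 4 * i + 2] = [x, y, 3.0]
        coords[:, 4 * i + 3] = [x + 0.76, y, 3.58]  # HG1, ~0.96 A from OG1
    # free-water home positions: grid in the slab z in [8, 16]
    homes = np.column_stack(
        [rng.uniform(1.0, box[0, 0] - 1.0, n_waters),
         rng.uniform(1.0, box[1, 1] - 1.0, n_waters),
         rng.uniform(8.0, 16.0, n_waters)]
    )
    half = math.radians(HOH_ANGLE)
    h2_dir = np.array([math.sin(half), 0.0, -math.cos(half)])
    for t in range(n_frames):
        base = n_prot
        for wi in range(n_waters):
            if wi < n_pinned:
                og1 = coords[t, 4 * wi + 2]
                o = og1 + np.array([0, 0, 2.8]) + rng.normal(
                    scale=pinned_jitter, size=3
                )
                h1 = o + np.array([0, 0, -OH_BOND])
                h2 = o + OH_BOND * h2_dir
            else:
                o = homes[wi] + rng.normal(scale=free_jitter, size=3)
                dip = _random_unit(rng, 1)[0]
                hh = _perpendicular_unit(rng, dip[None])[0]
                h1, h2 = _water_h_positions(o, dip, hh)
            coords[t, base + 3 * wi] = o
            coords[t, base + 3 * wi + 1] = h1
            coords[t, base + 3 * wi + 2] = h2
    traj = Trajectory(coords, box, atoms, dt=dt)
    spec = SyntheticSpec(
        generator="toy_ibs",
        params=dict(grid=list(grid), spacing=spacing, n_waters=n_waters,
                    n_pinned=n_pinned, n_frames=n_frames,
                    free_jitter=free_jitter, pinned_jitter=pinned_jitter),
        seed=seed,
        ground_truth=dict(
            pinned_waters=list(range(n_pinned)),
            theta_S_deg=90.0,
            theta_T_deg=90.0,
            n_sites=n_sites,
        ),
    )
    return traj, spec


# ----------------------------------------------------------------------- I/O
def write_system(
    traj: Trajectory, out_prefix: str, fmt: str = "gro+xtc"
) -> list[str]:
    """Write a trajectory to standard formats so the I/O path is exercised.

    ``gro+xtc`` writes a GRO topology (first frame) plus an XTC trajectory;
    ``pdb`` writes a single multi-model PDB.  Returns the written paths.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader
    from MDAnalysis.lib.mdamath import triclinic_box

    resids = traj.atoms["resid"].to_numpy()
    unique_resids, resindex = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        traj.n_atoms, n_residues=len(unique_resids),
        atom_resindex=resindex, trajectory=True,
    )
    u.add_TopologyAttr("names", traj.atoms["name"].to_list())
    u.add_TopologyAttr(
        "resnames",
        traj.atoms.groupby("resid", sort=True)["resname"].first().to_list(),
    )
    u.add_TopologyAttr("resids", unique_resids)
    dims = np.array([triclinic_box(b[0], b[1], b[2]) for b in traj.boxes])
    u.load_new(
        traj.coords.astype(np.float32), format=MemoryReader,
        dimensions=dims, dt=traj.dt,
    )
    paths: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "gro+xtc":
            gro = f"{out_prefix}.gro"
            xtc = f"{out_prefix}.xtc"
            u.atoms.write(gro)
            with mda.Writer(xtc, traj.n_atoms) as w:
                for ts in u.trajectory:
                    w.write(u.atoms)
            paths = [gro, xtc]
        elif fmt == "pdb":
            pdb = f"{out_prefix}.pdb"
            with mda.Writer(pdb, traj.n_atoms, multiframe=True) as w:
                for ts in u.trajectory:
                    w.write(u.atoms)
            # readers only honour CRYST1 inside each MODEL block, so repeat
            # the per-frame cell there
            lines = open(pdb).read().splitlines(keepends=True)
            out_lines: list[str] = []
            frame_no = 0
            for line in lines:
                out_lines.append(line)
                if line.startswith("MODEL"):
                    d = dims[min(frame_no, len(dims) - 1)]
                    out_lines.append(
                        f"CRYST1{d[0]:9.3f}{d[1]:9.3f}{d[2]:9.3f}"
                        f"{d[3]:7.2f}{d[4]:7.2f}{d[5]:7.2f} P 1           1\n"
                    )
                    frame_no += 1
            with open(pdb, "w") as fh:
                fh.writelines(out_lines)
            paths = [pdb]
        else:
            raise ValueError(f"unknown output format {fmt!r}")
    return paths
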