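"""Shared synthetic fixtures; everything is generated at test time."""

import numpy as np
import pandas as pd
import pytest

from hydroshell.trajectory import Trajectory
from hydroshell import synthetic as syn


def make_water_trajectory(
    waters: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    box_length: float = 100.0,
    n_frames: int = 1,
) -> Trajectory:
    """Build a single/multi-frame trajectory from explicit (O, H1, H2) triples."""
    coords0 = np.array([p for w in waters for p in w], dtype=float)
    coords = np.repeat(coords0[None], n_frames, axis=0)
    atoms = pd.DataFrame(
        [
            {"name": n, "resname": "SOL", "resid": i + 1, "element": n[0]}
            for i in range(len(waters))
            for n in ("OW", "HW1", "HW2")
        ]
    )
    return Trajectory(coords, np.diag([box_length] * 3), atoms, dt=1.0)


def simple_water(o, direction=(0, 0, 1.0)):
    """A rigid water at ``o`` with its dipole along ``direction``."""
    o = np.asarray(o, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    perp = np.cross(d, [1.0, 0, 0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(d, [0, 1.0, 0])
    perp /= np.linalg.norm(perp)
    h1, h2 = syn._water_h_positions(o, d, perp)
    return o, h1, h2


@pytest.fixture(scope="session")
def lattice_ideal():
    """Zero-jitter diamond-cubic water lattice (64 waters, 1 frame)."""
    return syn.gen_tetrahedral_lattice(n_cells=2, n_frames=1, jitter_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def lattice_jittered():
    """Jittered lattice with generator-side brute-force H-bond counts."""
    return syn.gen_tetrahedral_lattice(
        n_cells=2, n_frames=3, jitter_sigma=0.25, seed=12
    )


@pytest.fixture(scope="session")
def toy_ibs():
    """Planar hydroxyl surface with 2 pinned + 10 free waters, 40 frames."""
    return syn.gen_toy_ibs(n_frames=40, n_waters=12, n_pinned=2, seed=13)


@pytest.fixture(scope="session")
def brownian():
    """Diffusive water box, D = 0.2 A^2/ps, 300 frames of 400 walkers."""
    return syn.gen_brownian_box(0.2, n_waters=400, dt=1.0, n_frames=300, seed=14)


@pytest.fixture(scope="session")
def exchanger():
    """Poisson shell exchanger, k_exit = 0.02/ps, 600 waters."""
    return syn.gen_exchange_trajectory(
        0.02, 0.0, n_waters=600, dt=1.0, n_frames=400, seed=15
    )
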