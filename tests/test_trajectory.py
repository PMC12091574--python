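"""Trajectory model: minimum image, water detection, selections, RDF, I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hydroshell.trajectory import (
    Frame,
    SiteSet,
    Trajectory,
    TrajectoryError,
    detect_waters,
    load_trajectory,
    minimum_image,
    minimum_image_vector,
    nearest_waters_to_sites,
    pair_distances,
    site_water_rdf,
)
from hydroshell import synthetic as syn

from conftest import make_water_trajectory, simple_water


def brute_force_min_image(d, box, reach=2):
    """Independent oracle: exhaustive scan over (2*reach+1)^3 images."""
    best = None
    for i, j, k in itertools.product(range(-reach, reach + 1), repeat=3):
        cand = d + i * box[0] + j * box[1] + k * box[2]
        n = np.linalg.norm(cand)
        if best is None or n < best[1]:
            best = (cand, n)
    return best[0]


class TestMinimumImage:
    def test_cubic_wraparound(self):
        frame = Frame(0.0, np.diag([10.0, 10, 10]), np.array([[1, 1, 1], [9, 1, 1]], float))
        assert np.allclose(minimum_image_vector(frame, 0, 1), [-2, 0, 0])

    def test_identity(self):
        frame = Frame(0.0, np.diag([10.0, 10, 10]), np.array([[3, 4, 5], [3, 4, 5]], float))
        assert np.allclose(minimum_image_vector(frame, 0, 0), [0, 0, 0])

    def test_triclinic_matches_brute_force(self):
        rng = np.random.default_rng(0)
        box = np.array([[10.0, 0, 0], [3.0, 9.0, 0], [2.0, 1.0, 8.0]])
        for _ in range(50):
            d = rng.uniform(-15, 15, 3)
            got = minimum_image(d, box)
            want = brute_force_min_image(d, box)
            assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(want), abs=1e-9)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        box = np.array([[10.0, 0, 0], [2.0, 9.0, 0], [1.0, 3.0, 8.0]])
        pts = rng.uniform(0, 10, (8, 3))
        d = pair_distances(pts, pts, box)
        assert np.allclose(d, d.T, atol=1e-9)
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_degenerate_box_rejected(self):
        with pytest.raises(TrajectoryError, match="degenerate"):
            minimum_image(np.zeros(3), np.zeros((3, 3)))


class TestWaterDetection:
    def test_atom_order_invariance(self):
        o, h1, h2 = simple_water([5, 5, 5])
        coords = np.array([h1, o, h2])  # H, O, H ordering inside the residue
        atoms = pd.DataFrame(
            [{"name": "HW1", "resname": "SOL", "resid": 1, "element": "H"},
             {"name": "OW", "resname": "SOL", "resid": 1, "element": "O"},
             {"name": "HW2", "resname": "SOL", "resid": 1, "element": "H"}]
        )
        w = detect_waters(atoms, coords, np.diag([20.0] * 3))
        assert w.n_waters == 1 and w.o[0] == 1

    def test_no_waters_detected(self):
        atoms = pd.DataFrame(
            [{"name": "CA", "resname": "THR", "resid": 1, "element": "C"}]
        )
        with pytest.raises(TrajectoryError, match="no waters detected"):
            detect_waters(atoms, np.zeros((1, 3)), np.diag([10.0] * 3))

    def test_bad_oh_distance_rejected(self):
        o = np.zeros(3)
        bad = make_water_trajectory
        atoms = pd.DataFrame(
            [{"name": n, "resname": "SOL", "resid": 1, "element": n[0]}
             for n in ("OW", "HW1", "HW2")]
        )
        coords = np.array([o, o + [3.0, 0, 0], o + [0, 0.96, 0]])
        with pytest.raises(TrajectoryError, match="O-H distance"):
            detect_waters(atoms, coords, np.diag([20.0] * 3))


class TestNearestWaters:
    def test_constructed_slab(self):
        waters = [simple_water([float(2 + 3 * i), 5, 5]) for i in range(10)]
        traj = make_water_trajectory(waters)
        sites = SiteSet("probe", np.array([0]))  # O of the first water
        got = nearest_waters_to_sites(traj, sites, 3)
        assert list(got) == [0, 1, 2]

    def test_k_equals_all(self):
        waters = [simple_water([float(2 + 3 * i), 5, 5]) for i in range(5)]
        traj = make_water_trajectory(waters)
        got = nearest_waters_to_sites(traj, SiteSet("probe", np.array([0])), 5)
        assert sorted(got) == list(range(5))

    def test_k_too_large(self):
        traj = make_water_trajectory([simple_water([5, 5, 5])])
        with pytest.raises(TrajectoryError, match="exceeds"):
            nearest_waters_to_sites(traj, SiteSet("probe", np.array([0])), 2)

    def test_matches_brute_force(self, toy_ibs):
        traj, _ = toy_ibs
        og = traj.site_set("og", resname="THR", atom_name="OG1")
        k = traj.waters.n_waters
        got = nearest_waters_to_sites(traj, og, k)
        # independent O(N * sites) scan
        frame = traj.frame(0)
        dmin = np.array(
            [min(np.linalg.norm(minimum_image(frame.coords[s] - frame.coords[o], frame.box))
                 for s in og.indices)
             for o in traj.waters.o]
        )
        want = np.lexsort((np.arange(k), dmin))
        assert np.array_equal(got, want)


class TestRDF:
    def test_ideal_gas_flat(self):
        rng = np.random.default_rng(7)
        n, L = 400, 20.0
        waters = [simple_water(rng.uniform(0, L, 3)) for _ in range(n)]
        traj = make_water_trajectory(waters, box_length=L)
        sites = SiteSet("probes", np.arange(0, 60, 3))  # 20 water O atoms
        g = site_water_rdf(traj, sites, r_max=8.0, dr=1.0)
        sel = g[g["r"] > 2.0]  # skip the noisy self/core region
        assert np.all(np.abs(sel["g"] - 1.0) < 0.3)

    def test_single_pair_delta(self):
        traj = make_water_trajectory(
            [simple_water([5, 5, 5]), simple_water([8, 5, 5])], box_length=30.0
        )
        g = site_water_rdf(traj, SiteSet("probe", np.array([0])), r_max=6.0, dr=0.5)
        nonzero = g[g["count"] > 0]
        # bins: the self water at r=0 and the partner at r=3
        assert set(np.round(nonzero["r"], 2)) == {0.25, 3.25}

    def test_lattice_first_peak(self, lattice_ideal):
        traj, spec = lattice_ideal
        g = site_water_rdf(traj, SiteSet("probe", np.array([0])), r_max=4.0, dr=0.2)
        g = g[g["r"] > 1.0]  # drop the self-pair bin at r = 0
        peak_r = g.loc[g["g"].idxmax(), "r"]
        assert peak_r == pytest.approx(spec.params["oo_distance"], abs=0.2)

    def test_bad_dr(self, lattice_ideal):
        traj, _ = lattice_ideal
        with pytest.raises(TrajectoryError, match="dr"):
            site_water_rdf(traj, SiteSet("probe", np.array([0])), 4.0, 0.0)


class TestIO:
    def test_gro_xtc_roundtrip(self, tmp_path, toy_ibs):
        traj, _ = toy_ibs
        paths = syn.write_system(traj, str(tmp_path / "toy"), fmt="gro+xtc")
        back = load_trajectory(*paths)
        assert back.n_frames == traj.n_frames
        assert back.waters.n_waters == traj.waters.n_waters
        # XTC stores single precision; coordinates survive to ~1e-3 A
        assert np.allclose(back.coords, traj.coords, atol=5e-3)

    def test_multimodel_pdb(self, tmp_path, toy_ibs):
        traj, _ = toy_ibs
        (pdb,) = syn.write_system(traj, str(tmp_path / "toy"), fmt="pdb")
        back = load_trajectory(pdb, dt_override=0.5)
        assert back.n_frames == traj.n_frames
        assert back.dt == pytest.approx(0.5)

    def test_unreadable_input(self, tmp_path):
        bad = tmp_path / "nope.gro"
        with pytest.raises(TrajectoryError):
            load_trajectory(str(bad))

    def test_no_water_topology(self, tmp_path):
        # protein-only system written and read back
        atoms = pd.DataFrame(
            [{"name": "CA", "resname": "ALA", "resid": 1, "element": "C"},
             {"name": "CB", "resname": "ALA", "resid": 1, "element": "C"}]
        )
        traj = Trajectory(
            np.zeros((1, 2, 3)) + 5.0, np.diag([20.0] * 3), atoms,
            require_waters=False,
        )
        paths = syn.write_system(traj, str(tmp_path / "prot"), fmt="pdb")
        with pytest.raises(TrajectoryError, match="no waters detected"):
            load_trajectory(paths[0])
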