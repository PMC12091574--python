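"""IBS geometry: orientation angles, side-chain RMSD, spacings, distances."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hydroshell import protein as prot
from hydroshell.trajectory import Trajectory


def make_protein(residues: dict[int, dict[str, np.ndarray]],
                 n_frames: int = 1, box_length: float = 100.0) -> Trajectory:
    """Trajectory from {resid: {atom_name: xyz}}; waters not required."""
    rows, coords0 = [], []
    for resid in sorted(residues):
        for name, pos in residues[resid].items():
            rows.append(
                {"name": name, "resname": "THR", "resid": resid,
                 "element": name[0]}
            )
            coords0.append(np.asarray(pos, float))
    coords = np.repeat(np.array(coords0)[None], n_frames, axis=0)
    return Trajectory(
        coords, np.diag([box_length] * 3), pd.DataFrame(rows),
        dt=1.0, require_waters=False,
    )


def thr(resid, ca, cb=None, og1=None):
    ca = np.asarray(ca, float)
    cb = np.asarray(cb if cb is not None else ca + [0, 0, 1.5], float)
    og1 = np.asarray(og1 if og1 is not None else cb + [0, 0, 1.4], float)
    return {"CA": ca, "CB": cb, "OG1": og1}


class TestOrientationAngles:
    def test_theta_s_parallel(self):
        # side-chain vector along the ladder axis -> 0 degrees
        res = {
            1: thr(1, [0, 0, 0], cb=[0, 0, 1.5], og1=[1.4, 0, 1.5]),
            9: thr(9, [10, 0, 0]),
        }
        traj = make_protein(res)
        ladder = prot.ThrLadder([1, 9])
        (series, *_) = prot.theta_S(traj, ladder, (1, 9))
        assert series.angles[0] == pytest.approx(0.0, abs=1e-9)

    def test_theta_s_hand_geometry_45(self):
        res = {
            1: thr(1, [0, 0, 0], cb=[0, 0, 1.5], og1=[1.0, 1.0, 1.5]),
            9: thr(9, [10, 0, 0]),
        }
        traj = make_protein(res)
        (series, *_) = prot.theta_S(traj, prot.ThrLadder([1, 9]), (1, 9))
        assert series.angles[0] == pytest.approx(45.0, abs=1e-9)

    def test_theta_t_neighbor_axis(self):
        res = {
            1: thr(1, [0, 0, 0], cb=[0, 0, 1.5], og1=[0, 0, 3.0]),
            2: thr(2, [7.4, 0, 0]),
        }
        traj = make_protein(res)
        series = prot.theta_T(traj, prot.ThrLadder([1, 2]))
        assert len(series) == 1  # terminal residue skipped
        assert series[0].angles[0] == pytest.approx(90.0, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(2)
        res = {
            i: thr(i, rng.uniform(0, 10, 3), cb=rng.uniform(0, 10, 3),
                   og1=rng.uniform(0, 10, 3))
            for i in (1, 2, 3)
        }
        traj = make_protein(res)
        rot = Rotation.random(random_state=5)
        traj_rot = make_protein(res)
        traj_rot.coords = rot.apply(traj.coords[0])[None] + 50.0
        for f in (prot.theta_T,):
            a = f(traj, prot.ThrLadder([1, 2, 3]))
            b = f(traj_rot, prot.ThrLadder([1, 2, 3]))
            for sa, sb in zip(a, b):
                assert np.allclose(sa.angles, sb.angles, atol=1e-6)

    def test_distribution_normalized(self):
        res = {1: thr(1, [0, 0, 0]), 2: thr(2, [7.4, 0, 0])}
        traj = make_protein(res, n_frames=5)
        series = prot.theta_T(traj, prot.ThrLadder([1, 2]))[0]
        total = np.sum(series.distribution["density"]) * 2.0  # 2-degree bins
        assert total == pytest.approx(1.0, abs=1e-9)


class TestSidechainRMSD:
    def _system(self, n_frames=2):
        res = {
            1: {"CA": [0, 0, 0], "C": [1.2, 0, 0], "N": [-1.2, 0, 0],
                "CB": [0, 1.5, 0], "OG1": [0, 2.9, 0], "CG2": [1.2, 2.2, 0]},
            2: {"CA": [5, 0, 0], "C": [6.2, 0, 0], "N": [3.8, 0, 0],
                "CB": [5, 1.5, 0], "OG1": [5, 2.9, 0], "CG2": [6.2, 2.2, 0]},
        }
        return make_protein(res, n_frames=n_frames)

    def test_reference_frame_zero(self):
        traj = self._system()
        rmsd = prot.sidechain_rmsd(traj, [1, 2])
        assert np.allclose(rmsd["rmsd"], 0.0, atol=1e-9)

    def test_rigid_motion_removed(self):
        traj = self._system()
        rot = Rotation.from_euler("z", 35, degrees=True)
        traj.coords[1] = rot.apply(traj.coords[0]) + np.array([3.0, -2.0, 1.0])
        rmsd = prot.sidechain_rmsd(traj, [1, 2])
        assert np.allclose(rmsd["rmsd"], 0.0, atol=1e-7)

    def test_single_displaced_atom_closed_form(self):
        traj = self._system()
        d = 0.6
        og1 = traj.atoms.index[
            (traj.atoms["resid"] == 1) & (traj.atoms["name"] == "OG1")
        ][0]
        traj.coords[1, og1] += [0, 0, d]
        rmsd = prot.sidechain_rmsd(traj, [1])
        got = rmsd[(rmsd["frame"] == 1)]["rmsd"].iloc[0]
        m = 3  # CB, OG1, CG2 heavy side-chain atoms
        assert got == pytest.approx(d / np.sqrt(m), rel=1e-6)


class TestSpacings:
    def test_static_pair(self):
        res = {1: thr(1, [0, 0, 0]), 3: thr(3, [6.9, 0, 0])}
        traj = make_protein(res, n_frames=3)
        df = prot.ladder_spacing(traj, prot.ThrLadder([1, 3]), "intra_strand_TxT")
        assert df.attrs["overall_mean"] == pytest.approx(6.9)

    def test_harmonic_jitter_second_order(self):
        rng = np.random.default_rng(9)
        d, a, n = 7.0, 0.15, 4000
        res = {1: thr(1, [0, 0, 0]), 2: thr(2, [d, 0, 0])}
        traj = make_protein(res, n_frames=n)
        # transverse harmonic jitter of one CA
        ca2 = traj.atoms.index[
            (traj.atoms["resid"] == 2) & (traj.atoms["name"] == "CA")
        ][0]
        traj.coords[:, ca2, 1] += a * np.sin(np.linspace(0, 40 * np.pi, n))
        df = prot.ladder_spacing(traj, prot.ThrLadder([1, 2]))
        mean = df.attrs["overall_mean"]
        assert abs(mean - d) < a**2 / d  # mean = d + O(a^2/d)
        assert mean > d  # transverse jitter only lengthens the mean

    def test_no_qualifying_pairs(self):
        res = {1: thr(1, [0, 0, 0]), 2: thr(2, [7, 0, 0])}
        traj = make_protein(res)
        with pytest.raises(prot.ProteinGeometryError, match="no qualifying"):
            prot.ladder_spacing(traj, prot.ThrLadder([1, 2]), "intra_strand_TxT")


class TestLoopDistances:
    def test_fixed_pair_delta(self):
        res = {
            1: {"CA": [0, 0, 0], "CB": [0, 1.5, 0]},
            2: {"CA": [5, 0, 0], "CB": [5, 1.5, 0]},
        }
        traj = make_protein(res, n_frames=4)
        df = prot.stacking_distances(traj, [1, 2])
        assert df["mean"].iloc[0] == pytest.approx(5.0)
        assert df["std"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_identity_pair_rejected(self):
        res = {1: {"CA": [0, 0, 0], "CB": [0, 1.5, 0]}}
        traj = make_protein(res)
        with pytest.raises(prot.ProteinGeometryError, match="duplicate"):
            prot.stacking_distances(traj, [1, 1])

    def test_gaussian_spread_moments(self):
        rng = np.random.default_rng(10)
        n, d, sigma = 3000, 6.0, 0.3
        res = {
            1: {"CA": [0, 0, 0], "CB": [0, 0, 0]},
            2: {"CA": [d, 0, 0], "CB": [d, 0, 0]},
        }
        traj = make_protein(res, n_frames=n)
        traj.coords[:, 3, 0] += rng.normal(scale=sigma, size=n)  # CB of resid 2
        df = prot.stacking_distances(traj, [1, 2])
        assert df["mean"].iloc[0] == pytest.approx(d, abs=0.05)
        assert df["std"].iloc[0] == pytest.approx(sigma, rel=0.1)

    def test_ser_gly_sharp_vs_broad(self):
        rng = np.random.default_rng(11)
        n = 2000
        res = {
            1: {"OG": [0, 0, 0]}, 2: {"O": [2.7, 0, 0]},   # stable H-bond
            3: {"OG": [10, 0, 0]}, 4: {"O": [14.0, 0, 0]},  # loose loop
        }
        traj = make_protein(res, n_frames=n)
        traj.coords[:, 3, 0] += rng.normal(scale=1.0, size=n)  # loose Gly O
        df = prot.ser_gly_distances(traj, [(1, 2), (3, 4)])
        assert df["iqr"].iloc[0] < 1e-9 < df["iqr"].iloc[1]

    def test_unresolvable_atoms(self):
        res = {1: {"CA": [0, 0, 0]}}
        traj = make_protein(res)
        with pytest.raises(prot.ProteinGeometryError, match="cannot resolve"):
            prot.ser_gly_distances(traj, [(1, 1)])
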