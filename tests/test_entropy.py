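"""Entropy estimators: orientation angles, closed forms, bias, convergence."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydroshell.entropy import (
    KB_KCAL,
    entropy_convergence,
    grid_bin_measures,
    orientation_angles,
    rotational_entropy,
    translational_entropy,
)
from hydroshell import synthetic as syn

T = 273.0
KT = KB_KCAL * T


class TestOrientationAngles:
    def test_dipole_parallel_to_solute(self):
        o, h1, h2 = np.zeros(3), *syn._water_h_positions(
            np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0])
        )
        s = orientation_angles(o, h1, h2, np.array([0, 0, 5.0]))
        assert s.theta == pytest.approx(0.0, abs=1e-6)
        assert s.degenerate.all()  # normal undefined when parallel

    def test_orthogonal_construction(self):
        # solute along +z, dipole along +x, H-H along +y:
        # normal = z x x = y, chi = angle(y, y) = 0
        o = np.zeros(3)
        h1, h2 = syn._water_h_positions(o, np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        s = orientation_angles(o, h1, h2, np.array([0, 0, 5.0]))
        assert s.theta == pytest.approx(90.0, abs=1e-6)
        assert s.chi == pytest.approx(0.0, abs=1e-6)
        assert not s.degenerate.any()

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(3)
        o = rng.uniform(-5, 5, (100, 3))
        dip = rng.normal(size=(100, 3))
        dip /= np.linalg.norm(dip, axis=1, keepdims=True)
        hh = np.cross(dip, rng.normal(size=(100, 3)))
        hh /= np.linalg.norm(hh, axis=1, keepdims=True)
        h1 = np.empty_like(o)
        h2 = np.empty_like(o)
        for i in range(100):
            h1[i], h2[i] = syn._water_h_positions(o[i], dip[i], hh[i])
        sol = rng.uniform(-5, 5, (100, 3))
        base = orientation_angles(o, h1, h2, sol)
        rot = Rotation.random(random_state=7)
        rotated = orientation_angles(
            rot.apply(o), rot.apply(h1), rot.apply(h2), rot.apply(sol)
        )
        assert np.allclose(base.theta, rotated.theta, atol=1e-9)
        assert np.allclose(base.chi, rotated.chi, atol=1e-9)

    def test_h_swap_maps_chi(self):
        o = np.zeros(3)
        h1, h2 = syn._water_h_positions(
            o, np.array([1.0, 0, 0]), np.array([0, 0.6, 0.8])
        )
        a = orientation_angles(o, h1, h2, np.array([0, 0, 5.0]))
        b = orientation_angles(o, h2, h1, np.array([0, 0, 5.0]))
        assert a.theta == pytest.approx(b.theta)
        assert float(a.chi + b.chi) == pytest.approx(180.0, abs=1e-9)


class TestRotationalEntropy:
    def test_uniform_is_zero(self):
        th, ch, spec = syn.gen_oriented_waters("uniform", 10**6, seed=21)
        assert rotational_entropy(th, ch, T) == pytest.approx(0.0, abs=0.01)

    def test_half_domain_closed_form(self):
        th, ch, spec = syn.gen_oriented_waters("half_domain", 10**6, seed=22)
        want = -KT * math.log(2.0)
        assert want == pytest.approx(-0.376, abs=0.001)
        assert rotational_entropy(th, ch, T) == pytest.approx(want, abs=0.01)
        assert spec.ground_truth["ts_rot"] == pytest.approx(want)

    def test_single_bin_closed_form(self):
        bin_index = (5, 12)
        th, ch, spec = syn.gen_oriented_waters(
            "single_bin", 10**5, seed=23, bin_index=bin_index
        )
        _, _, measures, c = grid_bin_measures((30, 30))
        want = -KT * math.log(c / measures[bin_index])
        assert rotational_entropy(th, ch, T) == pytest.approx(want, abs=0.01)
        assert spec.ground_truth["ts_rot"] == pytest.approx(want)

    def test_concentrated_vs_quadrature_and_closed_form(self):
        kappa = 4.0
        th, ch, spec = syn.gen_oriented_waters(
            "concentrated", 10**6, seed=24, kappa=kappa
        )
        quad = spec.ground_truth["ts_rot"]
        closed = KT * (
            math.log(math.sinh(kappa) / kappa) - kappa / math.tanh(kappa) + 1
        )
        assert quad == pytest.approx(closed, rel=1e-4)
        assert rotational_entropy(th, ch, T) == pytest.approx(quad, rel=0.02)

    def test_estimator_nonpositive_and_bias_shrinks(self):
        """Plug-in estimate is <= 0 on uniform data, with bias vanishing in n."""
        th, ch, _ = syn.gen_oriented_waters("uniform", 10**6, seed=25)
        vals = [
            rotational_entropy(th[:n], ch[:n], T, min_samples=0)
            for n in (10**3, 10**4, 10**5, 10**6)
        ]
        assert all(v <= 1e-12 for v in vals)
        assert abs(vals[0]) > abs(vals[1]) > abs(vals[2]) > abs(vals[3])

    def test_convergence_plateau(self):
        """Entropy on growing prefixes plateaus (< 5% over the last doubling)."""
        th, ch, _ = syn.gen_oriented_waters("concentrated", 4 * 10**5, seed=26)
        table = entropy_convergence(th, ch, fractions=[0.25, 0.5, 1.0])
        last, prev = table["ts_rot"].iloc[-1], table["ts_rot"].iloc[-2]
        assert abs(last - prev) < 0.05 * abs(last)

    def test_errors(self):
        with pytest.raises(ValueError):
            rotational_entropy(np.array([]), np.array([]))
        with pytest.raises(ValueError, match="minimum sample"):
            rotational_entropy(np.ones(10), np.ones(10), min_samples=100)


class TestTranslationalEntropy:
    def test_uniform_is_zero(self):
        rng = np.random.default_rng(31)
        pos = rng.uniform(0, 4.0, (10**5, 3))
        cell = (np.zeros(3), np.full(3, 4.0))
        assert translational_entropy(pos, T, cell=cell) == pytest.approx(0.0, abs=0.01)

    def test_octant_closed_form(self):
        rng = np.random.default_rng(32)
        pos = rng.uniform(0, 2.0, (10**5, 3))  # one octant of a 4 A cell
        cell = (np.zeros(3), np.full(3, 4.0))
        want = -KT * math.log(8.0)
        assert want == pytest.approx(-1.128, abs=0.001)
        assert translational_entropy(pos, T, cell=cell) == pytest.approx(want, abs=0.02)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(33)
        sigma = 1.0
        pos = rng.normal(scale=sigma, size=(10**5, 3))
        lim = 5.0 * sigma
        cell = (np.full(3, -lim), np.full(3, lim))
        v_cell = (2 * lim) ** 3
        want = KT * (1.5 * math.log(2 * math.pi * math.e * sigma**2)
                     - math.log(v_cell))
        got = translational_entropy(pos, T, voxels=(20, 20, 20), cell=cell)
        assert got == pytest.approx(want, rel=0.02)

    def test_degenerate_cell(self):
        with pytest.raises(ValueError, match="degenerate"):
            translational_entropy(
                np.zeros((200, 3)), T, cell=(np.zeros(3), np.zeros(3))
            )


class TestProfileOrdering:
    def test_mixture_ordering_matches_concentration(self):
        """Recovered TS ordering reverses the concentration-parameter order."""
        streams, spec = syn.gen_orientation_mixture(
            [0.0, 2.0, 8.0], n_samples=10**5, seed=41
        )
        est = [rotational_entropy(*streams[i], T) for i in range(3)]
        assert est[0] > est[1] > est[2]
        truth = spec.ground_truth["ts_rot_per_label"]
        assert np.argsort(est).tolist() == np.argsort(truth).tolist()

    def test_frozen_label_ranks_first(self, toy_ibs):
        from hydroshell.entropy import entropy_profile
        from hydroshell.permutation import permute_trajectory

        traj, spec = toy_ibs
        pmap = permute_trajectory(traj)
        og = traj.site_set("og", resname="THR", atom_name="OG1")
        prof = entropy_profile(
            traj, pmap, np.arange(traj.waters.n_waters), og, min_samples=1
        )
        top = set(prof.head(len(spec.ground_truth["pinned_waters"]))["water_label"])
        assert top == set(spec.ground_truth["pinned_waters"])
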