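"""Superposition, RMSD triage, and the opening-angle order parameter."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import loxtraj as lx
from loxtraj.errors import GeometryError
from loxtraj.geometry import AngleSeries, RmsdSeries, _angle_deg
from loxtraj.structure_io import AtomIndexSet


def _series(values, times=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None else times
    return RmsdSeries(times=t, rmsd=values, reference_frame=0)


def _grid_rmsd_oracle(ref, mob, n_coarse=50_000, seed=0):
    """Independent brute-force search for the minimal superposition RMSD.

    Dense scan over random rotations followed by stochastic refinement
    with shrinking rotation-vector perturbations; never calls the Kabsch
    path it checks. Accuracy ~1e-6 Å on few-point sets.
    """
    ref = ref - ref.mean(axis=0)
    mob = mob - mob.mean(axis=0)

    def batch_rmsd(rots):
        moved = np.einsum("nij,kj->nki", rots, mob)
        return np.sqrt(np.mean(np.sum((ref[None] - moved) ** 2, axis=2),
                               axis=1))

    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_coarse, random_state=rng).as_matrix()
    r = batch_rmsd(rots)
    best_i = int(np.argmin(r))
    best_rot = Rotation.from_matrix(rots[best_i])
    best = float(r[best_i])
    for scale in (0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4):
        perturb = Rotation.from_rotvec(
            rng.normal(scale=scale, size=(3000, 3)))
        cand = (perturb * best_rot).as_matrix()
        rr = batch_rmsd(cand)
        i = int(np.argmin(rr))
        if rr[i] < best:
            best = float(rr[i])
            best_rot = Rotation.from_matrix(cand[i])
    return best


class TestCenterOfMass:
    def test_symmetry_weighted_and_identity(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        s01 = AtomIndexSet(np.array([0, 1]))
        assert lx.center_of_mass(coords, s01, np.ones(3))[0] == 1.0
        com = lx.center_of_mass(coords, AtomIndexSet(np.array([0, 2])),
                                np.array([1.0, 1.0, 3.0]))
        assert com[0] == pytest.approx(3.0)
        single = lx.center_of_mass(coords, AtomIndexSet(np.array([1])),
                                   np.ones(3))
        assert np.allclose(single, [2.0, 0, 0])

    def test_empty_set_rejected(self):
        with pytest.raises(GeometryError):
            lx.center_of_mass(np.zeros((3, 3)),
                              AtomIndexSet(np.array([], dtype=int)),
                              np.ones(3))


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        R, t, r = lx.kabsch_superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_zero_rmsd_under_rigid_motion(self, rng):
        pts = rng.normal(size=(8, 3))
        R0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R0.T + np.array([3.0, 4.0, 0.0])
        R, t, r = lx.kabsch_superpose(pts, moved)
        assert r == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(moved @ R.T + t, pts, atol=1e-6)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_rotation_grid_oracle(self, rng):
        ref = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 2.0, 0],
                        [0.5, 0.5, 1.5]])
        mob = ref.copy()
        mob[3] += [0.6, -0.8, 0.0]  # 1 Å displacement of one point
        _, _, r = lx.kabsch_superpose(ref, mob)
        oracle = _grid_rmsd_oracle(ref, mob)
        assert r == pytest.approx(oracle, abs=1e-3)
        # on random <=6-point sets as well
        for _ in range(3):
            a = rng.normal(size=(5, 3))
            b = a + rng.normal(scale=0.5, size=a.shape)
            _, _, r = lx.kabsch_superpose(a, b)
            assert r <= _grid_rmsd_oracle(a, b) + 1e-3

    @pytest.mark.parametrize("pts", [
        np.zeros((2, 3)),
        np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),  # collinear
    ])
    def test_degenerate_sets_rejected(self, pts):
        with pytest.raises(GeometryError):
            lx.kabsch_superpose(pts, pts)


class TestRmsdSeries:
    def _traj(self, frames, model):
        return lx.Trajectory(model=model, frames=frames,
                             times=np.arange(len(frames), dtype=float))

    def test_identical_and_rigidly_moved_frames_are_zero(self, toy_model,
                                                         rng):
        base = toy_model.coordinates
        frames = [base.copy()]
        for _ in range(4):
            R = Rotation.random(random_state=rng.integers(2 ** 31)
                                ).as_matrix()
            frames.append(base @ R.T + rng.normal(scale=5.0, size=3))
        traj = self._traj(np.array(frames), toy_model)
        sel = lx.select(toy_model, "name CA")
        series = lx.rmsd_series(traj, sel, 0)
        assert np.all(series.rmsd < 1e-6)
        assert series.rmsd[0] == 0.0

    def test_gaussian_noise_gives_sqrt3_sigma(self, toy_model, rng):
        base = toy_model.coordinates
        sel = lx.select(toy_model, "chain B or chain C")  # ~1000 atoms
        sigma = 1.0
        frames = [base.copy()]
        for _ in range(20):
            f = base.copy()
            f[sel.indices] += rng.normal(scale=sigma,
                                         size=(len(sel), 3))
            frames.append(f)
        traj = self._traj(np.array(frames), toy_model)
        series = lx.rmsd_series(traj, sel, 0)
        assert np.mean(series.rmsd[1:]) == pytest.approx(
            np.sqrt(3) * sigma, rel=0.05)

    def test_invalid_reference_frame(self, toy_model):
        traj = self._traj(toy_model.coordinates[None], toy_model)
        with pytest.raises(IndexError):
            lx.rmsd_series(traj, lx.select(toy_model, "name CA"), 5)


class TestStabilityTriage:
    @pytest.mark.parametrize("median,expected", [
        (3.5, "stable"), (6.0, "intermediate"), (13.5, "unstable")])
    def test_band_labels(self, median, expected):
        lab = lx.classify_stability(_series(np.full(100, median)))
        assert lab.label == expected
        assert lab.median_rmsd == pytest.approx(median)

    def test_trailing_window_only(self):
        # early instability forgiven: converged tail is what counts
        vals = np.concatenate([np.full(50, 20.0), np.full(50, 3.0)])
        assert lx.classify_stability(_series(vals)).label == "stable"

    def test_monotone_in_rmsd(self, rng):
        order = {"stable": 0, "intermediate": 1, "unstable": 2}
        vals = rng.uniform(1, 6, size=200)
        for bump in (0.0, 3.0, 8.0, 20.0):
            labels = [lx.classify_stability(_series(vals + b)).label
                      for b in (bump, bump + 2.0)]
            assert order[labels[1]] >= order[labels[0]]


class TestOpeningAngle:
    @pytest.mark.parametrize("a,b,c,expected", [
        ((0, 1, 0), (0, 0, 0), (1, 0, 0), 90.0),
        ((0, 0, 0), (2, 0, 0), (4, 0, 0), 180.0),
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
    ])
    def test_closed_form_vertex_angles(self, a, b, c, expected):
        got = _angle_deg(np.array(a, float), np.array(b, float),
                         np.array(c, float))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_model, partition, rng):
        base = toy_model.coordinates
        frames = [base]
        for _ in range(100):
            R = Rotation.random(random_state=rng.integers(2 ** 31)
                                ).as_matrix()
            frames.append(base @ R.T + rng.normal(scale=10.0, size=3))
        traj = lx.Trajectory(model=toy_model, frames=np.array(frames),
                             times=np.arange(101, dtype=float))
        series = lx.opening_angle_series(traj, partition)
        assert np.abs(series.theta - series.theta[0]).max() < 1e-9

    def test_coincident_centers_rejected(self, toy_model):
        part = lx.DomainPartition(
            beta_barrel=lx.select(toy_model, "chain B"),
            catalytic_domain=lx.select(toy_model, "chain C and not name FE"),
            scaffold=lx.select(toy_model, "chain P"))
        frames = toy_model.coordinates[None].copy()
        frames[0, part.scaffold.indices] = lx.center_of_mass(
            frames[0], part.catalytic_domain, toy_model.masses)
        traj = lx.Trajectory(model=toy_model, frames=frames,
                             times=np.array([0.0]))
        with pytest.raises(GeometryError):
            lx.opening_angle_series(traj, part)


class TestAngleShift:
    def _angle(self, values):
        return AngleSeries(times=np.arange(len(values), dtype=float),
                           theta=np.asarray(values, dtype=float))

    def test_self_shift_is_exactly_zero(self, rng):
        s = self._angle(rng.uniform(80, 120, size=500))
        assert lx.angle_shift(s, s) == 0.0

    def test_membrane_association_shift_recovered(self, toy_model):
        from loxtraj import synthetic as syn
        closed, _ = lx.simulate_two_state_trajectory(
            toy_model, syn.solution_preset(n_frames=2000, seed=5))
        opened, _ = lx.simulate_two_state_trajectory(
            toy_model, syn.membrane_preset(n_frames=2000, seed=6))
        part = lx.DomainPartition(
            beta_barrel=lx.select(toy_model, "chain B"),
            catalytic_domain=lx.select(toy_model, "chain C and not name FE"),
            scaffold=lx.select(toy_model, "chain P"))
        sa = lx.opening_angle_series(closed, part)
        sb = lx.opening_angle_series(opened, part)
        assert lx.angle_shift(sa, sb) == pytest.approx(20.0, abs=0.5)

    def test_substrate_binding_shift_is_negative(self, toy_model):
        from loxtraj import synthetic as syn
        pre, _ = lx.simulate_two_state_trajectory(
            toy_model, syn.DynamicsSpec(n_frames=800, theta_closed=110.0,
                                        theta_open=110.0,
                                        p_closed_to_open=0.0, seed=7))
        bound, _ = lx.simulate_two_state_trajectory(
            toy_model, syn.substrate_preset(n_frames=800, seed=8))
        part = lx.DomainPartition(
            beta_barrel=lx.select(toy_model, "chain B"),
            catalytic_domain=lx.select(toy_model, "chain C and not name FE"),
            scaffold=lx.select(toy_model, "chain P"))
        shift = lx.angle_shift(lx.opening_angle_series(pre, part),
                               lx.opening_angle_series(bound, part))
        assert shift < 0
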