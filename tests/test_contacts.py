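"""Interface contacts, frequencies, and hydrogen-bond detection."""

import numpy as np
import pytest

import loxtraj as lx
from loxtraj.errors import ConfigurationError, GeometryError
from loxtraj.structure_io import Atom


def _model(spec_rows, coords):
    """spec_rows: (chain, resid, name, element, resname)."""
    atoms = [Atom(serial=i + 1, name=n, element=e, residue_name=rn,
                  residue_id=r, chain_id=c, mass=12.0, vdw_radius=1.7)
             for i, (c, r, n, e, rn) in enumerate(spec_rows)]
    return lx.StructureModel.from_atoms(atoms, np.asarray(coords, float))


def _two_residue_model(separation):
    return _model(
        [("A", 1, "CA", "C", "GLY"), ("B", 1, "CA", "C", "GLY")],
        [[0, 0, 0], [separation, 0, 0]])


def _sets(model, expr_a, expr_b):
    return lx.select(model, expr_a), lx.select(model, expr_b)


class TestContactMap:
    def test_single_pair_within_cutoff(self):
        m = _two_residue_model(4.0)
        a, b = _sets(m, "chain A", "chain B")
        recs = lx.contact_map(m, a, b, cutoff=4.5)
        assert len(recs) == 1
        assert recs[0].min_distance == pytest.approx(4.0)

    def test_pair_beyond_cutoff_is_empty(self):
        m = _two_residue_model(5.0)
        a, b = _sets(m, "chain A", "chain B")
        assert lx.contact_map(m, a, b, cutoff=4.5) == []

    def test_matches_all_pairs_enumeration(self, rng):
        # 3 residues vs 2 residues, several atoms each, random geometry
        rows, coords = [], []
        for c, nres in (("A", 3), ("B", 2)):
            for r in range(1, nres + 1):
                for k, name in enumerate(("N", "CA", "O")):
                    rows.append((c, r, name, name[0], "GLY"))
                    coords.append(rng.uniform(-4, 4, size=3))
        m = _model(rows, coords)
        a, b = _sets(m, "chain A", "chain B")
        recs = lx.contact_map(m, a, b, cutoff=4.5)
        got = {(r.residue_a[:2], r.residue_b[:2]):
               pytest.approx(r.min_distance) for r in recs}
        # brute-force oracle over all residue pairs
        expected = {}
        for ra in range(1, 4):
            ia = [i for i in range(m.n_atoms)
                  if m.chains[i] == "A" and m.resids[i] == ra]
            for rb in range(1, 3):
                ib = [i for i in range(m.n_atoms)
                      if m.chains[i] == "B" and m.resids[i] == rb]
                dmin = min(np.linalg.norm(m.coordinates[i] -
                                          m.coordinates[j])
                           for i in ia for j in ib)
                if dmin <= 4.5:
                    expected[(("A", ra), ("B", rb))] = dmin
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == expected[k]

    def test_symmetric_under_swap(self, rng):
        rows, coords = [], []
        for c in "AB":
            for r in range(1, 4):
                rows.append((c, r, "CA", "C", "GLY"))
                coords.append(rng.uniform(-5, 5, size=3))
        m = _model(rows, coords)
        a, b = _sets(m, "chain A", "chain B")
        fwd = {(r.residue_a, r.residue_b) for r in
               lx.contact_map(m, a, b)}
        rev = {(r.residue_b, r.residue_a) for r in
               lx.contact_map(m, b, a)}
        assert fwd == rev

    def test_cutoff_monotonicity(self, rng):
        rows = [("A", r, "CA", "C", "GLY") for r in range(1, 6)] + \
               [("B", r, "CA", "C", "GLY") for r in range(1, 6)]
        m = _model(rows, rng.uniform(-6, 6, size=(10, 3)))
        a, b = _sets(m, "chain A", "chain B")
        small = {(r.residue_a, r.residue_b)
                 for r in lx.contact_map(m, a, b, cutoff=3.5)}
        large = {(r.residue_a, r.residue_b)
                 for r in lx.contact_map(m, a, b, cutoff=6.0)}
        assert small <= large

    def test_overlapping_sets_rejected(self):
        m = _two_residue_model(4.0)
        s = lx.select(m, "chain A or chain B")
        with pytest.raises(GeometryError):
            lx.contact_map(m, s, lx.select(m, "chain B"))


class TestContactFrequency:
    def _traj(self, model, frames):
        return lx.Trajectory(model=model, frames=np.asarray(frames, float),
                             times=np.arange(len(frames), dtype=float))

    def test_half_time_contact_gives_half_frequency(self):
        m = _two_residue_model(4.0)
        near = m.coordinates.copy()
        far = near.copy()
        far[1, 0] = 9.0
        traj = self._traj(m, [near] * 50 + [far] * 50)
        a, b = _sets(m, "chain A", "chain B")
        table = lx.contact_frequency(traj, a, b).table
        assert len(table) == 1
        assert table.iloc[0].frequency == pytest.approx(0.5)
        assert table.iloc[0].normalized == 1.0  # single pair anchors at 1

    def test_scripted_ratio_recovered(self, toy_model, membrane_run):
        traj, labels = membrane_run
        lox = lx.select(toy_model, "chain C and not name FE")
        scaffold = lx.select(toy_model, "chain P")
        table = lx.contact_frequency(traj, lox, scaffold).table

        def raw(resid_a, resid_b):
            row = table[(table.resid_a == resid_a)
                        & (table.resid_b == resid_b)
                        & (table.chain_b == "P")]
            return 0 if row.empty else int(row.iloc[0].raw_count)

        # generator script is the oracle: recorded per-frame flags
        for (ra, rb), key in ((((10), (20)), (("C", 10), ("P", 20))),
                              (((11), (21)), (("C", 11), ("P", 21)))):
            expected = int(labels.contact_flags[key].sum())
            assert abs(raw(ra, rb) - expected) <= 1  # one frame quantum

    def test_frequencies_in_unit_interval_and_normalized_anchor(
            self, toy_model, membrane_run):
        traj, _ = membrane_run
        lox = lx.select(toy_model, "chain C and not name FE")
        scaffold = lx.select(toy_model, "chain P")
        table = lx.contact_frequency(traj, lox, scaffold).table
        assert len(table) > 0
        assert ((table.frequency >= 0) & (table.frequency <= 1)).all()
        assert table.normalized.max() == 1.0


class TestHBonds:
    def _donor_acceptor_model(self, acceptor_xyz, with_h=True):
        rows = [("A", 1, "N", "N", "GLY")]
        coords = [[0.0, 0, 0]]
        if with_h:
            rows.append(("A", 1, "H", "H", "GLY"))
            coords.append([1.0, 0, 0])
        rows.append(("B", 1, "O", "O", "HOH"))
        coords.append(list(acceptor_xyz))
        return _model(rows, coords)

    def test_good_geometry_detected(self):
        m = self._donor_acceptor_model([2.9, 0, 0])  # D-H-A 180 deg
        recs = lx.detect_hbonds(m, lx.select(m, "chain A and name N"),
                                lx.select(m, "chain B"))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.9)
        assert recs[0].angle == pytest.approx(180.0)

    def test_long_distance_rejected(self):
        m = self._donor_acceptor_model([3.6, 0, 0])
        assert lx.detect_hbonds(m, lx.select(m, "chain A and name N"),
                                lx.select(m, "chain B")) == []

    def test_bent_angle_rejected(self):
        # D-A 3.0 Å but D-H-A = 90°
        m = self._donor_acceptor_model([1.0, np.sqrt(9.0 - 1.0), 0])
        assert lx.detect_hbonds(m, lx.select(m, "chain A and name N"),
                                lx.select(m, "chain B")) == []

    def test_hydrogen_free_distance_criterion(self):
        m = self._donor_acceptor_model([3.0, 0, 0], with_h=False)
        recs = lx.detect_hbonds(m, lx.select(m, "chain A and name N"),
                                lx.select(m, "chain B"))
        assert len(recs) == 1 and recs[0].hydrogen is None
        m2 = self._donor_acceptor_model([3.4, 0, 0], with_h=False)
        assert lx.detect_hbonds(m2, lx.select(m2, "chain A and name N"),
                                lx.select(m2, "chain B")) == []

    def test_non_polar_donor_named_in_error(self):
        m = _two_residue_model(3.0)  # carbon atoms only
        with pytest.raises(GeometryError, match="A:1:CA"):
            lx.detect_hbonds(m, lx.select(m, "chain A"),
                             lx.select(m, "chain B"))

    def test_subset_of_contact_map_on_polar_atoms(self, rng):
        rows, coords = [], []
        for c, names in (("A", ("N", "O")), ("B", ("O", "N"))):
            for r in range(1, 5):
                for name in names:
                    rows.append((c, r, name, name, "GLY"))
                    coords.append(rng.uniform(-4, 4, size=3))
        m = _model(rows, coords)
        a, b = _sets(m, "chain A", "chain B")
        d_cut = 3.2  # hydrogen-free criterion
        hb_pairs = {(m.residue_key(r.donor), m.residue_key(r.acceptor))
                    for r in lx.detect_hbonds(m, a, b)}
        contact_pairs = {(r.residue_a, r.residue_b)
                         for r in lx.contact_map(m, a, b, cutoff=d_cut)}
        assert hb_pairs <= contact_pairs


class TestHBondReorganization:
    def _scripted_traj(self, gain=True):
        rows = [("A", 1, "N", "N", "SER"), ("M", 1, "O3", "O", "DPC")]
        near = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        far = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        m = _model(rows, near if not gain else far)
        first, second = (far, near) if gain else (near, far)
        frames = [first] * 10 + [second] * 10
        return m, lx.Trajectory(model=m, frames=np.asarray(frames),
                                times=np.arange(20, dtype=float))

    def test_gained_bond_scores_plus_one(self):
        m, traj = self._scripted_traj(gain=True)
        df = lx.hbond_reorganization(traj, lx.select(m, "chain A"),
                                     lx.select(m, "chain M"))
        assert len(df) == 1
        assert df.iloc[0].delta == pytest.approx(1.0)

    def test_lost_bond_scores_minus_one(self):
        m, traj = self._scripted_traj(gain=False)
        df = lx.hbond_reorganization(traj, lx.select(m, "chain A"),
                                     lx.select(m, "chain M"))
        assert df.iloc[0].delta == pytest.approx(-1.0)

    def test_static_trajectory_has_zero_deltas(self):
        m, _ = self._scripted_traj()
        frames = [m.coordinates] * 10
        traj = lx.Trajectory(model=m, frames=np.asarray(frames),
                             times=np.arange(10, dtype=float))
        df = lx.hbond_reorganization(traj, lx.select(m, "chain A"),
                                     lx.select(m, "chain M"))
        assert (df.delta == 0).all() if len(df) else True

    def test_overlapping_windows_rejected(self):
        m, traj = self._scripted_traj()
        with pytest.raises(ConfigurationError):
            lx.hbond_reorganization(traj, lx.select(m, "chain A"),
                                    lx.select(m, "chain M"),
                                    initial_window=0.6, final_window=0.6)
        with pytest.raises(ConfigurationError):
            lx.hbond_reorganization(traj, lx.select(m, "chain A"),
                                    lx.select(m, "chain M"),
                                    initial_window=0.0)

    def test_generator_scripted_gains_recovered(self, toy_model,
                                                membrane_run):
        traj, labels = membrane_run
        df = lx.hbond_reorganization(traj, lx.select(toy_model, "chain B"),
                                     lx.select(toy_model, "chain M"))
        gained = {int(r.resid) for r in df.itertuples() if r.delta > 0.5}
        assert {37, 38, 40} <= gained  # the scripted onset residues
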