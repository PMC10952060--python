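"""Interface contact statistics and lipid-protein hydrogen-bond turnover.

A "contact" between two residues is a minimum heavy-atom distance at or
below a cutoff (default 4.5 Å). Contact frequencies over a trajectory
are reported both as raw fractions of frames and normalized by the most
frequent pair, matching how interfacial contact distributions are
usually plotted.

Hydrogen bonds use the standard geometric criterion: donor-acceptor
distance <= 3.5 Å and donor-H-acceptor angle >= 140° when hydrogens are
present; on hydrogen-free (coarse) models a tighter distance-only
criterion of 3.2 Å is applied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, GeometryError
from .structure_io import AtomIndexSet, StructureModel, Trajectory

__all__ = [
    "ContactRecord", "ContactFrequencyTable", "HBondRecord",
    "contact_map", "contact_frequency", "detect_hbonds",
    "hbond_reorganization",
]

ResidueKey = tuple[str, int, str]  # (chain, resid, resname)


@dataclass(frozen=True)
class ContactRecord:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float


@dataclass
class ContactFrequencyTable:
    """Per-residue-pair contact counts over a trajectory.

    ``frequency`` is raw_count / n_frames; ``normalized`` is
    raw_count / max(raw_count) so the most frequent pair reads 1.0
    (stated in ``metadata``).
    """

    table: pd.DataFrame
    n_frames: int
    cutoff: float
    metadata: dict

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.nlargest(k, "raw_count", keep="first")


@dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float | None


def _heavy(model: StructureModel, index_set: AtomIndexSet) -> np.ndarray:
    idx = index_set.indices
    els = model.elements[idx]
    return idx[np.array([str(e).upper() != "H" for e in els])]


def _check_disjoint(set_a: AtomIndexSet, set_b: AtomIndexSet):
    if len(set_a) == 0 or len(set_b) == 0:
        raise GeometryError("contact sets must be non-empty")
    if np.intersect1d(set_a.indices, set_b.indices).size:
        raise GeometryError("contact sets overlap")


def _residue_pair_min_distances(model: StructureModel, coords: np.ndarray,
                                idx_a: np.ndarray, idx_b: np.ndarray,
                                cutoff: float) -> dict:
    """Min heavy-atom distance per residue pair, within cutoff."""
    pairs: dict[tuple[ResidueKey, ResidueKey], float] = {}
    if len(idx_a) == 0 or len(idx_b) == 0:
        return pairs
    tree_b = cKDTree(coords[idx_b])
    neighbors = tree_b.query_ball_point(coords[idx_a], cutoff)
    for ia, nb_list in zip(idx_a, neighbors):
        if not nb_list:
            continue
        key_a = model.residue_key(ia)
        d = np.linalg.norm(coords[idx_b[nb_list]] - coords[ia], axis=1)
        for j, dist in zip(nb_list, d):
            key_b = model.residue_key(idx_b[j])
            key = (key_a, key_b)
            if dist < pairs.get(key, np.inf):
                pairs[key] = float(dist)
    return pairs


def contact_map(model: StructureModel, set_a: AtomIndexSet,
                set_b: AtomIndexSet, cutoff: float = 4.5, *,
                coords: np.ndarray | None = None) -> list[ContactRecord]:
    """Residue pairs of set_a × set_b in contact in one frame.

    One record per residue pair whose minimum heavy-atom distance is at
    or below ``cutoff``, ordered by (chain_a, resid_a, chain_b, resid_b).
    """
    _check_disjoint(set_a, set_b)
    if coords is None:
        coords = model.coordinates
    pairs = _residue_pair_min_distances(
        model, coords, _heavy(model, set_a), _heavy(model, set_b), cutoff)
    records = [ContactRecord(a, b, d) for (a, b), d in pairs.items()]
    records.sort(key=lambda r: (r.residue_a[0], r.residue_a[1],
                                r.residue_b[0], r.residue_b[1]))
    return records


def contact_frequency(traj: Trajectory, set_a: AtomIndexSet,
                      set_b: AtomIndexSet, cutoff: float = 4.5
                      ) -> ContactFrequencyTable:
    """Count, per residue pair, the frames in which the pair is in contact."""
    _check_disjoint(set_a, set_b)
    model = traj.model
    idx_a = _heavy(model, set_a)
    idx_b = _heavy(model, set_b)
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for t in range(traj.n_frames):
        pairs = _residue_pair_min_distances(
            model, traj.frames[t], idx_a, idx_b, cutoff)
        for key in pairs:
            counts[key] = counts.get(key, 0) + 1
    rows = []
    max_count = max(counts.values()) if counts else 1
    for (a, b), c in counts.items():
        rows.append({
            "chain_a": a[0], "resid_a": a[1], "resname_a": a[2],
            "chain_b": b[0], "resid_b": b[1], "resname_b": b[2],
            "raw_count": c,
            "frequency": c / traj.n_frames,
            "normalized": c / max_count,
        })
    df = pd.DataFrame(rows, columns=[
        "chain_a", "resid_a", "resname_a", "chain_b", "resid_b",
        "resname_b", "raw_count", "frequency", "normalized"])
    if len(df):
        df = df.sort_values(
            ["raw_count", "chain_a", "resid_a", "chain_b", "resid_b"],
            ascending=[False, True, True, True, True]).reset_index(drop=True)
    return ContactFrequencyTable(
        table=df, n_frames=traj.n_frames, cutoff=cutoff,
        metadata={"normalization": "raw_count / max(raw_count)",
                  "criterion": f"min heavy-atom distance <= {cutoff} A"})


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _polar_indices(model: StructureModel, index_set: AtomIndexSet,
                   role: str) -> np.ndarray:
    idx = index_set.indices
    els = np.array([str(e).upper() for e in model.elements[idx]])
    bad = idx[~np.isin(els, ("N", "O"))]
    if role == "donor" and len(bad):
        names = ", ".join(
            f"{model.chains[i]}:{model.resids[i]}:{model.names[i]}"
            for i in bad[:5])
        raise GeometryError(
            f"donor set contains non-N/O atoms: {names}"
            + (" ..." if len(bad) > 5 else ""))
    return idx[np.isin(els, ("N", "O"))]


def _attached_hydrogens(model: StructureModel, coords: np.ndarray,
                        donor_idx: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens within 1.2 Å of a donor in the same residue."""
    h_idx = np.array([i for i in range(model.n_atoms)
                      if str(model.elements[i]).upper() == "H"], dtype=int)
    attached: dict[int, list[int]] = {int(d): [] for d in donor_idx}
    if len(h_idx) == 0:
        return attached
    tree = cKDTree(coords[h_idx])
    for d in donor_idx:
        for j in tree.query_ball_point(coords[d], 1.2):
            h = int(h_idx[j])
            if (model.chains[h], model.resids[h]) == (
                    model.chains[d], model.resids[d]):
                attached[int(d)].append(h)
    return attached


def detect_hbonds(model: StructureModel, donor_set: AtomIndexSet,
                  acceptor_set: AtomIndexSet, *,
                  coords: np.ndarray | None = None, d_cut: float = 3.5,
                  angle_cut: float = 140.0, d_cut_no_h: float = 3.2
                  ) -> list[HBondRecord]:
    """Geometric hydrogen-bond detection between two atom sets.

    With hydrogens in the model: donor-acceptor distance <= ``d_cut``
    and best donor-H-acceptor angle >= ``angle_cut``. Hydrogen-free
    models fall back to the distance-only criterion ``d_cut_no_h``.
    Donors must be N/O (error otherwise); non-N/O acceptors are ignored.
    """
    if coords is None:
        coords = model.coordinates
    donors = _polar_indices(model, donor_set, "donor")
    acceptors = _polar_indices(model, acceptor_set, "acceptor")
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    has_h = any(str(e).upper() == "H" for e in model.elements)
    cutoff = d_cut if has_h else d_cut_no_h
    attached = _attached_hydrogens(model, coords, donors) if has_h else {}

    tree = cKDTree(coords[acceptors])
    records: list[HBondRecord] = []
    for d in donors:
        for j in tree.query_ball_point(coords[d], cutoff):
            a = int(acceptors[j])
            if (model.chains[a], model.resids[a]) == (
                    model.chains[d], model.resids[d]):
                continue  # intra-residue pairs are not interface H-bonds
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if not has_h:
                records.append(HBondRecord(int(d), None, a, dist, None))
                continue
            best_angle, best_h = None, None
            for h in attached.get(int(d), []):
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if best_angle is None or ang > best_angle:
                    best_angle, best_h = ang, h
            if best_angle is not None and best_angle >= angle_cut:
                records.append(HBondRecord(int(d), best_h, a, dist,
                                           best_angle))
    records.sort(key=lambda r: (r.donor, r.acceptor))
    return records


def _polar_pair_set(model, coords, set_a, set_b, **kw) -> set:
    """Unordered atom pairs H-bonded in either donor/acceptor direction."""
    pairs = set()
    for d_set, a_set, flip in ((set_a, set_b, False), (set_b, set_a, True)):
        try:
            recs = detect_hbonds(model, d_set, a_set, coords=coords, **kw)
        except GeometryError:
            continue  # that side holds no valid donors
        for r in recs:
            pairs.add((r.acceptor, r.donor) if flip else (r.donor, r.acceptor))
    return {frozenset(p) for p in pairs}


def hbond_reorganization(traj: Trajectory, protein_set: AtomIndexSet,
                         lipid_set: AtomIndexSet,
                         initial_window: float = 0.1,
                         final_window: float = 0.1,
                         **hbond_kwargs) -> pd.DataFrame:
    """Per-residue change in lipid H-bond count, final vs initial stage.

    For each protein residue, the mean number of hydrogen bonds to lipid
    atoms is averaged over the first ``initial_window`` and last
    ``final_window`` fractions of frames; ``delta`` = final - initial,
    so a positive delta means bonds gained during the run. Donor and
    acceptor roles are considered in both directions; each atom pair
    counts once. Residues never bonded in either window are omitted.
    """
    if initial_window <= 0 or final_window <= 0:
        raise ConfigurationError("window fractions must be positive")
    n = traj.n_frames
    n_i = max(1, int(round(initial_window * n)))
    n_f = max(1, int(round(final_window * n)))
    if n_i + n_f > n:
        raise ConfigurationError(
            f"initial ({n_i}) and final ({n_f}) windows overlap for "
            f"{n} frames")
    model = traj.model
    polar_protein = _polar_indices(model, protein_set, "acceptor")
    lipid_lookup = set(int(i) for i in lipid_set.indices)

    def window_counts(frame_range):
        totals: dict[ResidueKey, float] = {}
        for t in frame_range:
            pairs = _polar_pair_set(model, traj.frames[t],
                                    AtomIndexSet(polar_protein, "protein"),
                                    lipid_set, **hbond_kwargs)
            for pair in pairs:
                for atom in pair:
                    if atom not in lipid_lookup:
                        key = model.residue_key(atom)
                        totals[key] = totals.get(key, 0.0) + 1.0
        return {k: v / len(frame_range) for k, v in totals.items()}

    mean_i = window_counts(range(n_i))
    mean_f = window_counts(range(n - n_f, n))
    residues = sorted(set(mean_i) | set(mean_f))
    rows = [{
        "chain": r[0], "resid": r[1], "resname": r[2],
        "mean_initial": mean_i.get(r, 0.0),
        "mean_final": mean_f.get(r, 0.0),
        "delta": mean_f.get(r, 0.0) - mean_i.get(r, 0.0),
    } for r in residues]
    return pd.DataFrame(rows, columns=[
        "chain", "resid", "resname", "mean_initial", "mean_final", "delta"])
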