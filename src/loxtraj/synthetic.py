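"""Deterministic toy complexes and two-state trajectories.

The generator emulates the structural layout of a membrane-bound
lipoxygenase/scaffold complex — three pseudo-atom domains (β-barrel,
catalytic domain, scaffold protein) beside a lipid slab of DOPC/DOPE/
SAPE beads at 50/30/20%, one substrate lipid with labelled C13/C10
carbons, and one catalytic iron — together with two-state (closed/open)
dynamics in which the domain-opening angle θ, the Fe–carbon distance
distributions, and scripted contact/H-bond patterns are *imposed by
construction*. The generator tests the analyses; it does not simulate
physics. Identical seeds give bit-identical output (numpy PCG64).

Default dynamics mirror the study conditions the analyses are meant to
recover: a +20° θ shift on membrane association (−5° on substrate
binding), Fe–C13 distances around 7.2 Å versus Fe–C10 around 9.0 Å
(0.5 Å spread), and an optionally carved catalytic-site channel of
configurable bottleneck radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import SpecError
from .structure_io import (Atom, StructureModel, Trajectory,
                           _ELEMENT_TABLE, write_structure, write_trajectory)

__all__ = [
    "ComplexSpec", "DynamicsSpec", "ScriptedContact", "ScriptedHBond",
    "TrajectoryLabels", "build_toy_complex", "simulate_two_state_trajectory",
    "sample_state_chain", "write_fixture", "membrane_preset",
    "substrate_preset", "solution_preset",
]

_EL = _ELEMENT_TABLE["elements"]


def _props(element: str):
    e = _EL[element.upper()]
    return e["mass"], e["vdw_radius"]


# Polar β-barrel residues that can gain lipid H-bonds during a run;
# numbering echoes the PLAT-domain stretches known to engage lipids
# (N19, K37-R43, E48-E52, R68-H69, K72-D74).
DEFAULT_POLAR_BARREL_RESIDUES = (
    19, 37, 38, 39, 40, 41, 42, 43, 48, 49, 50, 51, 52, 68, 69, 72, 73, 74)

# cyclic resname pattern for pseudo-residues: mostly neutral with a
# balanced sprinkling of charged residues (net 0 per period of 10)
_RESNAME_PATTERN = ("GLY", "ALA", "ASP", "GLY", "LYS",
                    "GLY", "GLU", "ALA", "ARG", "GLY")

_CATALYTIC_MARKERS = ((365, "HIS", "NE2", "N"), (540, "HIS", "NE2", "N"),
                      (544, "HIS", "NE2", "N"), (662, "ILE", "CD1", "C"))


@dataclass
class ChannelSpec:
    """A carved substrate-access channel through the catalytic cloud."""

    direction: tuple = (0.0, 0.0, 1.0)
    bottleneck: float = 1.8  # Å clearance of the constriction
    shell_radius: float = 6.0  # Å cage radius around the iron
    tube_length: float = 8.0  # Å tube beyond the cage


@dataclass
class ComplexSpec:
    """Static layout of the toy complex.

    ``domain_centroid_geometry`` places the closed-state centers of
    mass: catalytic domain at the origin, scaffold along +x, β-barrel in
    the xy-plane at ``theta_built`` degrees from the scaffold direction.
    The membrane slab lies below the protein at z = ``membrane_z``.
    """

    atoms_per_domain: tuple = (200, 1000, 150)  # barrel, catalytic, scaffold
    barrel_distance: float = 28.0
    scaffold_distance: float = 26.0
    theta_built: float = 90.0  # closed-state angle of the built geometry
    domain_sigma: tuple = (4.0, 6.0, 4.0)
    n_lipids: int = 120
    composition: tuple = (0.5, 0.3, 0.2)  # DOPC, DOPE, SAPE
    membrane_z: float = -18.0
    membrane_halfwidth: float = 35.0
    substrate: bool = True
    fe_c13_init: float = 7.2
    fe_c10_init: float = 9.0
    carved_channel: ChannelSpec | None = field(default_factory=ChannelSpec)
    polar_barrel_residues: tuple = DEFAULT_POLAR_BARREL_RESIDUES
    interface_residue: int = 112  # scaffold Pro at the interface
    seed: int = 0

    def validate(self):
        if any(n < 3 for n in self.atoms_per_domain):
            raise SpecError("each domain needs at least 3 atoms")
        if abs(sum(self.composition) - 1.0) > 1e-6:
            raise SpecError(
                f"composition fractions sum to {sum(self.composition)}, "
                "expected 1")
        if min(self.barrel_distance, self.scaffold_distance) < 1.0:
            raise SpecError("domain COMs overlap the catalytic center")


@dataclass
class ScriptedContact:
    """A residue pair whose contact state is scripted per frame.

    ``p_closed``/``p_open`` are the per-frame probabilities of being in
    contact in each conformational state (1.0/0.0 give deterministic
    state-tied contacts). Residue a stays where the builder put it;
    residue b is placed at ``contact_distance`` or ``far_distance`` from
    it.
    """

    residue_a: tuple  # (chain, resid)
    residue_b: tuple
    p_closed: float = 1.0
    p_open: float = 1.0
    contact_distance: float = 3.5
    far_distance: float = 7.0


@dataclass
class ScriptedHBond:
    """A lipid that H-bonds a barrel residue after ``onset`` of the run."""

    barrel_resid: int
    lipid_resid: int
    onset: float = 0.5  # fraction of frames after which the bond exists
    bond_distance: float = 2.6
    far_distance: float = 6.0


def _default_contacts():
    # catalytic-domain residues vs scaffold residues; X in contact ~80%
    # of frames, Y ~16%, plus one state-tied interface pair
    return [
        ScriptedContact(("C", 10), ("P", 20), p_closed=0.8, p_open=0.8),
        ScriptedContact(("C", 11), ("P", 21), p_closed=0.16, p_open=0.16),
        ScriptedContact(("C", 12), ("P", 112), p_closed=1.0, p_open=0.0),
    ]


def _default_hbonds():
    return [ScriptedHBond(37, 1, 0.5), ScriptedHBond(38, 2, 0.5),
            ScriptedHBond(40, 3, 0.5)]


@dataclass
class DynamicsSpec:
    """Two-state (closed/open) dynamics imposed on a toy complex."""

    n_frames: int = 2000
    dt: float = 0.1  # ns between frames
    theta_closed: float = 90.0
    theta_open: float = 110.0
    sigma_theta: float = 2.0
    p_closed_to_open: float = 0.05
    p_open_to_closed: float = 0.0
    start_state: str = "closed"
    fe_c13: dict = field(default_factory=lambda: {
        "closed": (7.2, 0.5), "open": (7.2, 0.5)})
    fe_c10: dict = field(default_factory=lambda: {
        "closed": (9.0, 0.5), "open": (9.0, 0.5)})
    scripted_contacts: list = field(default_factory=_default_contacts)
    scripted_hbonds: list = field(default_factory=_default_hbonds)
    positional_noise_sigma: float = 0.15
    seed: int = 0

    def validate(self):
        if self.n_frames < 2:
            raise SpecError("need at least 2 frames")
        for p in (self.p_closed_to_open, self.p_open_to_closed):
            if not 0 <= p <= 1:
                raise SpecError(f"transition probability {p} outside [0, 1]")
        for d in (self.fe_c13, self.fe_c10):
            for state, (mu, sd) in d.items():
                if sd <= 0:
                    raise SpecError(f"sd for state {state!r} must be > 0")
        if self.start_state not in ("closed", "open"):
            raise SpecError(f"unknown start state {self.start_state!r}")


@dataclass
class TrajectoryLabels:
    """Ground truth emitted alongside a synthetic trajectory."""

    states: np.ndarray  # per-frame "closed"/"open"
    contact_flags: dict  # pair key -> per-frame bool array
    hbond_flags: dict  # (barrel_resid, lipid_resid) -> per-frame bool array
    theta_targets: np.ndarray  # per-frame realized θ target (degrees)


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise SpecError("zero direction vector")
    return v / n


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def _channel_cage(channel: ChannelSpec, atom_radius: float = 1.7):
    """Cage atom positions (relative to the iron) realizing the channel.

    A spherical shell with a hole plus a tube of rings; the tube's
    on-axis clearance equals the configured bottleneck.
    """
    u = _unit(channel.direction)
    rs = channel.shell_radius
    rho = channel.bottleneck + atom_radius  # ring radius hitting the target
    spacing = 1.5  # cage lattice spacing; gaps stay below ~1 Å clearance
    # shell with an aperture slightly wider than the tube
    hole_cos = np.sqrt(max(0.0, 1 - ((rho + 1.0) / rs) ** 2))
    n_shell = int(np.ceil(4 * np.pi * rs ** 2 / spacing ** 2))
    pts = _fibonacci_sphere(n_shell) * rs
    keep = pts @ u < hole_cos * rs
    shell = pts[keep]
    # tube rings from the shell surface outward
    a = _unit(np.cross(u, [1.0, 0.0, 0.0]) if abs(u[0]) < 0.9
              else np.cross(u, [0.0, 1.0, 0.0]))
    b = np.cross(u, a)
    z0 = np.sqrt(max(rs ** 2 - rho ** 2, 0.0))
    zs = np.arange(z0, z0 + channel.tube_length + spacing / 2, spacing)
    n_ring = int(np.ceil(2 * np.pi * rho / spacing))
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    rings = [z * u + rho * (np.cos(t) * a + np.sin(t) * b)
             for z in zs for t in ang]
    cage = np.vstack([shell, np.array(rings)])
    tube_end = float(zs[-1])
    return cage, u, rho, tube_end


def _in_channel_zone(points, u, rs, rho, tube_end):
    """Mask of positions (relative to Fe) intruding on the carved channel."""
    points = np.atleast_2d(points)
    r = np.linalg.norm(points, axis=1)
    z = points @ u
    radial = np.linalg.norm(points - np.outer(z, u), axis=1)
    in_sphere = r < rs + 1.2
    in_tube = (z > 0) & (z < tube_end + 4.0) & (radial < rho + 2.2)
    return in_sphere | in_tube


def build_toy_complex(spec: ComplexSpec) -> tuple[StructureModel, dict]:
    """Build the toy complex; returns (model, manifest).

    Atom order: β-barrel (chain B), catalytic domain incl. cage, markers
    and iron (chain C), scaffold (chain P), membrane lipids (chain M),
    substrate (chain S). Identical seed → bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    th = np.radians(spec.theta_built)
    com_cat = np.zeros(3)
    com_scaffold = np.array([spec.scaffold_distance, 0.0, 0.0])
    com_barrel = spec.barrel_distance * np.array(
        [np.cos(th), np.sin(th), 0.0])

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def add(name, element, resname, resid, chain, pos, charge=0.0):
        mass, radius = _props(element) if element.upper() in _EL else (
            12.0, 1.7)
        atoms.append(Atom(serial=len(atoms) + 1, name=name, element=element,
                          residue_name=resname, residue_id=resid,
                          chain_id=chain, mass=mass, vdw_radius=radius,
                          coarse_charge=charge))
        coords.append(np.asarray(pos, dtype=float))

    def cloud(n, com, sigma, reject=None):
        out = np.empty((n, 3))
        got = 0
        while got < n:
            cand = com + rng.normal(scale=sigma, size=(n - got, 3))
            if reject is not None:
                cand = cand[~reject(cand)]
            take = len(cand)
            out[got:got + take] = cand
            got += take
        return out

    n_barrel, n_cat, n_scaffold = spec.atoms_per_domain

    # --- β-barrel (chain B): 1-atom pseudo-residues; designated polar
    # residues carry an N atom so they can donate/accept H-bonds.
    barrel_pos = cloud(n_barrel, com_barrel, spec.domain_sigma[0])
    for i in range(n_barrel):
        resid = i + 1
        if resid in spec.polar_barrel_residues:
            add("N", "N", "SER", resid, "B", barrel_pos[i])
        else:
            add("CA", "C", _RESNAME_PATTERN[i % 10], resid, "B",
                barrel_pos[i])

    # --- catalytic domain (chain C): cage first (if carved), then cloud
    channel_meta = None
    reject = None
    n_cage = 0
    if spec.carved_channel is not None:
        cage_rel, u, rho, tube_end = _channel_cage(spec.carved_channel)
        n_cage = len(cage_rel)
        if n_cage + 10 > n_cat:
            raise SpecError(
                f"catalytic domain budget {n_cat} too small for the "
                f"{n_cage}-atom channel cage")
        rs = spec.carved_channel.shell_radius

        def reject(pts):
            return _in_channel_zone(pts - com_cat, u, rs, rho, tube_end)

        channel_meta = {"direction": [float(x) for x in u],
                        "bottleneck": spec.carved_channel.bottleneck,
                        "shell_radius": rs, "tube_end": tube_end,
                        "n_cage_atoms": n_cage}
    n_cloud = n_cat - n_cage
    cat_pos = cloud(n_cloud, com_cat, spec.domain_sigma[1], reject=reject)
    marker_resids = {m[0]: m for m in _CATALYTIC_MARKERS}
    # marker directions: fixed, in the z<0 half away from the channel axis
    marker_dirs = np.array([[1, 1, -1], [-1, 1, -1], [1, -1, -1],
                            [-1, -1, -1]], dtype=float) / np.sqrt(3)
    marker_iter = iter(marker_dirs)
    for i in range(n_cloud):
        resid = i + 1
        if resid in marker_resids:
            _, resname, name, element = marker_resids[resid]
            add(name, element, resname, resid, "C",
                com_cat + 4.5 * next(marker_iter))
        else:
            add("CA", "C", _RESNAME_PATTERN[i % 10], resid, "C", cat_pos[i])
    cage_start_resid = n_cloud + 1
    if n_cage:
        for j, rel in enumerate(cage_rel):
            add("CA", "C", "GLY", cage_start_resid + j, "C", com_cat + rel)
    fe_resid = n_cat + 10
    add("FE", "FE", "FE", fe_resid, "C", com_cat)

    # --- scaffold (chain P): interface Pro faces the catalytic domain
    scaffold_pos = cloud(n_scaffold, com_scaffold, spec.domain_sigma[2])
    toward = _unit(com_cat - com_scaffold)
    for i in range(n_scaffold):
        resid = i + 1
        if resid == spec.interface_residue:
            add("CA", "C", "PRO", resid, "P", com_scaffold + 5.0 * toward)
        else:
            add("CA", "C", _RESNAME_PATTERN[i % 10], resid, "P",
                scaffold_pos[i])

    # --- membrane slab (chain M): one polar bead per lipid on a jittered
    # grid; type counts are the rounded composition, adjusted to sum.
    fracs = np.asarray(spec.composition, dtype=float)
    counts = np.round(fracs * spec.n_lipids).astype(int)
    while counts.sum() != spec.n_lipids:  # largest-remainder adjustment
        diff = spec.n_lipids - counts.sum()
        order = np.argsort(-(fracs * spec.n_lipids - counts))
        counts[order[0 if diff > 0 else -1]] += np.sign(diff)
    lipid_resnames = ["DPC"] * counts[0] + ["DPE"] * counts[1] + \
        ["SPE"] * counts[2]
    side = int(np.ceil(np.sqrt(spec.n_lipids)))
    pitch = 2 * spec.membrane_halfwidth / max(side, 1)
    for li, resname in enumerate(lipid_resnames):
        gx, gy = li % side, li // side
        pos = np.array([
            -spec.membrane_halfwidth + (gx + 0.5) * pitch,
            -spec.membrane_halfwidth + (gy + 0.5) * pitch,
            spec.membrane_z])
        pos += rng.normal(scale=0.5, size=3)
        add("O3", "O", resname, li + 1, "M", pos)

    # --- substrate SAPE (chain S): labelled hydrogen-donor carbons plus
    # a polar headgroup bead
    if spec.substrate:
        u13 = _unit([0.3, 0.25, 0.92])
        u10 = _unit([-0.35, 0.2, 0.91])
        add("C13", "C", "SPE", 1, "S", com_cat + spec.fe_c13_init * u13)
        add("C10", "C", "SPE", 1, "S", com_cat + spec.fe_c10_init * u10)
        add("O3", "O", "SPE", 1, "S",
            com_cat + (spec.fe_c13_init + 3.0) * u13)

    model = StructureModel.from_atoms(atoms, np.array(coords))
    manifest = {
        "generator": "loxtraj.synthetic.build_toy_complex",
        "version": __version__,
        "rng": "numpy PCG64",
        "seed": spec.seed,
        "n_atoms": model.n_atoms,
        "n_protein_atoms": int(sum(spec.atoms_per_domain)),
        "atoms_per_domain": list(spec.atoms_per_domain),
        "n_lipids": spec.n_lipids,
        "lipid_counts": {"DPC": int(counts[0]), "DPE": int(counts[1]),
                         "SPE": int(counts[2])},
        "composition": list(spec.composition),
        "substrate": bool(spec.substrate),
        "fe_c13_init": spec.fe_c13_init,
        "fe_c10_init": spec.fe_c10_init,
        "domain_coms": {"beta_barrel": com_barrel.tolist(),
                        "catalytic": com_cat.tolist(),
                        "scaffold": com_scaffold.tolist()},
        "theta_built": spec.theta_built,
        "channel": channel_meta,
        "chains": {"beta_barrel": "B", "catalytic": "C", "scaffold": "P",
                   "lipids": "M", "substrate": "S"},
    }
    return model, manifest


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def sample_state_chain(n_frames: int, p_closed_to_open: float,
                       p_open_to_closed: float, rng: np.random.Generator,
                       start_state: str = "closed") -> np.ndarray:
    """Two-state Markov chain over {closed, open}, one label per frame."""
    states = np.empty(n_frames, dtype=object)
    state = start_state
    for t in range(n_frames):
        states[t] = state
        p = p_closed_to_open if state == "closed" else p_open_to_closed
        if rng.random() < p:
            state = "open" if state == "closed" else "closed"
    return states


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def simulate_two_state_trajectory(model: StructureModel, dyn: DynamicsSpec
                                  ) -> tuple[Trajectory, TrajectoryLabels]:
    """Impose two-state dynamics on a toy complex.

    Per frame the conformational state follows the Markov chain; the
    β-barrel cloud is rigidly rotated about the catalytic center of mass
    (z-axis) so the realized θ equals the state's target plus
    N(0, sigma_theta); substrate C13/C10 are placed so their
    Fe-distances are draws from the state's (mean, sd); scripted contact
    and H-bond pairs are moved to their scripted distances; Gaussian
    positional noise is added to every atom.
    """
    dyn.validate()
    rng = np.random.default_rng(dyn.seed)

    chains = np.array([str(c) for c in model.chains])
    names = np.array([str(n) for n in model.names])
    barrel_idx = np.nonzero(chains == "B")[0]
    cat_idx = np.nonzero((chains == "C") & (names != "FE"))[0]
    fe_idx = np.nonzero((chains == "C") & (names == "FE"))[0]
    if len(fe_idx) != 1 or len(barrel_idx) == 0 or len(cat_idx) == 0:
        raise SpecError("model does not look like a toy complex "
                        "(expected chains B/C with one FE)")
    fe_i = int(fe_idx[0])
    masses = model.masses
    com_cat = np.average(model.coordinates[cat_idx], axis=0,
                         weights=masses[cat_idx])

    # built angle of the static geometry (mass-weighted, vertex at C)
    def com(idx):
        return np.average(model.coordinates[idx], axis=0,
                          weights=masses[idx])

    scaffold_idx = np.nonzero(chains == "P")[0]
    v_barrel = com(barrel_idx) - com_cat
    v_scaffold = com(scaffold_idx) - com_cat
    theta_built = float(np.degrees(np.arccos(np.clip(
        np.dot(v_barrel, v_scaffold)
        / (np.linalg.norm(v_barrel) * np.linalg.norm(v_scaffold)), -1, 1))))
    for target in (dyn.theta_closed, dyn.theta_open):
        if not (1.0 <= target <= 179.0):
            raise SpecError(
                f"theta target {target}° unreachable by in-plane rotation")

    states = sample_state_chain(dyn.n_frames, dyn.p_closed_to_open,
                                dyn.p_open_to_closed, rng, dyn.start_state)
    theta_targets = np.where(
        states == "closed", dyn.theta_closed, dyn.theta_open
    ).astype(float) + rng.normal(scale=dyn.sigma_theta, size=dyn.n_frames)
    theta_targets = np.clip(theta_targets, 1.0, 179.0)

    # per-frame scripted flags
    contact_flags = {}
    for sc in dyn.scripted_contacts:
        p = np.where(states == "closed", sc.p_closed, sc.p_open).astype(float)
        contact_flags[(tuple(sc.residue_a), tuple(sc.residue_b))] = \
            rng.random(dyn.n_frames) < p
    hbond_flags = {}
    for sh in dyn.scripted_hbonds:
        onset_frame = int(round(sh.onset * dyn.n_frames))
        hbond_flags[(sh.barrel_resid, sh.lipid_resid)] = \
            np.arange(dyn.n_frames) >= onset_frame

    # distance draws
    d13 = np.empty(dyn.n_frames)
    d10 = np.empty(dyn.n_frames)
    for t, st in enumerate(states):
        mu13, sd13 = dyn.fe_c13[st]
        mu10, sd10 = dyn.fe_c10[st]
        d13[t] = rng.normal(mu13, sd13)
        d10[t] = rng.normal(mu10, sd10)
    d13 = np.abs(d13)
    d10 = np.abs(d10)

    resid_arr = model.resids
    u13 = _unit([0.3, 0.25, 0.92])
    u10 = _unit([-0.35, 0.2, 0.91])
    sub_c13 = np.nonzero((chains == "S") & (names == "C13"))[0]
    sub_c10 = np.nonzero((chains == "S") & (names == "C10"))[0]
    sub_o = np.nonzero((chains == "S") & (names == "O3"))[0]

    def residue_atoms(chain, resid):
        return np.nonzero((chains == chain) & (resid_arr == resid))[0]

    # fixed displacement directions per scripted pair / H-bond
    pair_dirs = {key: _unit(rng.normal(size=3))
                 for key in contact_flags}
    hb_dirs = {key: _unit(rng.normal(size=3)) for key in hbond_flags}

    frames = np.empty((dyn.n_frames, model.n_atoms, 3))
    base = model.coordinates
    fe_pos = base[fe_i]
    for t in range(dyn.n_frames):
        frame = base.copy()
        rot = _rotation_about_z(theta_targets[t] - theta_built)
        frame[barrel_idx] = (frame[barrel_idx] - com_cat) @ rot.T + com_cat
        if len(sub_c13):
            frame[sub_c13[0]] = fe_pos + d13[t] * u13
        if len(sub_c10):
            frame[sub_c10[0]] = fe_pos + d10[t] * u10
        if len(sub_o):
            frame[sub_o[0]] = fe_pos + (d13[t] + 3.0) * u13
        for sc in dyn.scripted_contacts:
            key = (tuple(sc.residue_a), tuple(sc.residue_b))
            a_atoms = residue_atoms(*sc.residue_a)
            b_atoms = residue_atoms(*sc.residue_b)
            if len(a_atoms) == 0 or len(b_atoms) == 0:
                raise SpecError(f"scripted contact {key} names residues "
                                "missing from the model")
            dist = sc.contact_distance if contact_flags[key][t] else \
                sc.far_distance
            frame[b_atoms] = frame[a_atoms[0]] + dist * pair_dirs[key]
        for sh in dyn.scripted_hbonds:
            key = (sh.barrel_resid, sh.lipid_resid)
            b_atoms = residue_atoms("B", sh.barrel_resid)
            l_atoms = residue_atoms("M", sh.lipid_resid)
            if len(b_atoms) == 0 or len(l_atoms) == 0:
                raise SpecError(f"scripted H-bond {key} names residues "
                                "missing from the model")
            dist = sh.bond_distance if hbond_flags[key][t] else \
                sh.far_distance
            frame[l_atoms] = frame[b_atoms[0]] + dist * hb_dirs[key]
        frames[t] = frame
    frames += rng.normal(scale=dyn.positional_noise_sigma,
                         size=frames.shape)

    times = dyn.dt * np.arange(dyn.n_frames)
    # strictly increasing even at dt=0 misconfiguration
    if dyn.dt <= 0:
        times = np.arange(dyn.n_frames, dtype=float)
    traj = Trajectory(model=model, frames=frames, times=times)
    labels = TrajectoryLabels(states=states, contact_flags=contact_flags,
                              hbond_flags=hbond_flags,
                              theta_targets=theta_targets)
    return traj, labels


# ---------------------------------------------------------------------------
# Presets and fixture writing
# ---------------------------------------------------------------------------

def solution_preset(n_frames: int = 2000, seed: int = 0) -> DynamicsSpec:
    """Closed complex in solution: no opening transition."""
    return DynamicsSpec(n_frames=n_frames, p_closed_to_open=0.0, seed=seed)


def membrane_preset(n_frames: int = 2000, seed: int = 0) -> DynamicsSpec:
    """Membrane-associated complex: opens by +20° and stays open."""
    return DynamicsSpec(n_frames=n_frames, theta_closed=90.0,
                        theta_open=110.0, p_closed_to_open=0.05,
                        p_open_to_closed=0.0, seed=seed)


def substrate_preset(n_frames: int = 2000, seed: int = 0) -> DynamicsSpec:
    """Substrate-bound complex: recloses by ~5° from the open form."""
    return DynamicsSpec(n_frames=n_frames, theta_closed=110.0,
                        theta_open=105.0, p_closed_to_open=0.05,
                        p_open_to_closed=0.0, seed=seed)


def write_fixture(model: StructureModel, traj: Trajectory,
                  labels: TrajectoryLabels, manifest: dict,
                  out_dir) -> dict:
    """Write toy_complex.pdb, traj.pdb, states.tsv and manifest.json.

    Returns the paths written. Re-reading the files reproduces the
    inputs within PDB format precision (10⁻³ Å).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "structure": out / "toy_complex.pdb",
        "trajectory": out / "traj.pdb",
        "states": out / "states.tsv",
        "manifest": out / "manifest.json",
    }
    write_structure(model, paths["structure"])
    write_trajectory(traj, paths["trajectory"])
    with open(paths["states"], "w") as fh:
        fh.write("frame\ttime_ns\tstate\n")
        for t in range(traj.n_frames):
            fh.write(f"{t}\t{traj.times[t]:.6f}\t{labels.states[t]}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
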