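"""Coarse residue charges and screened-Coulomb (Debye–Hückel) potentials.

This module characterizes the *direction* of interface electrostatics
and of charge-altering point mutations (e.g. a Pro→Glu substitution at a
scaffold interface residue), not Poisson–Boltzmann magnitudes. Charges
are integer formal charges placed at side-chain charge centers; the
potential is the linearized screened Coulomb form

    φ(r) = Σ_i q_i · (l_B / |r − r_i|) · exp(−κ |r − r_i|)   [kT/e]

with Bjerrum length l_B = e² / (4π ε₀ ε_r k_B T) (≈ 7.1 Å in water at
300 K) and inverse Debye length κ from the ionic strength. Outputs carry
a ``model: DH-coarse`` tag so they are never confused with full
Poisson–Boltzmann results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import ConfigurationError, GeometryError, SingularityError
from .structure_io import AtomIndexSet, StructureModel

__all__ = [
    "ChargeSet", "PotentialSample", "bjerrum_length", "debye_kappa",
    "assign_coarse_charges", "screened_potential",
    "patch_potential_summary", "charge_mutation_delta",
]

MODEL_TAG = "DH-coarse"

# formal charge and preferred side-chain charge-center atom names
_CHARGE_SCHEME = {
    "ASP": (-1.0, ("CG", "OD1", "OD2")),
    "GLU": (-1.0, ("CD", "OE1", "OE2")),
    "LYS": (+1.0, ("NZ",)),
    "ARG": (+1.0, ("NE", "NH1", "NH2")),
}

_NEUTRAL = {
    "ALA", "ASN", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU", "MET", "PHE",
    "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # zwitterionic/neutral non-residue species common in these systems:
    # PC/PE lipid beads, the catalytic iron (handled outside the formal
    # residue-charge scheme), water
    "DPC", "DPE", "SPE", "FE", "HOH",
}


@dataclass
class ChargeSet:
    """Point charges (elementary charges) at explicit sites (Å)."""

    keys: list  # (chain, resid, resname) per entry
    charges: np.ndarray
    sites: np.ndarray
    model: str = MODEL_TAG

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.sites = np.asarray(self.sites, dtype=float).reshape(-1, 3)
        if len(self.charges) != len(self.sites) or \
                len(self.keys) != len(self.charges):
            raise GeometryError("keys, charges and sites lengths differ")
        if not (np.all(np.isfinite(self.charges))
                and np.all(np.isfinite(self.sites))):
            raise GeometryError("non-finite charges or sites")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class PotentialSample:
    """φ values (kT/e) at evaluation points, with model parameters."""

    points: np.ndarray
    phi: np.ndarray
    parameters: dict

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.phi = np.asarray(self.phi, dtype=float)
        if len(self.points) != len(self.phi):
            raise GeometryError("points and phi lengths differ")


def bjerrum_length(dielectric: float = 78.5,
                   temperature: float = 300.0) -> float:
    """Bjerrum length in Å."""
    lb_m = constants.e ** 2 / (4 * np.pi * constants.epsilon_0 * dielectric
                               * constants.k * temperature)
    return lb_m * 1e10


def debye_kappa(ionic_strength: float = 0.15, dielectric: float = 78.5,
                temperature: float = 300.0) -> float:
    """Inverse Debye screening length κ in 1/Å for a 1:1 electrolyte.

    κ² = 8π l_B n with n the number density of either ion species
    (ionic_strength in mol/L converted to Å⁻³).
    """
    if ionic_strength < 0:
        raise ConfigurationError("ionic strength must be non-negative")
    n_per_A3 = ionic_strength * constants.N_A * 1e-27
    lb = bjerrum_length(dielectric, temperature)
    return float(np.sqrt(8 * np.pi * lb * n_per_A3))


def _residue_groups(model: StructureModel):
    groups: dict[tuple[str, int], list[int]] = {}
    for i in range(model.n_atoms):
        groups.setdefault(
            (str(model.chains[i]), int(model.resids[i])), []).append(i)
    return groups


def _charge_site(model: StructureModel, atom_ids: list[int],
                 center_names: tuple[str, ...]) -> np.ndarray:
    named = [i for i in atom_ids
             if str(model.names[i]).upper() in center_names]
    pick = named if named else atom_ids
    return model.coordinates[pick].mean(axis=0)


def assign_coarse_charges(model: StructureModel, scheme: str = "residue",
                          *, resname_override: dict | None = None
                          ) -> ChargeSet:
    """Formal residue charges: Asp/Glu −1, Lys/Arg +1, His and others 0.

    Charges are placed at the side-chain charge-center atom centroid
    when those atoms exist, else at the residue centroid. Termini are
    ignored. Histidine is neutral by default (pKa ≈ 6 at physiological
    pH). Unknown residue codes warn and contribute no charge.
    ``resname_override`` maps (chain, resid) to a replacement residue
    code — the hook used for charge-only point mutations.
    """
    if scheme != "residue":
        raise ConfigurationError(f"unknown charge scheme {scheme!r}")
    override = resname_override or {}
    keys, charges, sites = [], [], []
    warned: set[str] = set()
    for (chain, resid), atom_ids in _residue_groups(model).items():
        resname = str(model.resnames[atom_ids[0]]).upper()
        resname = str(override.get((chain, resid), resname)).upper()
        entry = _CHARGE_SCHEME.get(resname)
        if entry is None:
            if resname not in _NEUTRAL and resname not in warned:
                warnings.warn(
                    f"unknown residue code {resname!r}: assigned charge 0",
                    stacklevel=2)
                warned.add(resname)
            continue
        q, center_names = entry
        keys.append((chain, resid, resname))
        charges.append(q)
        sites.append(_charge_site(model, atom_ids, center_names))
    if not keys:
        return ChargeSet(keys=[], charges=np.zeros(0),
                         sites=np.zeros((0, 3)))
    return ChargeSet(keys=keys, charges=np.array(charges),
                     sites=np.array(sites))


def screened_potential(charges: ChargeSet, points: np.ndarray,
                       dielectric: float = 78.5,
                       ionic_strength: float = 0.15,
                       temperature: float = 300.0) -> PotentialSample:
    """Debye–Hückel potential of ``charges`` at ``points``, in kT/e.

    Raises :class:`SingularityError` if any evaluation point lies within
    0.1 Å of a charge site.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    params = {"dielectric": dielectric, "ionic_strength": ionic_strength,
              "temperature": temperature, "model": MODEL_TAG}
    if len(charges.charges) == 0:
        return PotentialSample(points=pts, phi=np.zeros(len(pts)),
                               parameters=params)
    diff = pts[:, None, :] - charges.sites[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    close = np.argwhere(r < 0.1)
    if len(close):
        pairs = ", ".join(f"(point {int(i)}, charge {int(j)})"
                          for i, j in close[:5])
        raise SingularityError(
            f"evaluation points within 0.1 A of charge sites: {pairs}")
    lb = bjerrum_length(dielectric, temperature)
    kappa = debye_kappa(ionic_strength, dielectric, temperature)
    phi = np.sum(charges.charges[None, :] * lb / r * np.exp(-kappa * r),
                 axis=1)
    return PotentialSample(points=pts, phi=phi, parameters=params)


def _sphere_points(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def patch_potential_summary(model: StructureModel, residue_set: AtomIndexSet,
                            shell_radius: float = 5.0, n_points: int = 256,
                            seed: int = 0, *,
                            charges: ChargeSet | None = None,
                            dielectric: float = 78.5,
                            ionic_strength: float = 0.15,
                            temperature: float = 300.0) -> dict:
    """Potential statistics on a sampling shell around a residue patch.

    Points are sampled uniformly on a sphere of ``shell_radius`` around
    the centroid of ``residue_set``; points inside any atom's vdW sphere
    are discarded. Deterministic given ``seed``. Returns mean/min/max in
    kT/e plus the retained point count and model parameters.
    """
    if len(residue_set) == 0:
        raise GeometryError("residue set for patch summary is empty")
    if charges is None:
        charges = assign_coarse_charges(model)
    centroid = model.coordinates[residue_set.indices].mean(axis=0)
    rng = np.random.default_rng(seed)
    pts = centroid + shell_radius * _sphere_points(n_points, rng)
    from scipy.spatial import cKDTree
    tree = cKDTree(model.coordinates)
    d, i = tree.query(pts)
    keep = d > model.vdw_radii[i]
    pts = pts[keep]
    if len(pts) == 0:
        raise GeometryError(
            "all sampling points fall inside atoms; enlarge shell_radius")
    sample = screened_potential(charges, pts, dielectric, ionic_strength,
                                temperature)
    return {
        "mean": float(sample.phi.mean()),
        "min": float(sample.phi.min()),
        "max": float(sample.phi.max()),
        "n_points": int(len(pts)),
        "parameters": sample.parameters,
    }


def charge_mutation_delta(model: StructureModel, chain: str, resid: int,
                          new_residue_code: str, probe_points: np.ndarray,
                          *, dielectric: float = 78.5,
                          ionic_strength: float = 0.15,
                          temperature: float = 300.0) -> np.ndarray:
    """Δφ(point) = φ(mutant) − φ(wild type), charge-only mutation.

    Coordinates are unchanged (no side-chain repacking): only the formal
    charge assigned to residue ``(chain, resid)`` switches to that of
    ``new_residue_code``. Characterizes the electrostatic direction of a
    substitution; conformational response is out of this model's scope.
    """
    new_code = new_residue_code.upper()
    if new_code not in _CHARGE_SCHEME and new_code not in _NEUTRAL:
        raise ConfigurationError(f"unknown residue code {new_code!r}")
    groups = _residue_groups(model)
    if (str(chain), int(resid)) not in groups:
        raise ConfigurationError(
            f"residue {chain}:{resid} not found in model")
    wt = assign_coarse_charges(model)
    mut = assign_coarse_charges(
        model, resname_override={(str(chain), int(resid)): new_code})
    kw = dict(dielectric=dielectric, ionic_strength=ionic_strength,
              temperature=temperature)
    phi_wt = screened_potential(wt, probe_points, **kw).phi
    phi_mut = screened_potential(mut, probe_points, **kw).phi
    return phi_mut - phi_wt
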