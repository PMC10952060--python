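"""Structure and trajectory I/O plus atom selection.

The in-memory containers are plain numpy-backed dataclasses:

* :class:`StructureModel` — the static molecular system (atoms, coordinates,
  optional box),
* :class:`Trajectory` — ordered coordinate frames over a model,
* :class:`AtomIndexSet` — a sorted, unique set of 0-based atom positions.

Residue numbering follows the 1-based PDB convention everywhere a
``resid`` appears; atom indices are 0-based internal positions into
``StructureModel.atoms``.

File reading (PDB, multi-model PDB, DCD/XTC) is delegated to MDAnalysis;
PDB writing uses an in-house fixed-column formatter so that pseudo-atom
B-factors (tunnel clearances) and HETATM records are under direct control.
HETATM records are parsed identically to ATOM — the systems of interest
mix protein, a catalytic iron, and lipids. Alternate locations keep
altloc "A" or blank and drop the rest.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, SelectionError, ShapeError

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "AtomIndexSet",
    "read_structure",
    "read_trajectory",
    "select",
    "write_structure",
    "write_trajectory",
    "element_properties",
]

# Residue names written as ATOM records; everything else becomes HETATM.
_STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_TWO_LETTER_ELEMENTS = {"FE", "CL", "BR", "NA", "MG", "ZN", "SE", "CA"}


def element_properties() -> dict:
    """Return the packaged element table: symbol -> {mass, vdw_radius}."""
    text = resources.files("loxtraj.data").joinpath("elements.json").read_text()
    return json.loads(text)


_ELEMENT_TABLE = element_properties()


def _lookup_element(symbol: str, default_mass: float, default_radius: float):
    entry = _ELEMENT_TABLE["elements"].get(symbol.upper())
    if entry is None:
        return default_mass, default_radius
    return entry["mass"], entry["vdw_radius"]


def guess_element(name: str) -> str:
    """Guess an element symbol from a PDB atom name.

    Two-letter metals and halogens (FE, CL, NA, MG, ZN, BR, SE) are
    recognized from the first two characters; otherwise the first
    alphabetic character is used. ``CA`` as an *atom name* is an
    alpha-carbon, so the two-letter calcium match is only taken when the
    whole name is the element symbol.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        return ""
    if stripped in _TWO_LETTER_ELEMENTS and stripped != "CA":
        return stripped
    if stripped == "CA":
        return "C"  # alpha carbon by convention
    if stripped[:2] in _TWO_LETTER_ELEMENTS - {"CA"}:
        return stripped[:2]
    return stripped[0]


@dataclass(frozen=True)
class Atom:
    """A single atom record (metadata only; coordinates live in the model)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    mass: float
    vdw_radius: float
    coarse_charge: float = 0.0


@dataclass
class StructureModel:
    """A static molecular system stored as parallel numpy arrays.

    ``(chain_id, residue_id, name)`` is unique per atom; validated on
    construction via :meth:`validate`.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    masses: np.ndarray
    vdw_radii: np.ndarray
    coordinates: np.ndarray
    charges: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.chains = np.asarray(self.chains, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.charges is None:
            self.charges = np.zeros(len(self.names), dtype=float)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
        self.validate()

    def validate(self):
        n = len(self.names)
        if n == 0:
            raise FormatError("structure has zero atoms")
        for arr, label in [
            (self.elements, "elements"), (self.resnames, "resnames"),
            (self.resids, "resids"), (self.chains, "chains"),
            (self.masses, "masses"), (self.vdw_radii, "vdw_radii"),
            (self.charges, "charges"),
        ]:
            if len(arr) != n:
                raise ShapeError(f"{label} has length {len(arr)}, expected {n}")
        if self.coordinates.shape != (n, 3):
            raise ShapeError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"atom count {n}")
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("non-finite coordinates")
        if np.any(self.masses <= 0) or np.any(self.vdw_radii <= 0):
            raise FormatError("masses and vdW radii must be positive")
        keys = list(zip(self.chains, self.resids, self.names))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise FormatError(
                f"duplicate atom key (chain={dup[0]!r}, resid={dup[1]}, "
                f"name={dup[2]!r})")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=i + 1, name=str(self.names[i]), element=str(self.elements[i]),
            residue_name=str(self.resnames[i]), residue_id=int(self.resids[i]),
            chain_id=str(self.chains[i]), mass=float(self.masses[i]),
            vdw_radius=float(self.vdw_radii[i]),
            coarse_charge=float(self.charges[i]))

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def residue_key(self, i: int) -> tuple[str, int, str]:
        """(chain, resid, resname) of the residue owning atom ``i``."""
        return (str(self.chains[i]), int(self.resids[i]), str(self.resnames[i]))

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], coordinates, box=None
                   ) -> "StructureModel":
        return cls(
            names=[a.name for a in atoms],
            elements=[a.element for a in atoms],
            resnames=[a.residue_name for a in atoms],
            resids=[a.residue_id for a in atoms],
            chains=[a.chain_id for a in atoms],
            masses=[a.mass for a in atoms],
            vdw_radii=[a.vdw_radius for a in atoms],
            coordinates=coordinates,
            charges=[a.coarse_charge for a in atoms],
            box=None if box is None else np.asarray(box, dtype=float),
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames (T, N, 3) over a :class:`StructureModel`.

    Times are strictly increasing; units are whatever the source file
    declares (the synthetic generator writes ns).
    """

    model: StructureModel
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeError(f"frames must be (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ShapeError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.model.n_atoms:
            raise ShapeError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"model atom count {self.model.n_atoms}")
        if len(self.times) != self.frames.shape[0]:
            raise ShapeError("times length does not match frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ShapeError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class AtomIndexSet:
    """Sorted unique 0-based atom positions with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)

    def validate_against(self, model: StructureModel) -> "AtomIndexSet":
        if len(self.indices) and (
                self.indices[0] < 0 or self.indices[-1] >= model.n_atoms):
            raise SelectionError(
                f"index set {self.label!r} out of range [0, {model.n_atoms})")
        return self

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# Reading (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _universe_arrays(u, default_mass: float, default_radius: float):
    """Extract metadata arrays from an MDAnalysis Universe, filling gaps."""
    ag = u.atoms
    n = len(ag)

    def attr(name, fallback):
        try:
            return [str(v) for v in getattr(ag, name)]
        except Exception:
            return [fallback] * n

    names = attr("names", "X")
    resnames = attr("resnames", "UNK")
    try:
        resids = [int(r) for r in ag.resids]
    except Exception:
        resids = list(range(1, n + 1))
    chains = attr("chainIDs", "")
    if all(c in ("", " ") for c in chains):
        chains = attr("segids", "A")
    chains = [(c.strip() or "A")[0] for c in chains]
    try:
        elements = [str(e).upper() for e in ag.elements]
    except Exception:
        elements = [guess_element(nm) for nm in names]
    elements = [e if e else guess_element(nm) for e, nm in zip(elements, names)]
    try:
        altlocs = [str(a).strip() for a in ag.altLocs]
    except Exception:
        altlocs = [""] * n
    return names, resnames, resids, chains, elements, altlocs


def read_structure(path, format: str = "pdb", *, default_mass: float = 12.0,
                   default_radius: float = 1.7) -> StructureModel:
    """Read a structure file into a :class:`StructureModel`.

    Masses and vdW radii are filled from the packaged element table;
    unknown elements fall back to ``default_mass`` / ``default_radius``.
    Only altloc "A" or blank atoms are kept.
    """
    import MDAnalysis as mda

    path = Path(path)
    if format.lower() != "pdb":
        raise FormatError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise IOError(f"cannot read structure file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except OSError:
        raise
    except Exception as exc:  # malformed content
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc

    if len(u.atoms) == 0:
        raise FormatError(f"{path} contains zero atoms")

    names, resnames, resids, chains, elements, altlocs = _universe_arrays(
        u, default_mass, default_radius)
    keep = [i for i, a in enumerate(altlocs) if a in ("", "A")]
    coords = u.atoms.positions.astype(float)[keep]

    masses, radii = [], []
    for i in keep:
        m, r = _lookup_element(elements[i], default_mass, default_radius)
        masses.append(m)
        radii.append(r)

    box = None
    if u.dimensions is not None and np.any(np.asarray(u.dimensions)[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float)

    return StructureModel(
        names=[names[i] for i in keep],
        elements=[elements[i] for i in keep],
        resnames=[resnames[i] for i in keep],
        resids=[resids[i] for i in keep],
        chains=[chains[i] for i in keep],
        masses=masses, vdw_radii=radii, coordinates=coords, box=box)


def read_trajectory(path, model: StructureModel) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) over ``model``.

    Frame times are taken from the file when strictly increasing and
    finite, otherwise synthesized as 0, 1, 2, ... frame units.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read trajectory file: {path}")
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix in (".pdb", ".ent"):
            u = mda.Universe(str(path))
        else:
            u = mda.Universe.empty(model.n_atoms, trajectory=True)
            try:
                u.load_new(str(path))
            except (ValueError, OSError) as exc:
                raise ShapeError(
                    f"trajectory {path} does not match model with "
                    f"{model.n_atoms} atoms: {exc}") from exc
        if len(u.atoms) != model.n_atoms:
            raise ShapeError(
                f"trajectory atom count {len(u.atoms)} does not match model "
                f"atom count {model.n_atoms}")
        frames, times = [], []
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) if ts.time is not None else np.nan)
    frames = np.asarray(frames)
    times = np.asarray(times, dtype=float)
    if (not np.all(np.isfinite(times))) or np.any(np.diff(times) <= 0):
        times = np.arange(len(frames), dtype=float)
    return Trajectory(model=model, frames=frames, times=times)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
# expr    := term { "or" term }
# term    := factor { "and" factor }
# factor  := "not" factor | "(" expr ")" | field value
# field   := chain | resid | resname | name | element
# value   := token, or lo:hi range for resid

_FIELDS = ("chain", "resid", "resname", "name", "element")
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    def __init__(self, expression: str, model: StructureModel):
        self.expr = expression
        self.model = model
        self.tokens = [(m.group(0), m.start()) for m in
                       _TOKEN_RE.finditer(expression)]
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression", 0)
        mask = self.expr_rule()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def expr_rule(self):
        mask = self.term_rule()
        while self.peek()[0] is not None and self.peek()[0].lower() == "or":
            self.next()
            mask = mask | self.term_rule()
        return mask

    def term_rule(self):
        mask = self.factor_rule()
        while self.peek()[0] is not None and self.peek()[0].lower() == "and":
            self.next()
            mask = mask & self.factor_rule()
        return mask

    def factor_rule(self):
        tok, at = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", at)
        low = tok.lower()
        if low == "not":
            self.next()
            return ~self.factor_rule()
        if tok == "(":
            self.next()
            mask = self.expr_rule()
            tok2, at2 = self.next()
            if tok2 != ")":
                raise SelectionError("expected ')'", at2)
            return mask
        if low in _FIELDS:
            self.next()
            val, vat = self.next()
            if val is None or val in ("(", ")") or val.lower() in (
                    "and", "or", "not"):
                raise SelectionError(f"field {tok!r} needs a value", vat)
            return self.match(low, val, vat)
        raise SelectionError(f"unknown token {tok!r}", at)

    def match(self, fieldname: str, value: str, at: int) -> np.ndarray:
        m = self.model
        if fieldname == "resid":
            if ":" in value:
                lo_s, _, hi_s = value.partition(":")
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError:
                    raise SelectionError(f"bad resid range {value!r}", at)
                return (m.resids >= lo) & (m.resids <= hi)
            try:
                rid = int(value)
            except ValueError:
                raise SelectionError(f"bad resid {value!r}", at)
            return m.resids == rid
        val = value.upper()
        if fieldname == "chain":
            return np.array([str(c).upper() == val for c in m.chains])
        if fieldname == "resname":
            return np.array([str(r).upper() == val for r in m.resnames])
        if fieldname == "name":
            return np.array([str(n).upper() == val for n in m.names])
        if fieldname == "element":
            return np.array([str(e).upper() == val for e in m.elements])
        raise SelectionError(f"unknown field {fieldname!r}", at)


def select(model: StructureModel, expression: str) -> AtomIndexSet:
    """Resolve a selection expression into an :class:`AtomIndexSet`.

    Grammar: fields ``chain/resid/resname/name/element``, resid ranges
    (``resid 37:43``, inclusive), boolean ``and/or/not``, parentheses.
    An empty result is valid; syntax errors raise :class:`SelectionError`
    with the offending character position.
    """
    mask = _Parser(expression, model).parse()
    return AtomIndexSet(indices=np.nonzero(mask)[0], label=expression)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(record: str, serial: int, name: str, resname: str,
                   chain: str, resid: int, xyz, occupancy: float,
                   bfactor: float, element: str) -> str:
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = name[:4]
    return (f"{record:<6s}{min(serial, 99999):>5d} {name_field}"
            f" {resname[:3]:>3s} {chain[:1]:1s}{resid:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occupancy:6.2f}{bfactor:6.2f}          {element[:2]:>2s}\n")


def _write_model_atoms(fh, model: StructureModel, coords, bfactors):
    for i in range(model.n_atoms):
        resname = str(model.resnames[i])
        record = "ATOM" if resname.upper() in _STANDARD_RESNAMES else "HETATM"
        fh.write(_pdb_atom_line(
            record, i + 1, str(model.names[i]), resname,
            str(model.chains[i]), int(model.resids[i]), coords[i],
            1.00, float(bfactors[i]) if bfactors is not None else 0.0,
            str(model.elements[i])))


def write_structure(model: StructureModel, path, format: str = "pdb", *,
                    bfactors=None) -> None:
    """Write ``model`` as a PDB file (fixed columns, 10^-3 A precision)."""
    if format.lower() != "pdb":
        raise FormatError(f"unsupported structure format {format!r}")
    path = Path(path)
    try:
        with open(path, "w") as fh:
            if model.box is not None:
                b = model.box
                fh.write(f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                         f"  90.00  90.00  90.00 P 1           1\n")
            _write_model_atoms(fh, model, model.coordinates, bfactors)
            fh.write("END\n")
    except OSError as exc:
        raise IOError(f"cannot write structure to {path}: {exc}") from exc


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    path = Path(path)
    model = traj.model
    try:
        with open(path, "w") as fh:
            for t in range(traj.n_frames):
                fh.write(f"MODEL     {t + 1:>4d}\n")
                _write_model_atoms(fh, model, traj.frames[t], None)
                fh.write("ENDMDL\n")
            fh.write("END\n")
    except OSError as exc:
        raise IOError(f"cannot write trajectory to {path}: {exc}") from exc
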