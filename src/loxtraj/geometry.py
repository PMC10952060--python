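"""Superposition, RMSD triage, and the domain-opening order parameter.

The opening angle θ quantifies exposure of the lipoxygenase catalytic
site within the 15LOX-1/PEBP1 complex: it is the angle at the catalytic
domain's center of mass between the directions to the β-barrel (PLAT)
center of mass and the scaffold-protein (PEBP1) center of mass. Because
θ is built purely from internal mass centers it is invariant under any
global rigid motion of a frame, so no superposition is applied before
measuring it.

RMSD-based triage mirrors the stability screening used to discard
implausible complex models: a trajectory whose trailing-window median
Cα RMSD stays in the few-Å band is "stable"; one whose median reaches
several times that band is "unstable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, GeometryError
from .structure_io import AtomIndexSet, StructureModel, Trajectory

__all__ = [
    "DomainPartition", "AngleSeries", "RmsdSeries", "StabilityLabel",
    "center_of_mass", "kabsch_superpose", "rmsd_series",
    "classify_stability", "opening_angle_series", "angle_shift",
    "state_conditional_shift",
]


@dataclass
class DomainPartition:
    """Named atom index sets for the three bodies defining θ, plus extras.

    ``beta_barrel``, ``catalytic_domain`` and ``scaffold`` must be
    pairwise disjoint and non-empty. Optional marks: catalytic iron,
    substrate carbons C13/C10, and the lipid slab.
    """

    beta_barrel: AtomIndexSet
    catalytic_domain: AtomIndexSet
    scaffold: AtomIndexSet
    fe: AtomIndexSet | None = None
    substrate_c13: AtomIndexSet | None = None
    substrate_c10: AtomIndexSet | None = None
    lipids: AtomIndexSet | None = None

    def __post_init__(self):
        bodies = {"beta_barrel": self.beta_barrel,
                  "catalytic_domain": self.catalytic_domain,
                  "scaffold": self.scaffold}
        for label, s in bodies.items():
            if len(s) == 0:
                raise GeometryError(f"partition body {label!r} is empty")
        names = list(bodies)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.intersect1d(bodies[a].indices, bodies[b].indices).size:
                    raise GeometryError(
                        f"partition bodies {a!r} and {b!r} overlap")


@dataclass
class AngleSeries:
    """Per-frame opening angle θ in degrees, within [0, 180]."""

    times: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.times) != len(self.theta):
            raise GeometryError("times and theta lengths differ")
        if np.any(self.theta < 0) or np.any(self.theta > 180):
            raise GeometryError("theta values outside [0, 180] degrees")


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) to a reference frame after superposition."""

    times: np.ndarray
    rmsd: np.ndarray
    reference_frame: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if len(self.times) != len(self.rmsd):
            raise GeometryError("times and rmsd lengths differ")


@dataclass(frozen=True)
class StabilityLabel:
    """Triage verdict from the trailing-window median RMSD."""

    label: str  # stable | intermediate | unstable
    median_rmsd: float
    window: tuple[int, int]  # [start, end) frame range used


def center_of_mass(coordinates: np.ndarray, index_set: AtomIndexSet,
                   masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of the atoms in ``index_set``."""
    idx = index_set.indices
    if len(idx) == 0:
        raise GeometryError(f"empty atom set {index_set.label!r} has no "
                            "center of mass")
    w = np.asarray(masses, dtype=float)[idx]
    return np.average(np.asarray(coordinates, dtype=float)[idx], axis=0,
                      weights=w)


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD.
    The rotation is proper (det +1). Requires at least 3 non-collinear
    points.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError(
            f"point sets must share an (M, 3) shape, got {ref.shape} and "
            f"{mob.shape}")
    m = ref.shape[0]
    if m < 3:
        raise GeometryError(f"need >= 3 points for superposition, got {m}")
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
    com_ref = np.average(ref, axis=0, weights=w)
    com_mob = np.average(mob, axis=0, weights=w)
    ref_c = ref - com_ref
    mob_c = mob - com_mob
    sv = np.linalg.svd(ref_c * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("reference points are (nearly) collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c, weights=w)
    matrix = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(w.sum())
    translation = com_ref - matrix @ com_mob
    return matrix, translation, rmsd


def rmsd_series(traj: Trajectory, index_set: AtomIndexSet,
                reference_frame: int = 0,
                weights: np.ndarray | None = None) -> RmsdSeries:
    """RMSD of every frame to ``reference_frame`` over ``index_set``.

    Each frame is optimally superposed onto the reference over the set
    before the RMSD is taken (unweighted by default).
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(
            f"reference frame {reference_frame} outside [0, {traj.n_frames})")
    idx = index_set.indices
    if len(idx) == 0:
        raise GeometryError(f"empty atom set {index_set.label!r}")
    ref = traj.frames[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        if t == reference_frame:
            out[t] = 0.0
            continue
        _, _, out[t] = kabsch_superpose(ref, traj.frames[t][idx], weights)
    return RmsdSeries(times=traj.times, rmsd=out,
                      reference_frame=reference_frame)


def classify_stability(series: RmsdSeries, stable_cut: float = 4.5,
                       unstable_factor: float = 3.0,
                       window_fraction: float = 0.5) -> StabilityLabel:
    """Label a trajectory stable/intermediate/unstable from its RMSD tail.

    The median RMSD over the trailing ``window_fraction`` of frames is
    compared with ``stable_cut`` (stable if at or below) and
    ``unstable_factor * stable_cut`` (unstable if at or above);
    everything between is intermediate. Defaults encode a few-Å stable
    band and a "several times higher" instability signature.
    """
    n = len(series.rmsd)
    if n == 0:
        raise GeometryError("empty RMSD series")
    if not (0 < window_fraction <= 1):
        raise ConfigurationError(
            f"window_fraction must be in (0, 1], got {window_fraction}")
    start = n - max(1, int(round(window_fraction * n)))
    window = series.rmsd[start:]
    med = float(np.median(window))
    if med <= stable_cut:
        label = "stable"
    elif med >= unstable_factor * stable_cut:
        label = "unstable"
    else:
        label = "intermediate"
    return StabilityLabel(label=label, median_rmsd=med, window=(start, n))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at vertex b between b->a and b->c, degrees; vectorized."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-6) or np.any(nv < 1e-6):
        raise GeometryError("coincident centers of mass (distance < 1e-6 A)")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def opening_angle_series(traj: Trajectory, partition: DomainPartition,
                         *, mass_weighted: bool = True,
                         vertex: str = "catalytic_domain") -> AngleSeries:
    """Per-frame opening angle θ of the three-body partition.

    θ is the angle at the center of mass of ``vertex`` (default the
    catalytic domain) between the directions to the other two body
    centers. Centers are mass-weighted unless ``mass_weighted=False``
    (geometric centers). θ is rigid-motion invariant, so frames are used
    as-is.
    """
    bodies = {"beta_barrel": partition.beta_barrel,
              "catalytic_domain": partition.catalytic_domain,
              "scaffold": partition.scaffold}
    if vertex not in bodies:
        raise ConfigurationError(f"unknown vertex body {vertex!r}")
    order = [k for k in ("beta_barrel", "catalytic_domain", "scaffold")
             if k != vertex]
    masses = traj.model.masses if mass_weighted else np.ones(
        traj.model.n_atoms)

    def coms(index_set):
        idx = index_set.indices
        w = masses[idx]
        return np.einsum("tnd,n->td", traj.frames[:, idx, :], w) / w.sum()

    a = coms(bodies[order[0]])
    b = coms(bodies[vertex])
    c = coms(bodies[order[1]])
    return AngleSeries(times=traj.times, theta=_angle_deg(a, b, c))


def _trailing_mean(series: AngleSeries, window_fraction: float) -> float:
    n = len(series.theta)
    if n == 0:
        raise GeometryError("empty angle series")
    if not (0 < window_fraction <= 1):
        raise ConfigurationError(
            f"window_fraction must be in (0, 1], got {window_fraction}")
    k = max(1, int(round(window_fraction * n)))
    return float(np.mean(series.theta[n - k:]))


def angle_shift(series_a: AngleSeries, series_b: AngleSeries,
                window_fraction: float = 0.25) -> float:
    """Difference of trailing-window mean angles, b minus a (degrees).

    Positive values mean the second condition is more open. Comparing a
    series with itself returns exactly 0.
    """
    return (_trailing_mean(series_b, window_fraction)
            - _trailing_mean(series_a, window_fraction))


def state_conditional_shift(series: AngleSeries, states) -> float:
    """Mean θ over "open"-labelled frames minus mean over "closed" ones.

    Used for parameter recovery on synthetic trajectories where the
    ground-truth conformational state of each frame is known.
    """
    states = np.asarray([str(s) for s in states])
    if len(states) != len(series.theta):
        raise GeometryError("state labels length does not match series")
    open_mask = states == "open"
    closed_mask = states == "closed"
    if not open_mask.any() or not closed_mask.any():
        raise GeometryError("need at least one frame in each state")
    return float(series.theta[open_mask].mean()
                 - series.theta[closed_mask].mean())
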