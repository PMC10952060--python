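# Methods

This note documents the models, defaults and numerical choices behind
`loxtraj`, what the synthetic generator does and does not emulate, and
the limits of each analysis.

## The system and the order parameter

The package targets peripheral membrane complexes of the
15LOX-1/PEBP1 type: a lipoxygenase with an N-terminal β-barrel (PLAT)
domain and a C-terminal catalytic domain carrying a non-heme iron,
bound by a scaffold protein, adjacent to a PC/PE bilayer containing the
oxidizable substrate SAPE. Catalytic-site exposure is summarized by a
single opening angle θ: with A, B, C the mass centers of the β-barrel,
the catalytic domain and the scaffold, θ is the angle at vertex B
between B→A and B→C. The vertex choice (the middle of the three bodies)
reflects the geometry of the complex — the catalytic domain is the
hinge the other two bodies open around — and is configurable. Centers
are mass-weighted over all atoms of each body by default; geometric
centers are an option. Because θ is built from internal centers it is
exactly invariant under global rigid motions, so no superposition is
applied; the property is asserted to 1e-9 degrees in the tests.

Angle shifts between two conditions are reported as the difference of
trailing-window means (default last 25% of frames, positive = more
open). On synthetic data with known per-frame state labels the
state-conditional shift (mean θ over open frames minus closed frames)
is also reported; it is the sharper estimator because it does not mix
the transient.

## RMSD triage

Superposition uses the Kabsch algorithm (via
`scipy.spatial.transform.Rotation.align_vectors`); rotations are always
proper. RMSD series are computed over a configurable atom set, Cα-like
atoms by default, after per-frame superposition onto a reference frame.
Stability labels come from the median RMSD over the trailing half of
the run: stable at ≤ 4.5 Å (the upper edge of the few-Å band typical of
well-behaved complex models, plus margin), unstable at ≥ 3 × 4.5 Å
(a "several times higher" signature), intermediate between. The label
is monotone in the RMSD values by construction.

## Contacts and hydrogen bonds

A residue pair is "in contact" when its minimum heavy-atom distance is
at or below 4.5 Å — a conventional heavy-atom criterion; the cutoff is
configuration, since published contact analyses rarely print theirs.
Frequencies over a trajectory are reported raw (fraction of frames) and
normalized by the maximum raw count, so the most frequent pair reads
1.0; the normalization convention is echoed in the output metadata.

Hydrogen bonds use the standard geometric criterion: donor–acceptor
distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 140° when hydrogens are
present (hydrogens are associated to donors by a 1.2 Å same-residue
search, no bond table needed). Coarse models without hydrogens fall
back to a tighter distance-only criterion of 3.2 Å, which keeps the
false-positive rate comparable. H-bond reorganization compares the
mean per-residue bond count to lipids over the first and last 10% of
frames (window sizes configurable, overlap rejected); positive deltas
are gained bonds. Donor and acceptor roles are counted in both
directions, each atom pair once.

## Regioselectivity proxy

Lipoxygenase regiospecificity follows from which substrate carbon the
iron can abstract a hydrogen from: C13 leads to the 15-hydroperoxide,
C10 to the 12-hydroperoxide. The package reports per-frame Fe–C
distances, 0.1 Å histograms (half-open bins, counts conserved, mean =
arithmetic series mean over all frames), and the fraction of frames
with each carbon within a reactive cutoff of the iron. The default
cutoff of 7.5 Å sits just above the ~7.2 Å distance at which reactive
poses are observed. The ratio of the two fractions is an explicitly
labelled proxy ("tail-fraction proxy" in the output): it captures the
direction and strength of the C13 preference, not a calibrated product
ratio — no abstraction kinetics, no oxygen insertion stereochemistry.
A zero C10 fraction yields a flagged-infinite ratio rather than an
exception. Distances are measured to the Fe atom center.

## Tunnel detection

The structure is discretized onto a regular grid (default spacing
0.8 Å) of voxel-center clearances: min over atoms of (distance to atom
center − vdW radius), negative inside atoms. The clearance field is
exact — a k-nearest-neighbor query with a radius-spread bound, with
brute-force fallback where the bound is inconclusive. The grid covers
the atom bounding box plus a 4 Å margin, so boundary voxels are
solvent; it is aligned so the seed (the catalytic iron, excluded from
occupancy) falls exactly on a voxel center, which lets straight
channels through the seed be sampled on-axis instead of up to half a
voxel diagonal off.

The tunnel is the maximin path: among all 6-connected voxel paths from
the seed to any boundary voxel, one maximizing the minimum clearance.
It is found by widest-path (best-first) search — voxels are expanded in
decreasing order of achievable bottleneck, so the first boundary
contact is optimal; ties prefer fewer steps, then lexicographic voxel
order, making the result deterministic. Voxels below the probe radius
(default 1.4 Å, water) are not traversed; a buried seed and an
unreachable boundary raise distinct errors. Optimality is verified in
the tests against an independent threshold-connectivity search on
random grids. 6-connectivity (faces only) is used rather than 26
because diagonal steps would let paths slip through voxel corners whose
clearance the grid never sampled. A bound substrate should be excluded
from the occupancy (it occupies the very channel being measured); the
pipeline does so by default. On large systems the grid can be
restricted to atoms within a configurable radius of the seed
(14 Å in the pipeline default, which comfortably contains the toy
complex's carved channel); the discretization error of the reported
bottleneck is at most one voxel diagonal (spacing·√3).

## Coarse electrostatics

Charges are integer formal charges per residue: Asp/Glu −1 at the
side-chain carboxylate centroid, Lys/Arg +1 at the terminal-nitrogen
centroid (residue centroid when those atoms are absent, as in
pseudo-atom models), His 0 by default (pKa ≈ 6 at physiological pH;
configurable), everything else 0, termini ignored, unknown codes warn
and contribute nothing. The potential is linearized screened Coulomb
(Debye–Hückel): φ(r) = Σᵢ qᵢ (l_B/|r−rᵢ|) exp(−κ|r−rᵢ|) in kT/e, with
the Bjerrum length l_B ≈ 7.1 Å (ε 78.5, 300 K) and κ from a 1:1
electrolyte at 0.15 M by default (Debye length ≈ 7.9 Å). Patch
summaries sample points uniformly on a sphere (default 5 Å, 256 points,
seeded and deterministic) around a residue set's centroid, discarding
points inside atoms.

Point mutations are charge-only: the formal charge of one residue is
switched to that of the new residue code with coordinates untouched —
no side-chain rebuild, no conformational response. The model therefore
supports only directional statements (a Pro→Glu substitution at an
interface makes the local potential strictly more negative, by
superposition); outputs carry a `model: DH-coarse` tag so they are
never confused with Poisson–Boltzmann magnitudes, which this package
deliberately does not compute.

## The synthetic generator

The generator produces the study conditions every analysis is tested
under. The toy complex places three Gaussian pseudo-atom clouds
(defaults: 200 β-barrel, 1000 catalytic, 150 scaffold atoms; σ 4/6/4 Å)
with the catalytic center at the origin, the scaffold 26 Å along +x and
the β-barrel 28 Å away at the built (closed) angle of 90°; a lipid slab
of single polar beads lies below at z = −18 Å with DOPC/DOPE/SAPE
counts rounded from the 50/30/20 composition (largest-remainder
adjustment, exact sum); one substrate lipid carries atoms named C10 and
C13 at the configured initial iron distances (7.2 and 9.0 Å); one FE
pseudo-atom sits at the catalytic center, ringed by HIS/ILE marker
residues. An optional carved channel (default on, bottleneck 1.8 Å,
direction +z) is realized as an explicit cage — a spherical shell
around the iron with an aperture plus a tube of atom rings whose
on-axis clearance equals the configured bottleneck — with the Gaussian
cloud rejection-sampled out of the channel zone so atom counts stay
exactly as specified.

Dynamics are imposed, not simulated: a two-state Markov chain
(closed/open) drives per-frame targets; the β-barrel cloud is rigidly
rotated about the catalytic mass center so the realized θ equals the
state target plus N(0, σ_θ) noise; substrate carbons are placed so
their Fe distances are exact draws from the state's (mean, sd); and
scripted residue pairs are moved to fixed contact (3.5 Å) or
non-contact (7 Å) distances, scripted lipids to H-bonding (2.6 Å) or
distant (6 Å) positions of β-barrel residues after a configurable
onset. Gaussian positional noise (default 0.15 Å) is added to every
atom. All randomness is numpy PCG64 under a single seed; identical
seeds give bit-identical structures and trajectories.

Defaults mirror the study conditions: θ 90° → 110° on membrane
association (+20°), 110° → 105° on substrate binding (−5°), Fe–C13
7.2 Å vs Fe–C10 9.0 Å with 0.5 Å spread (the spread is a free fixture
parameter; only the means are constrained), polar β-barrel residues at
the lipid-engaging stretches 19, 37–43, 48–52, 68–69, 72–74. The
membrane preset uses an open-absorbing chain (one opening transition);
parameter-recovery tests use the same geometry on a recurrent
0.05/0.05 chain so both states are well-sampled.

What the generator does *not* emulate — and what passing tests
therefore do not show about real data: no force field, no emergent
dynamics (distances and angles are placed, not propagated), no lipid
conformational sampling, no water, no hydrogens, single-bead lipids,
pseudo-atom side chains. The generator validates that the analyses
measure what they claim on data with known ground truth; it says
nothing about sampling convergence or force-field accuracy of real
trajectories.

## Pipeline and reproducibility

The pipeline validates its configuration against the loaded model
before any stage runs: every chain-map entry and selection must resolve
to a non-empty atom set, otherwise nothing executes and no output is
written. Stages run in a fixed order (angle, stability, contacts,
H-bonds, regioselectivity, tunnel, electrostatics); a stage failure is
recorded in its report block with the reason while independent stages
still run. Reports are JSON with sorted keys and carry a provenance
block (package version, SHA-256 of the canonical configuration, seed,
input description) sufficient for exact re-execution; identical
configurations produce byte-identical reports. Default problem sizes —
2000-frame trajectories of ~1500 atoms, a 14 Å tunnel region at 0.8 Å
spacing — were chosen so a full run completes in seconds on one CPU
while keeping Monte-Carlo errors of the recovered parameters an order
of magnitude below the assertion tolerances.

## Known limitations

* PDB and one binary trajectory family (DCD/XTC via MDAnalysis) only;
  no mmCIF, no topology/bond inference.
* The selection grammar is deliberately minimal (chain / resid /
  resname / name / element, ranges, boolean algebra).
* Contact and H-bond criteria are geometric; no energies, no
  salt-bridge/π classification.
* The tunnel finder returns one maximin path; it does not rank multiple
  tunnels and its bottleneck is voxel-quantized.
* Electrostatics is linearized, coarse-charged and unpolarized —
  directional conclusions only.
* The regioselectivity ratio is a defined proxy, not a kinetic
  prediction.
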